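"""Simulation-study runners: parameter recovery, level estimation, power.

Each runner regenerates data with the study's published generator settings,
pushes it through the two-stage pipeline (stage-1 control fit, stage-2 GLM)
and returns tidy per-unit result frames plus condition summaries.  Dataset
seeds are spawned from the master seed and never reused within a study.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .backends import InferenceConfig
from .control import fit_control, posterior_experimental_params
from .differential import auroc, call_differential, true_positive_rate
from .glm import GLMSpec, fit_methylation, fit_reduced
from .simulate import (
    ControlSimConfig,
    DiffSimConfig,
    MethSimConfig,
    simulate_control,
    simulate_differential,
    simulate_methylation,
)

__all__ = [
    "run_control_study",
    "run_levels_study",
    "run_differential_study",
    "run_benchmark",
]


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _default_inference(inference: Optional[InferenceConfig]):
    return inference or InferenceConfig(backend="advi", s_draws=1000)


def run_control_study(
    scale: float = 1.0,
    seed: int = 1,
    inference: Optional[InferenceConfig] = None,
    bs_eff_values: Sequence[float] = (0.995, 0.9),
    coverages: Sequence = ((1, 3), 10),
    n_replicates: int = 20,
) -> pd.DataFrame:
    """Recovery of conversion efficiency and sequencing error from controls.

    For each (true bs_eff, coverage) condition, ``n_replicates * scale``
    control replicates (444 cytosines each) are generated and fitted
    jointly; one row per replicate reports posterior means and errors.
    """
    inference = _default_inference(inference)
    n_rep = max(1, round(n_replicates * scale))
    conditions = [(b, cov) for b in bs_eff_values for cov in coverages]
    seeds = _spawn_seeds(seed, len(conditions))
    rows = []
    for (bs, cov), s in zip(conditions, seeds):
        cfg = ControlSimConfig(bs_eff=bs, coverage=cov, n_replicates=n_rep)
        tables, truth = simulate_control(cfg, int(s))
        draws = fit_control(
            tables, inference=inference.with_seed(int(s) % (2**31))
        )
        bs_mean = draws.mean("bs_eff")
        err_mean = draws.mean("seq_err")
        cov_label = "low(1-3)" if isinstance(cov, tuple) else f"const{cov}"
        for j in range(n_rep):
            rows.append(
                {
                    "bs_eff_true": bs,
                    "coverage": cov_label,
                    "replicate": j,
                    "bs_eff_mean": float(bs_mean[j]),
                    "seq_err_mean": float(err_mean[j]),
                    "bs_eff_abs_error": float(abs(bs_mean[j] - bs)),
                }
            )
    return pd.DataFrame(rows)


def _stage1_params(dataset, inference: InferenceConfig, seed: int):
    draws = fit_control(
        dataset.control_tables, inference=inference.with_seed(seed)
    )
    return posterior_experimental_params(draws)


def run_levels_study(
    n_datasets: int = 100,
    scenarios: Sequence[str] = ("GGB", "GBB"),
    coverage: int = 12,
    seed: int = 1,
    inference: Optional[InferenceConfig] = None,
) -> pd.DataFrame:
    """Methylation-level estimation with full vs reduced models.

    Each dataset is one biological sample with three mixed-quality
    technical replicates and four cytosines at increasing methylation.
    The full model uses stage-1 parameter estimates and all replicates;
    the reduced model uses ideal parameters and only the good replicates.
    """
    inference = _default_inference(inference)
    sim_cfg = MethSimConfig(coverage=coverage)
    spec = GLMSpec.intercept_only(1)
    rows = []
    seeds = _spawn_seeds(seed, len(scenarios) * n_datasets).reshape(
        len(scenarios), n_datasets
    )
    for scen_i, scenario in enumerate(scenarios):
        for d in range(n_datasets):
            s = int(seeds[scen_i, d])
            data = simulate_methylation(sim_cfg, scenario, s)
            params = _stage1_params(data, inference, (s + 1) % (2**31))
            good_ids = [
                rid
                for rid, g in zip(
                    data.counts.replicate_ids, data.truth["good_replicate"]
                )
                if g
            ]
            reduced_counts = data.counts.restrict_replicates(good_ids)
            for k, level in enumerate(sim_cfg.theta_levels):
                level_mean = level[0] / (level[0] + level[1])
                base = {
                    "dataset": d,
                    "scenario": scenario,
                    "coverage": coverage,
                    "theta_level": level_mean,
                    "theta_true": data.truth["theta"][k],
                }
                full = fit_methylation(
                    data.counts, params, spec,
                    inference.with_seed((s + 2 + k) % (2**31)), cytosine=k,
                )
                rows.append(
                    {**base, "model": "full",
                     "theta_mean": float(full.mean("theta")[0])}
                )
                red = fit_reduced(
                    reduced_counts, spec,
                    inference.with_seed((s + 2 + k) % (2**31)), cytosine=k,
                )
                rows.append(
                    {**base, "model": "reduced",
                     "theta_mean": float(red.mean("theta")[0])}
                )
    return pd.DataFrame(rows)


def run_differential_study(
    n_positive: int = 50,
    n_negative: int = 50,
    scenario: str = "GBB",
    theta_pairs: Sequence[Tuple[float, float]] = (
        (0.2, 0.3),
        (0.2, 0.4),
        (0.2, 0.5),
    ),
    cytosines_per_dataset: int = 5,
    seed: int = 1,
    inference: Optional[InferenceConfig] = None,
    bf_cutoff: float = 3.0,
):
    """Differential-methylation power study: full vs reduced models.

    Positives are generated at each (theta_A, theta_B) pair, negatives at
    (theta_A, theta_A); per dataset the stage-1 fit is shared by its
    cytosines.  Returns ``(scores, summary)``: per-cytosine Bayes factors
    and per-condition AUROC / true-positive-rate tables (negatives shared
    across conditions).
    """
    inference = _default_inference(inference)
    theta_a = theta_pairs[0][0]
    conditions = [(a, b) for a, b in theta_pairs] + [(theta_a, theta_a)]
    n_per = {
        (a, b): (n_negative if a == b else n_positive)
        for a, b in conditions
    }
    rows = []
    master = np.random.SeedSequence(seed)
    for (a, b), sub in zip(conditions, master.spawn(len(conditions))):
        n_sets = math.ceil(n_per[(a, b)] / cytosines_per_dataset)
        seeds = sub.generate_state(2 * n_sets) % (2**31)
        produced = 0
        for e in range(n_sets):
            k = min(cytosines_per_dataset, n_per[(a, b)] - produced)
            cfg = DiffSimConfig(scenario=scenario, n_cytosines=k)
            data = simulate_differential(cfg, a, b, int(seeds[2 * e]))
            params = _stage1_params(
                data, inference, int(seeds[2 * e + 1])
            )
            full = call_differential(
                data.counts, params, data.design_table,
                inference.with_seed(int(seeds[2 * e])),
            )
            good_ids = [
                rid
                for rid, g in zip(
                    data.counts.replicate_ids, data.truth["good_replicate"]
                )
                if g
            ]
            red = call_differential(
                data.counts.restrict_replicates(good_ids),
                [], data.design_table,
                inference.with_seed(int(seeds[2 * e])),
                reduced=True,
            )
            for kk in range(k):
                rows.append(
                    {
                        "theta_a": a,
                        "theta_b": b,
                        "delta_theta": round(abs(b - a), 3),
                        "label": int(a != b),
                        "dataset": e,
                        "cytosine": kk,
                        "bf_full": full[kk].bf,
                        "bf_reduced": red[kk].bf,
                    }
                )
            produced += k
    scores = pd.DataFrame(rows)

    neg = scores[scores["label"] == 0]
    summary_rows = []
    for dt, grp in scores[scores["label"] == 1].groupby("delta_theta"):
        both = pd.concat([grp, neg], ignore_index=True)
        labels = both["label"].to_numpy()
        row = {"delta_theta": dt, "scenario": scenario}
        for model in ("full", "reduced"):
            s = both[f"bf_{model}"].to_numpy()
            row[f"auroc_{model}"] = auroc(s, labels)
            row[f"tpr_{model}"] = true_positive_rate(s, labels, bf_cutoff)
        row["auroc_gap"] = row["auroc_full"] - row["auroc_reduced"]
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows).sort_values("delta_theta")
    return scores, summary


def run_benchmark(
    study: str,
    scale: float = 1.0,
    seed: int = 1,
    inference: Optional[InferenceConfig] = None,
):
    """Dispatch a named study at a given scale factor in (0, 1]."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if study == "control":
        return run_control_study(scale=scale, seed=seed, inference=inference)
    if study == "levels":
        return run_levels_study(
            n_datasets=max(1, round(100 * scale)), seed=seed,
            inference=inference,
        )
    if study == "differential":
        scores, summary = run_differential_study(
            n_positive=max(2, round(50 * scale)),
            n_negative=max(2, round(50 * scale)),
            seed=seed,
            inference=inference,
        )
        return {"scores": scores, "summary": summary}
    raise ValueError("study must be one of control, levels, differential")
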