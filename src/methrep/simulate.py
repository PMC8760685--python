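"""Synthetic BS-seq data with ground truth.

Three generators mirror the three simulation designs used to validate the
method:

``simulate_control``
    Spike-in control counts for one or more technical replicates: trace
    methylation levels drawn from a Dirichlet over (unmethylated,
    methylated), fixed experimental parameters, binomial readout counts.
    Defaults: 444 control cytosines, conversion efficiency 0.995 or 0.9,
    sequencing error 0.001, coverage uniform on {1, 2, 3} or constant 10.

``simulate_methylation``
    One biological sample with three technical replicates of mixed library
    quality — scenario 'GGB' (two good, one bad) or 'GBB' (one good, two
    bad) — at four cytosines whose methylation levels are drawn from beta
    distributions spanning low to high methylation; paired spike-in control
    blocks share the replicate-level experimental parameters.  Good/bad
    conversion efficiencies are beta(99.5, 0.5) / beta(90, 10).

``simulate_differential``
    Two groups of four biological replicates, three technical replicates
    each; per biological replicate the cytosine's methylation level is
    drawn from its group's beta row (mean levels 0.2 ... 0.8, concentration
    1000).  Equal rows generate null (not differentially methylated) data.

All generators are deterministic given their seed, and return the full
latent ground truth alongside the count tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .control import ControlCountTable
from .glm import MethCountTable
from .model_core import ExperimentalParams, prob_c

__all__ = [
    "ControlSimConfig",
    "MethSimConfig",
    "DiffSimConfig",
    "THETA_BETA_TABLE",
    "MethDataset",
    "simulate_control",
    "simulate_methylation",
    "simulate_differential",
    "write_truth_json",
]

#: Group-level methylation beta rows (mean level -> (alpha, beta)),
#: concentration alpha + beta = 1000 throughout.
THETA_BETA_TABLE: Dict[float, Tuple[float, float]] = {
    0.2: (200.0, 800.0),
    0.3: (300.0, 700.0),
    0.4: (400.0, 600.0),
    0.5: (500.0, 500.0),
    0.6: (600.0, 400.0),
    0.7: (700.0, 300.0),
    0.8: (800.0, 200.0),
}

Coverage = Union[int, Tuple[int, int]]


def _draw_coverage(rng, rule: Coverage, size) -> np.ndarray:
    if isinstance(rule, tuple):
        lo, hi = rule
        return rng.integers(lo, hi + 1, size=size)
    return np.full(size, int(rule), dtype=np.int64)


@dataclass(frozen=True)
class ControlSimConfig:
    """Generator settings for spike-in control counts.

    ``coverage`` is a constant read depth or an inclusive uniform range per
    cytosine.  ``alpha_control`` orders the simplex (unmethylated,
    methylated).
    """

    alpha_control: Tuple[float, float] = (999.0, 1.0)
    bs_star_eff: float = 0.001
    seq_err: float = 0.001
    bs_eff: float = 0.995
    k_control: int = 444
    coverage: Coverage = 10
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.k_control < 1 or self.n_replicates < 1:
            raise ValueError("k_control and n_replicates must be >= 1")
        for name in ("bs_star_eff", "seq_err", "bs_eff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass(frozen=True)
class MethSimConfig:
    """Generator settings for the mixed-quality replicate study."""

    bs_eff_bad: Tuple[float, float] = (90.0, 10.0)
    bs_eff_good: Tuple[float, float] = (99.5, 0.5)
    seq_err_beta: Tuple[float, float] = (0.1, 99.9)
    bs_star_beta: Tuple[float, float] = (0.1, 99.9)
    coverage: int = 12
    theta_levels: Tuple[Tuple[float, float], ...] = (
        (100.0, 900.0),
        (300.0, 700.0),
        (700.0, 300.0),
        (900.0, 100.0),
    )
    control_coverage: int = 20
    control_k: int = 100
    control_alpha: Tuple[float, float] = (999.0, 1.0)

    def __post_init__(self) -> None:
        for pair in (
            self.bs_eff_bad,
            self.bs_eff_good,
            self.seq_err_beta,
            self.bs_star_beta,
            *self.theta_levels,
        ):
            if min(pair) <= 0:
                raise ValueError("beta shape parameters must be positive")


@dataclass(frozen=True)
class DiffSimConfig:
    """Generator settings for the two-group differential study.

    Coverage follows the scenario convention: 10 reads per technical
    replicate for 'GBB', 6 for 'GGB' (set explicitly to override).
    """

    scenario: str = "GBB"
    groups: int = 2
    biological_replicates_per_group: int = 4
    technical_replicates: int = 3
    coverage: Optional[int] = None
    n_cytosines: int = 1
    theta_beta_table: Tuple[Tuple[float, Tuple[float, float]], ...] = tuple(
        THETA_BETA_TABLE.items()
    )
    rep_quality: MethSimConfig = field(default_factory=MethSimConfig)

    def __post_init__(self) -> None:
        if self.scenario not in ("GGB", "GBB"):
            raise ValueError("scenario must be 'GGB' or 'GBB'")
        for _, (a, b) in self.theta_beta_table:
            if a + b != 1000.0:
                raise ValueError(
                    "theta beta rows must have concentration a + b = 1000"
                )

    @property
    def effective_coverage(self) -> int:
        if self.coverage is not None:
            return self.coverage
        return 10 if self.scenario == "GBB" else 6

    def beta_row(self, level: float) -> Tuple[float, float]:
        table = dict(self.theta_beta_table)
        if level not in table:
            raise KeyError(
                f"theta level {level} not in the configured beta table"
            )
        return table[level]


@dataclass
class MethDataset:
    """A simulated dataset bundle: counts, paired controls, truth."""

    counts: MethCountTable
    control_tables: List[ControlCountTable]
    design_table: pd.DataFrame
    truth: Dict

    @property
    def true_params(self) -> List[ExperimentalParams]:
        return [
            ExperimentalParams(**p) for p in self.truth["replicate_params"]
        ]


def _theta_meth(rng, alpha: Tuple[float, float], size) -> np.ndarray:
    """Methylated fraction of Dirichlet (unmethylated, methylated) draws."""
    a_u, a_m = alpha
    return rng.beta(a_m, a_u, size=size)


def _control_counts(
    rng, params: ExperimentalParams, k: int, coverage: Coverage,
    alpha: Tuple[float, float],
):
    t = _theta_meth(rng, alpha, k)
    n = _draw_coverage(rng, coverage, k)
    p = np.array([prob_c(tk, params) for tk in t])
    c = rng.binomial(n, p)
    return c, n, t


def simulate_control(
    config: ControlSimConfig, seed: int
) -> Tuple[List[ControlCountTable], Dict]:
    """Generate control count tables plus ground truth.

    Returns one :class:`ControlCountTable` per replicate (all sharing the
    configured fixed experimental parameters) and a truth dict recording
    seed, config and the latent per-cytosine methylation fractions.
    """
    rng = np.random.default_rng(seed)
    params = ExperimentalParams(
        bs_eff=config.bs_eff,
        seq_err=config.seq_err,
        bs_star_eff=config.bs_star_eff,
    )
    tables, thetas = [], []
    for j in range(config.n_replicates):
        c, n, t = _control_counts(
            rng, params, config.k_control, config.coverage,
            config.alpha_control,
        )
        tables.append(
            ControlCountTable(
                replicate_id=f"rep{j + 1}", c_counts=c, totals=n
            )
        )
        thetas.append(t.tolist())
    truth = {
        "seed": int(seed),
        "bs_eff": config.bs_eff,
        "seq_err": config.seq_err,
        "bs_star_eff": config.bs_star_eff,
        "theta_control": thetas,
    }
    return tables, truth


def _replicate_quality(scenario: str) -> List[bool]:
    """Good/bad pattern of one technical-replicate trio."""
    return {"GGB": [True, True, False], "GBB": [True, False, False]}[scenario]


def _draw_replicate_params(
    rng, cfg: MethSimConfig, good: bool
) -> ExperimentalParams:
    a, b = cfg.bs_eff_good if good else cfg.bs_eff_bad
    return ExperimentalParams(
        bs_eff=float(rng.beta(a, b)),
        seq_err=float(rng.beta(*cfg.seq_err_beta)),
        bs_star_eff=float(rng.beta(*cfg.bs_star_beta)),
    )


def _params_dict(p: ExperimentalParams) -> Dict[str, float]:
    return {
        "bs_eff": p.bs_eff,
        "seq_err": p.seq_err,
        "bs_star_eff": p.bs_star_eff,
    }


def simulate_methylation(
    config: MethSimConfig, scenario: str, seed: int
) -> MethDataset:
    """One biological sample, three mixed-quality technical replicates.

    Each configured theta level yields one cytosine whose level is shared
    by all replicates; counts are binomial through the replicate-specific
    observation model.  Paired control blocks are generated with the same
    replicate-level experimental parameters.
    """
    if scenario not in ("GGB", "GBB"):
        raise ValueError("scenario must be 'GGB' or 'GBB'")
    rng = np.random.default_rng(seed)
    quality = _replicate_quality(scenario)
    params = [_draw_replicate_params(rng, config, g) for g in quality]

    k = len(config.theta_levels)
    theta = np.array(
        [rng.beta(a, b) for a, b in config.theta_levels]
    )
    c = np.zeros((k, len(params)), dtype=np.int64)
    n = np.full((k, len(params)), config.coverage, dtype=np.int64)
    for j, pj in enumerate(params):
        p = np.array([prob_c(t, pj) for t in theta])
        c[:, j] = rng.binomial(n[:, j], p)

    rep_ids = [f"rep{j + 1}" for j in range(len(params))]
    counts = MethCountTable(
        chrom=np.array(["sim"] * k),
        pos=np.arange(1, k + 1),
        replicate_ids=rep_ids,
        sample_ids=("s1",),
        rep_to_sample=np.zeros(len(params), dtype=int),
        c=c,
        n=n,
    )
    controls = []
    control_theta = []
    for j, pj in enumerate(params):
        cc, cn, ct = _control_counts(
            rng, pj, config.control_k, config.control_coverage,
            config.control_alpha,
        )
        controls.append(
            ControlCountTable(replicate_id=rep_ids[j], c_counts=cc, totals=cn)
        )
        control_theta.append(ct.tolist())
    design = pd.DataFrame(
        {"replicate_id": rep_ids, "sample_id": ["s1"] * len(rep_ids)}
    )
    truth = {
        "seed": int(seed),
        "scenario": scenario,
        "good_replicate": quality,
        "replicate_params": [_params_dict(p) for p in params],
        "theta": theta.tolist(),
        "theta_levels": [list(t) for t in config.theta_levels],
        "control_theta": control_theta,
    }
    return MethDataset(
        counts=counts, control_tables=controls, design_table=design,
        truth=truth,
    )


def simulate_differential(
    config: DiffSimConfig,
    theta_a: float,
    theta_b: float,
    seed: int,
) -> MethDataset:
    """Two-group dataset for differential methylation benchmarking.

    ``theta_a`` / ``theta_b`` are mean methylation levels naming rows of
    the beta table; equal levels generate null data (label negative).  Per
    cytosine and biological replicate the methylation level is drawn from
    the group's beta row; per technical replicate the counts follow the
    replicate's own experimental parameters, drawn once per call.  Paired
    control blocks allow the stage-1 fit to be run on the same libraries.
    """
    rng = np.random.default_rng(seed)
    rows = (config.beta_row(theta_a), config.beta_row(theta_b))
    n_bio = config.biological_replicates_per_group
    n_tech = config.technical_replicates
    quality_trio = _replicate_quality(config.scenario)
    if len(quality_trio) != n_tech:
        quality_trio = (quality_trio * n_tech)[:n_tech]
    coverage = config.effective_coverage

    sample_ids, rep_ids, rep_to_sample, group_of_sample = [], [], [], []
    params, quality = [], []
    for g in range(config.groups):
        for i in range(n_bio):
            sid = f"g{g + 1}s{i + 1}"
            sample_ids.append(sid)
            group_of_sample.append(g)
            for j in range(n_tech):
                rep_ids.append(f"{sid}r{j + 1}")
                rep_to_sample.append(len(sample_ids) - 1)
                good = quality_trio[j]
                quality.append(good)
                params.append(
                    _draw_replicate_params(rng, config.rep_quality, good)
                )

    n_samples = len(sample_ids)
    k = config.n_cytosines
    theta = np.zeros((k, n_samples))
    for s in range(n_samples):
        a, b = rows[group_of_sample[s]]
        theta[:, s] = rng.beta(a, b, size=k)

    c = np.zeros((k, len(rep_ids)), dtype=np.int64)
    n = np.full((k, len(rep_ids)), coverage, dtype=np.int64)
    for j, pj in enumerate(params):
        s = rep_to_sample[j]
        p = np.array([prob_c(theta[kk, s], pj) for kk in range(k)])
        c[:, j] = rng.binomial(n[:, j], p)

    counts = MethCountTable(
        chrom=np.array(["sim"] * k),
        pos=np.arange(1, k + 1),
        replicate_ids=rep_ids,
        sample_ids=tuple(sample_ids),
        rep_to_sample=np.array(rep_to_sample),
        c=c,
        n=n,
    )
    controls = []
    for j, pj in enumerate(params):
        cc, cn, _ = _control_counts(
            rng,
            pj,
            config.rep_quality.control_k,
            config.rep_quality.control_coverage,
            config.rep_quality.control_alpha,
        )
        controls.append(
            ControlCountTable(replicate_id=rep_ids[j], c_counts=cc, totals=cn)
        )
    design = pd.DataFrame(
        {
            "replicate_id": rep_ids,
            "sample_id": [sample_ids[s] for s in rep_to_sample],
            "group": [
                float(group_of_sample[s]) for s in rep_to_sample
            ],
        }
    )
    truth = {
        "seed": int(seed),
        "scenario": config.scenario,
        "theta_a": theta_a,
        "theta_b": theta_b,
        "label_positive": bool(theta_a != theta_b),
        "coverage": coverage,
        "good_replicate": quality,
        "replicate_params": [_params_dict(p) for p in params],
        "theta": theta.tolist(),
    }
    return MethDataset(
        counts=counts, control_tables=controls, design_table=design,
        truth=truth,
    )


def write_truth_json(truth: Dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
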