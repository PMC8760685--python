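"""Stage-2 GLM: oracles, reduced-model equivalence, design handling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import invgamma

from methrep import (
    DiffSimConfig,
    ExperimentalParams,
    InferenceConfig,
    MethCountTable,
    build_design_matrix,
    estimate_theta,
    fit_methylation,
    fit_reduced,
    simulate_differential,
    simulate_methylation,
    MethSimConfig,
)
from methrep.backends import PosteriorDraws
from methrep.glm import GLMSpec, read_counts_tsv, write_counts_tsv


def single_cytosine_table(c, n):
    return MethCountTable(
        chrom=np.array(["chr1"]),
        pos=[1],
        replicate_ids=["r1"],
        sample_ids=("s1",),
        rep_to_sample=np.array([0]),
        c=np.array([[c]]),
        n=np.array([[n]]),
    )


def grid_posterior_mean_theta(c, n, sigma_b_sq=5.0, ab=(1.0, 1.0)):
    """Quadrature oracle for the intercept-only, single-sample model.

    theta = expit(d) with d = (b1 - b2) + (e1 - e2); marginally
    d | sigma_E^2 ~ N(0, 2 sigma_B^2 + 2 sigma_E^2) and sigma_E^2 is
    inverse-gamma.  Integrates the exact posterior over a (d, sigma_E^2)
    product grid with an ideal-instrument binomial likelihood.
    """
    a, b = ab
    v = invgamma.ppf(np.linspace(5e-4, 1 - 5e-4, 400), a, scale=b)
    d = np.linspace(-14, 14, 2001)
    sd = np.sqrt(2 * sigma_b_sq + 2 * v)[:, None]
    prior_d = np.exp(-0.5 * (d[None, :] / sd) ** 2) / sd
    prior_d = prior_d.mean(axis=0)  # equal-probability sigma_E^2 nodes
    theta = expit(d)
    loglik = c * np.log(theta) + (n - c) * np.log1p(-theta)
    w = prior_d * np.exp(loglik - loglik.max())
    return float(np.sum(w * theta) / np.sum(w))


@pytest.mark.parametrize("c, n, lo, hi", [(500, 1000, 0.48, 0.52),
                                          (100, 1000, 0.08, 0.12)])
def test_ideal_instrument_interval(advi_cfg, c, n, lo, hi):
    counts = single_cytosine_table(c, n)
    fit = fit_methylation(
        counts, [ExperimentalParams.ideal()], GLMSpec.intercept_only(1),
        advi_cfg.with_seed(11),
    )
    assert lo <= fit.mean("theta")[0] <= hi


@pytest.mark.parametrize("c, n", [(500, 1000), (100, 1000), (30, 50)])
def test_grid_oracle_equivalence(mcmc_cfg, c, n):
    """Sampler theta mean matches the 2-D quadrature oracle within 0.01."""
    counts = single_cytosine_table(c, n)
    fit = fit_methylation(
        counts, [ExperimentalParams.ideal()], GLMSpec.intercept_only(1),
        mcmc_cfg.with_seed(5),
    )
    oracle = grid_posterior_mean_theta(c, n)
    assert fit.mean("theta")[0] == pytest.approx(oracle, abs=0.01)


def test_no_data_posterior_equals_prior_pushforward(advi_cfg, mcmc_cfg, rng):
    """With zero counts the theta posterior is the prior push-forward."""
    counts = single_cytosine_table(0, 0)
    fit = fit_methylation(
        counts, [ExperimentalParams.ideal()], GLMSpec.intercept_only(1),
        mcmc_cfg.with_seed(2),
    )
    # simulate the prior push-forward directly
    v = invgamma.rvs(1.0, scale=1.0, size=20000, random_state=rng)
    d = rng.standard_normal(20000) * np.sqrt(10.0 + 2.0 * v)
    prior = expit(d)
    assert fit.mean("theta")[0] == pytest.approx(prior.mean(), abs=0.05)
    assert np.std(fit["theta"][:, 0]) == pytest.approx(prior.std(), rel=0.25)


def test_reduced_equals_full_with_ideal_params(advi_cfg):
    data = simulate_methylation(MethSimConfig(), "GGB", seed=31)
    ideal = [ExperimentalParams.ideal()] * 3
    cfg = advi_cfg.with_seed(9)
    full = fit_methylation(
        data.counts, ideal, GLMSpec.intercept_only(1), cfg
    )
    red = fit_reduced(data.counts, GLMSpec.intercept_only(1), cfg)
    assert np.array_equal(full["theta"], red["theta"])


def test_unconverted_bad_replicate_biases_reduced_model_up(advi_cfg):
    """Treating a poorly converted library as ideal inflates theta."""
    rng = np.random.default_rng(0)
    n = 200
    true_theta, bs_bad = 0.9, 0.85
    biases = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        # bad replicate: unconverted Cs read as methylated
        p = true_theta * 1.0 + (1 - true_theta) * (1 - bs_bad)
        c = r.binomial(n, p)
        counts = single_cytosine_table(c, n)
        fit = fit_reduced(
            counts, GLMSpec.intercept_only(1), advi_cfg.with_seed(seed)
        )
        biases.append(fit.mean("theta")[0] - true_theta)
    assert np.median(biases) > 0


def test_softmax_rows_normalised(advi_cfg):
    data = simulate_methylation(MethSimConfig(), "GBB", seed=3)
    fit = fit_methylation(
        data.counts, data.true_params, GLMSpec.intercept_only(1),
        advi_cfg.with_seed(4),
    )
    y = fit["Y"]
    soft = np.exp(y) / np.exp(y).sum(axis=2, keepdims=True)
    assert np.allclose(soft.sum(axis=2), 1.0, atol=1e-8)
    assert np.allclose(soft[:, :, 0], fit["theta"], atol=1e-12)


def test_ideal_instrument_consistency_high_coverage(advi_cfg):
    """At coverage 1000 the posterior mean approaches c/n within 0.02."""
    for theta in (0.2, 0.5, 0.8):
        c = int(round(theta * 1000))
        counts = single_cytosine_table(c, 1000)
        fit = fit_methylation(
            counts, [ExperimentalParams.ideal()], GLMSpec.intercept_only(1),
            advi_cfg.with_seed(c),
        )
        assert fit.mean("theta")[0] == pytest.approx(theta, abs=0.02)


def test_estimate_theta_summaries():
    draws = PosteriorDraws(
        arrays={"theta": np.full((100, 1), 0.7)}, backend_tag="advi", seed=0
    )
    est = estimate_theta(draws)
    assert est["mean"][0] == pytest.approx(0.7)
    assert est["high"][0] - est["low"][0] == pytest.approx(0.0)
    two = PosteriorDraws(
        arrays={"theta": np.array([[0.2], [0.4]])}, backend_tag="advi", seed=0
    )
    assert estimate_theta(two)["mean"][0] == pytest.approx(0.3)


def test_build_design_matrix_intercept_only():
    table = pd.DataFrame({"sample_id": ["a", "b", "c", "d"]})
    spec = build_design_matrix(table)
    assert spec.design.shape == (4, 1)
    assert np.all(spec.design == 1.0)
    assert spec.column_names == ("intercept",)


def test_build_design_matrix_two_groups():
    table = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(8)],
         "group": [0, 0, 0, 0, 1, 1, 1, 1]}
    )
    spec = build_design_matrix(table)
    assert spec.design.shape == (8, 2)
    assert list(spec.column_names) == ["intercept", "group"]


def test_build_design_matrix_rank_deficiency_warns():
    table = pd.DataFrame(
        {"sample_id": list("abcd"), "x": [1, 2, 3, 4], "y": [2, 4, 6, 8]}
    )
    with pytest.warns(RuntimeWarning, match="rank deficient"):
        build_design_matrix(table)


def test_group_coding_invariance_of_bf_ranking(advi_cfg):
    """0/1 vs +/-1 group coding yields the same Bayes-factor ranking."""
    from methrep.differential import call_differential

    cfg = DiffSimConfig(scenario="GBB", n_cytosines=6)
    data = simulate_differential(cfg, 0.2, 0.5, seed=17)
    logbf = []
    for coding in (None, "pm1"):
        design = data.design_table.copy()
        if coding == "pm1":
            design["group"] = 2.0 * design["group"] - 1.0
        res = call_differential(
            data.counts, data.true_params, design, advi_cfg.with_seed(13)
        )
        logbf.append(np.log10([r.bf for r in res]))
    # pairwise order must agree wherever the BFs are clearly separated
    # (near-ties may flip under Monte-Carlo noise in the density estimate)
    a, b = logbf
    for i in range(len(a)):
        for j in range(i + 1, len(a)):
            if abs(a[i] - a[j]) > 0.5 and abs(b[i] - b[j]) > 0.5:
                assert np.sign(a[i] - a[j]) == np.sign(b[i] - b[j])


def test_counts_tsv_round_trip(tmp_path):
    data = simulate_differential(DiffSimConfig(n_cytosines=3), 0.2, 0.2, 8)
    path = tmp_path / "counts.tsv"
    write_counts_tsv(data.counts, path)
    back = read_counts_tsv(path, data.design_table)
    assert np.array_equal(back.c, data.counts.c)
    assert np.array_equal(back.n, data.counts.n)
    assert back.sample_ids == data.counts.sample_ids


def test_missing_params_entry_is_contract_error(advi_cfg):
    data = simulate_methylation(MethSimConfig(), "GGB", seed=1)
    with pytest.raises(ValueError, match="ExperimentalParams"):
        fit_methylation(
            data.counts, data.true_params[:2], GLMSpec.intercept_only(1),
            advi_cfg,
        )


def test_bedgraph_round_trip(tmp_path):
    from methrep.glm import read_bedgraph, write_bedgraph

    data = simulate_differential(DiffSimConfig(n_cytosines=3), 0.2, 0.2, 4)
    write_bedgraph(data.counts, tmp_path)
    rid = data.counts.replicate_ids[0]
    track = read_bedgraph(tmp_path / f"{rid}.bedGraph")
    assert np.allclose(
        track["fraction"], data.counts.c[:, 0] / data.counts.n[:, 0]
    )
    assert np.array_equal(track["pos"], data.counts.pos)
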