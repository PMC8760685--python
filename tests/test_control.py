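"""Stage-1 control model: oracles, recovery, summaries, TSV round trips."""

import numpy as np
import pytest
from scipy.special import expit

from methrep import (
    ControlCountTable,
    ControlModelConfig,
    ControlSimConfig,
    InferenceConfig,
    PosteriorDraws,
    fit_control,
    posterior_experimental_params,
    read_control_tsv,
    simulate_control,
    write_control_tsv,
)
from methrep.control import ControlModel
from methrep.backends import run_inference
from methrep.model_core import BS_EFF_HYPER


def grid_posterior_mean_bs(table, seq_err, theta, n_grid=2001):
    """Brute-force quadrature oracle for the 1-D model reduction.

    With the hyper level fixed at its prior location and seq_err/theta
    frozen, the only latent is the standard-normal auxiliary r with
    bs_eff = expit(psi_mu_mu + exp(psi_sigma_mu) * r).  Integrates the
    exact posterior on a dense r grid.
    """
    r = np.linspace(-12.0, 12.0, n_grid)
    bs = expit(BS_EFF_HYPER.psi_mu_mu + np.exp(BS_EFF_HYPER.psi_sigma_mu) * r)
    pc = (1 - bs) * (1 - seq_err) + bs * seq_err
    p5 = (1 - 0.001) * (1 - seq_err) + 0.001 * seq_err
    p = theta * p5 + (1 - theta) * pc
    loglik = np.zeros_like(r)
    for c, n in zip(table.c_counts, table.totals):
        loglik += c * np.log(p) + (n - c) * np.log1p(-p)
    logpost = loglik - 0.5 * r**2
    w = np.exp(logpost - logpost.max())
    return float(np.sum(w * bs) / np.sum(w))


def test_grid_oracle_equivalence_one_dimensional_reduction(mcmc_cfg):
    """Sampler posterior mean equals dense-grid quadrature within 0.01."""
    table = ControlCountTable(
        replicate_id="r1",
        c_counts=np.array([0, 1, 0]),
        totals=np.array([5, 5, 5]),
    )
    seq_err, theta = 0.001, 0.001
    model = ControlModel(
        [table], fix_hyper=True, fixed_seq_err=seq_err, fixed_theta=theta
    )
    assert model.n_free == 1
    draws = run_inference(model, mcmc_cfg)
    oracle = grid_posterior_mean_bs(table, seq_err, theta)
    assert draws.mean("bs_eff")[0] == pytest.approx(oracle, abs=0.01)


def test_grid_oracle_equivalence_higher_count(mcmc_cfg):
    table = ControlCountTable(
        replicate_id="r1",
        c_counts=np.array([1, 0, 2, 0]),
        totals=np.array([10, 10, 10, 10]),
    )
    model = ControlModel(
        [table], fix_hyper=True, fixed_seq_err=0.001, fixed_theta=0.001
    )
    draws = run_inference(model, mcmc_cfg)
    oracle = grid_posterior_mean_bs(table, 0.001, 0.001)
    assert draws.mean("bs_eff")[0] == pytest.approx(oracle, abs=0.01)


def test_high_quality_replicate_recovered(advi_cfg):
    """bs_eff = 0.995 at coverage 10 recovered within half a point."""
    tables, _ = simulate_control(
        ControlSimConfig(bs_eff=0.995, coverage=10, n_replicates=1), seed=42
    )
    draws = fit_control(tables, inference=advi_cfg.with_seed(7))
    assert draws.mean("bs_eff")[0] == pytest.approx(0.995, abs=0.005)


def test_empty_data_posterior_is_prior_driven(advi_cfg):
    """Zero coverage leaves bs_eff at its prior push-forward location."""
    table = ControlCountTable(
        replicate_id="empty",
        c_counts=np.zeros(10, dtype=int),
        totals=np.zeros(10, dtype=int),
    )
    with pytest.warns(RuntimeWarning, match="zero total coverage"):
        draws = fit_control([table], inference=advi_cfg.with_seed(3))
    # Monte-Carlo prior push-forward of expit(mu + sigma r)
    rng = np.random.default_rng(99)
    mu = rng.normal(BS_EFF_HYPER.psi_mu_mu, BS_EFF_HYPER.psi_mu_sigma, 200000)
    sigma = np.exp(
        rng.normal(
            BS_EFF_HYPER.psi_sigma_mu, BS_EFF_HYPER.psi_sigma_sigma, 200000
        )
    )
    prior_mean = expit(mu + sigma * rng.standard_normal(200000)).mean()
    assert draws.mean("bs_eff")[0] == pytest.approx(prior_mean, abs=0.03)
    assert draws.mean("seq_err")[0] < 0.05


def test_recovery_error_shrinks_with_coverage(advi_cfg):
    """MAE of posterior-mean bs_eff: coverage 10 beats coverage 1-3."""
    maes = {}
    for cov in (10, (1, 3)):
        tables, _ = simulate_control(
            ControlSimConfig(bs_eff=0.9, coverage=cov, n_replicates=20),
            seed=77,
        )
        draws = fit_control(tables, inference=advi_cfg.with_seed(8))
        maes[cov] = np.abs(draws.mean("bs_eff") - 0.9).mean()
        # sanity bound on the error channel: simulated seq_err is 0.001
        assert np.all(draws.mean("seq_err") <= 0.1)
    assert maes[10] < maes[(1, 3)]


def test_independent_mode_matches_joint_roughly(advi_cfg):
    tables, _ = simulate_control(
        ControlSimConfig(bs_eff=0.995, coverage=10, n_replicates=3), seed=5
    )
    joint = fit_control(tables, inference=advi_cfg.with_seed(1))
    indep = fit_control(
        tables, inference=advi_cfg.with_seed(1), mode="independent"
    )
    assert joint["bs_eff"].shape == indep["bs_eff"].shape
    assert np.allclose(
        joint.mean("bs_eff"), indep.mean("bs_eff"), atol=0.01
    )


def test_advi_and_mcmc_agree_on_bs_eff(advi_cfg, mcmc_cfg):
    """Backend agreement on the 444-cytosine coverage-10 setting."""
    tables, _ = simulate_control(
        ControlSimConfig(bs_eff=0.9, coverage=10, n_replicates=2), seed=21
    )
    a = fit_control(tables, inference=advi_cfg.with_seed(2))
    m = fit_control(tables, inference=mcmc_cfg.with_seed(2))
    assert np.allclose(a.mean("bs_eff"), m.mean("bs_eff"), atol=0.02)


def test_posterior_experimental_params_summaries():
    draws = PosteriorDraws(
        arrays={
            "bs_eff": np.array([[0.8], [1.0]]),
            "seq_err": np.array([[0.001], [0.003]]),
        },
        backend_tag="advi",
        seed=0,
    )
    (params,) = posterior_experimental_params(draws, bs_star_eff=0.002)
    assert params.bs_eff == pytest.approx(0.9)  # mean of 0.8, 1.0
    assert params.seq_err == pytest.approx(0.002)
    assert params.bs_star_eff == 0.002


def test_posterior_experimental_params_requires_quantities():
    draws = PosteriorDraws(
        arrays={"bs_eff": np.ones((5, 1))}, backend_tag="advi", seed=0
    )
    with pytest.raises(KeyError, match="seq_err"):
        posterior_experimental_params(draws)


def test_summary_matches_recomputation_from_draws(advi_cfg):
    tables, _ = simulate_control(
        ControlSimConfig(bs_eff=0.995, coverage=10, n_replicates=2), seed=9
    )
    draws = fit_control(tables, inference=advi_cfg.with_seed(4))
    params = posterior_experimental_params(draws)
    assert params[0].bs_eff == pytest.approx(
        float(draws["bs_eff"][:, 0].mean()), abs=1e-12
    )


def test_control_tsv_round_trip(tmp_path):
    tables, _ = simulate_control(
        ControlSimConfig(k_control=5, n_replicates=2), seed=1
    )
    path = tmp_path / "control.tsv"
    write_control_tsv(tables, path)
    back = read_control_tsv(path)
    assert [t.replicate_id for t in back] == ["rep1", "rep2"]
    for a, b in zip(tables, back):
        assert np.array_equal(a.c_counts, b.c_counts)
        assert np.array_equal(a.totals, b.totals)


def test_control_tsv_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("replicate_id\tcytosine_id\tc_count\nr1\tk1\t0\n")
    with pytest.raises(ValueError, match="total_count"):
        read_control_tsv(path)


def test_count_table_invariants():
    with pytest.raises(ValueError, match="c_count <= total_count"):
        ControlCountTable("r", np.array([3]), np.array([2]))
    with pytest.raises(ValueError):
        ControlCountTable("r", np.array([]), np.array([]))
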