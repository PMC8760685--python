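"""Posterior-approximation engines behind a uniform contract.

Two backends produce the same currency, :class:`PosteriorDraws`:

``"mcmc"``
    Exact-posterior sampling with the affine-invariant ensemble sampler of
    ``emcee``, initialised from a diagonal Laplace approximation at the
    posterior mode.  ``"hmc"`` is accepted as an alias at the config surface.
``"advi"``
    Mean-field automatic-differentiation variational inference: a diagonal
    Gaussian in the unconstrained space is fitted by stochastic gradient
    ascent on the ELBO (reparameterisation gradient, ``advi_grad_samples``
    Monte-Carlo samples per step), with convergence declared when the
    relative change of the ELBO estimate (``advi_elbo_samples`` samples)
    falls below ``advi_tol``.  Draws are then sampled from the fitted
    approximation.

Either way the number of retrieved posterior draws equals ``s_draws``, so
downstream summaries are backend-agnostic.

Models plug in through a small duck-typed contract: an object with an
integer ``n_free``, a batched ``logp_and_grad(Z) -> (logp, grad)`` over an
``(m, n_free)`` array of unconstrained states, and a
``constrain(Z) -> dict`` mapping draws to named, interpretable arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Protocol, Tuple

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "InferenceConfig",
    "PosteriorDraws",
    "InferenceError",
    "run_inference",
    "sweep_advi_params",
]


class InferenceError(RuntimeError):
    """Backend failed to produce a usable posterior (non-finite ELBO, etc.)."""


class LogDensityModel(Protocol):
    n_free: int

    def logp_and_grad(self, z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Batched unnormalised log posterior and its gradient."""

    def constrain(self, z: np.ndarray) -> Dict[str, np.ndarray]:
        """Map unconstrained draws (S, n_free) to named latent arrays."""


@dataclass(frozen=True)
class InferenceConfig:
    """Settings shared by every model fit.

    ``s_draws`` is the number of posterior draws retrieved from either
    backend.  The MCMC backend runs ``mcmc_chains`` independent walker
    ensembles' worth of walkers for ``mcmc_iterations`` steps and discards
    the first half as warmup.  The ADVI knobs are the number of Monte-Carlo
    samples for the ELBO estimate (``advi_elbo_samples``, N_E) and for the
    gradient estimate (``advi_grad_samples``, N_G).  ``seed`` is required:
    every fit is reproducible.
    """

    backend: str = "advi"
    s_draws: int = 1000
    seed: int = 0
    mcmc_chains: int = 4
    mcmc_iterations: int = 1000
    advi_elbo_samples: int = 100
    advi_grad_samples: int = 1
    advi_tol: float = 0.01
    advi_max_iter: int = 3000
    advi_learning_rate: float = 0.08

    def __post_init__(self) -> None:
        backend = self.backend.lower()
        if backend == "hmc":  # alias kept for familiarity
            backend = "mcmc"
        if backend not in ("mcmc", "advi"):
            raise ValueError(f"unknown backend {self.backend!r}")
        object.__setattr__(self, "backend", backend)
        if self.s_draws < 1:
            raise ValueError("s_draws must be >= 1")
        if self.advi_elbo_samples < 1 or self.advi_grad_samples < 1:
            raise ValueError("ADVI sample counts must be >= 1")

    def with_seed(self, seed: int) -> "InferenceConfig":
        return replace(self, seed=int(seed))


@dataclass
class PosteriorDraws:
    """S labelled posterior draws plus provenance.

    ``arrays`` maps a quantity name (e.g. ``"bs_eff"``) to an array whose
    first axis has length ``s`` (the draw index); remaining axes index
    replicates, samples, or matrix coordinates.  ``diagnostics`` carries
    free-form numeric summaries from the backend.
    """

    arrays: Dict[str, np.ndarray]
    backend_tag: str
    seed: int
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = {v.shape[0] for v in self.arrays.values()}
        if len(sizes) > 1:
            raise ValueError(f"inconsistent draw counts: {sizes}")

    @property
    def s(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    def __contains__(self, name: str) -> bool:
        return name in self.arrays

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.arrays:
            raise KeyError(
                f"posterior draws do not contain {name!r}; "
                f"available: {sorted(self.arrays)}"
            )
        return self.arrays[name]

    def mean(self, name: str) -> np.ndarray:
        return np.mean(self[name], axis=0)

    def median(self, name: str) -> np.ndarray:
        return np.median(self[name], axis=0)

    def to_frame(self):
        """Flatten all scalar components into a draws-by-latents DataFrame."""
        import pandas as pd

        cols = {}
        for name, arr in self.arrays.items():
            flat = arr.reshape(arr.shape[0], -1)
            if flat.shape[1] == 1:
                cols[name] = flat[:, 0]
            else:
                for j in range(flat.shape[1]):
                    cols[f"{name}[{j}]"] = flat[:, j]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# mode finding


def find_map(
    model: LogDensityModel, x0: Optional[np.ndarray] = None
) -> np.ndarray:
    """Posterior mode by L-BFGS on the exact log joint and gradient."""
    d = model.n_free
    if x0 is None:
        x0 = getattr(model, "initial", lambda: np.zeros(d))()

    def neg(z):
        lp, g = model.logp_and_grad(z[None, :])
        return -float(lp[0]), -np.asarray(g[0], dtype=float)

    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    if not np.all(np.isfinite(res.x)):
        raise InferenceError("mode finding produced non-finite values")
    return res.x


def _laplace_scales(model: LogDensityModel, mode: np.ndarray) -> np.ndarray:
    """Diagonal Laplace standard deviations via central differences."""
    d = model.n_free
    h = 1e-4
    zs = np.repeat(mode[None, :], 2 * d, axis=0)
    for i in range(d):
        zs[2 * i, i] += h
        zs[2 * i + 1, i] -= h
    _, grads = model.logp_and_grad(zs)
    hess_diag = np.array(
        [(grads[2 * i, i] - grads[2 * i + 1, i]) / (2 * h) for i in range(d)]
    )
    # fall back to unit scale on flat/indefinite directions
    with np.errstate(invalid="ignore", divide="ignore"):
        scales = 1.0 / np.sqrt(np.clip(-hess_diag, 1e-8, None))
    scales[~np.isfinite(scales)] = 1.0
    return np.clip(scales, 1e-4, 10.0)


# ---------------------------------------------------------------------------
# ADVI


def _fit_advi(model: LogDensityModel, config: InferenceConfig):
    rng = np.random.default_rng(config.seed)
    d = model.n_free
    mode = find_map(model)
    mu = mode.copy()
    omega = np.log(np.clip(_laplace_scales(model, mode), 1e-3, 1.0))

    lr = config.advi_learning_rate
    b1, b2, eps = 0.9, 0.999, 1e-8
    m = np.zeros(2 * d)
    v = np.zeros(2 * d)

    def elbo(mu, omega, n):
        epsilons = rng.standard_normal((n, d))
        z = mu[None, :] + np.exp(omega)[None, :] * epsilons
        lp, _ = model.logp_and_grad(z)
        return float(np.mean(lp) + np.sum(omega))

    prev_elbo = None
    hits = 0
    check_every = 20
    n_iter = 0
    final_elbo = np.nan
    # Polyak tail averaging: with few gradient samples the Adam iterates
    # random-walk around the optimum at the learning-rate scale; averaging
    # the last `avg_window` iterates removes that noise.
    avg_window = 200
    from collections import deque

    tail: deque = deque(maxlen=avg_window)
    stop_at = None
    for t in range(1, config.advi_max_iter + avg_window + 1):
        n_iter = t
        epsilons = rng.standard_normal((config.advi_grad_samples, d))
        sd = np.exp(omega)
        z = mu[None, :] + sd[None, :] * epsilons
        _, g = model.logp_and_grad(z)
        grad_mu = g.mean(axis=0)
        grad_omega = (g * epsilons).mean(axis=0) * sd + 1.0  # +1: entropy
        grad = np.concatenate([grad_mu, grad_omega])
        if not np.all(np.isfinite(grad)):
            raise InferenceError("non-finite ADVI gradient")
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad * grad
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        # smaller steps in the averaging tail: the iterates then hover much
        # closer to the optimum and the average concentrates further
        lr_t = lr * (0.2 if stop_at is not None else 1.0)
        step = lr_t * mhat / (np.sqrt(vhat) + eps)
        mu = mu + step[:d]
        omega = np.clip(omega + step[d:], -12.0, 4.0)
        tail.append((mu, omega))
        if stop_at is not None:
            if t >= stop_at:
                break
            continue
        if t % check_every == 0:
            cur = elbo(mu, omega, config.advi_elbo_samples)
            if not np.isfinite(cur):
                raise InferenceError("non-finite ELBO")
            final_elbo = cur
            if prev_elbo is not None:
                rel = abs(cur - prev_elbo) / max(abs(prev_elbo), 1.0)
                hits = hits + 1 if rel < config.advi_tol else 0
                if hits >= 2:
                    stop_at = t + avg_window
            prev_elbo = cur
        if t >= config.advi_max_iter and stop_at is None:
            break

    converged = stop_at is not None
    mu = np.mean([p[0] for p in tail], axis=0)
    omega = np.mean([p[1] for p in tail], axis=0)
    if not converged:
        warnings.warn(
            "ADVI stopped at advi_max_iter without meeting the ELBO "
            "tolerance; treat posterior summaries with care",
            RuntimeWarning,
        )
    draws = mu[None, :] + np.exp(omega)[None, :] * rng.standard_normal(
        (config.s_draws, d)
    )
    diagnostics = {
        "elbo": final_elbo,
        "n_iter": float(n_iter),
        "converged": float(converged),
    }
    return draws, diagnostics


# ---------------------------------------------------------------------------
# MCMC (affine-invariant ensemble)


def _fit_mcmc(model: LogDensityModel, config: InferenceConfig):
    import emcee

    d = model.n_free
    rng = np.random.default_rng(config.seed)
    mode = find_map(model)
    scales = _laplace_scales(model, mode)

    nwalkers = max(2 * d + 2, 2 * config.mcmc_chains)
    if nwalkers % 2:
        nwalkers += 1

    def log_prob(z):
        lp, _ = model.logp_and_grad(np.atleast_2d(z))
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp

    p0 = mode[None, :] + scales[None, :] * rng.standard_normal((nwalkers, d))
    sampler = emcee.EnsembleSampler(nwalkers, d, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(
        config.seed % (2**32)
    ).get_state()
    sampler.run_mcmc(p0, config.mcmc_iterations, progress=False)
    burn = config.mcmc_iterations // 2
    chain = sampler.get_chain(discard=burn)  # (steps, walkers, d)
    flat = chain.reshape(-1, d)
    if flat.shape[0] < config.s_draws:
        raise InferenceError(
            f"requested {config.s_draws} draws but the post-warmup chain "
            f"holds only {flat.shape[0]}; increase mcmc_iterations"
        )
    idx = np.linspace(0, flat.shape[0] - 1, config.s_draws).astype(int)
    draws = flat[idx]
    diagnostics = {
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "n_walkers": float(nwalkers),
        "n_iterations": float(config.mcmc_iterations),
    }
    return draws, diagnostics


def run_inference(
    model: LogDensityModel, config: InferenceConfig
) -> PosteriorDraws:
    """Fit ``model`` with the configured backend and return labelled draws."""
    if config.backend == "advi":
        z, diagnostics = _fit_advi(model, config)
    else:
        z, diagnostics = _fit_mcmc(model, config)
    arrays = model.constrain(z)
    return PosteriorDraws(
        arrays=arrays,
        backend_tag=config.backend,
        seed=config.seed,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# ADVI tuning sweep


def sweep_advi_params(
    dataset,
    n_e_grid: Iterable[int],
    n_g_grid: Iterable[int],
    *,
    base_config: Optional[InferenceConfig] = None,
    reference_config: Optional[InferenceConfig] = None,
):
    """Grid-evaluate ADVI tuning parameters against an MCMC reference.

    ``dataset`` is a differential-methylation dataset as produced by
    :func:`methrep.simulate.simulate_differential` (counts, params, design).
    For every (N_E, N_G) cell the per-cytosine Bayes factors are recomputed
    with ADVI and compared to the MCMC reference by mean absolute log10-BF
    deviation.  Returns a DataFrame with columns ``n_e``, ``n_g``,
    ``mean_abs_log10_bf_dev``.
    """
    import pandas as pd

    from .differential import call_differential

    n_e_grid = list(n_e_grid)
    n_g_grid = list(n_g_grid)
    if not n_e_grid or not n_g_grid:
        return pd.DataFrame(columns=["n_e", "n_g", "mean_abs_log10_bf_dev"])

    base = base_config or InferenceConfig(backend="advi", s_draws=1000)
    ref_cfg = reference_config or InferenceConfig(
        backend="mcmc", s_draws=1600, seed=base.seed
    )
    ref = call_differential(
        dataset.counts, dataset.true_params, dataset.design_table, ref_cfg
    )
    ref_log = np.log10([r.bf for r in ref])

    rows = []
    for n_e in n_e_grid:
        for n_g in n_g_grid:
            cfg = replace(
                base, advi_elbo_samples=int(n_e), advi_grad_samples=int(n_g)
            )
            res = call_differential(
                dataset.counts, dataset.true_params, dataset.design_table, cfg
            )
            dev = np.mean(np.abs(np.log10([r.bf for r in res]) - ref_log))
            rows.append(
                {"n_e": n_e, "n_g": n_g, "mean_abs_log10_bf_dev": float(dev)}
            )
    return pd.DataFrame(rows)
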