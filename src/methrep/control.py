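"""Stage 1: experimental parameters from unmethylated spike-in controls.

BS-seq libraries are spiked with fully unmethylated DNA (typically lambda
phage).  Because every cytosine of the spike-in shares the replicate's
conversion efficiency and sequencing error, those two parameters can be
estimated per technical replicate from the control counts alone, and their
posterior means are then fixed inputs to the stage-2 methylation model.

Model, per technical replicate j and control cytosine k::

    logit(bs_eff_j)  = mu_bs  + sigma_bs  * r_bs_j,   r_bs_j  ~ N(0, 1)
    logit(seq_err_j) = mu_err + sigma_err * r_err_j,  r_err_j ~ N(0, 1)
    theta_k          ~ Dir(alpha)            (2-simplex; trace methylation)
    c_jk             ~ Bin(n_jk, prob_c(theta_k, params_j))

with normal hyperpriors on ``mu`` and ``ln sigma`` (see
:class:`~methrep.model_core.LogisticNormalHyper`).  The hyper level
(``mu``, ``sigma``) is shared across replicates in the default joint fit;
an independent per-replicate mode is available for parallel runs.

Implementation note: ``theta_k`` is marginalised by Gauss–Legendre
quadrature mapped through the Beta quantile function, which is equivalent
to sampling it explicitly but collapses all cytosines with identical
(total, "C") counts into one likelihood term.  Per-cytosine ``theta``
draws can be reconstructed from the fitted draws on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .backends import InferenceConfig, PosteriorDraws, run_inference
from .model_core import (
    BS_EFF_HYPER,
    DEFAULT_BS_STAR_EFF,
    SEQ_ERR_HYPER,
    ExperimentalParams,
    LogisticNormalHyper,
)

__all__ = [
    "ControlCountTable",
    "ControlModelConfig",
    "ControlModel",
    "fit_control",
    "posterior_experimental_params",
    "read_control_tsv",
    "write_control_tsv",
]

CONTROL_COLUMNS = ("replicate_id", "cytosine_id", "c_count", "total_count")


@dataclass(frozen=True)
class ControlCountTable:
    """Per-replicate "C"/total counts over the spike-in control cytosines."""

    replicate_id: str
    c_counts: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c_counts, dtype=np.int64)
        n = np.asarray(self.totals, dtype=np.int64)
        if c.ndim != 1 or n.shape != c.shape or c.size < 1:
            raise ValueError("c_counts and totals must be equal-length 1-D")
        if np.any(n < 0) or np.any(c < 0) or np.any(c > n):
            raise ValueError("need 0 <= c_count <= total_count everywhere")
        object.__setattr__(self, "c_counts", c)
        object.__setattr__(self, "totals", n)

    @property
    def n_cytosines(self) -> int:
        return int(self.c_counts.size)


@dataclass(frozen=True)
class ControlModelConfig:
    """Priors of the control model.

    ``theta_control_alpha`` is the Dirichlet concentration over the
    (unmethylated, methylated) simplex of the spike-in DNA; the default
    (999, 1) encodes that the control is unmethylated up to trace carryover.
    """

    bs_hyper: LogisticNormalHyper = BS_EFF_HYPER
    seq_hyper: LogisticNormalHyper = SEQ_ERR_HYPER
    theta_control_alpha: Tuple[float, float] = (999.0, 1.0)
    bs_star_eff: float = DEFAULT_BS_STAR_EFF
    quadrature_nodes: int = 32

    def __post_init__(self) -> None:
        if min(self.theta_control_alpha) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if not 0.0 <= self.bs_star_eff <= 1.0:
            raise ValueError("bs_star_eff must be a probability")


def _theta_quadrature(alpha: Tuple[float, float], q: int):
    """Nodes/log-weights integrating the methylated-fraction Beta prior.

    With theta ~ Dir(a_u, a_m) on (unmethylated, methylated), the methylated
    fraction t follows Beta(a_m, a_u).  Substituting t = F^{-1}(u) turns the
    prior integral into a uniform integral over u in (0, 1), evaluated with
    Gauss–Legendre nodes.
    """
    a_u, a_m = alpha
    x, w = np.polynomial.legendre.leggauss(q)
    u = 0.5 * (x + 1.0)
    t = beta_dist.ppf(u, a_m, a_u)
    return np.clip(t, 0.0, 1.0), np.log(0.5 * w)


class ControlModel:
    """Joint log posterior over replicate-level experimental parameters.

    Unconstrained state layout (``share_hyper`` with free ``seq_err``)::

        [mu_bs, log_sigma_bs, mu_err, log_sigma_err,
         r_bs_1..r_bs_R, r_err_1..r_err_R]

    ``fix_hyper=True`` pins mu/sigma to their hyperprior locations (used by
    the 1-D grid-reduction oracle tests), leaving only the r auxiliaries.
    ``fixed_seq_err`` / ``fixed_theta`` freeze those quantities to
    constants, removing the corresponding latents / the quadrature.
    """

    def __init__(
        self,
        tables: Sequence[ControlCountTable],
        config: ControlModelConfig = ControlModelConfig(),
        *,
        fix_hyper: bool = False,
        fixed_seq_err: Optional[float] = None,
        fixed_theta: Optional[float] = None,
    ) -> None:
        if not tables:
            raise ValueError("at least one control table is required")
        self.tables = list(tables)
        self.config = config
        self.fix_hyper = fix_hyper
        self.fixed_seq_err = fixed_seq_err
        self.fixed_theta = fixed_theta
        self.replicate_ids = [t.replicate_id for t in self.tables]
        self.n_replicates = len(self.tables)

        # compress each table to unique (total, c) pairs with multiplicities
        reps, ns, cs, ws = [], [], [], []
        for j, t in enumerate(self.tables):
            if int(t.totals.sum()) == 0:
                warnings.warn(
                    f"replicate {t.replicate_id!r} has zero total coverage; "
                    "its posterior is prior-driven",
                    RuntimeWarning,
                )
            pairs, counts = np.unique(
                np.stack([t.totals, t.c_counts], axis=1), axis=0,
                return_counts=True,
            )
            reps.append(np.full(len(pairs), j))
            ns.append(pairs[:, 0])
            cs.append(pairs[:, 1])
            ws.append(counts)
        self._rep = np.concatenate(reps)
        self._n = np.concatenate(ns).astype(float)
        self._c = np.concatenate(cs).astype(float)
        self._w = np.concatenate(ws).astype(float)

        if fixed_theta is None:
            self._t, self._logw_q = _theta_quadrature(
                config.theta_control_alpha, config.quadrature_nodes
            )
        else:
            if not 0.0 <= fixed_theta <= 1.0:
                raise ValueError("fixed_theta must be a probability")
            self._t = np.array([float(fixed_theta)])
            self._logw_q = np.array([0.0])

        blocks = 0 if fix_hyper else 2
        if fixed_seq_err is None:
            self.n_free = 2 * blocks + 2 * self.n_replicates
        else:
            self.n_free = blocks + self.n_replicates

    def initial(self) -> np.ndarray:
        """Mode-search start at the hyperprior locations.

        Starting at zero would put every probability at 0.5 — a saddle of
        the readout likelihood, from which the optimiser can slide into the
        mirror mode (bs_eff and seq_err jointly flipped) that the priors
        all but rule out.
        """
        z0 = np.zeros(self.n_free)
        if not self.fix_hyper:
            cfg = self.config
            z0[0] = cfg.bs_hyper.psi_mu_mu
            z0[1] = cfg.bs_hyper.psi_sigma_mu
            if self.fixed_seq_err is None:
                z0[2] = cfg.seq_hyper.psi_mu_mu
                z0[3] = cfg.seq_hyper.psi_sigma_mu
        return z0

    # -- state unpacking ---------------------------------------------------

    def _unpack(self, z: np.ndarray):
        """Return (bs, err, prior_logp, pack_grad) for a batch z (m, d)."""
        cfg = self.config
        R = self.n_replicates
        i = 0
        if self.fix_hyper:
            mu_bs = np.full(z.shape[0], cfg.bs_hyper.psi_mu_mu)
            ls_bs = np.full(z.shape[0], cfg.bs_hyper.psi_sigma_mu)
        else:
            mu_bs, ls_bs = z[:, 0], z[:, 1]
            i = 2
        if self.fixed_seq_err is None:
            if self.fix_hyper:
                mu_e = np.full(z.shape[0], cfg.seq_hyper.psi_mu_mu)
                ls_e = np.full(z.shape[0], cfg.seq_hyper.psi_sigma_mu)
            else:
                mu_e, ls_e = z[:, i], z[:, i + 1]
                i += 2
        r_bs = z[:, i:i + R]
        i += R
        if self.fixed_seq_err is None:
            r_e = z[:, i:i + R]

        sig_bs = np.exp(ls_bs)
        bs = expit(mu_bs[:, None] + sig_bs[:, None] * r_bs)
        if self.fixed_seq_err is None:
            sig_e = np.exp(ls_e)
            err = expit(mu_e[:, None] + sig_e[:, None] * r_e)
            return (mu_bs, ls_bs, r_bs, bs), (mu_e, ls_e, r_e, err)
        err = np.full_like(bs, float(self.fixed_seq_err))
        return (mu_bs, ls_bs, r_bs, bs), (None, None, None, err)

    @staticmethod
    def _normal_lp_grad(x, mu, sd):
        lp = -0.5 * ((x - mu) / sd) ** 2
        return lp, -(x - mu) / sd**2

    def logp_and_grad(self, z: np.ndarray):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        m = z.shape[0]
        cfg = self.config
        (mu_bs, ls_bs, r_bs, bs), (mu_e, ls_e, r_e, err) = self._unpack(z)
        bss = cfg.bs_star_eff

        # likelihood over flattened unique (replicate, total, c) entries
        rep = self._rep
        bs_e = bs[:, rep]       # (m, E)
        err_e = err[:, rep]
        t = self._t[None, None, :]  # (1, 1, Q)
        pc = (1.0 - bs_e) * (1.0 - err_e) + bs_e * err_e
        p5 = (1.0 - bss) * (1.0 - err_e) + bss * err_e
        p = t * p5[..., None] + (1.0 - t) * pc[..., None]  # (m, E, Q)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        c = self._c[None, :, None]
        n = self._n[None, :, None]
        logbin = c * np.log(p) + (n - c) * np.log1p(-p)
        a = self._logw_q[None, None, :] + logbin
        amax = a.max(axis=2, keepdims=True)
        expa = np.exp(a - amax)
        denom = expa.sum(axis=2)
        logmarg = amax[..., 0] + np.log(denom)  # (m, E)
        lp = (self._w[None, :] * logmarg).sum(axis=1)

        # gradient through the quadrature mixture
        s = expa / denom[..., None]  # responsibilities over nodes
        dlogbin_dp = c / p - (n - c) / (1.0 - p)
        common = s * dlogbin_dp
        # d p / d bs = (1 - t) (2 err - 1); d p / d err = t (2 bss - 1)
        #                                              + (1 - t) (2 bs - 1)
        g_bs_e = (common * (1.0 - t) * (2.0 * err_e[..., None] - 1.0)).sum(2)
        g_err_e = (
            common
            * (t * (2.0 * bss - 1.0)
               + (1.0 - t) * (2.0 * bs_e[..., None] - 1.0))
        ).sum(2)
        g_bs = np.zeros((m, self.n_replicates))
        g_err = np.zeros((m, self.n_replicates))
        wg_bs = self._w[None, :] * g_bs_e
        wg_err = self._w[None, :] * g_err_e
        for j in range(self.n_replicates):
            mask = rep == j
            g_bs[:, j] = wg_bs[:, mask].sum(axis=1)
            g_err[:, j] = wg_err[:, mask].sum(axis=1)

        grad = np.zeros_like(z)
        # conversion-efficiency block
        ga = g_bs * bs * (1.0 - bs)  # d lp / d (logit bs)
        sig_bs = np.exp(ls_bs)
        i = 0
        if not self.fix_hyper:
            lp_mu, g_mu = self._normal_lp_grad(
                mu_bs, cfg.bs_hyper.psi_mu_mu, cfg.bs_hyper.psi_mu_sigma
            )
            lp_ls, g_ls = self._normal_lp_grad(
                ls_bs, cfg.bs_hyper.psi_sigma_mu, cfg.bs_hyper.psi_sigma_sigma
            )
            lp += lp_mu + lp_ls
            grad[:, 0] = ga.sum(axis=1) + g_mu
            grad[:, 1] = (ga * r_bs).sum(axis=1) * sig_bs + g_ls
            i = 2
        # sequencing-error block
        if self.fixed_seq_err is None:
            ge = g_err * err * (1.0 - err)
            sig_e = np.exp(ls_e)
            if not self.fix_hyper:
                lp_mu, g_mu = self._normal_lp_grad(
                    mu_e, cfg.seq_hyper.psi_mu_mu, cfg.seq_hyper.psi_mu_sigma
                )
                lp_ls, g_ls = self._normal_lp_grad(
                    ls_e, cfg.seq_hyper.psi_sigma_mu,
                    cfg.seq_hyper.psi_sigma_sigma,
                )
                lp += lp_mu + lp_ls
                grad[:, i] = ge.sum(axis=1) + g_mu
                grad[:, i + 1] = (ge * r_e).sum(axis=1) * sig_e + g_ls
                i += 2
        R = self.n_replicates
        lp += -0.5 * (r_bs**2).sum(axis=1)
        grad[:, i:i + R] = ga * sig_bs[:, None] - r_bs
        i += R
        if self.fixed_seq_err is None:
            lp += -0.5 * (r_e**2).sum(axis=1)
            grad[:, i:i + R] = ge * sig_e[:, None] - r_e
        return lp, grad

    def constrain(self, z: np.ndarray) -> Dict[str, np.ndarray]:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        (mu_bs, ls_bs, _, bs), (mu_e, ls_e, _, err) = self._unpack(z)
        out = {"bs_eff": bs, "seq_err": err}
        if not self.fix_hyper:
            out["mu_bs"] = mu_bs
            out["sigma_bs"] = np.exp(ls_bs)
            if self.fixed_seq_err is None:
                out["mu_err"] = mu_e
                out["sigma_err"] = np.exp(ls_e)
        return out

    def sample_theta(
        self, draws: PosteriorDraws, rng: np.random.Generator
    ) -> Dict[str, np.ndarray]:
        """Reconstruct per-cytosine theta draws from fitted parameter draws.

        For each posterior draw the conditional of the methylated fraction
        given (bs_eff, seq_err) and a cytosine's counts is discretised on
        the quadrature grid and sampled.  Returns one (S, K_j) array per
        replicate id.
        """
        bs = draws["bs_eff"]
        err = draws["seq_err"]
        out = {}
        for j, table in enumerate(self.tables):
            pc = (1.0 - bs[:, j]) * (1.0 - err[:, j]) + bs[:, j] * err[:, j]
            p5 = (
                (1.0 - self.config.bs_star_eff) * (1.0 - err[:, j])
                + self.config.bs_star_eff * err[:, j]
            )
            t = self._t[None, None, :]
            p = np.clip(
                t * p5[:, None, None] + (1.0 - t) * pc[:, None, None],
                1e-12, 1.0 - 1e-12,
            )  # (S, K, Q)
            c = table.c_counts[None, :, None].astype(float)
            n = table.totals[None, :, None].astype(float)
            loga = (
                self._logw_q[None, None, :]
                + c * np.log(p) + (n - c) * np.log1p(-p)
            )
            prob = np.exp(loga - loga.max(axis=2, keepdims=True))
            prob /= prob.sum(axis=2, keepdims=True)
            cdf = np.cumsum(prob, axis=2)
            u = rng.random(cdf.shape[:2])[..., None]
            idx = (u > cdf).sum(axis=2)
            out[table.replicate_id] = self._t[idx]
        return out


def fit_control(
    tables: Sequence[ControlCountTable],
    config: ControlModelConfig = ControlModelConfig(),
    inference: InferenceConfig = InferenceConfig(),
    *,
    mode: str = "joint",
) -> PosteriorDraws:
    """Fit the control model and return draws of bs_eff/seq_err per replicate.

    ``mode="joint"`` (default) shares the logistic-normal hyper level across
    replicates; ``mode="independent"`` fits each replicate separately (its
    own hyper latents), which is embarrassingly parallel and matches
    per-library processing.  Draw arrays are keyed ``bs_eff`` / ``seq_err``
    with one column per replicate, in input order.
    """
    if mode == "joint":
        model = ControlModel(tables, config)
        draws = run_inference(model, inference)
        draws.diagnostics["replicate_ids"] = list(model.replicate_ids)
        return draws
    if mode != "independent":
        raise ValueError("mode must be 'joint' or 'independent'")
    seeds = np.random.SeedSequence(inference.seed).generate_state(len(tables))
    parts = [
        run_inference(
            ControlModel([t], config),
            inference.with_seed(int(s % (2**31))),
        )
        for t, s in zip(tables, seeds)
    ]
    arrays = {
        name: np.concatenate([p[name] for p in parts], axis=1)
        for name in ("bs_eff", "seq_err")
    }
    merged = PosteriorDraws(
        arrays=arrays, backend_tag=inference.backend, seed=inference.seed
    )
    merged.diagnostics["replicate_ids"] = [t.replicate_id for t in tables]
    return merged


def posterior_experimental_params(
    draws: PosteriorDraws,
    bs_star_eff: float = DEFAULT_BS_STAR_EFF,
    *,
    summary: str = "mean",
) -> List[ExperimentalParams]:
    """Summarise stage-1 draws into fixed per-replicate parameters.

    The default summary is the arithmetic mean of the draws; medians are
    available via ``summary="median"``.
    """
    if "bs_eff" not in draws or "seq_err" not in draws:
        raise KeyError("draws must contain 'bs_eff' and 'seq_err'")
    reduce = {"mean": np.mean, "median": np.median}[summary]
    bs = np.atleast_2d(reduce(draws["bs_eff"], axis=0))[0]
    err = np.atleast_2d(reduce(draws["seq_err"], axis=0))[0]
    return [
        ExperimentalParams(
            bs_eff=float(np.clip(b, 0.0, 1.0)),
            seq_err=float(np.clip(e, 0.0, 1.0)),
            bs_star_eff=bs_star_eff,
        )
        for b, e in zip(np.ravel(bs), np.ravel(err))
    ]


# ---------------------------------------------------------------------------
# TSV interface


def read_control_tsv(path) -> List[ControlCountTable]:
    """Read control counts (replicate_id, cytosine_id, c_count, total_count)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CONTROL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    tables = []
    for rid in df["replicate_id"].drop_duplicates():
        sub = df[df["replicate_id"] == rid]
        tables.append(
            ControlCountTable(
                replicate_id=str(rid),
                c_counts=sub["c_count"].to_numpy(),
                totals=sub["total_count"].to_numpy(),
            )
        )
    return tables


def write_control_tsv(tables: Sequence[ControlCountTable], path) -> None:
    rows = []
    for t in tables:
        for k in range(t.n_cytosines):
            rows.append(
                (t.replicate_id, f"control_{k + 1}",
                 int(t.c_counts[k]), int(t.totals[k]))
            )
    pd.DataFrame(rows, columns=list(CONTROL_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
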