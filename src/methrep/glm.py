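"""Stage 2: methylation levels via a general linear model with softmax link.

One cytosine at a time, the methylation level ``theta_i`` of each
biological sample i is tied to covariates through::

    Y = D B + E,            Y in R^{N x 2}
    theta_i = softmax(row_i(Y))[methylated]

where D is the N x p design matrix, B the p x 2 coefficient matrix with
prior vec(B) ~ N(0, sigma_B^2 I) (sigma_B^2 = 5), and E the N x 2 noise
matrix with vec(E) ~ N(0, sigma_E^2 I), sigma_E^2 ~ InvGamma(1, 1).  These
are the diagonal special cases of matrix-normal priors; the redundant
softmax degree of freedom is identified solely by the proper priors, so no
sum-to-zero constraint is imposed.

Each technical replicate j of sample i contributes an independent binomial
likelihood ``Bin(n_ij, prob_c(theta_i, params_ij))`` with its own fixed
experimental parameters from stage 1 — this is what lets libraries with
poor bisulfite conversion stay in the analysis instead of being discarded.
The *reduced* model mimics the traditional approach: experimental
parameters forced to the ideal (1, 0, 0) and, by caller restriction, only
the well-converted libraries included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .backends import InferenceConfig, PosteriorDraws, run_inference
from .model_core import ExperimentalParams

__all__ = [
    "MethCountTable",
    "GLMSpec",
    "GLMLatents",
    "GLMModel",
    "build_design_matrix",
    "fit_methylation",
    "fit_reduced",
    "fit_cytosines",
    "estimate_theta",
    "theta_summary_frame",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "cytosine_seed",
]


@dataclass(frozen=True)
class MethCountTable:
    """Per-cytosine, per-sample, per-technical-replicate count pairs.

    ``c`` and ``n`` are (n_cytosines, n_replicates) arrays of "C" and total
    counts; ``rep_to_sample`` maps each replicate column to its biological
    sample index (samples ordered as in ``sample_ids``).  A replicate with
    no coverage at a cytosine is encoded as ``n = 0`` and contributes a
    constant likelihood there.
    """

    chrom: np.ndarray
    pos: np.ndarray
    replicate_ids: Tuple[str, ...]
    sample_ids: Tuple[str, ...]
    rep_to_sample: np.ndarray
    c: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.int64)
        n = np.asarray(self.n, dtype=np.int64)
        if c.shape != n.shape or c.ndim != 2:
            raise ValueError("c and n must be matching 2-D arrays")
        if np.any(c < 0) or np.any(c > n):
            raise ValueError("need 0 <= c_count <= total_count everywhere")
        r2s = np.asarray(self.rep_to_sample, dtype=np.int64)
        if r2s.shape != (c.shape[1],):
            raise ValueError("rep_to_sample must have one entry per replicate")
        if len(self.sample_ids) < 1 or np.any(r2s < 0) or np.any(
            r2s >= len(self.sample_ids)
        ):
            raise ValueError("rep_to_sample indices out of range")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "rep_to_sample", r2s)
        object.__setattr__(self, "chrom", np.asarray(self.chrom))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_cytosines(self) -> int:
        return self.c.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cytosine_id(self, k: int) -> str:
        return f"{self.chrom[k]}:{self.pos[k]}"

    def restrict_replicates(self, keep: Sequence[str]) -> "MethCountTable":
        """Subset to the named replicates (e.g. good-conversion libraries)."""
        keep = list(keep)
        idx = [self.replicate_ids.index(r) for r in keep]
        return MethCountTable(
            chrom=self.chrom,
            pos=self.pos,
            replicate_ids=keep,
            sample_ids=self.sample_ids,
            rep_to_sample=self.rep_to_sample[idx],
            c=self.c[:, idx],
            n=self.n[:, idx],
        )


@dataclass(frozen=True)
class GLMSpec:
    """Design matrix and prior scales of the stage-2 model."""

    design: np.ndarray
    column_names: Tuple[str, ...] = ()
    sigma_b_sq: float = 5.0
    sigma_e_prior: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.sigma_b_sq <= 0 or min(self.sigma_e_prior) <= 0:
            raise ValueError("prior variances/shapes must be positive")
        object.__setattr__(self, "design", d)
        if not self.column_names:
            object.__setattr__(
                self,
                "column_names",
                tuple(f"b{j}" for j in range(d.shape[1])),
            )

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    @classmethod
    def intercept_only(cls, n_samples: int, **kw) -> "GLMSpec":
        return cls(
            design=np.ones((n_samples, 1)), column_names=("intercept",), **kw
        )


@dataclass(frozen=True)
class GLMLatents:
    """One deterministic realisation of the GLM latents.

    ``Y = D B + E`` exactly; ``theta`` is the methylated component of the
    row-wise softmax of Y.
    """

    B: np.ndarray
    E: np.ndarray

    def realise(self, design: np.ndarray):
        y = design @ self.B + self.E
        theta = expit(y[:, 0] - y[:, 1])
        return y, theta


def build_design_matrix(design_table: pd.DataFrame, **spec_kw) -> GLMSpec:
    """Assemble a GLMSpec from a per-sample covariate table.

    Expects one row per biological sample, covariates numeric.  A constant
    intercept column is prepended unless one is already present.  A
    rank-deficient design triggers a warning that reports a null-space
    basis rather than an error (the proper priors keep the posterior well
    defined).
    """
    df = design_table.copy()
    for drop in ("sample_id", "replicate_id"):
        if drop in df.columns:
            df = df.drop(columns=drop)
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError("design covariates must be numeric")
    mat = df.to_numpy(dtype=float)
    names = list(df.columns)
    has_const = any(
        np.ptp(mat[:, j]) == 0 and mat[0, j] != 0 for j in range(mat.shape[1])
    )
    if not has_const:
        mat = np.column_stack([np.ones(mat.shape[0]), mat])
        names = ["intercept"] + names
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, _, vt = np.linalg.svd(mat)
        null = vt[rank:]
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {mat.shape[1]}); "
            f"null-space basis rows: {np.round(null, 4).tolist()}",
            RuntimeWarning,
        )
    return GLMSpec(design=mat, column_names=tuple(names), **spec_kw)


class GLMModel:
    """Log posterior of the stage-2 model for a single cytosine.

    Unconstrained state: ``[vec(B) (p*2, row-major), vec(E) (N*2),
    log sigma_E^2]``.  Counts and experimental parameters enter as fixed
    per-replicate constants, so the per-entry readout probabilities are
    affine in theta and all gradients are closed-form.
    """

    def __init__(
        self,
        c: np.ndarray,
        n: np.ndarray,
        rep_to_sample: np.ndarray,
        params: Sequence[ExperimentalParams],
        spec: GLMSpec,
    ) -> None:
        c = np.asarray(c, dtype=float)
        n = np.asarray(n, dtype=float)
        if len(params) != c.size:
            raise ValueError(
                f"got {len(params)} ExperimentalParams for {c.size} "
                "replicate count pairs"
            )
        self.spec = spec
        self.D = spec.design
        self.N = spec.n_samples
        self.p = spec.n_params
        if rep_to_sample.max(initial=-1) >= self.N:
            raise ValueError("replicate maps to sample beyond design rows")
        self._c = c
        self._n = n
        self._i = np.asarray(rep_to_sample, dtype=np.int64)
        bs = np.array([q.bs_eff for q in params])
        err = np.array([q.seq_err for q in params])
        bss = np.array([q.bs_star_eff for q in params])
        self._pc = (1.0 - bs) * (1.0 - err) + bs * err
        self._p5 = (1.0 - bss) * (1.0 - err) + bss * err
        self.n_free = 2 * self.p + 2 * self.N + 1

    def _split(self, z: np.ndarray):
        m = z.shape[0]
        p, N = self.p, self.N
        B = z[:, : 2 * p].reshape(m, p, 2)
        E = z[:, 2 * p : 2 * p + 2 * N].reshape(m, N, 2)
        u = z[:, -1]
        return B, E, u

    def theta(self, z: np.ndarray) -> np.ndarray:
        B, E, _ = self._split(np.atleast_2d(z))
        y = np.einsum("np,mpk->mnk", self.D, B) + E
        return expit(y[:, :, 0] - y[:, :, 1])

    def logp_and_grad(self, z: np.ndarray):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        B, E, u = self._split(z)
        a, b = self.spec.sigma_e_prior
        sb2 = self.spec.sigma_b_sq
        y = np.einsum("np,mpk->mnk", self.D, B) + E
        th = expit(y[:, :, 0] - y[:, :, 1])  # (m, N)

        th_e = th[:, self._i]  # (m, J)
        p = th_e * self._p5[None, :] + (1.0 - th_e) * self._pc[None, :]
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        c, n = self._c[None, :], self._n[None, :]
        lp = (c * np.log(p) + (n - c) * np.log1p(-p)).sum(axis=1)

        dlp_dp = c / p - (n - c) / (1.0 - p)
        g_th_e = dlp_dp * (self._p5 - self._pc)[None, :]
        g_th = np.zeros_like(th)
        np.add.at(g_th.T, self._i, g_th_e.T)  # scatter replicate -> sample
        g_d = g_th * th * (1.0 - th)  # d lp / d (y0 - y1)
        gY = np.stack([g_d, -g_d], axis=2)  # (m, N, 2)

        e_neg_u = np.exp(-u)
        gB = np.einsum("np,mnk->mpk", self.D, gY) - B / sb2
        gE = gY - E * e_neg_u[:, None, None]
        sumE2 = (E**2).sum(axis=(1, 2))
        gu = 0.5 * sumE2 * e_neg_u - self.N - a + b * e_neg_u

        lp = (
            lp
            - 0.5 * (B**2).sum(axis=(1, 2)) / sb2
            - 0.5 * sumE2 * e_neg_u
            - self.N * u
            - a * u
            - b * e_neg_u
        )
        m = z.shape[0]
        grad = np.concatenate(
            [gB.reshape(m, -1), gE.reshape(m, -1), gu[:, None]], axis=1
        )
        return lp, grad

    def constrain(self, z: np.ndarray) -> Dict[str, np.ndarray]:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        B, E, u = self._split(z)
        y = np.einsum("np,mpk->mnk", self.D, B) + E
        return {
            "B": B,
            "E": E,
            "Y": y,
            "theta": expit(y[:, :, 0] - y[:, :, 1]),
            "sigma_e_sq": np.exp(u),
        }


def cytosine_seed(master_seed: int, index: int) -> int:
    """Deterministic per-cytosine seed derived from the master seed."""
    return int(
        np.random.SeedSequence([int(master_seed), int(index)]).generate_state(
            1
        )[0]
        % (2**31)
    )


def fit_methylation(
    counts: MethCountTable,
    params: Sequence[ExperimentalParams],
    spec: GLMSpec,
    inference: InferenceConfig = InferenceConfig(),
    *,
    cytosine: int = 0,
) -> PosteriorDraws:
    """Fit the full model for one cytosine of ``counts``.

    ``params`` supplies one entry per replicate column of ``counts`` (the
    stage-1 posterior means).  The returned draws contain ``B``, ``E``,
    ``Y``, ``theta`` and ``sigma_e_sq``.
    """
    model = GLMModel(
        counts.c[cytosine],
        counts.n[cytosine],
        counts.rep_to_sample,
        params,
        spec,
    )
    return run_inference(model, inference)


def fit_reduced(
    counts: MethCountTable,
    spec: GLMSpec,
    inference: InferenceConfig = InferenceConfig(),
    *,
    cytosine: int = 0,
) -> PosteriorDraws:
    """Baseline fit with ideal experimental parameters (1, 0, 0).

    The caller restricts ``counts`` to the replicates the traditional
    workflow would keep (see
    :meth:`MethCountTable.restrict_replicates`); this function only forces
    the parameters, so passing the full replicate set makes it identical to
    :func:`fit_methylation` with ideal parameters.
    """
    ideal = [ExperimentalParams.ideal()] * len(counts.replicate_ids)
    return fit_methylation(
        counts, ideal, spec, inference, cytosine=cytosine
    )


def fit_cytosines(
    counts: MethCountTable,
    params: Sequence[ExperimentalParams],
    spec: GLMSpec,
    inference: InferenceConfig = InferenceConfig(),
    *,
    reduced: bool = False,
) -> List[PosteriorDraws]:
    """Independent per-cytosine fits, seeded per cytosine from the master seed."""
    out = []
    for k in range(counts.n_cytosines):
        cfg = inference.with_seed(cytosine_seed(inference.seed, k))
        if reduced:
            out.append(fit_reduced(counts, spec, cfg, cytosine=k))
        else:
            out.append(fit_methylation(counts, params, spec, cfg, cytosine=k))
    return out


def estimate_theta(draws: PosteriorDraws, interval: float = 0.95):
    """Posterior mean and central credible interval of theta per sample.

    Returns a dict of arrays ``mean``, ``low``, ``high`` (length N).
    """
    th = np.atleast_2d(draws["theta"])
    lo = 50.0 * (1.0 - interval)
    return {
        "mean": th.mean(axis=0),
        "low": np.percentile(th, lo, axis=0),
        "high": np.percentile(th, 100.0 - lo, axis=0),
    }


def theta_summary_frame(
    counts: MethCountTable, fits: Sequence[PosteriorDraws]
) -> pd.DataFrame:
    """Per-cytosine theta summaries in the output TSV layout."""
    rows = []
    for k, d in enumerate(fits):
        est = estimate_theta(d)
        row = {"chrom": counts.chrom[k], "pos": int(counts.pos[k])}
        for s, sid in enumerate(counts.sample_ids):
            row[f"{sid}_theta_mean"] = est["mean"][s]
            row[f"{sid}_theta_low"] = est["low"][s]
            row[f"{sid}_theta_high"] = est["high"][s]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV interface


def read_design_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("replicate_id", "sample_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_counts_tsv(path, design_table: pd.DataFrame) -> MethCountTable:
    """Read a methylation count TSV against its replicate/sample design.

    Layout: ``chrom``, ``pos``, then ``<replicate_id>_C`` and
    ``<replicate_id>_total`` column pairs for every replicate in the design.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    replicate_ids = [str(r) for r in design_table["replicate_id"]]
    sample_ids = list(dict.fromkeys(str(s) for s in design_table["sample_id"]))
    rep_to_sample = np.array(
        [sample_ids.index(str(s)) for s in design_table["sample_id"]]
    )
    missing = [
        col
        for rid in replicate_ids
        for col in (f"{rid}_C", f"{rid}_total")
        if col not in df.columns
    ]
    if missing:
        raise ValueError(
            f"{path}: missing replicate column(s) {', '.join(missing)}"
        )
    c = np.column_stack([df[f"{r}_C"].to_numpy() for r in replicate_ids])
    n = np.column_stack([df[f"{r}_total"].to_numpy() for r in replicate_ids])
    return MethCountTable(
        chrom=df["chrom"].to_numpy(),
        pos=df["pos"].to_numpy(),
        replicate_ids=replicate_ids,
        sample_ids=sample_ids,
        rep_to_sample=rep_to_sample,
        c=c,
        n=n,
    )


def write_counts_tsv(counts: MethCountTable, path) -> None:
    data = {"chrom": counts.chrom, "pos": counts.pos}
    for j, rid in enumerate(counts.replicate_ids):
        data[f"{rid}_C"] = counts.c[:, j]
        data[f"{rid}_total"] = counts.n[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_bedgraph(counts: MethCountTable, directory) -> None:
    """Per-replicate bedGraph-style methylation fraction tracks.

    One 0-based half-open interval per covered cytosine with the raw
    C-fraction as the value; zero-coverage cytosines are omitted.  Lossy
    (fractions, not counts) — provided for genome-browser interoperability.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for j, rid in enumerate(counts.replicate_ids):
        covered = counts.n[:, j] > 0
        df = pd.DataFrame(
            {
                "chrom": counts.chrom[covered],
                "start": counts.pos[covered] - 1,
                "end": counts.pos[covered],
                "fraction": counts.c[covered, j] / counts.n[covered, j],
            }
        )
        df.to_csv(
            directory / f"{rid}.bedGraph", sep="\t", index=False,
            header=False,
        )


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph-style track back into a tidy frame (1-based pos)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "fraction"],
    )
    df["pos"] = df["end"]
    return df[["chrom", "pos", "fraction"]]
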