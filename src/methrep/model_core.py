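"""Observation model for bisulfite-converted sequencing readouts.

Bisulfite treatment converts unmethylated cytosine (C) to uracil, read out
as "T" after PCR and sequencing, while 5-methylcytosine (5mC) is protected
and reads out as "C".  The conversion is imperfect: a library has a
bisulfite conversion efficiency ``bs_eff`` (probability that an
unmethylated C is actually converted), an incorrect-conversion rate
``bs_star_eff`` (probability that a methylated C is converted anyway) and a
sequencing error rate ``seq_err``.  The probability of reading "C" at a
cytosine is a mixture of the two conditional readout probabilities weighted
by the methylation level ``theta``.

These are pure functions shared by the inference models and the synthetic
data generators.  The methylation state space is the two-state simplex
(C, 5mC); a third state (5hmC) is a documented extension point but is not
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ExperimentalParams",
    "LogisticNormalHyper",
    "LogisticNormalState",
    "DEFAULT_BS_STAR_EFF",
    "BS_EFF_HYPER",
    "SEQ_ERR_HYPER",
    "prob_c_given_c",
    "prob_c_given_5mc",
    "prob_c",
    "logistic_normal_transform",
]

#: Incorrect bisulfite conversion rate used when no methylated control DNA is
#: available to estimate it (0.1%).
DEFAULT_BS_STAR_EFF = 0.001


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ExperimentalParams:
    """Library-specific experimental parameters of one technical replicate.

    Attributes
    ----------
    bs_eff:
        Bisulfite conversion efficiency, P(unmethylated C is converted).
    seq_err:
        Sequencing error rate, P(base is misread).
    bs_star_eff:
        Incorrect conversion rate, P(methylated C is converted).  Fixed to a
        constant (default 0.001) because libraries typically lack fully
        methylated spike-in controls.
    """

    bs_eff: float
    seq_err: float
    bs_star_eff: float = DEFAULT_BS_STAR_EFF

    def __post_init__(self) -> None:
        _check_prob("bs_eff", self.bs_eff)
        _check_prob("seq_err", self.seq_err)
        _check_prob("bs_star_eff", self.bs_star_eff)

    @classmethod
    def ideal(cls) -> "ExperimentalParams":
        """Perfect instrument: full conversion, no errors."""
        return cls(bs_eff=1.0, seq_err=0.0, bs_star_eff=0.0)


@dataclass(frozen=True)
class LogisticNormalHyper:
    """Hyperparameters of a logistic-normal prior on a probability.

    The probability is ``logit^{-1}(mu + sigma * r)`` with
    ``mu ~ N(psi_mu_mu, psi_mu_sigma)``, ``ln(sigma) ~ N(psi_sigma_mu,
    psi_sigma_sigma)`` and ``r ~ N(0, 1)``; the psi's are the fixed
    hyperparameters collected here (scales are standard deviations).
    """

    psi_mu_mu: float
    psi_mu_sigma: float
    psi_sigma_mu: float
    psi_sigma_sigma: float

    def __post_init__(self) -> None:
        if self.psi_mu_sigma <= 0 or self.psi_sigma_sigma <= 0:
            raise ValueError("hyperprior scales must be strictly positive")


#: Default hyperparameters for the conversion-efficiency prior
#: (prior median of bs_eff is logit^{-1}(4) ~ 0.982).
BS_EFF_HYPER = LogisticNormalHyper(4.0, 1.29, 0.4, 0.5)

#: Default hyperparameters for the sequencing-error prior
#: (prior median of seq_err is logit^{-1}(-8) ~ 3.4e-4).
SEQ_ERR_HYPER = LogisticNormalHyper(-8.0, 1.29, 0.4, 0.5)


@dataclass(frozen=True)
class LogisticNormalState:
    """A realisation (mu, ln sigma, r) of the logistic-normal hierarchy."""

    mu: float
    log_sigma: float
    r: float

    def __post_init__(self) -> None:
        for name in ("mu", "log_sigma", "r"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def prob_c_given_c(bs_eff, seq_err):
    """P("C" readout | unmethylated C).

    Either the cytosine escapes conversion and is read correctly, or it is
    converted and the resulting T is misread as C:
    ``(1 - bs_eff) (1 - seq_err) + bs_eff seq_err``.
    """
    _check_prob("bs_eff", bs_eff)
    _check_prob("seq_err", seq_err)
    bs_eff = np.asarray(bs_eff, dtype=float)
    seq_err = np.asarray(seq_err, dtype=float)
    out = (1.0 - bs_eff) * (1.0 - seq_err) + bs_eff * seq_err
    return out if out.ndim else float(out)


def prob_c_given_5mc(bs_star_eff, seq_err):
    """P("C" readout | methylated C).

    Either the 5mC is (correctly) not converted and read correctly, or it is
    erroneously converted and the T misread as C:
    ``(1 - bs_star_eff) (1 - seq_err) + bs_star_eff seq_err``.
    """
    _check_prob("bs_star_eff", bs_star_eff)
    _check_prob("seq_err", seq_err)
    bs_star_eff = np.asarray(bs_star_eff, dtype=float)
    seq_err = np.asarray(seq_err, dtype=float)
    out = (1.0 - bs_star_eff) * (1.0 - seq_err) + bs_star_eff * seq_err
    return out if out.ndim else float(out)


def prob_c(theta, params: ExperimentalParams):
    """Marginal P("C" readout) at a cytosine with methylation level ``theta``.

    Convex mixture of the conditional readout probabilities,
    ``p("C"|5mC) theta + p("C"|C) (1 - theta)``.  With the ideal instrument
    (1, 0, 0) this reduces to ``theta`` itself.
    """
    _check_prob("theta", theta)
    theta = np.asarray(theta, dtype=float)
    p5 = prob_c_given_5mc(params.bs_star_eff, params.seq_err)
    pc = prob_c_given_c(params.bs_eff, params.seq_err)
    out = theta * p5 + (1.0 - theta) * pc
    return out if out.ndim else float(out)


def logistic_normal_transform(state: LogisticNormalState) -> float:
    """Map a logistic-normal state to its probability.

    Returns ``logit^{-1}(mu + exp(log_sigma) * r)``, always in the open
    interval (0, 1).  ``scipy.special.expit`` is overflow-safe for any
    finite argument but rounds to exactly 0 or 1 beyond |x| ~ 37; the
    result is nudged to the nearest representable interior value so the
    open-interval contract holds for all finite states.
    """
    val = float(expit(state.mu + np.exp(state.log_sigma) * state.r))
    return float(
        np.clip(val, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    )
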