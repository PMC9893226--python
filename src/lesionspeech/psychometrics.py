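"""Logistic psychometric fitting for word report over log2 channel count.

The response curve is

    f(x) = gamma + (1 - gamma - lambda) / (1 + exp(-beta * (x - alpha)))

with x = log2(number of vocoder channels), guess rate gamma fixed at 0 for
this open-set task and the lapse rate lambda fixed per participant at 1 minus
their observed clear-speech accuracy.  alpha is the location: with gamma = 0
and lambda = 0 the curve passes through 50% exactly at x = alpha, so
2**alpha is the threshold number of channels at which 50% word report is
predicted.  Parameters are estimated by direct maximisation of the binomial
likelihood from multiple deterministic starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "CLEAR_CHANNELS",
    "PsychometricFit",
    "ChannelCondition",
    "psychometric",
    "fit_participant",
    "threshold_channels",
    "adaptation_effect",
    "ALPHA_BOUNDS",
    "BETA_BOUNDS",
]

#: clear speech is treated as equivalent to this many vocoder channels
CLEAR_CHANNELS = 32

ALPHA_BOUNDS = (0.0, 6.0)   # 1 .. 64 channels
BETA_BOUNDS = (0.05, 20.0)
_PCLIP = 1e-9


@dataclass(frozen=True)
class ChannelCondition:
    """Pooled word-report counts at one degradation level."""

    channels: int
    k_correct: int
    n_words: int

    def __post_init__(self):
        if not 0 <= self.k_correct <= self.n_words:
            raise ValueError("require 0 <= k_correct <= n_words")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")

    @property
    def x(self) -> float:
        return float(np.log2(self.channels))


@dataclass(frozen=True)
class PsychometricFit:
    alpha: float
    beta: float
    gamma: float
    lambda_: float
    log_likelihood: float
    converged: bool
    phase: str = "pooled"


def psychometric(x, alpha: float, beta: float, gamma: float = 0.0,
                 lambda_: float = 0.0):
    """Four-parameter logistic; strictly increasing in x, range (gamma, 1-lambda)."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    x = np.asarray(x, dtype=float)
    out = gamma + (1.0 - gamma - lambda_) / (1.0 + np.exp(-beta * (x - alpha)))
    return float(out) if out.ndim == 0 else out


def _neg_log_likelihood(params, xs, ks, ns, lambda_):
    alpha, beta = params
    p = psychometric(xs, alpha, max(beta, 1e-12), 0.0, lambda_)
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    return -float(np.sum(ks * np.log(p) + (ns - ks) * np.log1p(-p)))


def fit_participant(conditions, clear_accuracy: float,
                    phase: str = "pooled") -> PsychometricFit:
    """Maximum-likelihood fit of (alpha, beta) with gamma = 0 and lambda fixed.

    Parameters
    ----------
    conditions
        ``ChannelCondition`` records; at least two distinct channel counts
        with nonzero word totals are required.
    clear_accuracy
        Proportion correct for clear speech; the lapse rate is fixed at
        ``1 - clear_accuracy``.
    phase
        Label carried through to the fit (``pre``/``post``/``pooled``).

    Returns
    -------
    PsychometricFit
        Degenerate data (all correct or all wrong at every level) returns a
        fit pinned at the parameter bounds with ``converged=False`` rather
        than raising.
    """
    if not 0.0 <= clear_accuracy <= 1.0:
        raise ValueError("clear_accuracy must be in [0, 1]")
    conds = [c for c in conditions if c.n_words > 0]
    xs = np.array([c.x for c in conds])
    if np.unique(xs).size < 2:
        raise ValueError("need >= 2 distinct channel levels with data")
    ks = np.array([c.k_correct for c in conds], dtype=float)
    ns = np.array([c.n_words for c in conds], dtype=float)
    lambda_ = 1.0 - clear_accuracy

    if ks.sum() == 0 or ks.sum() == ns.sum():
        # no gradient information: pin at the appropriate bound
        alpha = ALPHA_BOUNDS[1] if ks.sum() == 0 else ALPHA_BOUNDS[0]
        ll = -_neg_log_likelihood((alpha, BETA_BOUNDS[0]), xs, ks, ns, lambda_)
        return PsychometricFit(alpha=alpha, beta=BETA_BOUNDS[0], gamma=0.0,
                               lambda_=lambda_, log_likelihood=ll,
                               converged=False, phase=phase)

    # deterministic multi-start over the admissible box
    starts = [(2.0, 1.0), (3.0, 2.0), (4.0, 0.5), (1.0, 4.0), (5.0, 1.5)]
    best = None
    for s in starts:
        res = minimize(_neg_log_likelihood, s, args=(xs, ks, ns, lambda_),
                       method="L-BFGS-B", bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
                       options={"ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    alpha, beta = best.x
    return PsychometricFit(alpha=float(alpha), beta=float(beta), gamma=0.0,
                           lambda_=lambda_, log_likelihood=-float(best.fun),
                           converged=bool(best.success), phase=phase)


def threshold_channels(fit: PsychometricFit) -> float:
    """Channel count at which 50% word report is predicted (2**alpha)."""
    return float(2.0 ** fit.alpha)


def adaptation_effect(fit_pre: PsychometricFit, fit_post: PsychometricFit) -> float:
    """Training effect in log2 channels, alpha_pre - alpha_post (positive = improvement)."""
    if fit_pre.phase == "post" or fit_post.phase == "pre":
        raise ValueError(
            f"phase mismatch: got ({fit_pre.phase!r}, {fit_post.phase!r}), "
            "expected (pre, post)")
    return float(fit_pre.alpha - fit_post.alpha)
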