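"""Lesion-behaviour inference: directional Pearson correlations and Meng's z
for comparing dependent, overlapping correlations.

Meng's z is implemented directly from the published formula (Meng, Rosenthal
& Rubin, 1986) rather than wrapped from an external package, so that the
dependent-correlation comparison can be unit-tested against simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ComparisonResult",
    "pearson_one_tailed",
    "fisher_z",
    "meng_z",
]

#: accepted aliases for the hypothesised direction of a correlation
_POSITIVE = {"positive", "damage_impairs", "greater"}
_NEGATIVE = {"negative", "damage_improves", "less"}


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with a one-tailed p value."""

    r: float
    n: int
    p_one_tailed: float
    direction: str

    @property
    def p_two_tailed(self) -> float:
        return min(1.0, 2.0 * min(self.p_one_tailed, 1.0 - self.p_one_tailed))


@dataclass(frozen=True)
class ComparisonResult:
    """Meng's z comparison of two correlations sharing one variable."""

    r1: float
    r2: float
    r12: float
    n: int
    z: float
    p_two_tailed: float


def pearson_one_tailed(x, y, direction: str = "positive") -> CorrelationResult:
    """Pearson's r with a one-tailed p value in the hypothesised direction.

    Correlations opposite to the hypothesis yield p > 0.5; the two one-tailed
    p values for opposite directions sum to 1.

    Parameters
    ----------
    x, y
        Paired finite observations, length >= 4.
    direction
        ``"positive"`` (alias ``"damage_impairs"``) tests r > 0;
        ``"negative"`` (alias ``"damage_improves"``) tests r < 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    if direction in _POSITIVE:
        alternative = "greater"
    elif direction in _NEGATIVE:
        alternative = "less"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    res = sps.pearsonr(x, y, alternative=alternative)
    return CorrelationResult(r=float(res.statistic), n=n,
                             p_one_tailed=float(res.pvalue), direction=direction)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform artanh(r); odd in r."""
    r = float(r)
    if not math.isfinite(r) or abs(r) >= 1.0:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return math.atanh(r)


def _check_triple(r1: float, r2: float, r12: float) -> None:
    # the 3x3 correlation matrix [[1,r1,r2],[r1,1,r12],[r2,r12,1]] must be PSD
    m = np.array([[1.0, r1, r2], [r1, 1.0, r12], [r2, r12, 1.0]])
    eigmin = np.linalg.eigvalsh(m)[0]
    if eigmin < -1e-10:
        raise ValueError(
            f"infeasible correlation triple r1={r1}, r2={r2}, r12={r12}")


def meng_z(r1: float, r2: float, r12: float, n: int) -> ComparisonResult:
    """Compare two dependent correlations r1 = r(x1, y), r2 = r(x2, y).

    Computes z = (z1 - z2) * sqrt((n - 3) / (2 (1 - r12) h)) where z1, z2
    are Fisher transforms, rbar2 = (r1^2 + r2^2) / 2,
    f = min(1, (1 - r12) / (2 (1 - rbar2))) and h = (1 - f rbar2) / (1 - rbar2),
    with a two-tailed standard-normal p value.
    """
    r1, r2, r12 = float(r1), float(r2), float(r12)
    n = int(n)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if abs(r12) > 1.0:
        raise ValueError("r12 must lie in [-1, 1]")
    _check_triple(r1, r2, r12)
    if r1 == r2 or r12 == 1.0:
        # identical predictors or identical correlations: no difference to
        # test (r12 = 1 forces r1 = r2 by positive semidefiniteness)
        return ComparisonResult(r1=r1, r2=r2, r12=r12, n=n, z=0.0,
                                p_two_tailed=1.0)
    z1, z2 = fisher_z(r1), fisher_z(r2)
    rbar2 = (r1 * r1 + r2 * r2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return ComparisonResult(r1=r1, r2=r2, r12=r12, n=n, z=float(z),
                            p_two_tailed=float(min(p, 1.0)))
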