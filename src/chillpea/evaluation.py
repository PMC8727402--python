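"""Goodness-of-fit statistics between simulated and measured series.

RMSD here uses an N-1 divisor (as conventionally reported alongside the
Willmott index in the crop-modelling literature); the conventional 1/N form
is available via ``divisor="n"``.  Willmott's index of agreement d is
bounded in [0, 1] with 1 for perfect agreement, and R^2 is the squared
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["GofReport", "rmsd", "willmott_d", "r_squared", "evaluate_pairs"]


def _pairs(s: Sequence[float], m: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    if s.shape != m.shape or s.ndim != 1:
        raise ValueError("simulated and measured series must be equal-length 1-D")
    return s, m


def rmsd(s: Sequence[float], m: Sequence[float], divisor: str = "n_minus_1") -> float:
    """Root-mean-square deviation, sqrt(sum((S-M)^2) / (N-1)) by default."""
    s, m = _pairs(s, m)
    n = len(s)
    if n < 2:
        raise ValueError("RMSD requires at least 2 pairs (divides by N - 1)")
    if divisor == "n_minus_1":
        denom = n - 1
    elif divisor == "n":
        denom = n
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    return float(np.sqrt(np.sum((s - m) ** 2) / denom))


def willmott_d(s: Sequence[float], m: Sequence[float]) -> Optional[float]:
    """Willmott's index of agreement.

    d = 1 - sum((S-M)^2) / sum((|S - Mbar| + |M - Mbar|)^2) with Mbar the
    measured mean.  Returns None when the denominator is zero (all values
    equal to the measured mean), where d is undefined.
    """
    s, m = _pairs(s, m)
    mbar = m.mean()
    denom = float(np.sum((np.abs(s - mbar) + np.abs(m - mbar)) ** 2))
    if denom == 0.0:
        return None
    return float(1.0 - np.sum((s - m) ** 2) / denom)


def r_squared(s: Sequence[float], m: Sequence[float]) -> Optional[float]:
    """Squared Pearson correlation; None when either series is constant."""
    s, m = _pairs(s, m)
    if np.std(s) == 0.0 or np.std(m) == 0.0:
        return None
    return float(np.corrcoef(s, m)[0, 1] ** 2)


@dataclass
class GofReport:
    rmsd: float
    d: Optional[float]
    r_squared: Optional[float]
    n: int


def evaluate_pairs(
    s: Sequence[float], m: Sequence[float], divisor: str = "n_minus_1"
) -> GofReport:
    """All three statistics for one simulated/measured pairing."""
    s_arr, m_arr = _pairs(s, m)
    return GofReport(
        rmsd=rmsd(s_arr, m_arr, divisor=divisor),
        d=willmott_d(s_arr, m_arr),
        r_squared=r_squared(s_arr, m_arr),
        n=len(s_arr),
    )
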