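"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero at `ndigits` decimal places.

    Python's built-in ``round`` is banker's rounding; reported rates in this
    package use the conventional half-up rule (0.615 -> 0.62 at 2 dp).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def zscore(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z-score a 1-D array; constant input maps to all zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def fractional_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks scaled to (0, 1] (rank / n)."""
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    return rankdata(x) / x.size


def minmax(x: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; constant input maps to all zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)
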