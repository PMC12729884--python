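"""Quartile stratification into LOX / DTOX / HOX and mito-threshold sensitivity.

Cells below the first quartile of the composite oxidative-stress score form
the low-stress LOX stratum, cells above the third quartile the high-stress
HOX stratum, and the inclusive interquartile interval the dynamic-transient
DTOX stratum.  Quartiles use linear-interpolation (type 7) quantiles, which
on n distinct scores puts floor(n/4) cells strictly outside each hinge —
e.g. 64,510 distinct scores split exactly 16,128 / 32,254 / 16,128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .exceptions import DegenerateDataError, MetadataError

STRATA = ("LOX", "DTOX", "HOX")


@dataclass
class StratumThresholds:
    q1: float
    q3: float
    quantile_method: str = "linear-interpolation, type 7"

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError("q1 must not exceed q3")


@dataclass
class StratumAssignment:
    labels: pd.Series               # per-cell label in {LOX, DTOX, HOX}
    counts: dict[str, int]
    thresholds: StratumThresholds

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)

    def to_dict(self) -> dict:
        return {
            "q1": self.thresholds.q1,
            "q3": self.thresholds.q3,
            "counts": dict(self.counts),
        }


def quantile_thresholds(scores: np.ndarray | pd.Series) -> StratumThresholds:
    """Q1/Q3 by linear-interpolation quantiles (scores 1..8 -> 2.75, 6.25)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 4:
        raise DegenerateDataError(f"need at least 4 scores, got {x.size}")
    if not np.isfinite(x).all():
        raise DegenerateDataError("scores must be finite")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # numpy default: linear, type 7
    return StratumThresholds(q1=float(q1), q3=float(q3))


def assign_strata(
    scores: np.ndarray | pd.Series, thresholds: StratumThresholds | None = None
) -> StratumAssignment:
    """Label every cell: LOX (< Q1), HOX (> Q3), DTOX (Q1 <= score <= Q3).

    Boundary cells exactly at a hinge are DTOX (inclusive interval).
    """
    if isinstance(scores, pd.Series):
        index = scores.index
        x = scores.to_numpy(dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
        index = pd.RangeIndex(x.size)
    if thresholds is None:
        thresholds = quantile_thresholds(x)
    labels = np.full(x.shape, "DTOX", dtype=object)
    labels[x < thresholds.q1] = "LOX"
    labels[x > thresholds.q3] = "HOX"
    series = pd.Series(labels.astype(str), index=index, name="stratum")
    counts = {s: int((series == s).sum()) for s in STRATA}
    return StratumAssignment(labels=series, counts=counts, thresholds=thresholds)


def mito_sensitivity(
    adata: AnnData,
    scores: pd.Series,
    thresholds_list: list[float] | None = None,
    recompute_quartiles: bool = True,
) -> pd.DataFrame:
    """HOX-proportion stability across mitochondrial-content cutoffs.

    For each threshold (fraction of mito content; 0.05-0.30 by default),
    cells at or above the cutoff are removed, quartiles are optionally
    re-derived on the retained scores, and the HOX proportion among
    retained cells is reported.  Columns: mito_max, n_retained,
    hox_proportion (NaN when no cell survives).
    """
    if "percent_mt" not in adata.obs.columns:
        raise MetadataError("percent_mt missing from cell metadata")
    if thresholds_list is None:
        thresholds_list = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
    mt = adata.obs["percent_mt"].to_numpy(dtype=float)
    scores = scores.loc[adata.obs_names]
    base_thr = quantile_thresholds(scores.to_numpy())
    rows = []
    for cutoff in thresholds_list:
        keep = mt < 100.0 * cutoff
        retained = scores[keep]
        if retained.size == 0:
            rows.append({"mito_max": cutoff, "n_retained": 0,
                         "hox_proportion": np.nan})
            continue
        thr = (
            quantile_thresholds(retained.to_numpy())
            if recompute_quartiles and retained.size >= 4
            else base_thr
        )
        assignment = assign_strata(retained, thr)
        rows.append(
            {
                "mito_max": cutoff,
                "n_retained": int(retained.size),
                "hox_proportion": assignment.counts["HOX"] / retained.size,
            }
        )
    return pd.DataFrame(rows)
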