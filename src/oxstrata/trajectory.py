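"""Cellular plasticity and principal-curve pseudotime.

Plasticity is quantified per cell as the variance of log-normalized
expression over highly variable genes (HVGs), with Shannon entropy of the
cell's expression proportions reported alongside.  Raw variance is
residualized by ordinary least squares against library size, detected
features, and mitochondrial fraction, and the residual is Z-scored into the
final plasticity score.

Pseudotime comes from a principal curve fitted in the top principal-
component space of the HVG expression, by the classical alternating
projection/smoothing iteration initialized from PC1.  Arc-length position
along the curve is linearly rescaled to [0,1] and oriented so the
low-stress (LOX) centroid sits near the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from sklearn.decomposition import PCA

from ._utils import zscore
from .exceptions import DegenerateDataError
from .scoring import NormalizedExpression
from .stratify import StratumAssignment


@dataclass
class HVGSet:
    genes: list[str]
    dispersion: pd.Series  # variance statistic per selected gene, descending


@dataclass
class PlasticityScores:
    raw_variance: pd.Series
    entropy: pd.Series
    residual: pd.Series
    z: pd.Series


@dataclass
class TrajectoryResult:
    pcs: pd.DataFrame            # per-cell PC coordinates
    pseudotime: pd.Series        # in [0,1]
    root_coord: float            # mean PC1 of LOX cells
    pc1_score_rho: float         # Spearman(PC1, composite)


def select_hvgs(expr: NormalizedExpression, n: int = 2000) -> HVGSet:
    """Top-n genes by variance of log-normalized expression.

    Ties are broken by gene identifier so repeated calls give identical
    ordering.
    """
    var = expr.X.var(axis=0)
    stats = pd.Series(var, index=expr.genes)
    ordered = stats.sort_values(ascending=False, kind="stable")
    # deterministic tie-break: within equal variance, sort by gene id
    ordered = (
        ordered.to_frame("v")
        .assign(g=ordered.index)
        .sort_values(["v", "g"], ascending=[False, True], kind="stable")["v"]
    )
    top = ordered.iloc[: min(n, len(ordered))]
    return HVGSet(genes=list(top.index), dispersion=top)


def plasticity_raw(
    expr: NormalizedExpression, hvgs: HVGSet
) -> tuple[pd.Series, pd.Series]:
    """Per-cell (variance, entropy) over the HVG panel.

    Entropy (natural log) is computed on the cell's expression proportions
    after undoing the log1p transform; an all-zero cell gets entropy 0 and
    variance 0.
    """
    if not hvgs.genes:
        raise DegenerateDataError("HVG set is empty")
    idx = expr.gene_indices(hvgs.genes, "(plasticity)")
    sub = expr.X[:, idx]
    raw_var = sub.var(axis=1)
    counts = np.expm1(sub)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with no HVG expression")
    p = counts / np.where(zero, 1.0, totals)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1)
    entropy[zero] = 0.0
    return (
        pd.Series(raw_var, index=expr.cells, name="raw_variance"),
        pd.Series(entropy, index=expr.cells, name="entropy"),
    )


def residualize(
    raw: pd.Series, covariates: pd.DataFrame, entropy: pd.Series | None = None
) -> PlasticityScores:
    """OLS-residualize raw plasticity on QC covariates and Z-score.

    ``covariates`` should carry n_count, n_feature and percent_mt (any
    numeric columns are accepted).  Collinear columns are dropped with a
    warning; residuals are orthogonal to the retained design.
    """
    y = raw.to_numpy(dtype=float)
    if y.size <= 4:
        raise DegenerateDataError("need more than 4 cells to residualize")
    X = covariates.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        dropped = [
            covariates.columns[i - 1] for i in np.where(~keep)[0] if i > 0
        ]
        warnings.warn(f"dropping collinear covariate(s): {dropped}")
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return PlasticityScores(
        raw_variance=raw.copy(),
        entropy=(entropy if entropy is not None
                 else pd.Series(np.nan, index=raw.index, name="entropy")),
        residual=pd.Series(resid, index=raw.index, name="residual"),
        z=pd.Series(zscore(resid), index=raw.index, name="z"),
    )


# ---------------------------------------------------------------------------
# principal curve
# ---------------------------------------------------------------------------

def _smooth_nodes(points: np.ndarray, lam: np.ndarray, span: float,
                  n_nodes: int) -> np.ndarray:
    """Local-average smoother: node coordinates along the lam ordering."""
    n = len(lam)
    order = np.argsort(lam, kind="stable")
    sorted_pts = points[order]
    half = max(1, int(round(span * n / 2)))
    centers = np.linspace(0, n - 1, num=min(n_nodes, n)).round().astype(int)
    nodes = np.empty((len(centers), points.shape[1]))
    for j, c in enumerate(centers):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        nodes[j] = sorted_pts[lo:hi].mean(axis=0)
    # drop consecutive duplicate nodes (flat stretches of the smoother)
    keep = np.ones(len(nodes), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(nodes, axis=0), axis=1) > 1e-12
    nodes = nodes[keep]
    if len(nodes) < 2:
        nodes = np.vstack([sorted_pts[0], sorted_pts[-1]])
    return nodes


def _project_polyline(points: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's nearest location on the polyline.

    The terminal segments are extrapolated (no clamping) so points beyond
    the smoothed curve's ends keep distinct, ordered positions instead of
    piling up at the endpoints.
    """
    seg = np.diff(nodes, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_seg = len(seg)
    best_d2 = np.full(len(points), np.inf)
    best_lam = np.zeros(len(points))
    for i in range(n_seg):
        a, d = nodes[i], seg[i]
        denom = seg_len[i] ** 2
        t = ((points - a) @ d) / denom
        lo = -np.inf if i == 0 else 0.0
        hi = np.inf if i == n_seg - 1 else 1.0
        t = np.clip(t, lo, hi)
        proj = a + t[:, None] * d
        d2 = ((points - proj) ** 2).sum(axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_lam[better] = cum[i] + t[better] * seg_len[i]
    return best_lam


def principal_curve(
    points: np.ndarray,
    span: float = 0.1,
    max_iter: int = 20,
    tol: float = 1e-4,
    n_nodes: int = 100,
) -> np.ndarray:
    """Arc-length positions along a principal curve through ``points``.

    Alternating projection/smoothing initialized from the first coordinate
    (callers pass PC-space data, so this is PC1).  Deterministic: no random
    draws are involved.
    """
    lam = points[:, 0].astype(float).copy()
    if np.ptp(lam) == 0:
        return np.zeros(len(lam))
    for _ in range(max_iter):
        nodes = _smooth_nodes(points, lam, span, n_nodes)
        new_lam = _project_polyline(points, nodes)
        old_n = (lam - lam.min()) / max(np.ptp(lam), 1e-12)
        new_n = (new_lam - new_lam.min()) / max(np.ptp(new_lam), 1e-12)
        change = float(np.mean(np.abs(new_n - old_n)))
        lam = new_lam
        if change < tol:
            break
    return lam


def fit_trajectory(
    expr: NormalizedExpression,
    hvgs: HVGSet,
    strata: StratumAssignment,
    composite: pd.Series,
    seed: int = 0,
    n_pcs: int = 10,
) -> TrajectoryResult:
    """PCA + principal-curve pseudotime rooted at the LOX centroid.

    The curve is fitted in the top ``n_pcs`` PC space; arc-length position
    is rescaled to [0,1] and the direction flipped if needed so the cell
    nearest the mean PC1 of LOX cells maps below the midpoint.
    ``pc1_score_rho`` is the Spearman correlation of PC1 with the composite
    oxidative-stress score.
    """
    idx = expr.gene_indices(hvgs.genes, "(trajectory)")
    X = expr.X[:, idx]
    # centered, not variance-scaled: the HVG panel is already variance-
    # selected, and unit-scaling would drown the dominant program in noise
    X = X - X.mean(axis=0)
    k = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if k < 2:
        raise DegenerateDataError("PCA rank below 2; trajectory undefined")
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    P = pca.fit_transform(X)

    lam = principal_curve(P)
    rng_span = np.ptp(lam)
    pt = (lam - lam.min()) / (rng_span if rng_span > 0 else 1.0)

    stratum = strata.labels.reindex(expr.cells).to_numpy()
    lox = stratum == "LOX"
    if not lox.any():
        raise DegenerateDataError("no LOX cells to root the trajectory")
    root_coord = float(P[lox, 0].mean())
    # orient so the LOX root end maps toward 0: compare the mean position of
    # LOX cells against the high-stress end (HOX if present, else the rest)
    hox = stratum == "HOX"
    other = hox if hox.any() else ~lox
    if other.any() and pt[lox].mean() > pt[other].mean():
        pt = 1.0 - pt

    comp = composite.reindex(expr.cells).to_numpy(dtype=float)
    rho = float(spearmanr(P[:, 0], comp).statistic)
    pcs = pd.DataFrame(
        P, index=expr.cells, columns=[f"PC{i+1}" for i in range(k)]
    )
    return TrajectoryResult(
        pcs=pcs,
        pseudotime=pd.Series(pt, index=expr.cells, name="pseudotime"),
        root_coord=root_coord,
        pc1_score_rho=rho,
    )


def stress_along_pseudotime(
    pseudotime: pd.Series, composite: pd.Series, n_bins: int = 20
) -> pd.DataFrame:
    """Mean composite score in equal-width pseudotime bins.

    Empty bins are flagged (count 0, mean NaN).  A biphasic stress
    trajectory shows up as a falling-then-rising profile of the bin means.
    """
    if n_bins < 2:
        raise DegenerateDataError("need at least 2 bins")
    pt = pseudotime.to_numpy(dtype=float)
    comp = composite.reindex(pseudotime.index).to_numpy(dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pt, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        rows.append(
            {
                "bin": b,
                "left": edges[b],
                "right": edges[b + 1],
                "count": int(mask.sum()),
                "mean_composite": float(comp[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def plasticity_ordering_test(
    z: pd.Series, strata: StratumAssignment
) -> pd.DataFrame:
    """Pairwise one-sided rank-sum tests for HOX > DTOX > LOX plasticity."""
    groups = {
        s: z[strata.labels.reindex(z.index) == s].to_numpy()
        for s in ("LOX", "DTOX", "HOX")
    }
    pairs = [("HOX", "DTOX"), ("HOX", "LOX"), ("DTOX", "LOX")]
    rows = []
    for hi, lo in pairs:
        res = mannwhitneyu(groups[hi], groups[lo], alternative="greater")
        rows.append(
            {
                "higher": hi,
                "lower": lo,
                "mean_diff": float(groups[hi].mean() - groups[lo].mean()),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)
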