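"""Donor-level pseudobulk counts, CPM filtering, and TMM scaling factors.

These are the documented inputs to downstream count-based differential
testing: raw counts are summed per donor, lowly expressed genes are dropped
(CPM > 1 in at least three donors), and trimmed-mean-of-M-values (TMM)
factors correct for library composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .exceptions import DegenerateDataError, MetadataError


@dataclass
class PseudobulkMatrix:
    counts: pd.DataFrame      # genes x donors, integer sums of raw counts
    lib_sizes: pd.Series      # per-donor column sums

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def donors(self) -> pd.Index:
        return self.counts.columns


def aggregate_by_donor(adata: AnnData) -> PseudobulkMatrix:
    """Sum raw counts over each donor's cells (donors ordered lexically)."""
    if "donor" not in adata.obs.columns:
        raise MetadataError("donor missing from cell metadata")
    donors = sorted(adata.obs["donor"].astype(str).unique())
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    cols = {}
    donor_arr = adata.obs["donor"].astype(str).to_numpy()
    for d in donors:
        mask = donor_arr == d
        cols[d] = np.asarray(X[mask].sum(axis=0)).ravel().astype(np.int64)
    counts = pd.DataFrame(cols, index=adata.var_names)
    return PseudobulkMatrix(counts=counts, lib_sizes=counts.sum(axis=0))


def cpm(pb: PseudobulkMatrix) -> pd.DataFrame:
    """Counts per million per donor column."""
    if (pb.lib_sizes <= 0).any():
        raise ZeroDivisionError("zero library size")
    return pb.counts * 1e6 / pb.lib_sizes


def filter_cpm(
    pb: PseudobulkMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> PseudobulkMatrix:
    """Keep genes with CPM strictly above ``min_cpm`` in >= ``min_samples`` donors.

    Library sizes are kept from the unfiltered matrix so the filter is
    idempotent.
    """
    rates = cpm(pb)
    keep = (rates > min_cpm).sum(axis=1) >= min_samples
    return PseudobulkMatrix(counts=pb.counts.loc[keep], lib_sizes=pb.lib_sizes)


def tmm_factors(
    pb: PseudobulkMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference donor is the one whose upper-quartile CPM is closest to
    the mean upper quartile.  For every other donor, gene-wise log2 ratios
    (M) against the reference are double-trimmed — the extreme
    ``logratio_trim`` tails of M and ``abs_trim`` tails of average
    log-abundance (A) are excluded, as are genes with a zero count in
    either library — and combined by a precision-weighted mean
    (inverse binomial variance weights).  Factors are rescaled so their
    geometric mean is exactly 1.
    """
    if pb.counts.shape[1] < 2:
        raise DegenerateDataError("TMM needs at least two donors")
    if (pb.lib_sizes <= 0).any():
        raise DegenerateDataError("donor with all-zero counts")
    Y = pb.counts.to_numpy(dtype=float)
    lib = pb.lib_sizes.to_numpy(dtype=float)
    props = Y / lib[None, :]

    uq = np.array([
        np.quantile(props[:, j][Y[:, j] > 0], 0.75) if (Y[:, j] > 0).any() else 0.0
        for j in range(Y.shape[1])
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(Y.shape[1])
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        ok = (Y[:, j] > 0) & (Y[:, ref] > 0)
        if not ok.any():
            factors[j] = 1.0
            continue
        pj, pr = props[ok, j], props[ok, ref]
        M = np.log2(pj / pr)
        A = 0.5 * (np.log2(pj) + np.log2(pr))
        w = (lib[j] - Y[ok, j]) / (lib[j] * Y[ok, j]) + (
            lib[ref] - Y[ok, ref]
        ) / (lib[ref] * Y[ok, ref])
        n = M.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (
            np.floor(n * logratio_trim) + 1
        )
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n + 1 - (np.floor(n * abs_trim) + 1)
        rank_m = pd.Series(M).rank().to_numpy()
        rank_a = pd.Series(A).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (
            rank_a <= hi_a
        )
        if not keep.any() or w[keep].sum() == 0:
            factors[j] = 1.0
            continue
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0 ** f

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=pb.donors, name="tmm_factor")
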