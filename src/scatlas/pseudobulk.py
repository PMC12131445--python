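"""Cluster pooling and nTPM normalization.

Cells of a cluster are summed into one pseudo-bulk library; pooled counts
are scaled to counts-per-million and then adjusted by trimmed-mean-of-
M-values (TMM) scaling factors so expression is comparable across
clusters. For UMI data there is no gene-length term, so nTPM here is
TMM-adjusted CPM. TMM is computed within each tissue's set of clusters by
default (each tissue is quantified as its own dataset), and clusters whose
annotation reliability is low or very low are excluded before any
downstream aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .io import CountMatrix

DEFAULT_KEEP_GRADES = frozenset({"high", "medium"})


@dataclass
class PooledCounts:
    """Gene x cluster matrix of summed UMI counts plus cluster metadata."""

    counts: pd.DataFrame
    meta: pd.DataFrame  # index: cluster; columns: tissue (optional), n_cells

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("metadata index must match count columns")


@dataclass
class PseudobulkProfile:
    """Gene x cluster nTPM matrix with the normalization factors used."""

    ntpm: pd.DataFrame
    factors: pd.Series
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)


def pool_clusters(
    counts: CountMatrix,
    cluster_labels: pd.Series,
    tissues: pd.Series | None = None,
) -> PooledCounts:
    """Sum cell counts into per-cluster pseudo-bulk libraries.

    ``cluster_labels`` maps every barcode to its cluster; an unlabeled cell
    is an error. ``tissues`` (barcode -> tissue) is carried into cluster
    metadata for per-tissue normalization; clusters spanning tissues are
    rejected.
    """
    labels = cluster_labels.reindex(counts.barcodes)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"{len(missing)} unlabeled cell(s), e.g. {missing[:3]}")
    clusters = sorted(labels.unique())
    cidx = {c: i for i, c in enumerate(clusters)}
    col = np.fromiter((cidx[c] for c in labels), dtype=np.int64, count=len(labels))
    # indicator matrix cells x clusters; pooled = counts @ indicator
    ind = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), col)),
        shape=(len(labels), len(clusters)),
    )
    pooled = np.asarray((counts.matrix @ ind).todense())
    df = pd.DataFrame(
        pooled.astype(np.int64),
        index=pd.Index(counts.genes, name="gene"),
        columns=clusters,
    )
    meta = pd.DataFrame(index=pd.Index(clusters, name="cluster"))
    meta["n_cells"] = labels.value_counts().reindex(clusters).astype(int)
    if tissues is not None:
        tl = tissues.reindex(counts.barcodes)
        per_cluster = tl.groupby(labels).unique()
        multi = [c for c, ts in per_cluster.items() if len(ts) > 1]
        if multi:
            raise ValueError(f"cluster(s) span multiple tissues: {multi}")
        meta["tissue"] = per_cluster.reindex(clusters).map(lambda ts: ts[0])
    return PooledCounts(df, meta)


def cpm(pooled: PooledCounts | pd.DataFrame) -> pd.DataFrame:
    """Scale each cluster column to counts-per-million (sums to 1e6)."""
    df = pooled.counts if isinstance(pooled, PooledCounts) else pooled
    colsum = df.sum(axis=0)
    zero = colsum.index[colsum == 0].tolist()
    if zero:
        raise ValueError(f"cluster(s) with zero total counts: {zero}")
    return df * (1e6 / colsum)


def _tmm_one(
    x: np.ndarray,
    ref: np.ndarray,
    trim_M: float,
    trim_A: float,
) -> float:
    """Log2 TMM factor of sample x against the reference column."""
    nx, nr = x.sum(), ref.sum()
    keep = (x > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("no genes expressed in both sample and reference; factor 1")
        return 0.0
    xs, rs = x[keep], ref[keep]
    M = np.log2((xs / nx) / (rs / nr))
    A = 0.5 * np.log2((xs / nx) * (rs / nr))
    w = (nx - xs) / (nx * xs) + (nr - rs) / (nr * rs)
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = M.size
    loM, hiM = np.floor(n * trim_M) + 1, n + 1 - (np.floor(n * trim_M) + 1)
    loA, hiA = np.floor(n * trim_A) + 1, n + 1 - (np.floor(n * trim_A) + 1)
    rM = rankdata(M)
    rA = rankdata(A)
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep2.any():
        warnings.warn("trimming removed every gene; factor 1")
        return 0.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    pooled: PooledCounts | pd.DataFrame,
    trim_M: float = 0.3,
    trim_A: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference column is the one whose upper quartile of nonzero CPM is
    closest to the mean upper quartile. M-values (log expression ratios vs
    the reference) are doubly trimmed — ``trim_M`` from each tail by
    M-value rank and ``trim_A`` by average-abundance rank — and averaged
    with inverse asymptotic binomial variance weights; the factor is 2 to
    that mean. Genes with zero counts in either column are excluded.
    """
    df = pooled.counts if isinstance(pooled, PooledCounts) else pooled
    X = df.to_numpy(dtype=float)
    libsize = X.sum(axis=0)
    if np.any(libsize == 0):
        raise ValueError("zero-count cluster; remove before TMM")
    cpm_mat = X * (1e6 / libsize)
    uq = np.array(
        [
            np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0
            for col in cpm_mat.T
        ]
    )
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    log2f = np.array(
        [_tmm_one(X[:, j], X[:, ref_j], trim_M, trim_A) for j in range(X.shape[1])]
    )
    factors = 2.0**log2f
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def ntpm(pooled: PooledCounts, by_tissue: bool = True) -> PseudobulkProfile:
    """Normalized transcripts-per-million: CPM divided by the TMM factor.

    With ``by_tissue`` (default) TMM factors are computed within each
    tissue's clusters and the normalized columns concatenated; without
    tissue metadata, or when disabled, factors are computed jointly.
    nTPM column sums need not equal 1e6 when factors differ from 1.
    """
    c = cpm(pooled)
    if by_tissue and "tissue" in pooled.meta.columns:
        factors = []
        for _, group in pooled.meta.groupby("tissue", sort=True):
            cols = group.index.tolist()
            factors.append(tmm_factors(pooled.counts[cols]))
        fac = pd.concat(factors).reindex(pooled.counts.columns)
    else:
        fac = tmm_factors(pooled)
    return PseudobulkProfile(c / fac, fac, pooled.meta.copy())


def filter_reliability(
    profile: PseudobulkProfile,
    grades: pd.Series | dict[str, str],
    keep: frozenset[str] | set[str] = DEFAULT_KEEP_GRADES,
) -> PseudobulkProfile:
    """Drop clusters whose annotation reliability grade is not kept.

    Grades must cover every cluster. Factors of retained clusters are kept
    as computed (no renormalization). An empty result is allowed with a
    warning.
    """
    g = pd.Series(grades)
    missing = [c for c in profile.ntpm.columns if c not in g.index]
    if missing:
        raise ValueError(f"ungraded cluster(s): {missing[:5]}")
    kept = [c for c in profile.ntpm.columns if g[c] in keep]
    if not kept:
        warnings.warn("reliability filtering removed every cluster")
    meta = profile.meta.loc[kept] if not profile.meta.empty else profile.meta
    return PseudobulkProfile(profile.ntpm[kept], profile.factors[kept], meta)
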