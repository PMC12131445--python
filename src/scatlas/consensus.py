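"""Consensus cell types and the atlas-level summaries.

Per-tissue cluster profiles are aggregated into consensus cell types by an
unweighted mean over contributing clusters (so one very large cluster
cannot dominate a cell type). On top of the consensus matrix the module
computes the per-tissue cell-type composition, the Spearman similarity
matrix, a Ward-D2 dendrogram on 1 - rho (exportable as Newick), per-gene
Z-scores for marker heatmaps, and the %-of-max display transform of
per-cell read counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from skbio import TreeNode

from .pseudobulk import PseudobulkProfile

PERCENT_BINS = ("<1%", "<25%", "<50%", "<75%", "≥75%")


@dataclass
class ConsensusProfile:
    """Gene x cell-type nTPM matrix with provenance."""

    ntpm: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    contributing: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Dendrogram:
    """Agglomerative tree over units: linkage matrix, leaf labels, Newick."""

    linkage: np.ndarray
    labels: list[str]
    newick: str


def aggregate_to_cell_types(
    profile: PseudobulkProfile | pd.DataFrame,
    cluster_to_type: pd.Series | dict[str, str],
    type_groups: dict[str, str] | None = None,
) -> ConsensusProfile:
    """Average cluster nTPM columns into consensus cell types.

    Every retained cluster must be mapped to a cell type; aggregation is
    the unweighted arithmetic mean over a type's clusters.
    """
    df = profile.ntpm if isinstance(profile, PseudobulkProfile) else profile
    mapping = pd.Series(cluster_to_type)
    unmapped = [c for c in df.columns if c not in mapping.index]
    if unmapped:
        raise ValueError(f"unmapped cluster(s): {unmapped[:5]}")
    by_type: dict[str, list[str]] = {}
    for c in df.columns:
        by_type.setdefault(str(mapping[c]), []).append(c)
    types = sorted(by_type)
    cons = pd.DataFrame(
        {t: df[by_type[t]].mean(axis=1) for t in types}, index=df.index
    )
    return ConsensusProfile(cons, dict(type_groups or {}), by_type)


def cell_type_fractions(
    metadata: pd.DataFrame,
    by: str = "cell_type",
) -> pd.DataFrame:
    """Tissue x cell-type (or group) matrix of cell fractions, rows sum to 1.

    ``metadata`` needs columns ``tissue`` and ``by``.
    """
    for col in ("tissue", by):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column '{col}'")
    counts = metadata.groupby(["tissue", by]).size().unstack(fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals.index[totals == 0].tolist()
    if empty:
        warnings.warn(f"tissue(s) with zero cells omitted: {empty}")
        counts = counts.loc[totals > 0]
        totals = totals[totals > 0]
    return counts.div(totals, axis=0)


def spearman_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of unit columns over genes.

    Symmetric with unit diagonal; ties get average ranks. A constant
    column has undefined correlations, reported as NaN.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need at least 2 units and 3 genes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns -> NaN, by contract
        rho = spearmanr(matrix.to_numpy(dtype=float)).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.columns, columns=matrix.columns)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = TreeNode.from_linkage_matrix(link, labels)
    return str(tree).strip()


def ward_dendrogram(corr: pd.DataFrame) -> Dendrogram:
    """Ward-D2 agglomerative clustering on distance 1 - rho.

    Leaves are pre-sorted by identifier so equal-distance merges resolve
    deterministically; heights are nondecreasing along merges. The Newick
    export carries branch lengths derived from merge heights.
    """
    if list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square and labeled")
    nan_pairs = [
        (str(a), str(b))
        for i, a in enumerate(corr.index)
        for j, b in enumerate(corr.columns)
        if i < j and not np.isfinite(corr.iat[i, j])
    ]
    if nan_pairs:
        raise ValueError(f"missing correlations for pairs: {nan_pairs[:5]}")
    labels = sorted(str(x) for x in corr.index)
    c = corr.loc[labels, labels].to_numpy(dtype=float)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    link = sch.linkage(condensed, method="ward")
    return Dendrogram(link, labels, _linkage_to_newick(link, labels))


def marker_zscore(
    profile: ConsensusProfile | pd.DataFrame,
    genes: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise Z-scores (mean 0, sd 1) for the listed genes.

    Constant rows cannot be standardized; they become all-zero and are
    returned in the flagged list.
    """
    df = profile.ntpm if isinstance(profile, ConsensusProfile) else profile
    absent = [g for g in genes if g not in df.index]
    if absent:
        raise ValueError(f"gene(s) absent from profile: {absent[:5]}")
    sub = df.loc[genes].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    flagged = sub.index[sd == 0].tolist()
    z = sub.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z, flagged


def percent_of_max(read_counts: np.ndarray | list[float]) -> tuple[np.ndarray, list[str]]:
    """Display transform: log2(rc + 1) / log2(max(rc) + 1) * 100 per cell.

    Returns the percentage per cell and its bin label among
    <1%, <25%, <50%, <75%, >=75%. With all-zero input every cell is 0%
    in the <1% bin.
    """
    rc = np.asarray(read_counts, dtype=float)
    if rc.size == 0:
        raise ValueError("need at least one cell")
    if np.any(rc < 0):
        raise ValueError("read counts must be nonnegative")
    mx = rc.max()
    if mx == 0:
        values = np.zeros_like(rc)
    else:
        values = np.log2(rc + 1.0) / np.log2(mx + 1.0) * 100.0
    bins = []
    for v in values:
        if v < 1:
            bins.append(PERCENT_BINS[0])
        elif v < 25:
            bins.append(PERCENT_BINS[1])
        elif v < 50:
            bins.append(PERCENT_BINS[2])
        elif v < 75:
            bins.append(PERCENT_BINS[3])
        else:
            bins.append(PERCENT_BINS[4])
    return values, bins
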