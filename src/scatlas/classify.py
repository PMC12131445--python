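"""Gene specificity classification across cell types.

Every gene is assigned exactly one of five mutually exclusive categories
from its nTPM profile across cell types:

``enriched``
    At least fourfold (by default) higher in a single cell type than in any
    other cell type.
``group_enriched``
    A small group of cell types (2 up to ``max_group_size``) whose mean
    expression is at least fourfold above every cell type outside the group.
``enhanced``
    Moderately elevated: at least fourfold above the mean of all *other*
    cell types, in one or more cell types, without meeting the stricter
    rules above.
``low_specificity``
    Detected but without cell-type contrast (housekeeping-like).
``not_detected``
    Below the detection limit (nTPM < 1 by default) in every cell type.

The module also provides the tau specificity score (0 = uniform,
1 = exclusive to one cell type) and the coarse detection-breadth category
(detected in a single / some / many / all cell types).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORIES = (
    "enriched",
    "group_enriched",
    "enhanced",
    "low_specificity",
    "not_detected",
)

DISTRIBUTION_CATEGORIES = (
    "detected_in_single",
    "detected_in_some",
    "detected_in_many",
    "detected_in_all",
    "not_detected",
)


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable thresholds of the specificity classifier.

    Parameters
    ----------
    detection_limit:
        nTPM below which a gene counts as not detected in a cell type.
    fold_threshold:
        Enrichment ratio required by the enriched / group-enriched /
        enhanced rules. Must exceed 1.
    max_group_size:
        Largest group of cell types the group-enriched rule may span.
    log_transform_tau:
        If True, tau is computed on log2(x + 1)-transformed values instead
        of raw nTPM.
    """

    detection_limit: float = 1.0
    fold_threshold: float = 4.0
    max_group_size: int = 10
    log_transform_tau: bool = False

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be positive")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.max_group_size < 2:
            raise ValueError("max_group_size must be at least 2")


@dataclass
class SpecificityRecord:
    """Per-gene classification outcome."""

    gene: str
    category: str
    elevated_types: list[str] = field(default_factory=list)
    fold: float = np.nan
    tau: float = np.nan
    distribution: str = "not_detected"


def _as_vector(x: Sequence[float]) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("expression vector must be 1-D with at least 2 entries")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("expression values must be finite and nonnegative")
    return v


def classify_gene(
    x: Sequence[float],
    params: ClassifierParams | None = None,
    cell_types: Sequence[str] | None = None,
    gene: str = "",
) -> SpecificityRecord:
    """Classify one gene from its nTPM vector over cell types.

    The rules are applied in order, first match wins:

    1. *not detected* if ``max(x) < detection_limit``;
    2. *enriched* if the unique maximum is at least ``fold_threshold`` times
       the second-largest value (ties at the maximum fall through);
    3. *group enriched* for the smallest group size ``g`` in
       ``2..max_group_size`` such that the top-``g`` values (descending,
       ties broken by cell-type identifier) average at least
       ``fold_threshold`` times the maximum outside the group, every member
       being detected;
    4. *enhanced* if any detected cell type is at least ``fold_threshold``
       times the mean of all remaining cell types;
    5. otherwise *low specificity*.

    All comparisons are multiplicative, so zero expression outside a group
    poses no division problem.
    """
    params = params or ClassifierParams()
    v = _as_vector(x)
    n = v.size
    if cell_types is None:
        cell_types = [f"ct{i}" for i in range(n)]
    elif len(cell_types) != n:
        raise ValueError("cell_types length must match vector length")
    types = list(cell_types)
    limit = params.detection_limit
    fold_t = params.fold_threshold

    rec = SpecificityRecord(gene=gene, category="low_specificity")

    # (1) not detected
    vmax = v.max()
    if vmax < limit:
        rec.category = "not_detected"
        return rec

    # descending order, stable tie-break by cell-type identifier
    order = sorted(range(n), key=lambda i: (-v[i], types[i]))
    sv = v[order]

    # (2) enriched: strict unique maximum
    if sv[0] >= limit and sv[0] > sv[1] and sv[0] >= fold_t * sv[1]:
        rec.category = "enriched"
        rec.elevated_types = [types[order[0]]]
        rec.fold = float(sv[0] / sv[1]) if sv[1] > 0 else np.inf
        return rec

    # (3) group enriched: smallest qualifying prefix of the descending sort
    gmax = min(params.max_group_size, n - 1)
    prefix_mean = np.cumsum(sv) / np.arange(1, n + 1)
    for g in range(2, gmax + 1):
        rest_max = sv[g]
        if sv[g - 1] >= limit and prefix_mean[g - 1] >= fold_t * rest_max:
            rec.category = "group_enriched"
            members = order[:g]
            rec.elevated_types = sorted(types[i] for i in members)
            rec.fold = (
                float(prefix_mean[g - 1] / rest_max) if rest_max > 0 else np.inf
            )
            return rec

    # (4) enhanced: each detected type vs the mean of the others
    total = v.sum()
    mean_rest = (total - v) / (n - 1)
    hit = (v >= limit) & (v >= fold_t * mean_rest)
    if hit.any():
        rec.category = "enhanced"
        rec.elevated_types = sorted(types[i] for i in np.flatnonzero(hit))
        with np.errstate(divide="ignore"):
            folds = np.where(mean_rest[hit] > 0, v[hit] / mean_rest[hit], np.inf)
        rec.fold = float(np.max(folds))
        return rec

    return rec


def tau_score(
    x: Sequence[float],
    detection_limit: float = 1.0,
    log_transform: bool = False,
) -> float:
    """Tau expression-specificity score in [0, 1].

    tau = sum_i (1 - x_i / max(x)) / (n - 1). A uniform profile scores 0;
    expression exclusive to one cell type scores 1. Undefined (NaN) when the
    gene is below the detection limit everywhere, as specificity of an
    undetected gene is meaningless.
    """
    v = _as_vector(x)
    if v.max() < detection_limit:
        return float("nan")
    if log_transform:
        v = np.log2(v + 1.0)
    xhat = v / v.max()
    return float(np.sum(1.0 - xhat) / (v.size - 1))


def distribution_category(
    x: Sequence[float],
    params: ClassifierParams | None = None,
    many_fraction: float = 1.0 / 3.0,
) -> str:
    """Detection-breadth category over K >= 3 cell types.

    With d = number of cell types at or above the detection limit:
    d = 0 -> not_detected; d = 1 -> single; 1 < d < K*many_fraction -> some;
    K*many_fraction <= d < K -> many; d = K -> all.
    """
    params = params or ClassifierParams()
    v = _as_vector(x)
    k = v.size
    if k < 3:
        raise ValueError("distribution category needs at least 3 cell types")
    d = int(np.sum(v >= params.detection_limit))
    if d == 0:
        return "not_detected"
    if d == 1:
        return "detected_in_single"
    if d == k:
        return "detected_in_all"
    if d < k * many_fraction:
        return "detected_in_some"
    return "detected_in_many"


def classify_all(
    profile: pd.DataFrame,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Classify every gene of a genes x cell-types nTPM table.

    Returns a DataFrame indexed by gene with columns ``category``,
    ``elevated_types`` (semicolon-joined), ``fold``, ``tau`` and
    ``distribution``.
    """
    params = params or ClassifierParams()
    types = list(profile.columns)
    rows = []
    values = profile.to_numpy(dtype=float)
    for gene, v in zip(profile.index, values):
        rec = classify_gene(v, params, cell_types=types, gene=str(gene))
        rec.tau = tau_score(
            v,
            detection_limit=params.detection_limit,
            log_transform=params.log_transform_tau,
        )
        rec.distribution = distribution_category(v, params)
        rows.append(
            {
                "gene": rec.gene,
                "category": rec.category,
                "elevated_types": ";".join(rec.elevated_types),
                "fold": rec.fold,
                "tau": rec.tau,
                "distribution": rec.distribution,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    return out


def category_summary(records: pd.DataFrame) -> dict[str, int]:
    """Category -> gene count, over all five categories (zeros included)."""
    counts = records["category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}
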