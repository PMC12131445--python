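"""Single-cell versus bulk concordance analyses.

Given specificity classifications computed on cell-type profiles
(single-cell) and on tissue profiles (bulk — same algorithm, tissue
columns), this module builds the category crosstab, correlates tau scores
(Spearman over genes; polyserial between tau and the ordered categories),
tests whether single-cell tau exceeds bulk tau (one-sided Wilcoxon
signed-rank), and partitions genes by where they are detected at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr, wilcoxon

from .classify import CATEGORIES

# ordinal specificity scale, least to most specific; not_detected excluded
# because tau is undefined for undetected genes
CATEGORY_ORDER = ("low_specificity", "enhanced", "group_enriched", "enriched")


@dataclass
class DetectabilityPartition:
    """Genes split by where they pass the detection limit."""

    both_detected: list[str]
    sc_only: list[str]
    bulk_only: list[str]
    neither: list[str]
    bulk_only_max: pd.DataFrame  # max bulk nTPM and its tissue, per gene
    sc_only_distribution: pd.Series  # distribution category per sc-only gene

    def sizes(self) -> dict[str, int]:
        return {
            "both_detected": len(self.both_detected),
            "sc_only": len(self.sc_only),
            "bulk_only": len(self.bulk_only),
            "neither": len(self.neither),
        }


def classification_crosstab(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Category x category gene counts over the shared gene universe.

    Rows index the categories of ``a``, columns those of ``b``; all five
    categories always appear, so margins equal each table's category counts
    on the intersection.
    """
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError("no shared genes between the two classifications")
    tab = pd.crosstab(a.loc[common, "category"], b.loc[common, "category"])
    tab = tab.reindex(index=list(CATEGORIES), columns=list(CATEGORIES), fill_value=0)
    tab.index.name = "a"
    tab.columns.name = "b"
    return tab


def tau_concordance(tau_a: pd.Series, tau_b: pd.Series) -> tuple[float, int]:
    """Spearman rho between two tau score sets over genes defined in both."""
    common = tau_a.dropna().index.intersection(tau_b.dropna().index)
    if len(common) < 3:
        raise ValueError("need at least 3 genes with tau defined in both")
    rho = spearmanr(tau_a[common], tau_b[common]).statistic
    return float(rho), len(common)


def polyserial_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polyserial correlation between continuous x and ordinal y.

    Assumes y arises by thresholding a latent normal correlated with x.
    Thresholds are estimated from the cumulative level proportions,
    tau_k = Phi^-1(P(Y <= k)); the estimate is

        rho = r_xy * s_y / sum_k phi(tau_k)

    with r_xy the Pearson correlation of x with integer-coded y, s_y the
    sample standard deviation of the codes, and phi the standard normal
    density. Clamped to [-1, 1]. Levels with zero count are dropped with a
    warning; constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.std(x) == 0:
        raise ValueError("x is constant; polyserial correlation undefined")
    levels, codes = np.unique(y, return_inverse=True)
    if levels.size < 2:
        raise ValueError("need at least 2 ordinal levels present")
    # np.unique drops empty levels implicitly; warn if the coding had gaps
    if np.issubdtype(levels.dtype, np.number) and levels.size != levels.max() - levels.min() + 1:
        warnings.warn("ordinal levels with zero count dropped")
    n = x.size
    props = np.bincount(codes) / n
    cum = np.cumsum(props)[:-1]
    thresholds = norm.ppf(cum)
    codes = codes.astype(float) + 1.0  # integer scores 1..K
    r_xy = np.corrcoef(x, codes)[0, 1]
    s_y = codes.std(ddof=1)
    rho = r_xy * s_y / norm.pdf(thresholds).sum()
    return float(np.clip(rho, -1.0, 1.0))


def paired_tau_test(tau_a: pd.Series, tau_b: pd.Series) -> dict:
    """One-sided Wilcoxon signed-rank test of tau_a > tau_b on paired genes.

    Zero differences are dropped (standard convention). Returns the test
    statistic, the number of non-zero pairs used, and the one-sided p.
    """
    common = tau_a.dropna().index.intersection(tau_b.dropna().index)
    if len(common) < 10:
        raise ValueError("need at least 10 paired genes")
    d = (tau_a[common] - tau_b[common]).to_numpy(dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; no evidence either way")
        return {"statistic": 0.0, "n": 0, "p_value": 1.0}
    res = wilcoxon(nz, alternative="greater")
    return {"statistic": float(res.statistic), "n": int(nz.size),
            "p_value": float(res.pvalue)}


def detectability_partition(
    sc: pd.DataFrame,
    bulk: pd.DataFrame,
    bulk_expr: pd.DataFrame,
) -> DetectabilityPartition:
    """Split the shared gene universe by single-cell vs bulk detection.

    A gene is detected in a table iff its category is not ``not_detected``.
    Bulk-only genes are annotated with their maximum bulk nTPM and the
    tissue achieving it; single-cell-only genes with their detection-
    breadth category across cell types.
    """
    common = sc.index.intersection(bulk.index)
    sc_det = sc.loc[common, "category"] != "not_detected"
    bulk_det = bulk.loc[common, "category"] != "not_detected"
    both = common[sc_det & bulk_det].tolist()
    sc_only = common[sc_det & ~bulk_det].tolist()
    bulk_only = common[~sc_det & bulk_det].tolist()
    neither = common[~sc_det & ~bulk_det].tolist()

    bo = [g for g in bulk_only if g in bulk_expr.index]
    if bo:
        sub = bulk_expr.loc[bo]
        bulk_only_max = pd.DataFrame(
            {"max_ntpm": sub.max(axis=1), "tissue": sub.idxmax(axis=1)}
        )
    else:
        bulk_only_max = pd.DataFrame(columns=["max_ntpm", "tissue"])
    sc_only_distribution = sc.loc[sc_only, "distribution"]
    return DetectabilityPartition(
        both, sc_only, bulk_only, neither, bulk_only_max, sc_only_distribution
    )
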