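"""Bulk deconvolution by dampened weighted least squares (DWLS).

The signature matrix restricts the consensus cell-type profile to
cell-type-enriched genes. Per bulk sample, proportions are estimated by
iteratively reweighted nonnegative least squares: weights are the inverse
squared predicted expression (so low-expressed signature genes are not
drowned out by highly expressed ones), dampened by capping them at a
constant multiple of the smallest positive weight. The dampening constant
is chosen from a power-of-two grid by k-fold cross-validation over
signature genes. Enriched-gene set overlaps between cell types and
tissues are scored with one-sided hypergeometric tests under
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_GRID = tuple(float(2**i) for i in range(15))
WEIGHT_FLOOR = 1e-8  # floors predicted expression in weights


@dataclass
class SignatureMatrix:
    """Enriched-gene x cell-type reference expression."""

    matrix: pd.DataFrame
    gene_categories: pd.Series
    unidentifiable_types: list[str] = field(default_factory=list)


@dataclass
class DeconvolutionResult:
    """Estimated composition of one bulk sample."""

    proportions: pd.Series
    residual_norm: float
    dampening: float
    iterations: int
    converged: bool


@dataclass
class OverlapTestResult:
    """One-sided hypergeometric overlap between two gene sets."""

    set_a: str
    set_b: str
    overlap: int
    size_a: int
    size_b: int
    universe: int
    p_value: float
    q_value: float | None = None


def build_signature(
    profile,
    records: pd.DataFrame,
) -> SignatureMatrix:
    """Restrict a consensus profile to cell-type-enriched genes.

    ``profile`` is a ConsensusProfile or a genes x cell-types DataFrame;
    ``records`` the classification table computed on it. Cell types with
    no enriched gene pointing at them are flagged unidentifiable (their
    proportions are not constrained by any signature row).
    """
    df = getattr(profile, "ntpm", profile)
    enriched = records.index[records["category"] == "enriched"]
    enriched = [g for g in enriched if g in df.index]
    if not enriched:
        raise ValueError("no enriched genes; cannot build a signature")
    covered = set()
    for g in enriched:
        covered.update(str(records.loc[g, "elevated_types"]).split(";"))
    unidentifiable = sorted(str(t) for t in df.columns if str(t) not in covered)
    return SignatureMatrix(
        df.loc[enriched].copy(),
        records.loc[enriched, "category"].copy(),
        unidentifiable,
    )


def _simplex(p: np.ndarray) -> np.ndarray:
    s = p.sum()
    return p / s if s > 0 else np.full_like(p, 1.0 / p.size)


def _weighted_nnls(S: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    sol, _ = nnls(sw[:, None] * S, sw * b)
    return sol


def _damped_weights(pred: np.ndarray, dampening: float) -> np.ndarray:
    w = 1.0 / np.maximum(pred, WEIGHT_FLOOR) ** 2
    pos = w[w > 0]
    cap = dampening * pos.min()
    return np.minimum(w, cap)


def _dwls_iterate(
    S: np.ndarray,
    b: np.ndarray,
    dampening: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Run the dampened reweighting loop; returns (simplex p, raw p, iters, converged)."""
    raw, _ = nnls(S, b)
    p = _simplex(raw)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = _damped_weights(S @ p, dampening)
        raw = _weighted_nnls(S, b, w)
        p_new = _simplex(raw)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return p, raw, it, converged


def dwls_solve(
    signature: SignatureMatrix | pd.DataFrame,
    bulk: pd.Series | np.ndarray,
    grid: tuple[float, ...] = DEFAULT_GRID,
    tol: float = 1e-6,
    max_iter: int = 100,
    cv_folds: int = 4,
    fold_seed: int = 0,
) -> DeconvolutionResult:
    """Estimate cell-type proportions of one bulk sample.

    The bulk vector is aligned to the signature genes and rescaled to the
    signature's per-million scale before solving (a scale mismatch would
    bias the weights). The dampening constant is selected from ``grid`` by
    ``cv_folds``-fold cross-validation over signature genes, minimizing
    held-out dampened-weighted squared error; folds are drawn from
    ``fold_seed``, making the choice reproducible.
    """
    Sdf = signature.matrix if isinstance(signature, SignatureMatrix) else signature
    if isinstance(bulk, pd.Series):
        missing = [g for g in Sdf.index if g not in bulk.index]
        if missing:
            raise ValueError(f"bulk vector lacks signature gene(s): {missing[:5]}")
        b = bulk.reindex(Sdf.index).to_numpy(dtype=float)
    else:
        b = np.asarray(bulk, dtype=float)
        if b.size != Sdf.shape[0]:
            raise ValueError("bulk vector length must match signature rows")
    S = Sdf.to_numpy(dtype=float)
    types = list(Sdf.columns)
    rank = np.linalg.matrix_rank(S)
    if rank < len(types):
        raise ValueError(
            f"signature is rank-deficient ({rank} < {len(types)}); "
            f"collinear cell types among {types}"
        )
    # match scales: mean signature column sum is the per-million yardstick
    if b.sum() > 0:
        b = b * (S.sum(axis=0).mean() / b.sum())

    n_genes = S.shape[0]
    if len(grid) > 1 and n_genes >= 2 * cv_folds:
        rng = np.random.default_rng(fold_seed)
        perm = rng.permutation(n_genes)
        folds = np.array_split(perm, cv_folds)
        errors = np.zeros(len(grid))
        for gi, d in enumerate(grid):
            for test_idx in folds:
                train = np.setdiff1d(perm, test_idx)
                if np.linalg.matrix_rank(S[train]) < len(types):
                    continue
                p, _, _, _ = _dwls_iterate(S[train], b[train], d, tol, max_iter)
                # rescale fitted mixture to the held-out genes' magnitude
                pred = S[test_idx] @ p
                scale = (
                    pred @ b[test_idx] / (pred @ pred) if pred @ pred > 0 else 0.0
                )
                w = _damped_weights(pred * scale, d)
                w = w / w.sum()  # comparable across dampening constants
                errors[gi] += float(w @ (pred * scale - b[test_idx]) ** 2)
        chosen = float(grid[int(np.argmin(errors))])
    else:
        chosen = float(grid[0])

    p, raw, iters, converged = _dwls_iterate(S, b, chosen, tol, max_iter)
    if not converged:
        warnings.warn(f"DWLS did not converge within {max_iter} iterations")
    residual = float(np.linalg.norm(S @ raw - b))
    return DeconvolutionResult(
        pd.Series(p, index=types, name="proportion"),
        residual,
        chosen,
        iters,
        converged,
    )


def deconvolve_all(
    signature: SignatureMatrix | pd.DataFrame,
    bulk: pd.DataFrame,
    k_top: int = 5,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, list[tuple[str, float]]]]:
    """Deconvolve every bulk column; report top-k cell types per sample.

    Ties in proportion are broken by cell-type identifier so the report is
    deterministic.
    """
    props = {}
    topk = {}
    for col in bulk.columns:
        res = dwls_solve(signature, bulk[col], **kwargs)
        props[col] = res.proportions
        order = sorted(res.proportions.items(), key=lambda kv: (-kv[1], kv[0]))
        topk[col] = [(t, float(v)) for t, v in order[:k_top]]
    return pd.DataFrame(props).T, topk


def hypergeometric_overlap(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapTestResult:
    """P(X >= k) for the overlap of two gene sets drawn from a universe."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return OverlapTestResult(name_a, name_b, k, K, n, N, min(p, 1.0))


def hypergeometric_overlap_batch(
    sets_a: dict[str, set[str]],
    sets_b: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs overlap tests with Benjamini-Hochberg correction.

    Returns one row per (a, b) pair with p, BH q and a significance flag
    at q < alpha.
    """
    rows = []
    for na, sa in sets_a.items():
        for nb, sb in sets_b.items():
            r = hypergeometric_overlap(sa, sb, universe, na, nb)
            rows.append(
                {
                    "set_a": na,
                    "set_b": nb,
                    "overlap": r.overlap,
                    "size_a": r.size_a,
                    "size_b": r.size_b,
                    "universe": r.universe,
                    "p_value": r.p_value,
                }
            )
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    df["significant"] = df["q_value"] < alpha
    return df
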