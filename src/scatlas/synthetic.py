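"""Synthetic multi-tissue single-cell datasets with planted ground truth.

The generator emulates the structure of droplet scRNA-seq atlas data:
cell-type-structured expression means, log-normal library sizes,
gamma-Poisson (negative binomial) UMI counts, mitochondrial/ribosomal gene
fractions, planted doublets and QC-outlier cells, and matched bulk mixtures
produced by the same forward model that deconvolution inverts. Every
planted signal — gene specificity category, cluster identity, doublet and
outlier flags, bulk mixing proportions — is recorded so each downstream
stage can be tested against a known answer.

Specificity planting uses a single fold factor F (default 8):

* *enriched* genes get one cell type raised to F times the largest other
  cell type;
* *group-enriched* genes get a group of cell types all raised to F times
  the largest non-member, with non-member expression damped so the group
  contrast (and hence tau) clearly exceeds that of enhanced genes;
* *enhanced* genes get one target type at 0.55 F times the mean of the
  other types plus a shadow type at 1.5 times the largest baseline value;
  the shadow denies the target a fourfold lead over the runner-up, so the
  gene is elevated over the mean without qualifying as enriched or
  group-enriched;
* *not-detected* genes are scaled so their expected nTPM stays well below
  the detection limit in every cell type;
* everything else is near-uniform baseline (low specificity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_10x_triplet

PLANT_CATEGORIES = (
    "enriched",
    "group_enriched",
    "enhanced",
    "low_specificity",
    "not_detected",
)

GROUP_REST_SUPPRESS = 0.15  # non-member damping for group-enriched plants
ENHANCED_TARGET_FRAC = 0.55  # enhanced target = this x fold_factor x mean(others)
ENHANCED_SHADOW_MULT = 1.5  # shadow = this x max(baseline others)
DOUBLET_SCORE_PLANTED = 0.9
DOUBLET_SCORE_BASELINE = 0.05
OUTLIER_MITO_SHARE = 0.45
NOT_DETECTED_NTPM = 0.2


PLANTED_FRACTIONS = {
    "enriched": 0.15,
    "group_enriched": 0.075,
    "enhanced": 0.10,
    "low_specificity": 0.0,
    "not_detected": 0.06,
}


def scaled_planted_counts(n_genes: int) -> dict[str, int]:
    """Default planted-category counts scaled to a gene universe size."""
    return {c: int(round(f * n_genes)) for c, f in PLANTED_FRACTIONS.items()}


def _default_planted() -> dict[str, int]:
    # category shares follow the atlas regime: ~10-15% enriched (about 25
    # enriched genes per cell type at the default 12 types, matching the
    # per-type signature density of genome-wide atlases), with smaller
    # group-enriched / enhanced / undetected fractions and the remainder
    # low-specificity background
    return {
        "enriched": 300,
        "group_enriched": 150,
        "enhanced": 200,
        "low_specificity": 0,
        "not_detected": 120,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic atlas.

    Defaults are sized so a full pipeline run (generation through
    classification) takes well under a minute while leaving every planted
    contrast comfortably above the sampling noise of a pooled cluster.
    """

    n_genes: int = 2000
    n_cell_types: int = 12
    clusters_per_type: int = 2
    cells_per_cluster: int = 300
    planted_counts: dict[str, int] = field(default_factory=_default_planted)
    fold_factor: float = 8.0
    group_size_range: tuple[int, int] = (2, 4)
    libsize_logmean: float = 8.5  # exp(8.5) ~ 4900 UMIs per cell
    libsize_logsd: float = 0.35
    nb_dispersion: float = 0.1
    mito_gene_frac: float = 0.01
    ribo_gene_frac: float = 0.04
    doublet_rate: float = 0.03
    qc_outlier_rate: float = 0.02
    bulk_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cell_types, self.clusters_per_type,
               self.cells_per_cluster) < 1:
            raise ValueError("counts and sizes must be positive")
        unknown = set(self.planted_counts) - set(PLANT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown planted categories: {sorted(unknown)}")
        if any(v < 0 for v in self.planted_counts.values()):
            raise ValueError("planted counts must be nonnegative")
        if sum(self.planted_counts.values()) > self.n_genes:
            raise ValueError("sum of planted counts exceeds n_genes")
        lo, hi = self.group_size_range
        if not (2 <= lo <= hi <= 10):
            raise ValueError("group_size_range must lie within [2, 10]")
        if self.planted_counts.get("group_enriched", 0) > 0 and hi >= self.n_cell_types:
            raise ValueError("group sizes must be smaller than n_cell_types")
        if self.fold_factor <= 1:
            raise ValueError("fold_factor must exceed 1")
        if self.nb_dispersion < 0 or self.bulk_noise_sd < 0:
            raise ValueError("dispersion and noise sd must be nonnegative")
        for name in ("mito_gene_frac", "ribo_gene_frac", "doublet_rate",
                     "qc_outlier_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return [f"type{t:02d}" for t in range(self.n_cell_types)]

    @property
    def tissues(self) -> list[str]:
        # one tissue per cluster replicate: each tissue holds one cluster of
        # every cell type, so shared types recur across tissues as in a
        # multi-organ atlas
        return [f"tissue{r:02d}" for r in range(self.clusters_per_type)]


@dataclass
class GroundTruth:
    """Planted truth recorded during simulation.

    ``genes`` has one row per gene (category, target cell types, planted
    fold); ``clusters`` maps cluster id to its true cell type; ``cells``
    (filled by :func:`simulate_counts`) carries per-barcode cluster,
    doublet and QC-outlier flags; ``bulk_proportions`` (filled by
    :func:`simulate_bulk`) stores the true mixing vectors.
    """

    genes: pd.DataFrame
    clusters: dict[str, str] = field(default_factory=dict)
    cells: pd.DataFrame | None = None
    bulk_proportions: pd.DataFrame | None = None

    def genes_in_category(self, category: str) -> list[str]:
        return self.genes.index[self.genes["category"] == category].tolist()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": {
                g: {
                    "category": row["category"],
                    "target_types": row["target_types"].split(";")
                    if row["target_types"]
                    else [],
                    "fold": row["fold"],
                }
                for g, row in self.genes.iterrows()
            },
            "clusters": self.clusters,
            "cells": None
            if self.cells is None
            else self.cells.reset_index().to_dict(orient="list"),
            "bulk_proportions": None
            if self.bulk_proportions is None
            else {
                "index": self.bulk_proportions.index.tolist(),
                "columns": self.bulk_proportions.columns.tolist(),
                "values": self.bulk_proportions.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")


def _gene_names(config: SimulationConfig, rng: np.random.Generator) -> tuple[list[str], np.ndarray, np.ndarray]:
    n = config.n_genes
    n_mito = int(round(config.mito_gene_frac * n))
    n_ribo = int(round(config.ribo_gene_frac * n))
    flagged = rng.choice(n, size=n_mito + n_ribo, replace=False)
    mito_idx = np.sort(flagged[:n_mito])
    ribo_idx = np.sort(flagged[n_mito:])
    names = [f"GENE{i:05d}" for i in range(n)]
    for j, i in enumerate(mito_idx):
        names[i] = f"MT-G{j:03d}"
    for j, i in enumerate(ribo_idx):
        names[i] = f"RPS{j:04d}"
    return names, mito_idx, ribo_idx


def simulate_profiles(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw per-cell-type mean expression with planted specificity.

    Returns a genes x cell-types matrix of (unnormalized) expected
    expression and the ground truth. Baseline gene means are log-normal
    with mild per-type jitter; planted genes are modified as described in
    the module docstring. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_genes, config.n_cell_types
    names, mito_idx, ribo_idx = _gene_names(config, rng)
    types = config.cell_types

    base = rng.lognormal(mean=1.0, sigma=1.0, size=n)
    jitter = rng.lognormal(mean=0.0, sigma=0.05, size=(n, k))
    P = base[:, None] * jitter

    flagged = set(mito_idx) | set(ribo_idx)
    eligible = np.array([i for i in range(n) if i not in flagged])
    rng.shuffle(eligible)

    counts = {c: config.planted_counts.get(c, 0) for c in PLANT_CATEGORIES}
    if sum(counts.values()) > eligible.size:
        raise ValueError("planted counts exceed the number of plantable genes")

    category = np.full(n, "low_specificity", dtype=object)
    targets: list[list[str]] = [[] for _ in range(n)]
    fold = np.ones(n)
    pos = 0
    F = config.fold_factor

    def take(m: int) -> np.ndarray:
        nonlocal pos
        out = eligible[pos : pos + m]
        pos += m
        return out

    # enriched: one type at F x max(others); targets round-robin over types
    for j, g in enumerate(take(counts["enriched"])):
        t = j % k
        others = np.delete(np.arange(k), t)
        P[g, t] = F * P[g, others].max()
        category[g] = "enriched"
        targets[g] = [types[t]]
        fold[g] = F

    # group enriched: g member types all at F x max(non-members), with the
    # non-members damped so group genes keep a tau above enhanced genes
    lo, hi = config.group_size_range
    for j, g in enumerate(take(counts["group_enriched"])):
        gsize = int(rng.integers(lo, hi + 1))
        members = rng.choice(k, size=gsize, replace=False)
        rest = np.setdiff1d(np.arange(k), members)
        P[g, members] = F * P[g, rest].max()
        P[g, rest] *= GROUP_REST_SUPPRESS
        category[g] = "group_enriched"
        targets[g] = sorted(types[t] for t in members)
        fold[g] = F

    # enhanced: one shadow type keeps a runner-up close enough that the
    # enriched rule cannot fire, then the target is placed just clear of
    # the elevation-over-the-mean bar
    for j, g in enumerate(take(counts["enhanced"])):
        t, shadow = rng.choice(k, size=2, replace=False)
        rest = np.setdiff1d(np.arange(k), [t, shadow])
        P[g, shadow] = ENHANCED_SHADOW_MULT * P[g, rest].max()
        mean_others = (P[g, shadow] + P[g, rest].sum()) / (k - 1)
        P[g, t] = ENHANCED_TARGET_FRAC * F * mean_others
        category[g] = "enhanced"
        targets[g] = [types[t]]
        fold[g] = ENHANCED_TARGET_FRAC * F

    # explicit low-specificity plants: baseline, just labeled
    take(counts["low_specificity"])

    # equalize column totals by rescaling the baseline genes: planted mass
    # differs per cell type, and per-million normalization would otherwise
    # distort the planted ratios by the column-sum differences
    baseline_rows = np.flatnonzero(category == "low_specificity")
    planted_rows = np.flatnonzero(category != "low_specificity")
    colsum = P.sum(axis=0)
    planted_sum = P[planted_rows, :].sum(axis=0) if planted_rows.size else 0.0
    target_sum = colsum.mean()
    scale = (target_sum - planted_sum) / (colsum - planted_sum)
    if np.any(scale <= 0):
        raise ValueError("planted signal mass too large to balance columns")
    P[baseline_rows, :] *= scale[None, :]

    # not detected: scale so expected nTPM sits far below the detection limit
    nd = take(counts["not_detected"])
    if nd.size:
        P[nd, :] = 0.0
        colsum = P.sum(axis=0)
        P[nd, :] = NOT_DETECTED_NTPM * colsum[None, :] / 1e6
        category[nd] = "not_detected"
        fold[nd] = 0.0

    genes_df = pd.DataFrame(
        {
            "category": category,
            "target_types": [";".join(t) for t in targets],
            "fold": fold,
        },
        index=pd.Index(names, name="gene"),
    )
    genes_df["is_mito"] = False
    genes_df["is_ribo"] = False
    genes_df.iloc[mito_idx, genes_df.columns.get_loc("is_mito")] = True
    genes_df.iloc[ribo_idx, genes_df.columns.get_loc("is_ribo")] = True

    profiles = pd.DataFrame(P, index=pd.Index(names, name="gene"), columns=types)
    return profiles, GroundTruth(genes=genes_df)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def _inflate_mito(pi: np.ndarray, mito_idx: np.ndarray, share: float) -> np.ndarray:
    """Rescale a probability vector so mito genes carry the given share."""
    s = pi[mito_idx].sum()
    if s <= 0 or s >= 1:
        return pi
    out = pi.copy()
    out[mito_idx] *= share / s
    rest = np.setdiff1d(np.arange(pi.size), mito_idx)
    out[rest] *= (1 - share) / (1 - s)
    return out


def simulate_counts(
    profiles: pd.DataFrame,
    config: SimulationConfig,
    ground_truth: GroundTruth | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sample a UMI count matrix and cell metadata from mean profiles.

    Cells are laid out as ``clusters_per_type`` clusters per cell type, one
    cluster per tissue, ``cells_per_cluster`` cells each, plus planted
    doublets whose expected profile is the sum of two random parents'.
    Metadata columns: barcode, tissue, cluster, doublet_score. When a
    :class:`GroundTruth` is passed, its cluster map and per-cell truth
    flags are filled in.
    """
    if profiles.shape[1] != config.n_cell_types:
        raise ValueError("profiles must have one column per cell type")
    if profiles.empty:
        raise ValueError("profiles must not be empty")
    rng = np.random.default_rng(config.seed + 1)
    n_genes = profiles.shape[0]
    types = list(profiles.columns)
    mito_idx = np.flatnonzero(profiles.index.str.startswith("MT-"))

    # per-type relative expression
    pis = profiles.to_numpy(dtype=float)
    pis = pis / pis.sum(axis=0, keepdims=True)

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    cell_pi: list[tuple[int, float]] = []  # (type index, libsize) for doublet parents

    n_base = config.n_cell_types * config.clusters_per_type * config.cells_per_cluster
    outlier_flags = rng.random(n_base) < config.qc_outlier_rate
    idx = 0
    for t, ctype in enumerate(types):
        for r, tissue in enumerate(config.tissues):
            cluster = f"{tissue}.{ctype}"
            if ground_truth is not None:
                ground_truth.clusters[cluster] = ctype
            nc = config.cells_per_cluster
            libsizes = rng.lognormal(config.libsize_logmean, config.libsize_logsd, nc)
            block = np.empty((n_genes, nc), dtype=np.int64)
            for j in range(nc):
                pi = pis[:, t]
                is_out = bool(outlier_flags[idx + j])
                if is_out and mito_idx.size:
                    pi = _inflate_mito(pi, mito_idx, OUTLIER_MITO_SHARE)
                block[:, j] = _nb_draw(rng, libsizes[j] * pi, config.nb_dispersion)
                barcode = f"cell{idx + j:06d}"
                meta_rows.append(
                    {
                        "barcode": barcode,
                        "tissue": tissue,
                        "cluster": cluster,
                        "doublet_score": DOUBLET_SCORE_BASELINE,
                    }
                )
                truth_rows.append(
                    {
                        "barcode": barcode,
                        "cluster": cluster,
                        "cell_type": ctype,
                        "is_doublet": False,
                        "is_qc_outlier": is_out,
                    }
                )
                cell_pi.append((t, libsizes[j]))
            blocks.append(sp.csr_matrix(block))
            idx += nc

    # doublets: expected profile is the sum of two random parents'
    n_doublets = int(round(config.doublet_rate * n_base))
    if n_doublets:
        parents = rng.integers(0, n_base, size=(n_doublets, 2))
        block = np.empty((n_genes, n_doublets), dtype=np.int64)
        for j, (a, b) in enumerate(parents):
            ta, la = cell_pi[a]
            tb, lb = cell_pi[b]
            mu = la * pis[:, ta] + lb * pis[:, tb]
            block[:, j] = _nb_draw(rng, mu, config.nb_dispersion)
            barcode = f"cell{n_base + j:06d}"
            host = meta_rows[a]
            meta_rows.append(
                {
                    "barcode": barcode,
                    "tissue": host["tissue"],
                    "cluster": host["cluster"],
                    "doublet_score": DOUBLET_SCORE_PLANTED,
                }
            )
            truth_rows.append(
                {
                    "barcode": barcode,
                    "cluster": host["cluster"],
                    "cell_type": truth_rows[a]["cell_type"],
                    "is_doublet": True,
                    "is_qc_outlier": False,
                }
            )
        blocks.append(sp.csr_matrix(block))

    matrix = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows).set_index("barcode", drop=False)
    counts = CountMatrix(matrix, list(profiles.index), meta["barcode"].tolist())
    if ground_truth is not None:
        ground_truth.cells = pd.DataFrame(truth_rows).set_index("barcode")
    return counts, meta


def simulate_bulk(
    profiles: pd.DataFrame,
    proportions: pd.DataFrame,
    config: SimulationConfig,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Mix cell-type profiles into bulk tissue columns.

    ``proportions`` is mixtures x cell-types, each row on the simplex
    (validated to 1e-9). Each bulk column is ``profiles @ p`` with
    per-gene multiplicative log-normal noise of sd ``bulk_noise_sd``
    (noiseless when 0).
    """
    if list(proportions.columns) != list(profiles.columns):
        raise ValueError("proportion columns must match profile cell types")
    sums = proportions.sum(axis=1).to_numpy()
    if np.any(np.abs(sums - 1.0) > 1e-9):
        bad = proportions.index[np.abs(sums - 1.0) > 1e-9].tolist()
        raise ValueError(f"proportion vectors not on the simplex: {bad}")
    rng = np.random.default_rng(config.seed + 2)
    mix = profiles.to_numpy(dtype=float) @ proportions.to_numpy(dtype=float).T
    if config.bulk_noise_sd > 0:
        mix = mix * rng.lognormal(0.0, config.bulk_noise_sd, size=mix.shape)
    bulk = pd.DataFrame(mix, index=profiles.index, columns=proportions.index)
    if ground_truth is not None:
        ground_truth.bulk_proportions = proportions.copy()
    return bulk


def simulate_bivariate_ordinal(
    rho: float,
    thresholds: np.ndarray | list[float],
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (continuous, ordinal) pairs from a thresholded bivariate normal.

    (X, Y*) is standard bivariate normal with correlation ``rho``; the
    ordinal Y is the category of Y* under the strictly increasing
    thresholds (K thresholds give K+1 levels, coded 0..K). These pairs are
    the textbook generative model behind the polyserial correlation, so
    the estimator can be checked by parameter recovery.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly within (-1, 1)")
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or thr.size == 0 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    ystar = rho * x + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    y = np.searchsorted(thr, ystar)
    return x, y


def write_simulation(
    outdir: str | Path,
    counts: CountMatrix,
    metadata: pd.DataFrame,
    ground_truth: GroundTruth,
) -> None:
    """Write the triplet directory, metadata TSV and ground-truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_10x_triplet(out / "counts", counts)
    metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    ground_truth.to_json(out / "ground_truth.json")


def default_annotation(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    metadata: pd.DataFrame,
    type_groups: dict[str, str] | None = None,
    reliability: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build a cluster-annotation table for a simulated dataset.

    All clusters default to high reliability; pass ``reliability`` to
    override individual clusters (e.g. to plant excludable low-grade ones).
    """
    rows = []
    cells_per_cluster = metadata.groupby("cluster").size()
    for cluster, ctype in ground_truth.clusters.items():
        tissue = cluster.split(".", 1)[0]
        rows.append(
            {
                "cluster": cluster,
                "tissue": tissue,
                "cell_type": ctype,
                "cell_type_group": (type_groups or {}).get(ctype, "default_group"),
                "reliability": (reliability or {}).get(cluster, "high"),
                "n_cells": int(cells_per_cluster.get(cluster, 0)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster", drop=False)
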