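"""Readers and writers for the on-disk exchange formats.

Sparse count matrices travel as 10x-style triplet directories (MatrixMarket
matrix plus gene and barcode lists, plain or gzipped); tables are TSV with a
header row, UTF-8, '.' decimal, no quoting. Gene identifiers are opaque
strings.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

VALID_GRADES = ("high", "medium", "low", "very_low")

ANNOTATION_COLUMNS = (
    "cluster",
    "tissue",
    "cell_type",
    "cell_type_group",
    "reliability",
    "n_cells",
)


@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix with identifiers."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = [str(g) for g in self.genes]
        self.barcodes = [str(b) for b in self.barcodes]
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


def _dedup(ids: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    dups = 0
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}_{seen[x]}")
            dups += 1
        else:
            seen[x] = 0
            out.append(x)
    if dups:
        warnings.warn(f"{dups} duplicate {what} ids disambiguated with suffixes")
    return out


def _find(dirpath: Path, stems: Iterable[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dirpath / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {list(stems)} (or .gz) found in {dirpath}"
    )


def _read_ids(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        # 10x feature files may carry extra columns (name, feature type)
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_10x_triplet(directory: str | Path) -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    Expects ``matrix.mtx``, a gene list (``genes.tsv`` or ``features.tsv``)
    and ``barcodes.tsv``, each optionally gzipped. Dimensions are validated
    against the MatrixMarket header; duplicated gene identifiers are
    disambiguated deterministically with ``_1``, ``_2`` ... suffixes.
    """
    d = Path(directory)
    mtx_path = _find(d, ["matrix.mtx"])
    genes_path = _find(d, ["genes.tsv", "features.tsv"])
    barcodes_path = _find(d, ["barcodes.tsv"])
    try:
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                m = scipy.io.mmread(fh)
        else:
            m = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    genes = _dedup(_read_ids(genes_path), "gene")
    barcodes = _dedup(_read_ids(barcodes_path), "barcode")
    if m.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{mtx_path}: matrix is {m.shape} but {genes_path.name} has "
            f"{len(genes)} genes and {barcodes_path.name} has "
            f"{len(barcodes)} barcodes"
        )
    return CountMatrix(sp.csr_matrix(m), genes, barcodes)


def write_10x_triplet(directory: str | Path, counts: CountMatrix) -> None:
    """Write a :class:`CountMatrix` as a plain-text triplet directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(counts.matrix))
    (d / "genes.tsv").write_text("\n".join(counts.genes) + "\n", encoding="utf-8")
    (d / "barcodes.tsv").write_text(
        "\n".join(counts.barcodes) + "\n", encoding="utf-8"
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate the cluster-annotation table.

    Required TSV columns: cluster, tissue, cell_type, cell_type_group,
    reliability, n_cells. Reliability grades are matched case-insensitively
    against {high, medium, low, very_low}; cluster ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {missing}")
    df["reliability"] = df["reliability"].str.strip().str.lower().str.replace(" ", "_")
    bad = sorted(set(df["reliability"]) - set(VALID_GRADES))
    if bad:
        raise ValueError(f"{path}: unknown reliability grade(s) {bad}")
    dup = df["cluster"][df["cluster"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate cluster id(s) {sorted(set(dup))}")
    df["n_cells"] = df["n_cells"].astype(int)
    return df.set_index("cluster", drop=False)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
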