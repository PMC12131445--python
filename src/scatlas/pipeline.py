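"""End-to-end pipeline: QC -> pooling -> nTPM -> consensus -> classification,
with optional bulk comparison and deconvolution, driven by a single config.

Each stage writes its artifact into the output directory and logs under a
stage tag; a manifest records the package version, seed and a hash of the
effective parameters so a rerun with identical inputs is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierParams, classify_all, category_summary
from .compare import (
    classification_crosstab,
    detectability_partition,
    paired_tau_test,
    polyserial_correlation,
    tau_concordance,
    CATEGORY_ORDER,
)
from .consensus import (
    aggregate_to_cell_types,
    cell_type_fractions,
    spearman_similarity,
    ward_dendrogram,
)
from .deconvolve import build_signature, deconvolve_all
from .io import read_10x_triplet, read_annotation, read_table, write_table
from .pseudobulk import filter_reliability, ntpm, pool_clusters
from .qc import QCThresholds, compute_cell_qc, filter_cells

log = logging.getLogger("scatlas")


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    counts_dir: str
    metadata: str
    annotation: str
    outdir: str
    bulk: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    mito_prefix: str = "MT-"
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        qc_raw = raw.pop("qc", {})
        per_tissue = {
            t: QCThresholds(**v) for t, v in qc_raw.pop("per_tissue", {}).items()
        }
        qc = QCThresholds(per_tissue=per_tissue, **qc_raw)
        clf = ClassifierParams(**raw.pop("classifier", {}))
        ribo = raw.pop("ribo_prefixes", None)
        cfg = cls(qc=qc, classifier=clf, **raw)
        if ribo is not None:
            cfg.ribo_prefixes = tuple(ribo)
        return cfg

    def parameter_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level,
                        format="%(name)s %(levelname)s %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stages": [],
    }

    def stage(name: str):
        log.info("[%s] starting", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        counts = read_10x_triplet(config.counts_dir)
        metadata = pd.read_csv(config.metadata, sep="\t").set_index(
            "barcode", drop=False
        )
        annotation = read_annotation(config.annotation)

        stage("qc")
        mito = [g for g in counts.genes if g.startswith(config.mito_prefix)]
        ribo = [g for g in counts.genes
                if g.startswith(tuple(config.ribo_prefixes))]
        qc_table = compute_cell_qc(
            counts, mito, ribo,
            doublet_scores=metadata.get("doublet_score"),
        )
        kept: list[str] = []
        report = {}
        for tissue, grp in metadata.groupby("tissue"):
            k, removed = filter_cells(qc_table.loc[grp.index], config.qc, tissue)
            kept.extend(k)
            report[tissue] = {"kept": len(k), "removed_by": removed}
        write_table(qc_table, out / "cell_qc.tsv", index_label="barcode")
        (out / "filter_report.json").write_text(json.dumps(report, indent=1))
        kept_set = set(kept)
        keep_mask = [b in kept_set for b in counts.barcodes]
        counts = _subset_cells(counts, keep_mask)
        metadata = metadata.loc[[b for b in counts.barcodes]]
        log.info("[qc] kept %d cells", len(kept))

        stage("pseudobulk")
        pooled = pool_clusters(counts, metadata["cluster"], metadata["tissue"])
        profile = ntpm(pooled)
        write_table(pooled.counts, out / "pooled_counts.tsv", index_label="gene")
        write_table(profile.ntpm, out / "ntpm_clusters.tsv", index_label="gene")
        profile.factors.to_csv(out / "tmm_factors.tsv", sep="\t",
                               index_label="cluster")

        stage("reliability_filter")
        grades = annotation["reliability"]
        profile = filter_reliability(profile, grades)
        log.info("[reliability_filter] kept %d clusters", profile.ntpm.shape[1])

        stage("consensus")
        cluster_to_type = annotation["cell_type"]
        groups = annotation.set_index("cell_type")["cell_type_group"].to_dict()
        cons = aggregate_to_cell_types(profile, cluster_to_type, groups)
        write_table(cons.ntpm, out / "ntpm_celltypes.tsv", index_label="gene")
        meta_typed = metadata.join(
            annotation["cell_type"], on="cluster", how="inner"
        )
        fr = cell_type_fractions(meta_typed)
        write_table(fr, out / "cell_type_fractions.tsv", index_label="tissue")
        if cons.ntpm.shape[1] >= 2:
            corr = spearman_similarity(cons.ntpm)
            write_table(corr, out / "celltype_spearman.tsv", index_label="cell_type")
            dend = ward_dendrogram(corr)
            (out / "celltype_dendrogram.nwk").write_text(dend.newick + "\n")

        stage("classify")
        records = classify_all(cons.ntpm, config.classifier)
        write_table(records, out / "classification.tsv", index_label="gene")
        (out / "category_summary.json").write_text(
            json.dumps(category_summary(records), indent=1)
        )

        if config.bulk is not None:
            stage("compare")
            bulk_expr = read_table(config.bulk)
            bulk_records = classify_all(bulk_expr, config.classifier)
            common = records.index.intersection(bulk_records.index)
            tab = classification_crosstab(records, bulk_records)
            write_table(tab, out / "crosstab.tsv")
            rho, n_rho = tau_concordance(records["tau"], bulk_records["tau"])
            wtest = paired_tau_test(records["tau"], bulk_records["tau"])
            cat_codes = {c: i for i, c in enumerate(CATEGORY_ORDER)}
            mask = records.loc[common, "category"].isin(cat_codes) & records.loc[
                common, "tau"
            ].notna()
            poly = polyserial_correlation(
                records.loc[common[mask], "tau"].to_numpy(),
                records.loc[common[mask], "category"].map(cat_codes).to_numpy(),
            )
            concordance = {
                "spearman_tau": rho,
                "n_spearman": n_rho,
                "polyserial_sc": poly,
                "wilcoxon": wtest,
            }
            (out / "concordance.json").write_text(json.dumps(concordance, indent=1))
            part = detectability_partition(records, bulk_records, bulk_expr)
            (out / "detectability.json").write_text(json.dumps(part.sizes(), indent=1))

            stage("deconvolve")
            sig = build_signature(cons, records)
            write_table(sig.matrix, out / "signature.tsv", index_label="gene")
            common_genes = sig.matrix.index.intersection(bulk_expr.index)
            if len(common_genes) >= sig.matrix.shape[1]:
                props, topk = deconvolve_all(
                    sig.matrix.loc[common_genes],
                    bulk_expr.loc[common_genes],
                    fold_seed=config.seed,
                )
                write_table(props, out / "proportions.tsv", index_label="tissue")
                (out / "top_celltypes.json").write_text(json.dumps(topk, indent=1))
            else:
                log.warning("[deconvolve] too few shared signature genes; skipped")
        else:
            log.info("[compare] no bulk input; compare/deconvolve skipped")

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{manifest['stages'][-1] if manifest['stages'] else '?'}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _subset_cells(counts, mask):
    from .io import CountMatrix
    import numpy as np

    idx = np.flatnonzero(mask)
    return CountMatrix(
        counts.matrix[:, idx],
        counts.genes,
        [counts.barcodes[i] for i in idx],
    )
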