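import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import scatlas as sa

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def atlas():
    """Default-size synthetic atlas run end-to-end once per session.

    Generates profiles and counts at the generator defaults, applies QC,
    pools, normalizes, aggregates to consensus cell types and classifies.
    """
    cfg = sa.SimulationConfig(seed=11)
    profiles, truth = sa.simulate_profiles(cfg)
    counts, meta = sa.simulate_counts(profiles, cfg, truth)
    mito = [g for g in counts.genes if g.startswith("MT-")]
    ribo = [g for g in counts.genes if g.startswith("RPS")]
    qc_table = sa.compute_cell_qc(counts, mito, ribo, meta["doublet_score"])
    kept, removed = sa.filter_cells(qc_table, sa.QCThresholds())
    idx = np.flatnonzero(pd.Index(counts.barcodes).isin(kept))
    filtered = sa.CountMatrix(
        counts.matrix[:, idx], counts.genes, [counts.barcodes[i] for i in idx]
    )
    meta_kept = meta.loc[filtered.barcodes]
    pooled = sa.pool_clusters(filtered, meta_kept["cluster"], meta_kept["tissue"])
    profile = sa.ntpm(pooled)
    annotation = sa.default_annotation(cfg, truth, meta_kept)
    consensus = sa.aggregate_to_cell_types(profile, annotation["cell_type"])
    records = sa.classify_all(consensus.ntpm)
    return {
        "config": cfg,
        "profiles": profiles,
        "truth": truth,
        "counts": counts,
        "meta": meta,
        "qc": qc_table,
        "kept": kept,
        "removed": removed,
        "pooled": pooled,
        "profile": profile,
        "annotation": annotation,
        "consensus": consensus,
        "records": records,
    }


@pytest.fixture(scope="session")
def small_sim():
    """Small simulation for fast structural tests."""
    cfg = sa.SimulationConfig(
        n_genes=300,
        n_cell_types=6,
        clusters_per_type=2,
        cells_per_cluster=40,
        planted_counts={
            "enriched": 18,
            "group_enriched": 8,
            "enhanced": 8,
            "not_detected": 10,
        },
        group_size_range=(2, 3),
        seed=5,
    )
    profiles, truth = sa.simulate_profiles(cfg)
    counts, meta = sa.simulate_counts(profiles, cfg, truth)
    return cfg, profiles, truth, counts, meta
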