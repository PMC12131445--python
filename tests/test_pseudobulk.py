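"""Pooling, CPM, TMM and reliability filtering."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import rankdata

import scatlas as sa
from scatlas.pseudobulk import PooledCounts


def _cm(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return sa.CountMatrix(sp.csr_matrix(arr), genes, cells)


def test_pooling_sums_cluster_members():
    cm = _cm([[1, 3], [2, 0]])
    labels = pd.Series({"c0": "A", "c1": "A"})
    pooled = sa.pool_clusters(cm, labels)
    assert pooled.counts["A"].tolist() == [4, 2]
    assert pooled.meta.loc["A", "n_cells"] == 2


def test_pooling_identity_and_conservation():
    rng = np.random.default_rng(1)
    arr = rng.integers(0, 10, (5, 4))
    cm = _cm(arr)
    labels = pd.Series({f"c{i}": f"k{i}" for i in range(4)})
    pooled = sa.pool_clusters(cm, labels)
    np.testing.assert_array_equal(
        pooled.counts[[f"k{i}" for i in range(4)]].to_numpy(), arr
    )
    assert pooled.counts.to_numpy().sum() == arr.sum()


def test_unlabeled_cell_is_error():
    cm = _cm([[1, 1]])
    with pytest.raises(ValueError, match="unlabeled"):
        sa.pool_clusters(cm, pd.Series({"c0": "A"}))


def test_cpm_arithmetic_and_scale_invariance():
    df = pd.DataFrame({"A": [1, 1, 2]})
    out = sa.cpm(df)
    assert out["A"].tolist() == [250000.0, 250000.0, 500000.0]
    np.testing.assert_allclose(sa.cpm(df * 2)["A"], out["A"])
    already = pd.DataFrame({"A": [4e5, 6e5]})
    np.testing.assert_allclose(sa.cpm(already)["A"], already["A"])


def test_cpm_names_zero_cluster():
    df = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
    with pytest.raises(ValueError, match="B"):
        sa.cpm(df)


def test_tmm_identical_and_scaled_columns_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.integers(1, 100, 200).astype(float)
    same = pd.DataFrame({"A": col, "B": col, "C": col})
    np.testing.assert_allclose(sa.tmm_factors(same), 1.0)
    scaled = pd.DataFrame({"A": col, "B": col * 7})
    np.testing.assert_allclose(sa.tmm_factors(scaled), 1.0, atol=1e-12)


def _tmm_oracle(df, ref_j, trim_M=0.3, trim_A=0.05):
    """Independent trimmed-mean computation using explicit sorting."""
    X = df.to_numpy(float)
    N = X.sum(axis=0)
    log2f = []
    for j in range(X.shape[1]):
        x, r = X[:, j], X[:, ref_j]
        keep = (x > 0) & (r > 0)
        x, r = x[keep], r[keep]
        M = np.log2((x / N[j]) / (r / N[ref_j]))
        A = 0.5 * np.log2((x / N[j]) * (r / N[ref_j]))
        w = (N[j] - x) / (N[j] * x) + (N[ref_j] - r) / (N[ref_j] * r)
        if np.max(np.abs(M)) < 1e-6:
            log2f.append(0.0)
            continue
        n = len(M)
        loM = np.floor(n * trim_M) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * trim_A) + 1
        hiA = n + 1 - loA
        rM, rA = rankdata(M), rankdata(A)
        sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        log2f.append(np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    f = 2.0 ** np.asarray(log2f)
    return f / np.exp(np.mean(np.log(f)))


def test_tmm_spiked_toy_matches_trimmed_mean_oracle():
    rng = np.random.default_rng(3)
    base = rng.integers(5, 200, 300).astype(float)
    df = pd.DataFrame({
        "A": base,
        "B": base * rng.lognormal(0, 0.1, 300),
        "C": base * rng.lognormal(0, 0.1, 300),
    })
    df.iloc[:20, 2] *= 30  # spiked genes in C inflate its library artificially
    factors = sa.tmm_factors(df)
    # reference choice: upper-quartile of nonzero CPM closest to the mean
    cpm = df / df.sum() * 1e6
    uq = np.array([np.percentile(c[c > 0], 75) for c in cpm.to_numpy().T])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    np.testing.assert_allclose(factors, _tmm_oracle(df, ref_j), rtol=1e-12)
    # spikes inflate C's library; its factor drops below 1 so the CPM of
    # its unspiked genes is scaled back up in nTPM
    assert factors["C"] < 1.0


def test_tmm_matches_edger():
    """Cross-check the scaling factors against edgeR's calcNormFactors."""
    rng = np.random.default_rng(0)
    X = rng.negative_binomial(2, 0.01, size=(400, 4)).astype(float)
    X[:40, 0] *= 5
    df = pd.DataFrame(X, columns=list("ABCD"))
    ours = sa.tmm_factors(df)
    csv = "\n".join(",".join(str(v) for v in row) for row in X)
    script = (
        'suppressMessages(library(edgeR));'
        'x <- as.matrix(read.csv("stdin", header=FALSE));'
        'cat(calcNormFactors(x, method="TMM"), sep="\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], input=csv, capture_output=True, text=True,
        check=True,
    )
    theirs = np.array([float(v) for v in out.stdout.split()])
    np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=1e-6)


def test_ntpm_identity_when_columns_identical():
    col = np.arange(1, 51, dtype=float)
    df = pd.DataFrame({"A": col, "B": col})
    meta = pd.DataFrame({"n_cells": [1, 1]}, index=["A", "B"])
    profile = sa.ntpm(PooledCounts(df, meta))
    np.testing.assert_allclose(profile.ntpm.to_numpy(), sa.cpm(df).to_numpy())
    np.testing.assert_allclose(profile.factors, 1.0)


def test_ntpm_preserves_within_column_ranking(atlas):
    pooled = atlas["pooled"]
    profile = atlas["profile"]
    col = pooled.counts.columns[0]
    raw_rank = pooled.counts[col].rank(method="average")
    ntpm_rank = profile.ntpm[col].rank(method="average")
    pd.testing.assert_series_equal(raw_rank, ntpm_rank, check_names=False)


def test_tmm_factor_geometric_mean_is_one(atlas):
    # per-tissue normalization: geometric mean 1 within each tissue
    profile, pooled = atlas["profile"], atlas["pooled"]
    for _, group in pooled.meta.groupby("tissue"):
        logf = np.log(profile.factors[group.index])
        assert abs(logf.mean()) < 1e-12


def test_reliability_filter_rules():
    df = pd.DataFrame(np.arange(6, dtype=float).reshape(2, 3) + 1,
                      columns=["A", "B", "C"])
    prof = sa.PseudobulkProfile(df, pd.Series(1.0, index=df.columns))
    grades = {"A": "high", "B": "low", "C": "very_low"}
    out = sa.filter_reliability(prof, grades)
    assert list(out.ntpm.columns) == ["A"]
    all_high = sa.filter_reliability(prof, {c: "high" for c in df.columns})
    pd.testing.assert_frame_equal(all_high.ntpm, df)
    with pytest.raises(ValueError, match="ungraded"):
        sa.filter_reliability(prof, {"A": "high"})


def test_reliability_filter_at_atlas_scale():
    """557 clusters with 39 low/very-low graded leave 518 columns."""
    rng = np.random.default_rng(0)
    n_clusters = 557
    cols = [f"cl{i:03d}" for i in range(n_clusters)]
    df = pd.DataFrame(rng.random((10, n_clusters)), columns=cols)
    prof = sa.PseudobulkProfile(df, pd.Series(1.0, index=cols))
    bad = rng.choice(n_clusters, size=39, replace=False)
    grades = {c: "high" for c in cols}
    for i, j in enumerate(bad):
        grades[cols[j]] = "low" if i % 2 else "very_low"
    out = sa.filter_reliability(prof, grades)
    assert out.ntpm.shape[1] == 518
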