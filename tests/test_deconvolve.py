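"""Signature construction, DWLS proportion recovery, overlap tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import scatlas as sa


@pytest.fixture(scope="module")
def signature(atlas):
    return sa.build_signature(atlas["consensus"], atlas["records"])


def test_signature_contains_planted_enriched_genes(atlas, signature):
    truth = atlas["truth"]
    planted = set(truth.genes_in_category("enriched"))
    assert planted <= set(signature.matrix.index)
    assert signature.unidentifiable_types == []
    # rows are a projection of the consensus profile
    cons = atlas["consensus"].ntpm
    pd.testing.assert_frame_equal(
        signature.matrix, cons.loc[signature.matrix.index]
    )
    assert (signature.gene_categories == "enriched").all()


def test_removing_a_types_genes_flags_it(atlas):
    records = atlas["records"].copy()
    cons = atlas["consensus"].ntpm
    victim = cons.columns[0]
    mask = (records["category"] == "enriched") & (
        records["elevated_types"] == victim
    )
    records.loc[mask, "category"] = "enhanced"
    sig = sa.build_signature(cons, records)
    assert victim in sig.unidentifiable_types


def test_no_enriched_genes_is_error():
    df = pd.DataFrame({"t1": [1.0], "t2": [1.0]}, index=["g"])
    recs = pd.DataFrame({"category": ["low_specificity"], "elevated_types": [""]},
                        index=["g"])
    with pytest.raises(ValueError, match="enriched"):
        sa.build_signature(df, recs)


def test_exact_mixture_recovered_to_machine_precision(atlas, signature):
    cons = atlas["consensus"].ntpm
    k = cons.shape[1]
    rng = np.random.default_rng(0)
    p_true = rng.dirichlet(np.ones(k))
    bulk = pd.Series(cons.to_numpy() @ p_true, index=cons.index)
    res = sa.dwls_solve(signature, bulk)
    assert np.abs(res.proportions.to_numpy() - p_true).max() < 1e-6
    assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)


def test_pure_type_bulk_yields_unit_proportion(atlas, signature):
    cons = atlas["consensus"].ntpm
    t = cons.columns[3]
    res = sa.dwls_solve(signature, cons[t])
    assert res.proportions[t] == pytest.approx(1.0, abs=1e-6)


def test_dominant_type_ranked_first(atlas, signature):
    """A thymus-like mixture dominated by one cell type puts that type on
    top of the top-k report."""
    cons = atlas["consensus"].ntpm
    k = cons.shape[1]
    dominant = cons.columns[5]
    p = np.full(k, 0.3 / (k - 1))
    p[5] = 0.7
    props = pd.DataFrame([p], columns=cons.columns, index=["thymus_like"])
    cfg = sa.SimulationConfig(bulk_noise_sd=0.1, seed=4)
    bulk = sa.simulate_bulk(cons, props, cfg)
    est, topk = sa.deconvolve_all(signature, bulk.loc[signature.matrix.index])
    assert topk["thymus_like"][0][0] == dominant
    assert len(topk["thymus_like"]) == 5
    np.testing.assert_allclose(est.sum(axis=1), 1.0, atol=1e-9)


def test_k_top_larger_than_types_lists_all(atlas, signature):
    cons = atlas["consensus"].ntpm
    bulk = cons.iloc[:, [0]].copy()
    bulk.columns = ["b"]
    _, topk = sa.deconvolve_all(signature, bulk.loc[signature.matrix.index],
                                k_top=999)
    assert len(topk["b"]) == cons.shape[1]


def test_rank_deficient_signature_rejected():
    df = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [2.0, 4.0, 6.0]},
                      index=["a", "b", "c"])
    with pytest.raises(ValueError, match="rank"):
        sa.dwls_solve(df, pd.Series([1.0, 2.0, 3.0], index=df.index))


def test_noisy_dirichlet_mixtures_recovered(atlas, signature):
    """20 mixtures at 10% multiplicative noise recover with mean L1 < 0.05."""
    cons = atlas["consensus"].ntpm
    k = cons.shape[1]
    rng = np.random.default_rng(17)
    p_true = rng.dirichlet(np.ones(k), size=20)
    props = pd.DataFrame(p_true, columns=cons.columns,
                         index=[f"mix{i}" for i in range(20)])
    cfg = sa.SimulationConfig(bulk_noise_sd=0.1, seed=17)
    bulk = sa.simulate_bulk(cons, props, cfg)
    est, _ = sa.deconvolve_all(signature, bulk.loc[signature.matrix.index])
    l1 = np.abs(est.to_numpy() - p_true).sum(axis=1)
    assert l1.mean() < 0.05


def test_hypergeometric_reference_values():
    universe = {f"g{i}" for i in range(20)}
    a = {f"g{i}" for i in range(5)}
    r = sa.hypergeometric_overlap(a, a, universe)
    assert r.p_value == pytest.approx(1.0 / comb(20, 5, exact=True), rel=1e-12)
    disjoint = sa.hypergeometric_overlap(a, {f"g{i}" for i in range(5, 10)},
                                         universe)
    assert disjoint.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError, match="universe"):
        sa.hypergeometric_overlap({"zz"}, a, universe)


def test_hypergeometric_matches_exhaustive_enumeration():
    """For N <= 12, P(overlap >= observed) equals the exact fraction of all
    equally likely draws of the second set."""
    N, K, n = 12, 5, 6
    universe = {f"g{i}" for i in range(N)}
    set_a = {f"g{i}" for i in range(K)}
    # several observed sets with different overlaps
    for start in range(0, N - n + 1):
        set_b = {f"g{i}" for i in range(start, start + n)}
        observed = len(set_a & set_b)
        hits = 0
        total = 0
        for draw in itertools.combinations(sorted(universe), n):
            total += 1
            if len(set_a & set(draw)) >= observed:
                hits += 1
        p = sa.hypergeometric_overlap(set_a, set_b, universe).p_value
        assert p == pytest.approx(hits / total, rel=1e-12), start


def test_batch_overlap_bh_and_monotonicity():
    universe = {f"g{i}" for i in range(60)}
    sets_a = {"ct1": {f"g{i}" for i in range(10)},
              "ct2": {f"g{i}" for i in range(20, 30)}}
    sets_b = {"tis1": {f"g{i}" for i in range(8)},
              "tis2": {f"g{i}" for i in range(40, 50)}}
    df = sa.hypergeometric_overlap_batch(sets_a, sets_b, universe)
    assert (df["q_value"] >= df["p_value"] - 1e-15).all()
    strong = df[(df.set_a == "ct1") & (df.set_b == "tis1")].iloc[0]
    assert strong["significant"]
    # p monotone decreasing in overlap for fixed sizes
    from scipy.stats import hypergeom
    ps = [float(hypergeom.sf(k - 1, 60, 10, 8)) for k in range(9)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
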