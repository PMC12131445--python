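"""Crosstabs, tau concordance, polyserial correlation, paired test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, pearsonr

import scatlas as sa


def _records(cats, taus=None):
    idx = [f"g{i}" for i in range(len(cats))]
    df = pd.DataFrame({"category": cats}, index=idx)
    df["tau"] = taus if taus is not None else np.nan
    return df


def test_crosstab_identity_is_diagonal():
    a = _records(["enriched", "enhanced", "not_detected"])
    tab = sa.classification_crosstab(a, a)
    assert tab.to_numpy().sum() == 3
    assert tab.loc["enriched", "enriched"] == 1
    off = tab.to_numpy() - np.diag(np.diag(tab.to_numpy()))
    assert off.sum() == 0


def test_crosstab_hand_counted():
    a = _records(["enriched", "enriched", "enhanced", "low_specificity",
                  "not_detected", "group_enriched"])
    b = _records(["enriched", "enhanced", "enhanced", "low_specificity",
                  "enriched", "group_enriched"])
    tab = sa.classification_crosstab(a, b)
    assert tab.loc["enriched", "enriched"] == 1
    assert tab.loc["enriched", "enhanced"] == 1
    assert tab.loc["not_detected", "enriched"] == 1
    # margins conserve the intersection
    assert tab.sum().sum() == 6
    assert tab.sum(axis=1)["enriched"] == 2
    with pytest.raises(ValueError, match="shared"):
        sa.classification_crosstab(a, _records(["enriched"]).rename(index={"g0": "zz"}))


def test_tau_concordance_identity_and_null():
    taus = pd.Series(np.linspace(0.1, 0.9, 50), index=[f"g{i}" for i in range(50)])
    rho, n = sa.tau_concordance(taus, taus)
    assert rho == pytest.approx(1.0)
    assert n == 50
    rng = np.random.default_rng(0)
    a = pd.Series(rng.random(10_000))
    b = pd.Series(rng.random(10_000))
    rho_null, _ = sa.tau_concordance(a, b)
    assert abs(rho_null) < 0.05


def test_tau_concordance_matches_rank_pearson_oracle():
    a = pd.Series([0.1, 0.5, 0.3, 0.9, 0.7], index=list("abcde"))
    b = pd.Series([0.2, 0.4, 0.1, 0.8, 0.95], index=list("abcde"))
    rho, _ = sa.tau_concordance(a, b)
    expect = pearsonr(a.rank(), b.rank()).statistic
    assert rho == pytest.approx(expect, abs=1e-12)


def test_polyserial_independence_is_near_zero():
    x, y = sa.simulate_bivariate_ordinal(0.0, [-0.5, 0.5], 20_000, seed=1)
    assert abs(sa.polyserial_correlation(x, y)) < 3 / np.sqrt(20_000)


def test_polyserial_recovers_planted_rho():
    x, y = sa.simulate_bivariate_ordinal(0.8, [-0.5, 0.5, 1.5], 20_000, seed=2)
    assert sa.polyserial_correlation(x, y) == pytest.approx(0.8, abs=0.03)


def test_polyserial_binary_matches_biserial_closed_form():
    x, y = sa.simulate_bivariate_ordinal(0.5, [0.3], 5_000, seed=3)
    est = sa.polyserial_correlation(x, y)
    p = y.mean()  # fraction in upper level
    r_pb = pearsonr(x, y).statistic
    tau_hat = norm.ppf(1 - p)
    biserial = r_pb * np.sqrt(p * (1 - p)) / norm.pdf(tau_hat)
    # the two-step estimator uses the ddof=1 sd; agreement to ~sqrt(n/(n-1))
    assert est == pytest.approx(biserial, rel=2e-4)


def test_polyserial_input_validation():
    with pytest.raises(ValueError, match="constant"):
        sa.polyserial_correlation(np.ones(100), np.arange(100) % 3)
    with pytest.raises(ValueError, match="levels"):
        sa.polyserial_correlation(np.random.default_rng(0).random(100),
                                  np.zeros(100))


def _signed_rank_exact_p(diffs):
    """Independent exact null of the signed-rank statistic by convolution."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    # distribution of W+ under random signs: polynomial product of (1 + z^r)
    total = int(n * (n + 1) // 2)
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:-r] if r else dist
        dist = dist + shifted
    dist /= dist.sum()
    return dist[int(round(w_obs)):].sum()


def test_paired_test_matches_exact_signed_rank_null():
    rng = np.random.default_rng(7)
    base = rng.random(50) * 0.5 + 0.2
    shift = base + rng.normal(0.03, 0.05, 50)
    idx = [f"g{i}" for i in range(50)]
    a = pd.Series(shift, index=idx)
    b = pd.Series(base, index=idx)
    out = sa.paired_tau_test(a, b)
    diffs = (a - b).to_numpy()
    assert out["p_value"] == pytest.approx(_signed_rank_exact_p(diffs), abs=1e-10)


def test_paired_test_boundaries():
    idx = [f"g{i}" for i in range(20)]
    b = pd.Series(np.linspace(0.1, 0.9, 20), index=idx)
    up = sa.paired_tau_test(b + 0.1, b)
    assert up["p_value"] < 1e-4
    with pytest.warns(UserWarning, match="zero"):
        same = sa.paired_tau_test(b, b)
    assert same["p_value"] == 1.0 and same["n"] == 0


def test_detectability_partition_toy():
    sc = _records(
        ["enriched", "not_detected", "enhanced", "not_detected",
         "low_specificity", "not_detected", "enriched", "group_enriched"]
    )
    sc["distribution"] = ["detected_in_single", "not_detected", "detected_in_all",
                          "not_detected", "detected_in_all", "not_detected",
                          "detected_in_some", "detected_in_many"]
    bulk = _records(
        ["enriched", "enhanced", "not_detected", "not_detected",
         "low_specificity", "enriched", "enriched", "not_detected"]
    )
    expr = pd.DataFrame(
        {"liver": [10.0, 55.0, 0, 0, 5, 80.0, 9, 0],
         "lung": [1.0, 5.0, 0, 0, 9, 2.0, 9, 0]},
        index=sc.index,
    )
    part = sa.detectability_partition(sc, bulk, expr)
    assert part.sizes() == {"both_detected": 3, "sc_only": 2, "bulk_only": 2,
                            "neither": 1}
    assert set(part.sc_only) == {"g2", "g7"}
    assert set(part.bulk_only) == {"g1", "g5"}
    assert part.bulk_only_max.loc["g1", "max_ntpm"] == 55.0
    assert part.bulk_only_max.loc["g1", "tissue"] == "liver"
    assert part.sc_only_distribution["g7"] == "detected_in_many"
    assert sum(part.sizes().values()) == 8


def test_partition_empty_when_detection_agrees():
    sc = _records(["enriched", "not_detected"])
    sc["distribution"] = ["detected_in_single", "not_detected"]
    bulk = _records(["low_specificity", "not_detected"])
    expr = pd.DataFrame({"t": [1.0, 0.0]}, index=sc.index)
    part = sa.detectability_partition(sc, bulk, expr)
    assert part.sc_only == [] and part.bulk_only == []
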