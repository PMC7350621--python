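"""Apoptotic index, body-weight change and the comparison decision tree."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurostereo import (FieldCount, WeightRecord, apoptotic_index,
                         body_weight_percent, compare_groups, dunn_test,
                         levene_variance_test, two_way_anova)


# -- apoptotic index --------------------------------------------------------

def test_index_single_field():
    res = apoptotic_index([FieldCount(0, 30, 100)])
    assert res.animal_index == 30.0


def test_index_zero_apoptotic():
    res = apoptotic_index([FieldCount(0, 0, 50), FieldCount(1, 0, 70)])
    assert res.animal_index == 0.0


def test_pooling_modes_agree_iff_totals_equal():
    equal = [FieldCount(0, 10, 100), FieldCount(1, 30, 100)]
    assert apoptotic_index(equal, "pooled_counts").animal_index == pytest.approx(20.0)
    assert apoptotic_index(equal, "mean_of_fields").animal_index == pytest.approx(20.0)
    unequal = [FieldCount(0, 10, 50), FieldCount(1, 10, 100)]
    pooled = apoptotic_index(unequal, "pooled_counts").animal_index
    meaned = apoptotic_index(unequal, "mean_of_fields").animal_index
    assert pooled == pytest.approx(20.0 / 150.0 * 100.0)  # 13.33
    assert meaned == pytest.approx((20.0 + 10.0) / 2.0)   # 15.0
    assert pooled != meaned


def test_index_bounded_and_monotone(rng):
    totals = rng.integers(10, 100, 20)
    for t in totals:
        lo = apoptotic_index([FieldCount(0, 0, int(t))]).animal_index
        hi = apoptotic_index([FieldCount(0, int(t), int(t))]).animal_index
        assert lo == 0.0 and hi == 100.0


def test_index_invalid_counts_rejected():
    with pytest.raises(ValueError):
        FieldCount(0, 5, 3)
    with pytest.raises(ValueError):
        apoptotic_index([])


# -- body weight ------------------------------------------------------------

def test_body_weight_gain():
    assert body_weight_percent(WeightRecord(day1=250, day21=295)) == pytest.approx(18.0)


def test_body_weight_identity_and_loss():
    assert body_weight_percent(WeightRecord(day1=280, day21=280)) == 0.0
    assert body_weight_percent(WeightRecord(day1=300, day21=292)) == pytest.approx(
        -2.6667, abs=1e-3)


def test_body_weight_missing_day():
    with pytest.raises(ValueError):
        body_weight_percent(WeightRecord(day1=250))


# -- Dunn's test ------------------------------------------------------------

def test_dunn_matches_brute_force_ranks():
    groups = {"a": np.array([1.0, 2.0, 4.0]),
              "b": np.array([3.0, 5.0, 6.0]),
              "c": np.array([7.0, 8.0, 9.0])}
    out = dunn_test(groups)
    # independent computation for the (a, b) pair, no ties
    pooled = np.concatenate(list(groups.values()))
    ranks = sps.rankdata(pooled)
    ra, rb = ranks[:3].mean(), ranks[3:6].mean()
    n = len(pooled)
    se = np.sqrt(n * (n + 1) / 12.0 * (1 / 3 + 1 / 3))
    z = (ra - rb) / se
    row = out[(out.group1 == "a") & (out.group2 == "b")].iloc[0]
    assert row.z == pytest.approx(z)
    assert row.p_value == pytest.approx(2 * sps.norm.sf(abs(z)))


def test_dunn_bonferroni_inflates_p():
    rng = np.random.default_rng(0)
    groups = {g: rng.normal(0, 1, 8) for g in "abc"}
    plain = dunn_test(groups)
    adj = dunn_test(groups, adjust="bonferroni")
    assert np.all(adj["p_adjusted"].to_numpy() >= plain["p_value"].to_numpy())


# -- decision tree ----------------------------------------------------------

def test_identical_groups_declare_no_difference():
    res = compare_groups({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0, 5.0]})
    assert res.p_value == 1.0
    assert res.degenerate
    assert not res.significant


def test_branches_recorded_and_consistent(rng):
    normal = {g: rng.normal(0, 1, 10) for g in "abcd"}
    res = compare_groups(normal)
    assert res.test_used in ("one-way-anova+tukey", "kruskal-wallis+dunn")
    assert res.parametric == (res.test_used == "one-way-anova+tukey")
    assert set(res.normality_p) == set("abcd")
    # forcing either branch runs the corresponding test
    assert compare_groups(normal, branch="parametric").parametric
    assert not compare_groups(normal, branch="nonparametric").parametric


def test_tree_is_deterministic(rng):
    groups = {g: rng.normal(0, 1, 8) for g in "abc"}
    r1 = compare_groups(groups)
    r2 = compare_groups(groups)
    assert r1.p_value == r2.p_value and r1.test_used == r2.test_used


def test_pairwise_design_runs_mann_whitney(rng):
    res = compare_groups({"a": rng.normal(0, 1, 8), "b": rng.normal(5, 1, 8)},
                         design="pairwise")
    assert res.test_used == "mann-whitney"
    assert res.significant
    assert len(res.posthoc) == 1


def test_strong_effect_detected_parametrically(rng):
    groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
              "c": rng.normal(4, 1, 10)}
    res = compare_groups(groups, branch="parametric")
    assert res.significant
    ph = res.posthoc
    assert ph is not None and len(ph) == 3  # all pairs in the Tukey table


def test_two_way_anova_detects_main_effect(rng):
    rows = []
    for g, shift in (("ctrl", 0.0), ("treated", 3.0)):
        for day in (1, 7, 14, 21):
            for _ in range(6):
                rows.append({"value": rng.normal(shift + day * 0.1, 1.0),
                             "group": g, "day": day})
    res = two_way_anova(pd.DataFrame(rows), "value", "group", "day")
    assert res.significant
    assert any("C(fa):C(fb)" in str(i) for i in res.posthoc["index"])


def test_levene_flags_unequal_variances(rng):
    res = levene_variance_test({"a": rng.normal(0, 1, 40),
                                "b": rng.normal(0, 6, 40)})
    assert res.test_used == "levene"
    assert res.significant
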