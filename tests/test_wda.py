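"""Weighted-digital-analysis fitting, prediction, and blinding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import breathval as bv
from breathval.errors import DegenerateInputError, ValidationError
from breathval.wda import _best_cutoff

from conftest import make_feature_matrix


def _single_feature_model(cancer, control, feature="seg0_mz43"):
    values = np.array(cancer + control, dtype=float)
    labels = np.array([1] * len(cancer) + [0] * len(control))
    fm = make_feature_matrix(values[:, None], [feature])
    key = bv.FeatureKey.from_column(feature)
    c, orient = bv.cstat(values, labels)
    score = bv.MarkerScore(key, c, orient, np.array([0.5, 0.5]))
    return bv.WDAModel(fm, labels, [key], [score]), key


def test_fit_finds_separating_midpoint_cutoff():
    model, key = _single_feature_model([2, 3, 4], [0, 0, 1])
    results = model.fit()
    rule = results.rules[0]
    assert rule.cutoff == pytest.approx(1.5)
    assert rule.sign == +1
    assert rule.weight == pytest.approx(1.0)  # perfectly separating feature
    assert results.training_summary["sensitivity"] == 1.0
    assert results.training_summary["specificity"] == 1.0


def test_constant_feature_warns_and_never_fires():
    model, key = _single_feature_model([1, 1, 1], [1, 1, 1])
    with pytest.warns(UserWarning, match="constant feature"):
        results = model.fit()
    dfs = results.predict(model.fm)
    assert (dfs == 0).all()


def test_refit_is_deterministic(small_cohort):
    screen = bv.screen_features(small_cohort["fm"], small_cohort["y"],
                                seed=2, groups=small_cohort["subjects"])
    r1 = bv.fit_wda(small_cohort["fm"], small_cohort["y"],
                    screen.selected, screen)
    r2 = bv.fit_wda(small_cohort["fm"], small_cohort["y"],
                    screen.selected, screen)
    assert r1.rules == r2.rules
    assert r1.frozen_hash == r2.frozen_hash


def test_fit_rejects_degenerate_inputs(small_cohort):
    screen = bv.screen_features(small_cohort["fm"], small_cohort["y"],
                                seed=2, groups=small_cohort["subjects"])
    with pytest.raises(ValidationError):
        bv.fit_wda(small_cohort["fm"], small_cohort["y"], [], screen)
    with pytest.raises(DegenerateInputError):
        bv.fit_wda(small_cohort["fm"],
                   np.ones_like(small_cohort["y"]),
                   screen.selected, screen)


def _two_rule_results():
    rules = [
        bv.WDARule(bv.FeatureKey(0, 43), cutoff=1.0, sign=+1, weight=0.70),
        bv.WDARule(bv.FeatureKey(0, 57), cutoff=2.0, sign=-1, weight=0.60),
    ]
    return bv.WDAResults(rules=rules)


def test_predict_sums_weighted_votes():
    results = _two_rule_results()
    fm = make_feature_matrix([[1.5, 1.5], [0.0, 0.0], [1.5, 3.0]],
                             ["seg0_mz43", "seg0_mz57"])
    dfs = results.predict(fm)
    # sample 0: both rules fire -> 0.70 + 0.60
    assert dfs.iloc[0] == pytest.approx(1.30)
    # sample 1: +1 rule below cutoff, -1 rule fires (0 < 2)
    assert dfs.iloc[1] == pytest.approx(0.60)
    # sample 2: only the +1 rule fires
    assert dfs.iloc[2] == pytest.approx(0.70)


def test_all_zero_sample_with_positive_signs_scores_zero():
    rules = [bv.WDARule(bv.FeatureKey(0, 43), 0.5, +1, 0.9),
             bv.WDARule(bv.FeatureKey(0, 57), 0.2, +1, 0.8)]
    results = bv.WDAResults(rules=rules)
    fm = make_feature_matrix([[0.0, 0.0]], ["seg0_mz43", "seg0_mz57"])
    assert results.predict(fm).iloc[0] == 0.0


def test_crossing_a_positive_cutoff_never_decreases_df():
    results = _two_rule_results()
    lo = make_feature_matrix([[0.9, 3.0]], ["seg0_mz43", "seg0_mz57"])
    hi = make_feature_matrix([[1.1, 3.0]], ["seg0_mz43", "seg0_mz57"])
    assert results.predict(hi).iloc[0] >= results.predict(lo).iloc[0]


def test_absent_feature_counts_as_zero_intensity():
    results = _two_rule_results()
    fm = make_feature_matrix([[1.5]], ["seg0_mz43"])  # mz-57 rule absent
    # x=0 for the -1 rule: 0 < 2 so it fires; +1 rule fires at 1.5 > 1
    assert results.predict(fm).iloc[0] == pytest.approx(1.30)


def test_classification_uses_strict_inequality():
    dfs = pd.Series([22.0, 22.5, 0.4], index=["a", "b", "c"])
    calls = bv.classify(dfs, 22.0)
    assert calls.tolist() == [0, 1, 0]  # DF equal to the cutoff is negative
    assert bv.classify(dfs, 0.0).tolist() == [1, 1, 1]
    assert bv.classify(dfs, 1e9).tolist() == [0, 0, 0]
    with pytest.raises(ValidationError):
        bv.classify(dfs, -1.0)


def test_df_values_bounded_by_total_weight(small_cohort):
    screen = bv.screen_features(small_cohort["fm"], small_cohort["y"],
                                seed=2, groups=small_cohort["subjects"])
    results = bv.fit_wda(small_cohort["fm"], small_cohort["y"],
                         screen.selected, screen)
    dfs = results.predict(small_cohort["fm"])
    assert (dfs >= 0).all()
    assert (dfs <= results.max_df + 1e-9).all()


def test_prediction_ignores_metadata(small_cohort):
    """Shuffling (or removing) sample metadata cannot change DF values."""
    screen = bv.screen_features(small_cohort["fm"], small_cohort["y"],
                                seed=2, groups=small_cohort["subjects"])
    results = bv.fit_wda(small_cohort["fm"], small_cohort["y"],
                         screen.selected, screen)
    fm = small_cohort["fm"]
    baseline = results.predict(fm)
    shuffled_meta = small_cohort["meta"].sample(
        frac=1.0, random_state=0).reset_index(drop=True)
    shuffled_meta["cancer_status"] = "unknown"
    fm_shuffled = bv.FeatureMatrix(fm.data.copy(), None)
    pd.testing.assert_series_equal(baseline, results.predict(fm_shuffled))


def brute_force_cutoff(values, labels, sign, criterion="youden"):
    """Independent exhaustive sweep over candidate midpoints."""
    distinct = sorted(set(values))
    if len(distinct) < 2:
        return distinct[0], 0.0
    best = None
    for a, b in zip(distinct, distinct[1:]):
        c = (a + b) / 2.0
        tp = fn = tn = fp = 0
        for v, l in zip(values, labels):
            pred = sign * (v - c) > 0
            if l and pred:
                tp += 1
            elif l:
                fn += 1
            elif pred:
                fp += 1
            else:
                tn += 1
        if criterion == "youden":
            score = tp / (tp + fn) + tn / (tn + fp) - 1.0
        else:
            score = (tp + tn) / len(values)
        if best is None or score > best[1]:
            best = (c, score)
    return best


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    values=st.lists(st.integers(min_value=0, max_value=12), min_size=4,
                    max_size=30),
    sign=st.sampled_from([-1, 1]),
    data=st.data(),
)
def test_fitted_cutoff_matches_exhaustive_sweep(values, sign, data):
    n = len(values)
    labels = data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n).filter(
            lambda ls: any(ls) and not all(ls)))
    x = np.array(values, dtype=float)
    y = np.array(labels, dtype=bool)
    got_c, got_s = _best_cutoff(x, y, sign, "youden")
    exp_c, exp_s = brute_force_cutoff(values, labels, sign)
    assert got_s == pytest.approx(exp_s)
    assert got_c == pytest.approx(exp_c)


def test_results_json_round_trip_and_summary(tmp_path, small_cohort):
    screen = bv.screen_features(small_cohort["fm"], small_cohort["y"],
                                seed=2, groups=small_cohort["subjects"])
    results = bv.fit_wda(small_cohort["fm"], small_cohort["y"],
                         screen.selected, screen)
    path = str(tmp_path / "model.json")
    results.to_json(path)
    back = bv.WDAResults.from_json(path)
    assert back.rules == results.rules
    assert back.frozen_hash == results.frozen_hash
    text = results.summary()
    assert f"Rules (markers):        {results.k}" in text
    assert "Training C-statistic" in text
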