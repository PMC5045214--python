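"""Confusion metrics, ROC, group statistics, and the LOOCV harness."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuromkl import (CohortConfig, ConfusionCounts, confusion_metrics,
                      counts_from_rates, extract_features, feature_frequency,
                      group_stats, loocv, make_atlas, roc_auc,
                      run_comparison_modes, simulate_cohort, top_features)
from neuromkl.features import FeatureTable
from neuromkl.selection import SelectionRecord


def auc_oracle(scores_patient_like, y):
    """Exhaustive Mann-Whitney pair counting, ties worth 1/2."""
    pos = scores_patient_like[y == -1]
    neg = scores_patient_like[y == 1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_confusion_metrics_reported_study_values():
    m = confusion_metrics(ConfusionCounts(tp=26, fn=2, tn=15, fp=6))
    assert round(m.sensitivity, 2) == 92.86
    assert round(m.specificity, 2) == 71.43
    assert round(m.accuracy, 2) == 83.67


def test_confusion_metrics_symmetric_and_perfect_cases():
    m = confusion_metrics(ConfusionCounts(tp=5, fn=5, tn=7, fp=7))
    assert m.sensitivity == m.specificity == m.accuracy == 50.0
    m = confusion_metrics(ConfusionCounts(tp=10, fn=0, tn=12, fp=0))
    assert m.sensitivity == m.specificity == m.accuracy == 100.0


@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
       st.integers(0, 30))
def test_confusion_identities_hold_on_integers(tp, fn, tn, fp):
    if tp + fn == 0 or tn + fp == 0:
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = confusion_metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
    assert m.accuracy == pytest.approx(100 * (tp + tn) / (tp + fn + tn + fp))
    assert 0 <= m.sensitivity <= 100 and 0 <= m.specificity <= 100


def test_counts_from_rates_recovers_integer_consistent_table():
    c = counts_from_rates(92.86, 71.43, (21, 28))
    assert (c.tp, c.fn, c.tn, c.fp) == (26, 2, 15, 6)
    c = counts_from_rates(85.71, 52.38, (21, 28))
    assert (c.tp + c.tn) == 35  # accuracy 71.43% of 49


def test_roc_auc_trivial_and_hand_enumerated():
    y = np.array([-1, -1, 1, 1])
    # control-like scores: patients very negative -> perfect separation
    auc, _, _ = roc_auc(np.array([-2.0, -1.0, 1.0, 2.0]), y)
    assert auc == 1.0
    scores = np.array([-0.9, 0.7, -0.8, 0.6])
    y2 = np.array([-1, -1, 1, 1])
    auc, _, _ = roc_auc(scores, y2)
    assert auc == auc_oracle(-scores, y2)


@given(st.integers(0, 10 ** 6))
def test_roc_auc_equals_mann_whitney_on_random_scores(seed):
    rng = np.random.default_rng(seed)
    n = 12
    y = np.array([-1] * 5 + [1] * 7)
    scores = rng.integers(-3, 4, size=n).astype(float)  # ties likely
    if np.ptp(scores) == 0:
        return
    auc, _, _ = roc_auc(scores, y)
    assert auc == pytest.approx(auc_oracle(-scores, y), abs=1e-12)


def test_shuffled_labels_give_chance_auc():
    rng = np.random.default_rng(0)
    scores = rng.standard_normal(40)
    aucs = []
    for s in range(100):
        perm = np.random.default_rng(s).permutation(40)
        y = np.array([-1] * 20 + [1] * 20)[perm]
        aucs.append(roc_auc(scores, y)[0])
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_group_statistics_match_reported_demographics():
    gs = group_stats(27.52, 8.15, 21, 29.18, 6.96, 28,
                     counts_2x2=np.array([[5, 16], [13, 15]]))
    assert gs.t_pooled == pytest.approx(-0.766, abs=0.01)
    assert gs.chi2 == pytest.approx(2.642, abs=5e-4)
    gs = group_stats(6.48, 6.46, 21, 2.46, 2.17, 28)
    assert gs.t_welch == pytest.approx(2.735, abs=0.01)


def _toy_tables(seed, n_per=8, p=6, informative=None, channels=("A", "B")):
    rng = np.random.default_rng(seed)
    labels = ("patient",) * n_per + ("control",) * n_per
    y = np.array([-1] * n_per + [1] * n_per)
    tables = {}
    for ch in channels:
        X = rng.standard_normal((2 * n_per, p))
        if informative and ch in informative:
            X[:, informative[ch]] += np.where(y == -1, 2.5, -2.5)
        tables[ch] = FeatureTable(
            matrix=X, channel=ch, roi_ids=tuple(range(1, p + 1)),
            subject_ids=tuple(f"s{i}" for i in range(2 * n_per)), labels=labels)
    return tables


def test_loocv_runs_one_fold_per_subject_and_separates_strong_effects():
    tables = _toy_tables(3, informative={"A": 1, "B": 4})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = loocv(tables)
    assert len(report.folds) == 16
    assert {f.test_subject for f in report.folds} == set(tables["A"].subject_ids)
    assert report.metrics.accuracy == 100.0
    # the informative features dominate the frequency tables
    assert top_features(report.feature_counts["A"], 1)[0][0] == 2
    assert top_features(report.feature_counts["B"], 1)[0][0] == 5


def test_loocv_never_leaks_held_out_subject():
    tables = _toy_tables(4, informative={"A": 0})
    mutated = {}
    for ch, tab in tables.items():
        m = tab.matrix.copy()
        m[3] += 57.0  # corrupt one subject's features wildly
        mutated[ch] = FeatureTable(matrix=m, channel=ch, roi_ids=tab.roi_ids,
                                   subject_ids=tab.subject_ids, labels=tab.labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1, r2 = loocv(tables), loocv(mutated)
    f1, f2 = r1.folds[3], r2.folds[3]
    for ch in tables:
        assert f1.selections[ch].final_subset == f2.selections[ch].final_subset
        assert f1.selections[ch].rfe_ranking == f2.selections[ch].rfe_ranking
    assert f1.beta == pytest.approx(f2.beta)


def test_comparison_modes_counting_and_single_channel_reduction():
    tables = _toy_tables(5, informative={"A": 1, "B": 4})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reports = run_comparison_modes(tables)
        # 2 channels -> 3 subsets + concatenation
        assert set(reports) == {"A", "B", "A+B", "concat"}
        report_a = loocv({"A": tables["A"]})
    np.testing.assert_allclose(reports["A"].scores, report_a.metrics.scores,
                               atol=1e-9)


def test_feature_frequency_counts_and_truncation():
    rec = SelectionRecord(channel="A", fold_index=0, feature_ids=(1, 2, 3),
                          ttest_survivors=(1, 2), t_values={}, p_values={},
                          rfe_ranking=(2, 1), final_subset=(2,))
    counts = feature_frequency([{"A": rec}] * 5)
    assert counts["A"] == {2: 5}
    assert top_features(counts["A"], top_k=10) == [(2, 5)]
    # ties broken by roi id ascending
    assert top_features({7: 3, 2: 3, 5: 1}, top_k=2) == [(2, 3), (7, 3)]
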