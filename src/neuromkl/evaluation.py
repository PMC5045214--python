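"""Leave-one-out evaluation of the multi-kernel pipeline.

Each subject is held out once; on the remaining subjects the features
are z-scored, filtered (pooled t-test, p < alpha) and ranked (SVM-RFE)
per channel, base kernels are built on the selected subsets, the
multi-kernel SVM is fitted, and the held-out subject is scored.  Pooled
decision scores give a single ROC over all subjects; confusion counts
give

    sensitivity = TP / (TP + FN)      (patients correctly classified)
    specificity = TN / (TN + FP)      (controls correctly classified)
    accuracy    = (TP + TN) / (TP + FN + TN + FP)

with patients as the positive class.  Comparison modes rerun the same
fold structure on every non-empty channel subset (single kernels for
single channels, multi-kernel otherwise) plus direct feature
concatenation under one single kernel.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .features import FeatureTable
from .mkl import (decision_score, fit_mkl, linear_kernel, make_bundle,
                  predict_label)
from .selection import SelectionRecord, fold_normalize, select_features

PATIENT, CONTROL = -1, 1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale confusion metrics plus AUC and per-subject scores."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None = None
    scores: tuple[float, ...] = ()
    predictions: tuple[int, ...] = ()


@dataclass(frozen=True)
class FoldRecord:
    fold_index: int
    test_subject: str
    true_label: int
    score: float
    prediction: int
    beta: dict[str, float]
    selections: dict[str, SelectionRecord]


@dataclass(frozen=True)
class CVReport:
    folds: tuple[FoldRecord, ...]
    metrics: MetricsReport
    feature_counts: dict[str, dict[int, int]]  # channel -> roi_id -> folds selected


@dataclass(frozen=True)
class GroupStats:
    t_pooled: float
    p_pooled: float
    t_welch: float
    p_welch: float
    chi2: float | None = None
    p_chi2: float | None = None


def confusion_metrics(counts: ConfusionCounts, scores=None, predictions=None,
                      auc: float | None = None) -> MetricsReport:
    """Sensitivity/specificity/accuracy (percent) from integer counts."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    npos, nneg = counts.tp + counts.fn, counts.tn + counts.fp
    if npos == 0 or nneg == 0:
        warnings.warn("a class is empty; sensitivity or specificity undefined",
                      stacklevel=2)
    sens = 100.0 * counts.tp / npos if npos else float("nan")
    spec = 100.0 * counts.tn / nneg if nneg else float("nan")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    return MetricsReport(counts=counts, sensitivity=sens, specificity=spec,
                         accuracy=acc, auc=auc,
                         scores=tuple(scores) if scores is not None else (),
                         predictions=tuple(predictions) if predictions is not None else ())


def counts_from_rates(sensitivity_pct: float, specificity_pct: float,
                      group_sizes: tuple[int, int]) -> ConfusionCounts:
    """Integer confusion table consistent with printed percentages.

    Tries both assignments of the two group sizes to the sensitivity and
    specificity denominators and returns the one whose implied counts
    are closest to integers (then rounds).  Useful for auditing reported
    percentages whose raw counts were not published.
    """
    best = None
    for npos, nneg in (group_sizes, group_sizes[::-1]):
        tp, tn = sensitivity_pct / 100.0 * npos, specificity_pct / 100.0 * nneg
        err = abs(tp - round(tp)) + abs(tn - round(tn))
        cand = ConfusionCounts(tp=round(tp), fn=npos - round(tp),
                               tn=round(tn), fp=nneg - round(tn))
        if best is None or err < best[0]:
            best = (err, cand)
    return best[1]


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC for the patient class with the score sign convention above.

    Scores are oriented so that larger means more control-like (+1), so
    the patient-positive AUC uses the negated score.  Equals the
    Mann-Whitney U statistic over (patient, control) pairs normalized by
    n1*n2, ties counting 1/2.  Returns (auc, fpr, tpr).
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if len(set(np.unique(y))) < 2:
        raise ValueError("both classes required for ROC")
    if np.ptp(scores) == 0:
        warnings.warn("constant decision scores; AUC degenerate at 0.5", stacklevel=2)
        return 0.5, np.array([0.0, 1.0]), np.array([0.0, 1.0])
    y_pos = (y == PATIENT).astype(int)
    auc = float(roc_auc_score(y_pos, -scores))
    fpr, tpr, _ = roc_curve(y_pos, -scores)
    return auc, fpr, tpr


def _tables_y(tables: dict[str, FeatureTable]) -> np.ndarray:
    ys = {t.labels for t in tables.values()}
    if len(ys) != 1:
        raise ValueError("channels disagree on subject labels")
    return next(iter(tables.values())).y


def _counts_from_predictions(y: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    y, pred = np.asarray(y), np.asarray(pred)
    return ConfusionCounts(
        tp=int(np.sum((y == PATIENT) & (pred == PATIENT))),
        fn=int(np.sum((y == PATIENT) & (pred == CONTROL))),
        tn=int(np.sum((y == CONTROL) & (pred == CONTROL))),
        fp=int(np.sum((y == CONTROL) & (pred == PATIENT))))


def _fold_channel_selection(tables, y, test_i, alpha, C, rfe_step, rfe_inner_cv):
    """Normalize + select per channel for one fold; returns per-channel
    (records, normalized train/test rows restricted to kept columns)."""
    n = len(y)
    train_idx = np.array([j for j in range(n) if j != test_i])
    mats, test_rows, fid_lists = {}, {}, {}
    for ch, tab in tables.items():
        tr, te, stats_ = fold_normalize(tab.matrix[train_idx],
                                        tab.matrix[test_i:test_i + 1])
        mats[ch] = (tr, tuple(tab.roi_ids[k] for k in stats_.kept))
        test_rows[ch] = te
    records = select_features(mats, y[train_idx], fold_index=test_i, alpha=alpha,
                              C=C, rfe_step=rfe_step, rfe_inner_cv=rfe_inner_cv)
    sel_train, sel_test = {}, {}
    for ch, rec in records.items():
        if rec.empty:
            continue
        fids = mats[ch][1]
        cols = [fids.index(f) for f in rec.final_subset]
        sel_train[ch] = mats[ch][0][:, cols]
        sel_test[ch] = test_rows[ch][:, cols]
    return records, sel_train, sel_test, train_idx


def _fit_and_score(sel_train, sel_test, y_train, C, mkl_kwargs):
    if not sel_train:
        return 0.0, {}
    bundle = make_bundle(sel_train)
    model = fit_mkl(bundle, y_train, C=C, **mkl_kwargs)
    k_rows = [linear_kernel(sel_test[ch], sel_train[ch]) / c
              for ch, c in zip(model.channel_names, model.norm_constants)]
    score = float(decision_score(model, k_rows)[0])
    beta = {ch: float(b) for ch, b in zip(model.channel_names, model.beta)}
    return score, beta


def feature_frequency(records_per_fold: list[dict[str, SelectionRecord]]
                      ) -> dict[str, dict[int, int]]:
    counts: dict[str, dict[int, int]] = {}
    for records in records_per_fold:
        for ch, rec in records.items():
            bucket = counts.setdefault(ch, {})
            for fid in rec.final_subset:
                bucket[fid] = bucket.get(fid, 0) + 1
    return counts


def top_features(counts: dict[int, int], top_k: int = 10) -> list[tuple[int, int]]:
    """(roi_id, count) sorted by count desc, roi_id asc; truncated to top_k."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def loocv(tables: dict[str, FeatureTable], alpha: float = 0.05, C: float = 1.0,
          rfe_step: int = 1, rfe_inner_cv: bool = True,
          mkl_kwargs: dict | None = None) -> CVReport:
    """Full leave-one-out cross-validation of the multi-kernel pipeline."""
    mkl_kwargs = mkl_kwargs or {}
    y = _tables_y(tables)
    n = len(y)
    if np.sum(y == PATIENT) < 3 or np.sum(y == CONTROL) < 3:
        raise ValueError("need at least 3 subjects per class for LOOCV")
    subject_ids = next(iter(tables.values())).subject_ids
    folds = []
    scores = np.empty(n)
    for i in range(n):
        records, sel_tr, sel_te, train_idx = _fold_channel_selection(
            tables, y, i, alpha, C, rfe_step, rfe_inner_cv)
        score, beta = _fit_and_score(sel_tr, sel_te, y[train_idx], C, mkl_kwargs)
        scores[i] = score
        folds.append(FoldRecord(fold_index=i, test_subject=subject_ids[i],
                                true_label=int(y[i]), score=score,
                                prediction=int(predict_label(score)),
                                beta=beta, selections=records))
    pred = predict_label(scores)
    counts = _counts_from_predictions(y, pred)
    auc, _, _ = roc_auc(scores, y)
    metrics = confusion_metrics(counts, scores=scores, predictions=pred, auc=auc)
    freq = feature_frequency([f.selections for f in folds])
    return CVReport(folds=tuple(folds), metrics=metrics, feature_counts=freq)


def _mode_names(channels: list[str]) -> list[tuple[str, tuple[str, ...]]]:
    modes = []
    for k in range(1, len(channels) + 1):
        for combo in itertools.combinations(channels, k):
            modes.append(("+".join(combo), combo))
    return modes


def concatenate_tables(tables: dict[str, FeatureTable]) -> FeatureTable:
    """Stack all channels into one long feature vector per subject.

    Column ids are re-coded as ``channel_index * 1000 + roi_id`` to keep
    them unique across channels.
    """
    mats, ids = [], []
    ref = next(iter(tables.values()))
    for ci, (ch, tab) in enumerate(tables.items()):
        mats.append(tab.matrix)
        ids.extend(ci * 1000 + r for r in tab.roi_ids)
    return FeatureTable(matrix=np.hstack(mats), channel="concat",
                        roi_ids=tuple(ids), subject_ids=ref.subject_ids,
                        labels=ref.labels)


def run_comparison_modes(tables: dict[str, FeatureTable], alpha: float = 0.05,
                         C: float = 1.0, rfe_step: int = 1,
                         rfe_inner_cv: bool = True,
                         modes: list[str] | None = None,
                         include_concatenation: bool = True,
                         mkl_kwargs: dict | None = None
                         ) -> dict[str, MetricsReport]:
    """LOOCV metrics for channel subsets and direct concatenation.

    Per-channel selection is computed once per fold and shared across
    modes, so every mode sees the identical selection protocol; the
    concatenation mode runs its own selection on the stacked vector.
    """
    mkl_kwargs = mkl_kwargs or {}
    channels = list(tables)
    y = _tables_y(tables)
    n = len(y)
    all_modes = _mode_names(channels)
    if modes is not None:
        wanted = set(modes)
        all_modes = [m for m in all_modes if m[0] in wanted]
        include_concatenation = include_concatenation and "concat" in wanted
    mode_scores = {name: np.empty(n) for name, _ in all_modes}
    if include_concatenation:
        mode_scores["concat"] = np.empty(n)
        concat = {"concat": concatenate_tables(tables)}
    for i in range(n):
        records, sel_tr, sel_te, train_idx = _fold_channel_selection(
            tables, y, i, alpha, C, rfe_step, rfe_inner_cv)
        for name, combo in all_modes:
            tr = {ch: sel_tr[ch] for ch in combo if ch in sel_tr}
            te = {ch: sel_te[ch] for ch in combo if ch in sel_te}
            score, _ = _fit_and_score(tr, te, y[train_idx], C, mkl_kwargs)
            mode_scores[name][i] = score
        if include_concatenation:
            _, ctr, cte, _ = _fold_channel_selection(
                concat, y, i, alpha, C, rfe_step, rfe_inner_cv)
            score, _ = _fit_and_score(ctr, cte, y[train_idx], C, mkl_kwargs)
            mode_scores["concat"][i] = score
    out = {}
    for name, sc in mode_scores.items():
        pred = predict_label(sc)
        auc, _, _ = roc_auc(sc, y)
        out[name] = confusion_metrics(_counts_from_predictions(y, pred),
                                      scores=sc, predictions=pred, auc=auc)
    return out


def group_stats_from_summary(mean1: float, sd1: float, n1: int,
                             mean2: float, sd2: float, n2: int) -> GroupStats:
    """Pooled and Welch two-sample t statistics from group summaries."""
    tp, pp = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    tw, pw = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=False)
    return GroupStats(t_pooled=float(tp), p_pooled=float(pp),
                      t_welch=float(tw), p_welch=float(pw))


def chi2_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    chi2, p, _, _ = sps.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def group_stats(mean1, sd1, n1, mean2, sd2, n2,
                counts_2x2: np.ndarray | None = None) -> GroupStats:
    """Demographic comparison: both t variants, plus chi-square if counts given."""
    gs = group_stats_from_summary(mean1, sd1, n1, mean2, sd2, n2)
    if counts_2x2 is not None:
        chi2, p = chi2_counts(counts_2x2)
        gs = GroupStats(t_pooled=gs.t_pooled, p_pooled=gs.p_pooled,
                        t_welch=gs.t_welch, p_welch=gs.p_welch,
                        chi2=chi2, p_chi2=p)
    return gs
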