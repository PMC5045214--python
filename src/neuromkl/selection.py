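"""Nested, training-set-only feature selection.

Within each cross-validation fold the pipeline is: z-score every feature
using training-set statistics, keep features whose pooled two-sample
t-test separates the groups at p < alpha (uncorrected), then rank the
survivors with SVM recursive feature elimination (SVM-RFE): a linear
soft-margin SVM is trained repeatedly and the feature with the smallest
squared weight is removed at each step.  A leave-one-out accuracy inside
the training fold is recorded at every elimination level, and the final
subset is the smallest feature count whose inner accuracy is at least
the accuracy obtained with all survivors.

Nothing here ever looks at the held-out rows; the test rows are only
transformed with the training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC


@dataclass(frozen=True)
class NormalizationStats:
    """Training-set per-feature means/SDs plus the retained column set."""

    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray  # indices into the original columns (zero-variance dropped)


@dataclass(frozen=True)
class SelectionRecord:
    """Audit trail of one channel's selection inside one fold."""

    channel: str
    fold_index: int
    feature_ids: tuple[int, ...]          # ids of columns entering selection
    ttest_survivors: tuple[int, ...]
    t_values: dict[int, float]
    p_values: dict[int, float]
    rfe_ranking: tuple[int, ...]          # best first
    final_subset: tuple[int, ...]
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty:
            if not set(self.final_subset) <= set(self.ttest_survivors):
                raise ValueError("final_subset must be a subset of the t-test survivors")
            if not set(self.ttest_survivors) <= set(self.feature_ids):
                raise ValueError("survivors must be a subset of the channel's features")
            if not self.final_subset:
                raise ValueError("non-empty record must have a non-empty final subset")


def fold_normalize(train: np.ndarray, test: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray | None, NormalizationStats]:
    """Z-score columns by training mean/SD (population divisor); drop zero-variance ones.

    Test rows, if given, are transformed with the training statistics
    only, so a test value equal to the training mean maps to 0.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need a 2-D training matrix with >= 2 rows")
    means = train.mean(axis=0)
    sds = train.std(axis=0)
    # relative threshold: a column of identical stored values can carry
    # an O(eps) spread from float summation
    kept = np.flatnonzero(sds > 1e-12 * np.maximum(1.0, np.abs(means)))
    if kept.size < train.shape[1]:
        warnings.warn(f"dropping {train.shape[1] - kept.size} zero-variance feature(s)",
                      stacklevel=2)
    stats_ = NormalizationStats(means=means[kept], sds=sds[kept], kept=kept)
    train_n = (train[:, kept] - stats_.means) / stats_.sds
    test_n = None
    if test is not None:
        test = np.atleast_2d(np.asarray(test, dtype=float))
        test_n = (test[:, kept] - stats_.means) / stats_.sds
    return train_n, test_n, stats_


def ttest_filter(train: np.ndarray, y: np.ndarray, alpha: float = 0.05
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t-test per column; keep p < alpha.

    Returns (survivor column indices, t, p).  ``y`` is the +-1 class
    vector; both classes need at least two members.
    """
    train = np.asarray(train, dtype=float)
    y = np.asarray(y)
    g1, g2 = train[y == -1], train[y == 1]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need >= 2 members for the t filter")
    t, p = stats.ttest_ind(g1, g2, axis=0, equal_var=True)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    return np.flatnonzero(p < alpha), t, p


def _loo_accuracy(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Leave-one-out accuracy of a linear soft-margin SVM on (X, y).

    Exact shortcut: a point with a zero dual coefficient is not a
    support vector, so the solution without it is unchanged and the
    point sits strictly outside the margin -- correctly classified.
    Only support vectors need an actual refit.
    """
    n = len(y)
    full = SVC(kernel="linear", C=C)
    full.fit(X, y)
    is_sv = np.zeros(n, dtype=bool)
    is_sv[full.support_] = True
    correct = int(np.sum(~is_sv))
    idx = np.arange(n)
    for i in np.flatnonzero(is_sv):
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[tr], y[tr])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return correct / n


@dataclass(frozen=True)
class RFEResult:
    ranking: tuple[int, ...]                 # column indices, best first
    levels: tuple[tuple[int, float], ...]    # (n_features, inner accuracy)
    final_subset: tuple[int, ...]


def svm_rfe(train: np.ndarray, y: np.ndarray, C: float = 1.0, step: int = 1,
            inner_cv: bool = True) -> RFEResult:
    """SVM recursive feature elimination with an inner accuracy curve.

    At each level a linear SVM (box constraint ``C``) is fitted on the
    remaining columns and the ``step`` features with the smallest squared
    weights are removed (ties broken by removing the larger column
    index).  ``inner_cv=False`` skips the leave-one-out accuracy curve
    and keeps all survivors as the final subset (ranking only).
    """
    train = np.asarray(train, dtype=float)
    y = np.asarray(y)
    p = train.shape[1]
    if p < 1:
        raise ValueError("need at least one feature")
    if step < 1:
        raise ValueError("step must be >= 1")
    remaining = list(range(p))
    eliminated: list[int] = []
    levels: list[tuple[int, float]] = []
    subsets: dict[int, tuple[int, ...]] = {}
    while remaining:
        subsets[len(remaining)] = tuple(remaining)
        if inner_cv:
            levels.append((len(remaining), _loo_accuracy(train[:, remaining], y, C)))
        if len(remaining) == 1:
            eliminated.append(remaining.pop())
            break
        clf = SVC(kernel="linear", C=C)
        clf.fit(train[:, remaining], y)
        w2 = np.ravel(clf.coef_) ** 2
        # remove the smallest-w^2 features; ties -> larger original index first
        order = sorted(range(len(remaining)), key=lambda j: (w2[j], -remaining[j]))
        batch = {remaining[j] for j in order[:min(step, len(remaining) - 1)]}
        for j in order[:min(step, len(remaining) - 1)]:
            eliminated.append(remaining[j])
        remaining = [f for f in remaining if f not in batch]
    ranking = tuple(reversed(eliminated))
    if inner_cv:
        acc_all = levels[0][1]
        eligible = [n for n, acc in levels if acc >= acc_all]
        n_final = min(eligible)
        final = subsets[n_final]
    else:
        final = tuple(range(p))
    return RFEResult(ranking=ranking, levels=tuple(levels), final_subset=final)


def select_features(channel_matrices: dict[str, tuple[np.ndarray, tuple[int, ...]]],
                    y: np.ndarray, fold_index: int = 0, alpha: float = 0.05,
                    C: float = 1.0, rfe_step: int = 1,
                    rfe_inner_cv: bool = True) -> dict[str, SelectionRecord]:
    """Run the t-test + SVM-RFE pipeline independently per channel.

    ``channel_matrices`` maps channel name to ``(normalized training
    matrix, feature ids)``.  A channel with zero t-test survivors is
    returned with ``empty=True`` and is excluded from kernel building.
    """
    records: dict[str, SelectionRecord] = {}
    for ch, (X, fids) in channel_matrices.items():
        fids = tuple(fids)
        surv_idx, t, p = ttest_filter(X, y, alpha=alpha)
        t_map = {fids[j]: float(t[j]) for j in range(len(fids))}
        p_map = {fids[j]: float(p[j]) for j in range(len(fids))}
        if surv_idx.size == 0:
            warnings.warn(f"channel {ch}: no t-test survivors in fold {fold_index}; "
                          "excluded from this fold's kernels", stacklevel=2)
            records[ch] = SelectionRecord(
                channel=ch, fold_index=fold_index, feature_ids=fids,
                ttest_survivors=(), t_values=t_map, p_values=p_map,
                rfe_ranking=(), final_subset=(), empty=True)
            continue
        rfe = svm_rfe(X[:, surv_idx], y, C=C, step=rfe_step, inner_cv=rfe_inner_cv)
        surv_ids = tuple(fids[j] for j in surv_idx)
        records[ch] = SelectionRecord(
            channel=ch, fold_index=fold_index, feature_ids=fids,
            ttest_survivors=surv_ids, t_values=t_map, p_values=p_map,
            rfe_ranking=tuple(surv_ids[j] for j in rfe.ranking),
            final_subset=tuple(surv_ids[j] for j in rfe.final_subset))
    return records
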