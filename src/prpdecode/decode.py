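"""Multi-voxel pattern decoding of stimulus-response mappings.

An 8-way task-specific decoder is a bank of 8 one-vs-rest L2-regularized
logistic discriminants (regularization strength 25 on the standard logistic
loss, i.e. sklearn ``C = 1/25``) over the top-k (default 50) most activated
voxels; prediction is the argmax of the 8 decision values, ties broken by
the lowest label.  Features are z-scored with statistics computed on the
training set only.

Decoding surfaces:

* leave-one-run-out cross-validated single-task decoding of trial patterns,
* cross-task specificity tests (train on one task, test on the other),
* time-resolved decoding of single-trial FIR timecourses: at each post-onset
  lag the trial's voxel pattern is classified, yielding a decoding-accuracy
  timecourse whose onset/peak latency tracks when mapping-specific
  information is present.  Dual-task task-2 curves are left-shifted by the
  SOA (exact for fitted curves, TR-quantized for raw ones) before comparison
  with single-task curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "PatternClassifier",
    "DecodingTimecourse",
    "select_features",
    "train_classifier",
    "predict_label",
    "decision_values",
    "cv_decode",
    "cross_decode",
    "time_resolved_decode",
    "time_resolved_decode_cv",
    "pool_task_order",
    "CHANCE_8WAY",
]

CHANCE_8WAY = 1.0 / 8.0


@dataclass
class PatternClassifier:
    task: str
    feature_idx: np.ndarray
    weights: np.ndarray            # (8, n_features)
    intercepts: np.ndarray         # (8,)
    classes: np.ndarray            # label values, ascending
    mu: np.ndarray                 # training-set feature means
    sd: np.ndarray                 # training-set feature sds
    penalty: float = 25.0

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class DecodingTimecourse:
    time: np.ndarray
    accuracy: np.ndarray
    decoder_task: str
    tested_condition: str
    n_trials: int
    shift_applied: float = 0.0

    def __post_init__(self) -> None:
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracy must lie in [0, 1]")


def select_features(tmaps, k: int, mode: str = "single") -> np.ndarray:
    """Indices of the top-k activated voxels.

    ``mode='single'``: ``tmaps`` is one t-map; rank by t.
    ``mode='conjunction'``: ``tmaps`` is a pair of t-maps; rank by the
    elementwise minimum (most co-activated voxels across the two tasks).
    Ties break toward the lower voxel index, making selection deterministic.
    """
    if mode == "conjunction":
        a, b = tmaps
        score = np.minimum(np.asarray(a, float), np.asarray(b, float))
    else:
        score = np.asarray(tmaps, float)
    if k > score.size:
        raise ValueError(f"k={k} exceeds {score.size} voxels")
    order = np.lexsort((np.arange(score.size), -score))
    return np.sort(order[:k])


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def train_classifier(
    patterns: np.ndarray,
    labels: np.ndarray,
    penalty: float = 25.0,
    feature_idx: np.ndarray | None = None,
    task: str = "",
    n_classes: int = 8,
    strict: bool = True,
) -> PatternClassifier:
    """Fit the 8-way one-vs-rest bank on trial x voxel patterns.

    With ``strict=False`` a mapping absent from the training set gets an
    always-losing submodel instead of raising, which keeps leave-one-run-out
    folds usable when correctness filtering empties a class in the training
    runs.
    """
    patterns = np.asarray(patterns, float)
    labels = np.asarray(labels)
    if feature_idx is None:
        feature_idx = np.arange(patterns.shape[1])
    X = patterns[:, feature_idx]
    classes = np.arange(1, n_classes + 1)
    missing = [int(c) for c in classes if not np.any(labels == c)]
    if missing:
        if strict:
            raise ValueError(f"missing label class(es): {missing}")
        warnings.warn(f"mapping(s) {missing} absent from training set; "
                      "their submodels will never win the argmax")
    counts = [int((labels == c).sum()) for c in classes if c not in missing]
    if counts and min(counts) < 2:
        warnings.warn("fewer than 2 training trials for some mapping")
    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    W = np.zeros((len(classes), Xz.shape[1]))
    b = np.zeros(len(classes))
    for i, c in enumerate(classes):
        if c in missing:
            b[i] = -1e9
            continue
        y = (labels == c).astype(int)
        clf = LogisticRegression(penalty="l2", C=1.0 / penalty, solver="lbfgs",
                                 max_iter=2000)
        clf.fit(Xz, y)
        # sklearn orders classes [0, 1]; take the positive-class row
        W[i] = clf.coef_[0] * (1 if clf.classes_[-1] == 1 else -1)
        b[i] = clf.intercept_[0] * (1 if clf.classes_[-1] == 1 else -1)
    return PatternClassifier(task=task, feature_idx=np.asarray(feature_idx),
                             weights=W, intercepts=b, classes=classes,
                             mu=mu, sd=sd, penalty=penalty)


def decision_values(clf: PatternClassifier, patterns: np.ndarray) -> np.ndarray:
    """(n_trials, 8) one-vs-rest decision values."""
    patterns = np.atleast_2d(np.asarray(patterns, float))
    if patterns.shape[1] == len(clf.mu):
        X = patterns
    else:
        if patterns.shape[1] < clf.feature_idx.max() + 1:
            raise ValueError("pattern dimension does not match the trained feature space")
        X = patterns[:, clf.feature_idx]
    Xz = (X - clf.mu) / clf.sd
    return Xz @ clf.weights.T + clf.intercepts


def predict_label(clf: PatternClassifier, patterns: np.ndarray) -> np.ndarray:
    """Argmax over the 8 decision values; ties go to the lowest label."""
    dv = decision_values(clf, patterns)
    return clf.classes[np.argmax(dv, axis=1)]


def cv_decode(
    patterns: np.ndarray,
    labels: np.ndarray,
    run_ids: np.ndarray,
    penalty: float = 25.0,
    feature_idx: np.ndarray | None = None,
    task: str = "",
) -> tuple[float, pd.DataFrame]:
    """Leave-one-run-out decoding accuracy (pooled proportion correct)."""
    labels = np.asarray(labels)
    run_ids = np.asarray(run_ids)
    folds = np.unique(run_ids)
    if len(folds) < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    rows = []
    n_correct = 0
    n_total = 0
    for f in folds:
        test = run_ids == f
        if not test.any():
            warnings.warn(f"fold {f} has no test trials; skipped")
            continue
        clf = train_classifier(patterns[~test], labels[~test], penalty=penalty,
                               feature_idx=feature_idx, task=task, strict=False)
        pred = predict_label(clf, patterns[test])
        hits = int((pred == labels[test]).sum())
        rows.append({"fold": f, "n": int(test.sum()), "n_correct": hits,
                     "accuracy": hits / test.sum()})
        n_correct += hits
        n_total += int(test.sum())
    return n_correct / n_total, pd.DataFrame(rows)


def cross_decode(clf: PatternClassifier, patterns: np.ndarray,
                 labels: np.ndarray) -> float:
    """Accuracy of a trained decoder on the other task's trials."""
    pred = predict_label(clf, patterns)
    return float(np.mean(pred == np.asarray(labels)))


def _accuracy_timecourse(clf, tc_stack, labels, tr):
    """tc_stack: (n_trials, window, n_voxels)."""
    n_trials, window, _ = tc_stack.shape
    acc = np.empty(window)
    for k in range(window):
        pred = predict_label(clf, tc_stack[:, k, :])
        acc[k] = np.mean(pred == labels)
    return np.arange(window) * tr, acc


def time_resolved_decode(
    clf: PatternClassifier,
    tc_stack: np.ndarray,
    labels: np.ndarray,
    tr: float,
    tested_condition: str = "",
) -> DecodingTimecourse:
    """Decode single-trial FIR timecourses at each post-onset lag.

    For dual-task testing the training set (single-task patterns) is already
    independent of the tested trials, so no cross-validation is required.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("no trials to decode")
    time, acc = _accuracy_timecourse(clf, tc_stack, labels, tr)
    return DecodingTimecourse(time=time, accuracy=acc, decoder_task=clf.task,
                              tested_condition=tested_condition, n_trials=len(labels))


def time_resolved_decode_cv(
    train_patterns: np.ndarray,
    train_labels: np.ndarray,
    train_runs: np.ndarray,
    tc_stack: np.ndarray,
    test_labels: np.ndarray,
    test_runs: np.ndarray,
    tr: float,
    penalty: float = 25.0,
    feature_idx: np.ndarray | None = None,
    task: str = "",
    tested_condition: str = "",
) -> DecodingTimecourse:
    """Single-task time-resolved decoding with leave-one-run-out pairing.

    The decoder tested on run r's trial timecourses is trained only on
    patterns from the other runs, preserving train/test independence.
    """
    train_runs = np.asarray(train_runs)
    test_runs = np.asarray(test_runs)
    test_labels = np.asarray(test_labels)
    window = tc_stack.shape[1]
    hits = np.zeros(window)
    n = 0
    for f in np.unique(test_runs):
        test = test_runs == f
        keep = train_runs != f
        clf = train_classifier(train_patterns[keep], train_labels[keep],
                               penalty=penalty, feature_idx=feature_idx, task=task,
                               strict=False)
        for k in range(window):
            pred = predict_label(clf, tc_stack[test][:, k, :])
            hits[k] += (pred == test_labels[test]).sum()
        n += int(test.sum())
    return DecodingTimecourse(time=np.arange(window) * tr, accuracy=hits / n,
                              decoder_task=task, tested_condition=tested_condition,
                              n_trials=n)


def pool_task_order(tc_a: DecodingTimecourse, tc_b: DecodingTimecourse,
                    target: str = "") -> DecodingTimecourse:
    """Average two decoding timecourses (e.g. AO-first and VM-first task-2
    curves at the same SOA) pointwise; trial counts add."""
    if tc_a.time.shape != tc_b.time.shape or not np.allclose(tc_a.time, tc_b.time):
        raise ValueError("time grids do not match")
    return DecodingTimecourse(
        time=tc_a.time.copy(),
        accuracy=0.5 * (tc_a.accuracy + tc_b.accuracy),
        decoder_task=f"{tc_a.decoder_task}+{tc_b.decoder_task}",
        tested_condition=target or f"{tc_a.tested_condition}|{tc_b.tested_condition}",
        n_trials=tc_a.n_trials + tc_b.n_trials,
    )
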