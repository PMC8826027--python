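"""Repeated stratified splits, class-imbalance-aware metrics and the
correlated t-test.

The evaluation protocol is five repeated class-stratified 80:20
train/hold-out splits. Headline metrics are balanced accuracy (unweighted
mean of per-class recall, reported as a percentage) and the weighted
one-vs-rest ROC AUC (per-class AUC averaged with weights equal to class
prevalence). Paired model comparisons over the repeated splits use the
correlated t-test with the Nadeau–Bengio variance correction, which
accounts for the train-set overlap between repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "SplitPlan",
    "make_splits",
    "balanced_accuracy",
    "weighted_ovr_auc",
    "secondary_metrics",
    "correlated_ttest",
    "CorrelatedTTestResult",
    "evaluate_model",
    "MetricsReport",
]


@dataclass
class SplitPlan:
    n_repeats: int
    test_fraction: float
    seed: int
    splits: list  # list of (train_idx, test_idx)

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def make_splits(labels, n_repeats: int = 5, test_fraction: float = 0.2,
                seed: int = 0) -> SplitPlan:
    """Repeated class-stratified train/hold-out splits (default 5 × 80:20)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=seed
    )
    splits = [(tr.copy(), te.copy())
              for tr, te in splitter.split(np.zeros(len(labels)), labels)]
    return SplitPlan(n_repeats=n_repeats, test_fraction=test_fraction,
                     seed=seed, splits=splits)


def balanced_accuracy(y_true, y_pred, labels=None) -> float:
    """Unweighted mean of per-class recall, in percent.

    A constant classifier scores exactly 100 / C on data with C represented
    classes. If ``labels`` names the full vocabulary, every class must occur
    in ``y_true``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    present = set(np.unique(y_true).tolist())
    if labels is not None:
        missing = set(labels) - present
        if missing:
            raise ValueError(f"classes absent from y_true: {sorted(missing)}")
    recalls = recall_score(
        y_true, y_pred, labels=sorted(present), average=None,
        zero_division=0.0,
    )
    return float(np.mean(recalls) * 100.0)


def weighted_ovr_auc(y_true, scores, labels=None) -> float:
    """One-vs-rest ROC AUC per class, weighted by class prevalence.

    ``scores`` columns follow ``labels`` (default: sorted distinct labels of
    ``y_true``). A class with zero positives or zero negatives is skipped
    with a warning and the prevalence weights are renormalized. Ties in the
    scores count one half, as in the Mann–Whitney statistic.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels is None:
        labels = sorted(set(y_true.tolist()))
    labels = list(labels)
    if scores.ndim != 2 or scores.shape[1] != len(labels):
        raise ValueError(
            f"scores must have one column per class ({len(labels)})"
        )
    aucs, weights = [], []
    for j, cls in enumerate(labels):
        pos = y_true == cls
        n_pos = int(pos.sum())
        if n_pos == 0 or n_pos == len(y_true):
            warnings.warn(
                f"class {cls!r} has no positives or no negatives; skipped "
                "from the weighted AUC", stacklevel=2,
            )
            continue
        col = scores[:, j]
        if np.ptp(col) == 0.0:
            auc = 0.5  # constant scores rank nothing
        else:
            auc = roc_auc_score(pos, col)
        aucs.append(auc)
        weights.append(n_pos / len(y_true))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    weights = np.asarray(weights) / np.sum(weights)
    return float(np.dot(aucs, weights))


def secondary_metrics(y_true, y_pred) -> dict:
    """Unbalanced accuracy and prevalence-weighted precision/recall/F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0.0
    )
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "weighted_precision": float(precision),
        "weighted_recall": float(recall),
        "weighted_f1": float(f1),
    }


@dataclass
class CorrelatedTTestResult:
    t: float
    p: float
    degenerate: bool = False  # zero variance with nonzero mean difference


def correlated_ttest(scores_a, scores_b, test_fraction: float = 0.2,
                     train_fraction: float = 0.8) -> CorrelatedTTestResult:
    """Paired t-test over repeated-split scores with the Nadeau–Bengio
    variance correction.

    t = mean(d) / sqrt(var(d) · (1/n + test_fraction/train_fraction)), with
    d the per-split score differences and a Student-t null with n − 1
    degrees of freedom. As test_fraction/train_fraction → 0 this reduces to
    the classical paired t-test.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired score vectors, n >= 2")
    d = a - b
    n = len(d)
    md = float(np.mean(d))
    vd = float(np.var(d, ddof=1))
    correction = 1.0 / n + test_fraction / train_fraction
    if vd == 0.0:
        if md == 0.0:
            return CorrelatedTTestResult(t=0.0, p=1.0)
        return CorrelatedTTestResult(
            t=float(np.sign(md) * np.inf), p=0.0, degenerate=True
        )
    t = md / np.sqrt(vd * correction)
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return CorrelatedTTestResult(t=float(t), p=p)


# ---------------------------------------------------------------------------
# repeated-split evaluation of a classifier
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    per_split: list = field(default_factory=list)  # one metrics dict per split
    summary: dict = field(default_factory=dict)    # metric -> (mean, sd)

    def scores(self, metric: str) -> np.ndarray:
        return np.asarray([m[metric] for m in self.per_split])


def evaluate_model(make_estimator, X, y, plan: SplitPlan) -> MetricsReport:
    """Train and score a fresh estimator on every split of ``plan``.

    ``make_estimator`` is called once per split (with the split index) and
    must return an unfitted classifier with predict/predict_proba.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    report = MetricsReport()
    for i, (tr, te) in enumerate(plan):
        clf = make_estimator(i)
        clf.fit(X[tr], y[tr])
        y_pred = clf.predict(X[te])
        proba = clf.predict_proba(X[te])
        metrics = {
            "balanced_accuracy": balanced_accuracy(y[te], y_pred),
            "weighted_ovr_auc": weighted_ovr_auc(y[te], proba, labels=labels),
        }
        metrics.update(secondary_metrics(y[te], y_pred))
        report.per_split.append(metrics)
    for key in report.per_split[0]:
        vals = report.scores(key)
        report.summary[key] = (float(vals.mean()),
                               float(vals.std(ddof=1)) if len(vals) > 1
                               else 0.0)
    return report
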