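"""Cross-validated evaluation with PC/MC/FA confusion counts.

The report metrics follow screening-style conventions for two-class
screening: PC ("perfect classification") counts every correctly labelled
sample of either class, MC ("missed classification") the positive-class
samples predicted negative, FA ("false alarm") the negative-class
samples predicted positive, so PC + MC + FA = n.  From the counts:

    sensitivity = PC / (PC + FA) * 100
    specificity = PC / (PC + MC) * 100
    accuracy    = (sensitivity + specificity) / 2
    PI          = (PC - MC - FA) / PC * 100   (can be negative)

These differ from the textbook true-positive-rate definitions, so the
conventional TP-based metrics are also reported under ``conv_*`` names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from . import classify
from .datasets import ExpressionDataset, warn_once

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "stratified_kfold",
    "confusion_counts",
    "metrics_from_counts",
    "cross_validated_report",
]


@dataclass
class FoldPlan:
    """Sample-to-fold assignment for k-fold CV (stratified, seeded)."""

    assignments: np.ndarray
    k: int
    seed: int

    def folds(self):
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Deterministic stratified fold plan; per-fold class counts within 1
    of exact stratification.

    Each class is shuffled and dealt round-robin across folds, the second
    class continuing from the fold where the first left off so fold sizes
    also stay within 1 of each other.  Unlike sklearn's StratifiedKFold
    this supports k up to n (folds then miss a class, with a warning).
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds n={len(labels)}")
    if k > int(np.bincount(labels).min()):
        warn_once(f"stratified_kfold: k={k} exceeds the minority class size; "
                  "some folds will miss a class")
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(labels), dtype=int)
    offset = 0
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        for j, i in enumerate(idx):
            assignments[i] = (offset + j) % k
        offset = (offset + len(idx)) % k
    return FoldPlan(assignments=assignments, k=k, seed=seed)


def confusion_counts(pred, truth, positive_class: int = 1):
    """(PC, MC, FA): all-correct, false-negative, false-positive counts."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if not (set(pred.tolist()) | set(truth.tolist())) <= {0, 1}:
        raise ValueError("labels outside the {0, 1} class set")
    pc = int((pred == truth).sum())
    mc = int(((truth == positive_class) & (pred != positive_class)).sum())
    fa = int(((truth != positive_class) & (pred == positive_class)).sum())
    return pc, mc, fa


@dataclass
class MetricsReport:
    PC: int
    MC: int
    FA: int
    sensitivity: float
    specificity: float
    accuracy: float
    performance_index: float
    folds: int = 1
    positive_class: int = 1
    per_fold: list = field(default_factory=list)
    conv_sensitivity: float | None = None
    conv_specificity: float | None = None
    conv_accuracy: float | None = None

    @property
    def n(self) -> int:
        return self.PC + self.MC + self.FA

    def to_dict(self) -> dict:
        return {
            "PC": self.PC, "MC": self.MC, "FA": self.FA,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "performance_index": self.performance_index,
            "folds": self.folds, "positive_class": self.positive_class,
            "per_fold": [list(t) for t in self.per_fold],
            "conv_sensitivity": self.conv_sensitivity,
            "conv_specificity": self.conv_specificity,
            "conv_accuracy": self.conv_accuracy,
        }


def metrics_from_counts(PC: int, MC: int, FA: int, **kwargs) -> MetricsReport:
    """Percent-scale metrics from the three counts (see module docstring).

    PC = 0 makes the performance index undefined; it is reported as -inf
    with a warning.  Zero denominators in sensitivity/specificity give 0.
    """
    if min(PC, MC, FA) < 0:
        raise ValueError("counts must be nonnegative")
    if PC + FA > 0:
        sens = PC / (PC + FA) * 100.0
    else:
        warn_once("metrics_from_counts: PC + FA = 0, sensitivity reported as 0")
        sens = 0.0
    if PC + MC > 0:
        spec = PC / (PC + MC) * 100.0
    else:
        warn_once("metrics_from_counts: PC + MC = 0, specificity reported as 0")
        spec = 0.0
    acc = (sens + spec) / 2.0
    if PC > 0:
        pi = (PC - MC - FA) / PC * 100.0
    else:
        warn_once("metrics_from_counts: PC = 0, performance index undefined (-inf)")
        pi = -np.inf
    return MetricsReport(
        PC=PC, MC=MC, FA=FA,
        sensitivity=sens, specificity=spec, accuracy=acc, performance_index=pi,
        **kwargs,
    )


def _conventional(pred, truth, positive_class):
    tp = int(((truth == positive_class) & (pred == positive_class)).sum())
    tn = int(((truth != positive_class) & (pred != positive_class)).sum())
    fn = int(((truth == positive_class) & (pred != positive_class)).sum())
    fp = int(((truth != positive_class) & (pred == positive_class)).sum())
    sens = tp / (tp + fn) * 100.0 if tp + fn else 0.0
    spec = tn / (tn + fp) * 100.0 if tn + fp else 0.0
    acc = (tp + tn) / max(len(truth), 1) * 100.0
    return sens, spec, acc


def minority_class(labels) -> int:
    """Default positive class: the rarer label (ties -> 1)."""
    c = np.bincount(np.asarray(labels, int), minlength=2)
    return 0 if c[0] < c[1] else 1


def cross_validated_report(
    ds: ExpressionDataset,
    genes,
    classifier_kind: str,
    hyperparams: dict | None = None,
    plan: FoldPlan | None = None,
    positive_class: int | None = None,
    seed: int = 0,
    aggregate: str = "pooled",
) -> MetricsReport:
    """Train/test over the fold plan on the given gene subset.

    ``aggregate="pooled"`` (default) sums PC/MC/FA over folds before
    computing metrics; ``"fold_mean"`` averages the per-fold metric values
    instead.  Per-fold count triples are retained either way.
    """
    genes = np.asarray(list(genes), dtype=int)
    if len(genes) == 0 or genes.max() >= ds.n_genes:
        raise ValueError("gene subset empty or out of range")
    if plan is None:
        plan = stratified_kfold(ds.labels, k=10, seed=seed)
    pos = minority_class(ds.labels) if positive_class is None else positive_class
    X = ds.samples_x_genes(genes)
    y = ds.labels
    per_fold = []
    preds = np.empty(len(y), dtype=int)
    for train_idx, test_idx in plan.folds():
        model = classify.train(classifier_kind, X[train_idx], y[train_idx],
                               hyperparams, seed=seed)
        p = model.predict(X[test_idx])
        preds[test_idx] = p
        per_fold.append(confusion_counts(p, y[test_idx], pos))
    pc = sum(f[0] for f in per_fold)
    mc = sum(f[1] for f in per_fold)
    fa = sum(f[2] for f in per_fold)
    report = metrics_from_counts(
        pc, mc, fa, folds=plan.k, positive_class=pos, per_fold=per_fold
    )
    if aggregate == "fold_mean":
        vals = np.array(
            [[m.sensitivity, m.specificity, m.accuracy, m.performance_index]
             for m in (metrics_from_counts(*f) for f in per_fold)]
        )
        report.sensitivity, report.specificity, report.accuracy, \
            report.performance_index = (float(v) for v in vals.mean(axis=0))
    elif aggregate != "pooled":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    report.conv_sensitivity, report.conv_specificity, report.conv_accuracy = \
        _conventional(preds, y, pos)
    return report
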