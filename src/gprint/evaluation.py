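"""Evaluation battery: stratified splits, k-fold cross-validation, confusion
matrices and the per-class one-vs-rest metric formulas.

Per class c, collapsing the confusion matrix one-vs-rest gives TP, FP, TN,
FN, from which:

    precision = TP / (TP + FP)          recall = TPR = TP / (TP + FN)
    accuracy  = (TP + TN) / total       F1 = 2TP / (2TP + FP + FN)
    FPR = FP / (FP + TN)

0/0 ratios are reported as 0 and flagged. The headline ``overall_accuracy``
is the plain fraction correct (trace / total); the per-class one-vs-rest
accuracy is emitted alongside. AUC is the rank statistic (mid-ranks for
ties), equivalent to trapezoidal ROC integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.stats

from gprint.geneprint import PrintMatrix
from gprint.io_prep import LabelTable

PER_CLASS_METRICS = ["precision", "recall", "f1", "tpr", "fpr", "accuracy"]


@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # rows = true, columns = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over labels")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class MetricsReport:
    per_class: pd.DataFrame  # one row per class: the six formulas + flags
    overall_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: ConfusionMatrix
    per_class_auc: dict[str, float | None] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.per_class.copy()
        if self.per_class_auc is not None:
            df["auc"] = [self.per_class_auc.get(l) for l in df.index]
        macro = pd.Series(
            {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "accuracy": self.overall_accuracy,
            },
            name="__macro__",
        )
        return pd.concat([df, macro.to_frame().T])


@dataclass
class CvResult:
    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    fold_assignments: dict[str, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.fold_reports)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rep in enumerate(self.fold_reports):
            rows.append(
                {
                    "fold": i + 1,
                    "accuracy": rep.overall_accuracy,
                    "macro_precision": rep.macro_precision,
                    "macro_recall": rep.macro_recall,
                    "macro_f1": rep.macro_f1,
                }
            )
        return pd.DataFrame(rows)


def stratified_split(
    labels: LabelTable, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Per-class random split; train share within one cell of the requested
    fraction for every class. Singleton classes go to train with a warning."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for c, l in zip(labels.cell_ids, labels.labels):
        by_class.setdefault(l, []).append(c)
    train: list[str] = []
    test: list[str] = []
    for label in sorted(by_class):
        members = list(by_class[label])
        if len(members) == 1:
            warnings.warn(f"class {label!r} has a single cell; assigned to train")
            train.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_train = int(np.floor(train_fraction * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return train, test


def confusion(true: LabelTable, pred) -> ConfusionMatrix:
    """Tally true-vs-predicted labels; label order is the sorted union."""
    true_map = true.to_dict()
    pred_map = dict(zip(pred.cell_ids, pred.predicted_labels))
    missing = sorted(set(true_map) ^ set(pred_map))
    if missing:
        raise ValueError(f"cell sets differ between truth and prediction: {missing[:5]}")
    labels = sorted(set(true_map.values()) | set(pred_map.values()))
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for cell, t in true_map.items():
        counts[index[t], index[pred_map[cell]]] += 1
    return ConfusionMatrix(labels, counts)


def compute_metrics(c: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest metrics plus unweighted macro averages."""
    total = c.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for i, label in enumerate(c.labels):
        tp = int(c.counts[i, i])
        fn = int(c.counts[i].sum() - tp)
        fp = int(c.counts[:, i].sum() - tp)
        tn = total - tp - fn - fp
        undefined = []

        def ratio(num: int, den: int, name: str) -> float:
            if den == 0:
                undefined.append(name)
                return 0.0
            return num / den

        precision = ratio(tp, tp + fp, "precision")
        recall = ratio(tp, tp + fn, "recall")
        f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
        fpr = ratio(fp, fp + tn, "fpr")
        rows.append(
            {
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "tpr": recall,
                "fpr": fpr,
                "accuracy": (tp + tn) / total,
                "support": tp + fn,
                "undefined": ";".join(undefined),
            }
        )
    per_class = pd.DataFrame(rows, index=c.labels)
    return MetricsReport(
        per_class=per_class,
        overall_accuracy=float(np.trace(c.counts)) / total,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        confusion=c,
    )


def roc_auc(true: LabelTable, pred) -> dict[str, float | None]:
    """One-vs-rest AUC per class from the rank statistic (mid-ranks for ties).

    Classes in the prediction vocabulary that never occur in the truth (or
    occur for every cell) have no defined AUC and map to None.
    """
    true_map = true.to_dict()
    y_true = np.asarray([true_map[c] for c in pred.cell_ids])
    out: dict[str, float | None] = {}
    for j, label in enumerate(pred.label_vocabulary):
        pos = y_true == label
        n_pos = int(pos.sum())
        n_neg = len(pos) - n_pos
        if n_pos == 0 or n_neg == 0:
            out[label] = None
            continue
        ranks = scipy.stats.rankdata(pred.probabilities[:, j])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
        out[label] = float(u / (n_pos * n_neg))
    return out


def evaluate(true: LabelTable, pred, with_auc: bool = True) -> MetricsReport:
    """Convenience wrapper: confusion + metrics (+ AUC when probabilities exist)."""
    report = compute_metrics(confusion(true, pred))
    if with_auc:
        report.per_class_auc = roc_auc(true, pred)
    return report


def _stratified_folds(
    labels: LabelTable, k: int, rng: np.random.Generator
) -> dict[str, int]:
    by_class: dict[str, list[str]] = {}
    for c, l in zip(labels.cell_ids, labels.labels):
        by_class.setdefault(l, []).append(c)
    assignment: dict[str, int] = {}
    offset = 0
    for label in sorted(by_class):
        members = by_class[label]
        if len(members) < k:
            warnings.warn(
                f"class {label!r} has {len(members)} < k={k} cells; "
                "fold stratification degrades"
            )
        perm = rng.permutation(len(members))
        for pos, i in enumerate(perm):
            assignment[members[i]] = (pos + offset) % k
        offset += len(members)  # stagger so small classes don't pile into fold 0
    return assignment


def kfold_cv(
    data: PrintMatrix,
    labels: LabelTable,
    trainer: Callable[[PrintMatrix, LabelTable], object],
    k: int = 5,
    seed: int = 0,
    with_auc: bool = False,
) -> CvResult:
    """Stratified k-fold cross-validation.

    ``trainer(train_prints, train_labels)`` must return an object with a
    ``predict(PrintMatrix) -> PredictionTable`` method. Each fold is held out
    once; per-fold reports are aggregated as mean ± SD per headline metric.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > data.n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({data.n_cells})")
    lab = labels.subset(data.cell_ids)
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(lab, k, rng)
    reports: list[MetricsReport] = []
    for fold in range(k):
        held = np.asarray([assignment[c] == fold for c in data.cell_ids])
        train_prints = PrintMatrix(
            data.signals[~held],
            [c for c, h in zip(data.cell_ids, held) if not h],
            data.ordered_genes,
        )
        val_prints = PrintMatrix(
            data.signals[held],
            [c for c, h in zip(data.cell_ids, held) if h],
            data.ordered_genes,
        )
        model = trainer(train_prints, lab.subset(train_prints.cell_ids))
        pred = model.predict(val_prints)
        reports.append(evaluate(lab.subset(val_prints.cell_ids), pred, with_auc=with_auc))
    keys = ["accuracy", "macro_precision", "macro_recall", "macro_f1"]
    table = {
        "accuracy": [r.overall_accuracy for r in reports],
        "macro_precision": [r.macro_precision for r in reports],
        "macro_recall": [r.macro_recall for r in reports],
        "macro_f1": [r.macro_f1 for r in reports],
    }
    mean = {key: float(np.mean(table[key])) for key in keys}
    sd = {key: float(np.std(table[key], ddof=1)) for key in keys}
    return CvResult(reports, mean, sd, assignment)


def binomial_chance_interval(n: int, p: float, confidence: float = 0.99) -> tuple[float, float]:
    """Exact binomial central interval for the *observed rate* under chance
    p, i.e. quantiles of Binomial(n, p)/n. Used by the null-safety checks."""
    alpha = (1 - confidence) / 2
    lo = scipy.stats.binom.ppf(alpha, n, p) / n
    hi = scipy.stats.binom.ppf(1 - alpha, n, p) / n
    return float(lo), float(hi)
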