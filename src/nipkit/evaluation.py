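"""Binary classification metrics and stratified cross-validation.

The metric suite is the standard confusion-matrix family: accuracy (ACC),
sensitivity/recall (SEN), specificity (SPE), precision (PE), Matthews
correlation coefficient (MCC), F1, plus the geometric mean GM =
sqrt(SEN * SPE) for imbalanced data and the area under the ROC curve
(AUC).  Degenerate ratios follow the usual conventions: PE with no
predicted positives is 0 (warned), MCC with a zero denominator factor is
0, F1 with an empty numerator and denominator is 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import EncodedPairDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """One evaluation's metrics, each as a fraction in [0, 1] (MCC in
    [-1, 1]).  ``auc`` is None when scores were unavailable."""

    acc: float
    sen: float
    spe: float
    pe: float
    mcc: float
    f1: float
    gm: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/FP/TN/FN from two equal-length binary vectors."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Compute the metric suite from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated pairs")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = (tp + tn) / c.total
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    if tp + fp:
        pe = tp / (tp + fp)
    else:
        pe = 0.0
        logger.warning("precision undefined (no predicted positives); using 0")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    gm = math.sqrt(sen * spe)
    return MetricReport(acc, sen, spe, pe, mcc, f1, gm, auc)


def auc(scores, true_labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney concordance probability with ties counted as
    half; requires both classes present.
    """
    y = np.asarray(true_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def evaluate(model, dataset: EncodedPairDataset, threshold: float = 0.5
             ) -> MetricReport:
    """Score a trained pair model on an encoded dataset."""
    prob = model.predict(dataset.xa, dataset.xb)
    pred = (prob >= threshold).astype(int)
    c = confusion(dataset.y, pred)
    auc_value = auc(prob, dataset.y) if len(np.unique(dataset.y)) == 2 else None
    return metrics(c, auc=auc_value)


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricReport]
    mean: dict[str, float]
    sd: dict[str, float]

    def summary(self) -> str:
        """Mean +/- sd over folds, percent formatted."""
        lines = []
        for name in ("acc", "pe", "sen", "spe", "mcc", "f1", "auc", "gm"):
            if name in self.mean:
                lines.append(
                    f"{name.upper()}\t{100 * self.mean[name]:.2f}% "
                    f"± {100 * self.sd[name]:.2f}%"
                )
        return "\n".join(lines)


def cross_validate(
    dataset: EncodedPairDataset,
    model_factory,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of a pair classifier.

    ``model_factory(train_dataset, fold_seed)`` must return a trained model
    with the ``predict(xa, xb)`` contract.  Folds are stratified so each
    preserves the dataset's class ratio; the fold assignment is seeded.
    Per-fold metrics are summarized as mean and sample standard deviation;
    GM is computed per fold, then averaged.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = dataset.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs at least {folds} members for {folds}-fold CV"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(len(y)), y)
    ):
        model = model_factory(dataset.subset(train_idx), seed + fold)
        reports.append(evaluate(model, dataset.subset(test_idx), threshold))
    names = [f.name for f in fields(MetricReport)]
    mean, sd = {}, {}
    for name in names:
        values = [getattr(r, name) for r in reports]
        if any(v is None for v in values):
            continue
        mean[name] = float(np.mean(values))
        sd[name] = float(np.std(values, ddof=1))
    return CrossValidationResult(reports, mean, sd)


def paired_t_test(values_a, values_b) -> tuple[float, float]:
    """Paired t-test over per-fold metric values; returns (t, p).

    A convenience for comparing two models evaluated on the same folds.
    """
    from scipy import stats

    t, p = stats.ttest_rel(np.asarray(values_a), np.asarray(values_b))
    return float(t), float(p)
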