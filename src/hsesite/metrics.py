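"""Binary-classification evaluation: confusion metrics, ROC/AUC, k-fold CV.

Metrics are the standard four plus the false-positive rate, all derived from
the confusion counts (TP, FP, TN, FN):

    Sens = TP / (FN + TP)            Spec = TN / (FP + TN)
    Accuracy = (TN + TP) / total     FPR  = FP / (TN + FP) = 1 − Spec
    MCC = (TP·TN − FP·FN) / sqrt((TN+FP)(TP+FN)(TP+FP)(TN+FN))

A metric with a zero denominator is undefined and reported as None — never
silently 0. The ROC curve sweeps the classifier score M over all thresholds
(sensitivity vs FPR) and the AUC is its trapezoidal integral, which equals
the Mann–Whitney rank statistic with the standard half-credit for ties.

Cross-validation partitions the data into k near-equal (by default
stratified) folds with a seeded shuffle, trains on k−1 folds and evaluates
on the held-out fold. Fold ROC curves are combined by vertical averaging of
the TPR on a fixed 101-point FPR grid, giving a mean curve with a per-point
standard deviation. Both the fold-mean and the pooled-confusion summary are
reported, since the two can differ slightly.

``implied_confusion`` inverts rounded sensitivity/specificity back to
integer confusion counts for a known class balance — useful for checking
published metric tables for internal consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .encoding import LabeledDataset
from .tree import TreeParams, fit, predict_score

ROC_GRID_POINTS = 101


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
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.count_nonzero((y_true == 1) & (y_pred == 1))),
        fp=int(np.count_nonzero((y_true == 0) & (y_pred == 1))),
        tn=int(np.count_nonzero((y_true == 0) & (y_pred == 0))),
        fn=int(np.count_nonzero((y_true == 1) & (y_pred == 0))),
    )


def sensitivity(c: ConfusionCounts) -> float | None:
    return c.tp / c.n_pos if c.n_pos else None


def specificity(c: ConfusionCounts) -> float | None:
    return c.tn / c.n_neg if c.n_neg else None


def accuracy(c: ConfusionCounts) -> float | None:
    total = c.n_pos + c.n_neg
    return (c.tn + c.tp) / total if total else None


def fpr(c: ConfusionCounts) -> float | None:
    return c.fp / c.n_neg if c.n_neg else None


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient; None when any marginal is zero."""
    denom2 = (c.tn + c.fp) * (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return None
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)


def implied_confusion(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Integer confusion counts implied by (rounded) sensitivity/specificity.

    TP = round(sens·n_pos) and TN = round(spec·n_neg) with half rounded away
    from zero; FN and FP are the complements.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sens and spec must be in [0, 1]")
    tp = int(math.floor(sens * n_pos + 0.5))
    tn = int(math.floor(spec * n_neg + 0.5))
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def round_metric(x: float | None, ndigits: int = 3) -> float | None:
    """Report rounding: ``ndigits`` decimals, half away from zero."""
    if x is None:
        return None
    scale = 10**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class MetricsReport:
    sens: float | None
    spec: float | None
    accuracy: float | None
    mcc: float | None
    fpr: float | None
    auc: float | None = None

    @classmethod
    def from_confusion(
        cls, c: ConfusionCounts, auc_value: float | None = None
    ) -> "MetricsReport":
        return cls(
            sens=sensitivity(c), spec=specificity(c), accuracy=accuracy(c),
            mcc=mcc(c), fpr=fpr(c), auc=auc_value,
        )

    def rounded(self, ndigits: int = 3) -> dict[str, float | None]:
        return {
            name: round_metric(getattr(self, name), ndigits)
            for name in ("sens", "spec", "accuracy", "mcc", "fpr", "auc")
        }


@dataclass
class RocCurve:
    """ROC points swept over score thresholds, sorted by FPR, from (0,0)
    to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0):
            raise ValueError("fpr must be non-decreasing")


def roc_curve(y_true, scores) -> RocCurve:
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    f, t, thr = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    return RocCurve(fpr=f, tpr=t, thresholds=thr)


def auc(curve: RocCurve) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


@dataclass(frozen=True)
class CvConfig:
    """k: number of folds (any >= 2; 6, 8 and 10 are the conventional
    choices here); seed: shuffle seed; stratified: preserve the class ratio
    in every fold (near-neutral on balanced data but stabilises small
    folds)."""

    k: int = 6
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class FoldResult:
    report: MetricsReport
    counts: ConfusionCounts
    curve: RocCurve
    n_test: int


@dataclass
class CvResult:
    folds: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]
    pooled: MetricsReport
    pooled_counts: ConfusionCounts
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    std_tpr: np.ndarray

    @property
    def mean_auc(self) -> float:
        return self.mean["auc"]


def kfold_cv(
    dataset: LabeledDataset,
    params: TreeParams = TreeParams(),
    cv: CvConfig = CvConfig(),
) -> CvResult:
    """Stratified k-fold cross-validation of the decision tree.

    Folds are near-equal in size (differing by at most one sample); the
    same seed always yields the same fold assignment and hence identical
    reports. Fold ROC curves are vertically averaged on a fixed FPR grid.
    """
    X, y = dataset.X, dataset.y
    if cv.stratified:
        counts = np.bincount(y, minlength=2)
        if cv.k > counts.min():
            raise ValueError(
                f"k={cv.k} exceeds the smaller class count {counts.min()}"
            )
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        if cv.k > len(y):
            raise ValueError(f"k={cv.k} exceeds dataset size {len(y)}")
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)

    grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    folds: list[FoldResult] = []
    tprs: list[np.ndarray] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for train_idx, test_idx in splitter.split(X, y):
        model = fit(X[train_idx], y[train_idx], params)
        scores = predict_score(model, X[test_idx])
        c = confusion(y[test_idx], (scores >= 0.5).astype(int))
        curve = roc_curve(y[test_idx], scores)
        folds.append(
            FoldResult(
                report=MetricsReport.from_confusion(c, auc_value=auc(curve)),
                counts=c,
                curve=curve,
                n_test=len(test_idx),
            )
        )
        tprs.append(np.interp(grid, curve.fpr, curve.tpr))
        pooled_counts = pooled_counts + c

    names = ("sens", "spec", "accuracy", "mcc", "fpr", "auc")
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for name in names:
        vals = [getattr(f.report, name) for f in folds]
        present = [v for v in vals if v is not None]
        mean[name] = float(np.mean(present)) if present else float("nan")
        std[name] = float(np.std(present)) if present else float("nan")
    tpr_stack = np.vstack(tprs)
    return CvResult(
        folds=folds,
        mean=mean,
        std=std,
        pooled=MetricsReport.from_confusion(pooled_counts),
        pooled_counts=pooled_counts,
        fpr_grid=grid,
        mean_tpr=tpr_stack.mean(axis=0),
        std_tpr=tpr_stack.std(axis=0),
    )
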