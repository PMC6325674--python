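"""Evaluation machinery: confusion-matrix metrics, ROC/AUC, cross-validation,
decision-threshold selection and hyperparameter grid search.

Throughout this package the *positive class is non-toxic* (encoded 0) and
the negative class is toxic (encoded 1): TP counts non-toxic compounds
classified as non-toxic, FP counts toxic compounds over-predicted as
non-toxic.  All rate metrics follow that convention.

Undefined quantities (zero denominators, single-class ROC, constant input to
the correlation) return NaN as an explicit undefined marker rather than
raising, and the event is logged.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import LabeledDataset
from .et_toxscore import DEFAULT_THRESHOLD, classify

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN under the positive = non-toxic convention."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Tally a confusion matrix from {0: non-toxic, 1: toxic} label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((t == 0) & (p == 0))),
        tn=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 1) & (p == 0))),
        fn=int(np.sum((t == 0) & (p == 1))),
    )


def acc(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if c.total == 0:
        logger.warning("ACC undefined: no instances")
        return UNDEFINED
    return (c.tp + c.tn) / c.total


def tpr(c: ConfusionCounts) -> float:
    """Sensitivity TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        logger.warning("TPR undefined: no positive instances")
        return UNDEFINED
    return c.tp / (c.tp + c.fn)


def fpr(c: ConfusionCounts) -> float:
    """Fall-out FP / (FP + TN)."""
    if c.fp + c.tn == 0:
        logger.warning("FPR undefined: no negative instances")
        return UNDEFINED
    return c.fp / (c.fp + c.tn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TN*TP - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 by convention
    when any of the four sums vanishes.
    """
    denom2 = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom2 == 0:
        return 0.0
    return (c.tn * c.tp - c.fp * c.fn) / math.sqrt(denom2)


def mse(yhat, y) -> float:
    """Mean squared error (1/N) * sum (yhat_i - y_i)^2."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.mean((yhat - y) ** 2))


def pcc(yhat, y) -> float:
    """Pearson correlation cov(yhat, y) / (sigma_yhat * sigma_y)."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("length mismatch")
    if yhat.size < 2:
        raise ValueError("pcc requires at least 2 points")
    sy, syh = np.std(y), np.std(yhat)
    if sy == 0 or syh == 0:
        logger.warning("PCC undefined: constant input")
        return UNDEFINED
    cov = np.mean((yhat - yhat.mean()) * (y - y.mean()))
    return float(cov / (syh * sy))


@dataclass
class RocCurve:
    """ROC points (FPR, TPR) from a full threshold sweep, with trapezoidal AUC."""

    points: np.ndarray
    auc: float


def roc_curve(scores, true_labels) -> RocCurve:
    """Sweep every distinct score as the decision threshold.

    Scores are toxicity scores (low = likely non-toxic); a molecule is
    predicted positive (non-toxic) when its score <= threshold.  Tied scores
    collapse onto one threshold point; AUC is the trapezoidal area.
    Single-class input yields an undefined (NaN) AUC.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels)
    if s.shape != t.shape:
        raise ValueError("length mismatch")
    n_pos = int(np.sum(t == 0))
    n_neg = int(np.sum(t == 1))
    pts = [(0.0, 0.0)]
    if n_pos == 0 or n_neg == 0:
        logger.warning("ROC undefined: single-class input")
        pts.append((1.0, 1.0))
        return RocCurve(np.array(pts), UNDEFINED)
    order = np.argsort(s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tp = fp = 0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        block = t_sorted[i:j]
        tp += int(np.sum(block == 0))
        fp += int(np.sum(block == 1))
        pts.append((fp / n_neg, tp / n_pos))
        i = j
    points = np.array(pts)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocCurve(points, auc)


def select_threshold(scores, true_labels, grid_step: float = 0.01):
    """Pick the toxicity-score cutoff maximizing the MCC on a regular grid.

    Evaluates ``classify(scores, t)`` for t in {0, grid_step, ..., 1};
    ties resolve to the smallest threshold.  Returns
    ``(threshold, mcc_at_threshold, sweep_table)`` where the table has one
    row per grid point with MCC/ACC/TPR/FPR.
    """
    if not 0.0 < grid_step <= 0.5:
        raise ValueError("grid_step must be in (0, 0.5]")
    t = np.asarray(true_labels)
    if len(set(t.tolist())) < 2:
        raise ValueError("threshold selection requires both classes")
    n_steps = int(round(1.0 / grid_step))
    grid = np.arange(n_steps + 1) * grid_step
    rows = []
    for thr in grid:
        c = confusion(t, classify(scores, float(thr)))
        rows.append({
            "threshold": float(thr), "mcc": mcc(c),
            "acc": acc(c), "tpr": tpr(c), "fpr": fpr(c),
        })
    table = pd.DataFrame(rows)
    best = int(np.argmax(table["mcc"].to_numpy()))  # first max = smallest t
    return float(table.loc[best, "threshold"]), float(table.loc[best, "mcc"]), table


@dataclass
class CvPlan:
    """Fold assignment for k-fold cross-validation.

    Folds partition the index set with sizes differing by at most one;
    for binary labels assignment is stratified so per-fold class ratios
    match the dataset within one instance.
    """

    k: int
    seed: int
    assignment: np.ndarray

    @classmethod
    def make(cls, y, k: int = 5, seed: int = 0) -> "CvPlan":
        y = np.asarray(y)
        n = y.shape[0]
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > n:
            raise ValueError(f"k={k} exceeds dataset size {n}")
        binary = y.dtype.kind in "biu" and set(np.unique(y).tolist()) <= {0, 1}
        splitter = (StratifiedKFold if binary else KFold)(
            n_splits=k, shuffle=True, random_state=seed
        )
        assignment = np.empty(n, dtype=int)
        for fold, (_, val_idx) in enumerate(splitter.split(np.zeros((n, 1)), y)):
            assignment[val_idx] = fold
        return cls(k, seed, assignment)


@dataclass
class CvResult:
    per_fold: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    oof_pred: np.ndarray = field(repr=False, default=None)


def kfold_cv(ds: LabeledDataset, k: int, seed: int, trainer, scorer) -> CvResult:
    """Cross-validate ``trainer`` on ``ds``.

    ``trainer(train_ds) -> predict`` where ``predict(X)`` maps fingerprints
    to scores; ``scorer(y_true, y_pred) -> dict`` of metric values.  Each
    instance is validated exactly once; out-of-fold predictions are
    collected in dataset order.
    """
    if ds.y is None:
        raise ValueError("cross-validation requires labels")
    plan = CvPlan.make(ds.y, k=k, seed=seed)
    oof = np.full(len(ds), np.nan)
    rows = []
    for fold in range(k):
        val = np.where(plan.assignment == fold)[0]
        trn = np.where(plan.assignment != fold)[0]
        predict = trainer(ds.subset(trn))
        pred = np.asarray(predict(ds.X[val]), dtype=float)
        oof[val] = pred
        rows.append({"fold": fold, **scorer(ds.y[val], pred)})
    per_fold = pd.DataFrame(rows).set_index("fold")
    return CvResult(per_fold, per_fold.mean(), per_fold.std(ddof=1), oof)


def classification_scorer(threshold: float = DEFAULT_THRESHOLD):
    """Per-fold ACC/TPR/FPR/MCC at a fixed cutoff, plus the fold AUC."""

    def score(y_true, y_score):
        c = confusion(y_true, classify(y_score, threshold))
        return {
            "acc": acc(c), "tpr": tpr(c), "fpr": fpr(c), "mcc": mcc(c),
            "auc": roc_curve(y_score, y_true).auc,
        }

    return score


def regression_scorer(y_true, y_pred):
    return {"mse": mse(y_pred, y_true), "pcc": pcc(y_pred, y_true)}


def expand_grid(param_grid) -> list[dict]:
    """A dict of lists becomes the ordered cross-product of configurations."""
    if isinstance(param_grid, dict):
        keys = list(param_grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(param_grid[k] for k in keys))
        ]
    return [dict(c) for c in param_grid]


def grid_search(param_grid, ds: LabeledDataset, k: int, seed: int,
                trainer_factory, threshold: float = DEFAULT_THRESHOLD):
    """Exhaustive hyperparameter search by k-fold cross-validation.

    Each configuration is scored by mean out-of-fold MCC; ties break by mean
    AUC, then by grid order.  Returns ``(best_config, score_table)``.
    """
    configs = expand_grid(param_grid)
    if not configs:
        raise ValueError("empty parameter grid")
    scorer = classification_scorer(threshold)
    rows = []
    for i, cfg in enumerate(configs):
        res = kfold_cv(ds, k, seed, trainer_factory(cfg), scorer)
        rows.append({"config_index": i, **cfg,
                     "mean_mcc": res.mean["mcc"], "mean_auc": res.mean["auc"]})
    table = pd.DataFrame(rows)
    ranked = sorted(
        range(len(configs)),
        key=lambda i: (-table.loc[i, "mean_mcc"], -table.loc[i, "mean_auc"], i),
    )
    return configs[ranked[0]], table
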