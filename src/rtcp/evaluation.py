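"""Binary-classification evaluation: confusion counts, the standard metric
bundle (accuracy, specificity, sensitivity, precision, F-score, MCC),
ROC/AUC, stratified k-fold cross-validation of the full feature->PCA->
classifier pipeline, and the repeated-training stable-misclassification
analysis.

Conventions: the positive class is 1 (transporter). Degenerate denominators
(no positives predicted, a single-class fold, a zero factor under the MCC
root) are reported as 0 and flagged rather than raising, so fold-level
aggregation stays total.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import Reducer, fit_reducer, apply_reducer


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricBundle:
    acc: float
    spec: float
    sens: float
    pre: float
    f_score: float
    mcc: float
    beta: float = 1.0
    degenerate: tuple[str, ...] = ()


def confusion(labels_true: Sequence[int], labels_pred: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN with class 1 positive."""
    yt = np.asarray(labels_true).astype(int)
    yp = np.asarray(labels_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics(c: ConfusionCounts, beta: float = 1.0) -> MetricBundle:
    """Compute Acc, Spec, Sens, Pre, F-score and MCC from a confusion table.

    F-score = (1+beta^2) * Pre * Sens / (beta^2 * (Pre + Sens)), the usual
    F1 at beta = 1. MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    reported as 0 when any factor under the root vanishes.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    degenerate = []

    def _ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / c.total
    spec = _ratio(tn, tn + fp, "spec")
    sens = _ratio(tp, tp + fn, "sens")
    pre = _ratio(tp, tp + fp, "pre")
    if pre + sens == 0:
        degenerate.append("f_score")
        f_score = 0.0
    else:
        f_score = (1 + beta**2) * pre * sens / (beta**2 * (pre + sens))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricBundle(acc, spec, sens, pre, f_score, mcc, beta, tuple(degenerate))


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> list[tuple[float, float]]:
    """Exact ROC step curve: one point per distinct threshold, ties shared.

    Thresholds sweep from +inf (no positives called) down through every
    distinct score, producing points monotone in false-positive rate from
    (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # all samples tied at this threshold
            tp += int(y[j] == 1)
            fp += int(y[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Area under an (fpr, tpr) polyline by the trapezoid rule."""
    pts = sorted(points)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def roc_auc(scores, labels) -> float:
    return auc(roc_points(scores, labels))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    """Per-fold metrics plus their mean for one cross-validated pipeline."""

    k: int
    fold_metrics: list[MetricBundle]
    mean_metrics: MetricBundle
    fold_auc: list[float]
    mean_auc: float
    fold_assignment: dict[str, int]
    fold_roc: list[list[tuple[float, float]]] = field(default_factory=list, repr=False)

    @property
    def accuracy(self) -> float:
        return self.mean_metrics.acc

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "k": self.k,
            "fold_metrics": [asdict(m) for m in self.fold_metrics],
            "mean_metrics": asdict(self.mean_metrics),
            "fold_auc": self.fold_auc,
            "mean_auc": self.mean_auc,
            "fold_assignment": self.fold_assignment,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _mean_bundle(bundles: list[MetricBundle]) -> MetricBundle:
    fields = ("acc", "spec", "sens", "pre", "f_score", "mcc")
    vals = {f: float(np.mean([getattr(b, f) for b in bundles])) for f in fields}
    return MetricBundle(beta=bundles[0].beta, **vals)


def stratified_kfold(
    ids: Sequence[str], labels: Sequence[int], k: int = 10, seed: int = 0
) -> dict[str, int]:
    """Seeded stratified fold assignment: id -> fold index in 0..k-1."""
    ids = list(ids)
    labels = np.asarray(labels).astype(int)
    if len(ids) != len(labels):
        raise ValueError("ids and labels differ in length")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds n={len(ids)}")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return assignment


@dataclass(frozen=True)
class PipelineSpec:
    """What to run inside each fold: optional PCA then a classifier.

    ``classifier`` is a factory ``(seed) -> model`` where the model exposes
    ``fit`` implicitly via the factory (DCNN) or is a callable train
    function; here we take a train function ``(X, y, seed) -> model`` with
    the model exposing predict_label / predict_proba.
    """

    train: Callable[[np.ndarray, np.ndarray, int], object]
    pca_dim: int | None = 80
    pca_scope: str = "fold"  # fit the reducer on training folds only, or "global"


def cross_validate(
    pipeline: PipelineSpec,
    X: np.ndarray,
    y: Sequence[int],
    ids: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold evaluation of the full pipeline.

    With ``pca_scope='fold'`` the PCA reducer is fit on the k-1 training
    folds only and applied to the held-out fold, so no information leaks
    from validation data into the projection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(y))]
    assignment = stratified_kfold(ids, y, k=k, seed=seed)
    folds = np.array([assignment[i] for i in ids])

    global_reducer: Reducer | None = None
    if pipeline.pca_dim is not None and pipeline.pca_scope == "global":
        global_reducer = fit_reducer(X, pipeline.pca_dim)

    fold_metrics, fold_auc, fold_roc = [], [], []
    for fold in range(k):
        train_mask = folds != fold
        Xtr, ytr = X[train_mask], y[train_mask]
        Xte, yte = X[~train_mask], y[~train_mask]
        if pipeline.pca_dim is not None:
            reducer = (
                global_reducer
                if global_reducer is not None
                else fit_reducer(Xtr, pipeline.pca_dim)
            )
            Xtr, Xte = apply_reducer(reducer, Xtr), apply_reducer(reducer, Xte)
        model = pipeline.train(Xtr, ytr, seed + fold)
        pred = model.predict_label(Xte)
        fold_metrics.append(metrics(confusion(yte, pred)))
        scores = model.predict_proba(Xte)
        pts = roc_points(scores, yte)
        fold_roc.append(pts)
        fold_auc.append(auc(pts))
    return CVReport(
        k=k,
        fold_metrics=fold_metrics,
        mean_metrics=_mean_bundle(fold_metrics),
        fold_auc=fold_auc,
        mean_auc=float(np.mean(fold_auc)),
        fold_assignment=assignment,
        fold_roc=fold_roc,
    )


def stable_misclassifications(
    pipeline: PipelineSpec,
    X: np.ndarray,
    y: Sequence[int],
    ids: Sequence[str] | None = None,
    k: int = 10,
    n_models: int = 100,
    threshold: int = 50,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Find samples systematically mispredicted across repeated trainings.

    Folds are fixed once from ``seed``; the classifier is retrained
    ``n_models`` times with fresh initialization seeds. A true negative
    predicted positive in strictly more than ``threshold`` runs is a stable
    false positive; symmetrically for stable false negatives. The two id
    sets are disjoint since each sample has one true label.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not 0 <= threshold <= n_models:
        raise ValueError("threshold must lie in [0, n_models]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    ids = list(ids) if ids is not None else [str(i) for i in range(len(y))]
    assignment = stratified_kfold(ids, y, k=k, seed=seed)
    folds = np.array([assignment[i] for i in ids])
    wrong = np.zeros(len(y), dtype=int)
    for run in range(n_models):
        for fold in range(k):
            train_mask = folds != fold
            Xtr, ytr = X[train_mask], y[train_mask]
            Xte, yte = X[~train_mask], y[~train_mask]
            if pipeline.pca_dim is not None:
                reducer = fit_reducer(Xtr, pipeline.pca_dim)
                Xtr, Xte = apply_reducer(reducer, Xtr), apply_reducer(reducer, Xte)
            model = pipeline.train(Xtr, ytr, seed + 1000 * run + fold)
            pred = model.predict_label(Xte)
            idx = np.where(~train_mask)[0]
            wrong[idx[pred != yte]] += 1
    stable = wrong > threshold
    stable_fp = [ids[i] for i in np.where(stable & (y == 0))[0]]
    stable_fn = [ids[i] for i in np.where(stable & (y == 1))[0]]
    return stable_fp, stable_fn
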