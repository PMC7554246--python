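"""Confusion-matrix metrics, rank-based AUC, repeated stratified k-fold CV.

Metrics follow the standard definitions: accuracy = (TP+TN)/total,
precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R).  Degenerate
denominators yield NaN with a warning rather than a silent zero.  AUC uses
the rank (Mann-Whitney) formulation with ties counted 1/2, which equals
the trapezoidal area under the empirical ROC curve.

Cross-validation draws a fresh stratified partition per repeat (one seed
per repeat) and aggregates mean +/- standard deviation over all
k x repeats fold results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .seq_data import FragmentDataset


@dataclass
class ConfusionMatrix:
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


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f_score: float
    auc: float = float("nan")

    _FIELDS = ("accuracy", "precision", "recall", "f_score", "auc")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass
class CVSummary:
    """Per-fold metric entries over k x repeats runs, with seeds used."""

    entries: list[Metrics]
    k: int
    repeats: int
    seeds: list[int]

    def mean(self, metric: str) -> float:
        return float(np.nanmean([getattr(m, metric) for m in self.entries]))

    def std(self, metric: str) -> float:
        vals = [getattr(m, metric) for m in self.entries]
        return float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m)) for m in Metrics._FIELDS}


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally predictions (positive iff score >= threshold) against 0/1 labels."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics_from_confusion(c: ConfusionMatrix) -> Metrics:
    """Accuracy/precision/recall/F from counts; undefined ratios become NaN."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (no predicted positives)")
        precision = float("nan")
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined (no actual positives)")
        recall = float("nan")
    else:
        recall = c.tp / (c.tp + c.fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f_score = float("nan")
    else:
        f_score = 2.0 * precision * recall / (precision + recall)
    return Metrics(accuracy, precision, recall, f_score)


def roc_auc(labels, scores) -> float:
    """AUC by the rank (Mann-Whitney) formulation; tied scores count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def evaluate_scores(labels, scores, threshold: float = 0.5) -> Metrics:
    """Threshold metrics plus AUC in one call."""
    m = metrics_from_confusion(confusion(labels, scores, threshold))
    m.auc = roc_auc(labels, scores)
    return m


def repeated_kfold(
    dataset: FragmentDataset,
    k: int,
    repeats: int,
    trainer: Callable[[FragmentDataset, FragmentDataset], Metrics],
    seeds: list[int],
    stratified: bool = True,
) -> CVSummary:
    """Repeated k-fold cross-validation.

    Per repeat, a fresh (stratified by default) partition into k near-equal
    folds; each fold is held out once and ``trainer(train_set, val_set)``
    returns the fold's metrics.  The summary aggregates all k x repeats
    entries.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if len(seeds) != repeats:
        raise ValueError(f"need {repeats} seeds, got {len(seeds)}")
    labels = dataset.labels()
    class_counts = np.bincount(labels, minlength=2)
    if stratified and k > class_counts.min():
        raise ValueError(
            f"k={k} exceeds the smaller class count {class_counts.min()}"
        )
    entries: list[Metrics] = []
    for seed in seeds:
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            splits = splitter.split(np.zeros(len(labels)), labels)
        else:
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(labels))
            splits = (
                (np.setdiff1d(order, fold), fold)
                for fold in np.array_split(order, k)
            )
        for train_idx, val_idx in splits:
            entries.append(
                trainer(dataset.subset(train_idx), dataset.subset(val_idx))
            )
    return CVSummary(entries=entries, k=k, repeats=repeats, seeds=list(seeds))


def roc_curve_points(labels, scores) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, threshold descending."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    n_pos = np.sum(labels == 1)
    n_neg = np.sum(labels == 0)
    tps = np.cumsum(labels == 1)
    fps = np.cumsum(labels == 0)
    # keep only the last point of each tied-score run
    distinct = np.r_[scores[1:] != scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return np.stack([fpr, tpr], axis=1)
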