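"""Stratified splitting and the binary-classification metric suite.

Accuracy, precision and recall come from the confusion table with glaucoma
as the positive class.  AUC is computed from the rank-sum (Mann–Whitney)
statistic with mid-rank tie handling,

    AUC = (sum of positive ranks - n_pos (n_pos + 1) / 2) / (n_pos * n_neg),

which equals the probability that a random positive outscores a random
negative (ties counted half) and is invariant under any strictly monotone
transform of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.stats import rankdata


@dataclass
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int


@dataclass
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass
class MetricReport:
    accuracy: float
    precision: float  # NaN when undefined (no positive predictions)
    recall: float     # NaN when undefined (no positive cases)
    auc: float | None = None
    loss: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "loss": self.loss,
        }


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items to fractions, largest remainder first."""
    exact = [n * f for f in fractions]
    base = [math.floor(e) for e in exact]
    leftover = n - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (exact[i] - base[i]), reverse=True
    )
    for i in remainders[:leftover]:
        base[i] += 1
    return base


def stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitIndices:
    """Per-class shuffled train/val/test partition.

    Within each class the item counts follow largest-remainder rounding of
    the fractions, so per-class proportions are within one item of the
    targets.  Deterministic under the seed.
    """
    labels = np.asarray(labels)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls} has fewer than 3 items")
        rng.shuffle(idx)
        counts = _largest_remainder(idx.size, tuple(fractions))
        splits = np.split(idx, np.cumsum(counts)[:-1])
        for part, s in zip(parts, splits):
            part.extend(s.tolist())
    return SplitIndices(
        train=np.sort(np.array(parts[0])),
        val=np.sort(np.array(parts[1])),
        test=np.sort(np.array(parts[2])),
        fractions=tuple(fractions),
        seed=seed,
    )


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionTable:
    """Confusion counts with label 1 (glaucoma) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    for arr in (y_true, y_pred):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionTable(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def basic_metrics(ct: ConfusionTable) -> tuple[float, float, float]:
    """(accuracy, precision, recall); undefined ratios reported as NaN."""
    if ct.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (ct.tp + ct.tn) / ct.total
    if ct.tp + ct.fp == 0:
        import warnings

        warnings.warn("no positive predictions; precision undefined")
        precision = float("nan")
    else:
        precision = ct.tp / (ct.tp + ct.fp)
    if ct.p == 0:
        import warnings

        warnings.warn("no positive cases; recall undefined")
        recall = float("nan")
    else:
        recall = ct.tp / ct.p
    return accuracy, precision, recall


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann–Whitney with mid-rank ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def binary_cross_entropy(y_true: np.ndarray, probs: np.ndarray, eps: float = 1e-7) -> float:
    y = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(probs, dtype=float), eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def metric_report(y_true: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> MetricReport:
    """Full report from predicted probabilities."""
    probs = np.asarray(probs, dtype=float)
    preds = (probs >= threshold).astype(int)
    ct = confusion(y_true, preds)
    acc, prec, rec = basic_metrics(ct)
    return MetricReport(
        accuracy=acc,
        precision=prec,
        recall=rec,
        auc=rank_auc(probs, y_true),
        loss=binary_cross_entropy(y_true, probs),
    )
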