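"""Pixel- and scan-level evaluation: Dice, confusion rates, PR curves.

Conventions: Dice of two empty masks is 1.0 (perfect agreement) and of one
empty mask 0.0; rates whose denominator class is absent are reported as NaN
rather than silently as 0; precision at a threshold with no predicted
positives is 1.0.
"""

from __future__ import annotations

import dataclasses

import numpy as np


def _binary(mask, class_id=1) -> np.ndarray:
    return np.asarray(mask) == class_id


def dice(pred_mask, true_mask, class_id: int = 1) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` for one class."""
    a = _binary(pred_mask, class_id)
    b = _binary(true_mask, class_id)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def dice_per_class(pred_mask, true_mask, n_classes: int = 2) -> list[float]:
    return [dice(pred_mask, true_mask, class_id=c) for c in range(n_classes)]


def pixel_confusion(pred, truth) -> dict:
    """Pixel-level sensitivity/specificity and misclassification rates.

    ``fn_rate`` is the fraction of true foreground pixels predicted background
    (so sensitivity = 1 − fn_rate); ``fp_rate`` the fraction of true
    background predicted foreground.  A rate whose truth class is empty is
    NaN.
    """
    p = _binary(pred)
    t = _binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    tp = int((p & t).sum())
    fn = int((~p & t).sum())
    fp = int((p & ~t).sum())
    tn = int((~p & ~t).sum())
    pos, neg = tp + fn, tn + fp
    sens = tp / pos if pos else float("nan")
    spec = tn / neg if neg else float("nan")
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens, "specificity": spec,
        "fn_rate": fn / pos if pos else float("nan"),
        "fp_rate": fp / neg if neg else float("nan"),
    }


def precision_recall_curve(prob_map, truth, thresholds=None):
    """Precision/recall of ``prob >= t`` over a sweep of thresholds.

    ``thresholds`` defaults to 101 evenly spaced values in [0, 1].  Returns a
    list of ``(precision, recall)`` in threshold order; recall is monotone
    non-increasing along it.  Raises if the truth contains no positive pixels
    (the curve is undefined).
    """
    prob = np.asarray(prob_map, dtype=np.float64).ravel()
    t = _binary(truth).ravel()
    if prob.shape != t.shape:
        raise ValueError("probability map and truth shapes differ")
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("precision-recall curve undefined: truth has no positive pixels")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    curve = []
    for thr in np.asarray(thresholds, dtype=np.float64):
        pred = prob >= thr
        tp = int((pred & t).sum())
        npred = int(pred.sum())
        precision = tp / npred if npred else 1.0
        curve.append((precision, tp / n_pos))
    return curve


@dataclasses.dataclass
class ScanMetrics:
    """Scan-level confusion counts with the standard derived ratios."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def precision(self) -> float:
        pred_pos = self.tp + self.fp
        return self.tp / pred_pos if pred_pos else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        if not np.isfinite(p) or not np.isfinite(r) or p + r == 0:
            return float("nan")
        return 2 * p * r / (p + r)

    def to_dict(self, decimals: int = 4) -> dict:
        rnd = lambda v: round(float(v), decimals)  # noqa: E731
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": rnd(self.accuracy), "sensitivity": rnd(self.sensitivity),
            "specificity": rnd(self.specificity), "precision": rnd(self.precision),
            "f1": rnd(self.f1),
        }


def scan_metrics(decisions, labels) -> ScanMetrics:
    """Confusion counts and ratios for binary per-scan decisions vs labels."""
    d = np.asarray(decisions, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if d.size == 0:
        raise ValueError("empty input")
    if d.shape != y.shape:
        raise ValueError("decisions and labels must have equal length")
    if not (np.isin(d, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("decisions and labels must be binary")
    return ScanMetrics(
        tp=int(((d == 1) & (y == 1)).sum()),
        fp=int(((d == 1) & (y == 0)).sum()),
        tn=int(((d == 0) & (y == 0)).sum()),
        fn=int(((d == 0) & (y == 1)).sum()),
    )
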