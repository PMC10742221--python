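"""Confusion-matrix metrics and split bookkeeping shared by both
classification branches.

The positive class is "expert" throughout; the confusion matrix follows
the ``C = [TP, FP; FN, TN]`` layout.  Metrics with a zero denominator are
defined as 0 and flagged as degenerate so repeated-CV summaries stay
finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError

__all__ = [
    "ClassifierReport",
    "confusion",
    "metrics",
    "kappa",
    "summarize_repeats",
    "SplitPlan",
    "make_splits",
]

POSITIVE = "expert"
NEGATIVE = "novice"

METRIC_NAMES = (
    "accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "f1",
    "mcc",
    "kappa",
)


@dataclass
class ClassifierReport:
    """Binary-classification outcome: counts plus derived metrics."""

    confusion: np.ndarray  # [[TP, FP], [FN, TN]]
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    kappa: float
    n_samples: int
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["n_samples"] = self.n_samples
        d["confusion"] = np.asarray(self.confusion).tolist()
        return d


def confusion(y_true, y_pred, positive: str = POSITIVE) -> np.ndarray:
    """2x2 count matrix ``[[TP, FP], [FN, TN]]`` over string labels."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValidationError("empty label sequence")
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred differ in length")
    allowed = {POSITIVE, NEGATIVE}
    bad = set(y_true) | set(y_pred) - allowed
    if not (set(y_true) | set(y_pred)) <= allowed:
        raise ValidationError(f"labels outside {allowed}: {bad - allowed}")
    tp = sum(t == positive and p == positive for t, p in zip(y_true, y_pred))
    fp = sum(t != positive and p == positive for t, p in zip(y_true, y_pred))
    fn = sum(t == positive and p != positive for t, p in zip(y_true, y_pred))
    tn = sum(t != positive and p != positive for t, p in zip(y_true, y_pred))
    return np.array([[tp, fp], [fn, tn]], dtype=int)


def _safe_div(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def kappa(conf: np.ndarray) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e): 0 at chance, 1 when perfect."""
    (tp, fp), (fn, tn) = np.asarray(conf, dtype=float)
    n = tp + fp + fn + tn
    if n == 0:
        raise ValidationError("empty confusion matrix")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1 - p_e)


def metrics(conf: np.ndarray) -> ClassifierReport:
    """Derive accuracy, precision, sensitivity/recall, specificity, F1,
    MCC and kappa from a ``[[TP, FP], [FN, TN]]`` matrix."""
    conf = np.asarray(conf)
    (tp, fp), (fn, tn) = conf.astype(float)
    n = tp + fp + fn + tn
    if n == 0:
        raise ValidationError("empty confusion matrix")
    deg: list[str] = []
    precision = _safe_div(tp, tp + fp, "precision", deg)
    sensitivity = _safe_div(tp, tp + fn, "sensitivity", deg)
    specificity = _safe_div(tn, fp + tn, "specificity", deg)
    f1 = _safe_div(
        2 * precision * sensitivity, precision + sensitivity, "f1", deg
    )
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc", deg)
    return ClassifierReport(
        confusion=conf.astype(int),
        accuracy=(tp + tn) / n,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        mcc=mcc,
        kappa=kappa(conf),
        n_samples=int(n),
        degenerate=deg,
    )


def summarize_repeats(reports: list[ClassifierReport]) -> dict:
    """mean +/- SD (population) and max per metric across repeats."""
    if not reports:
        raise ValidationError("no reports to summarize")
    out = {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        out[m] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)),
            "max": float(vals.max()),
        }
    return out


@dataclass
class SplitPlan:
    """Disjoint holdout plus a fold partition of the remaining indices."""

    holdout: np.ndarray
    folds: list[np.ndarray]

    @property
    def trainval(self) -> np.ndarray:
        return np.sort(np.concatenate(self.folds))


def make_splits(
    n: int, holdout: float = 0.1, folds: int = 5, seed: int = 0
) -> SplitPlan:
    """Shuffle ``n`` indices into a holdout set and ``folds`` near-equal
    folds of the remainder; deterministic under ``seed``."""
    if not 0 < holdout < 1:
        raise ValidationError("holdout fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = int(round(holdout * n))
    if n_hold == 0 or n - n_hold < folds:
        raise ValidationError("not enough samples for the requested splits")
    hold = np.sort(perm[:n_hold])
    rest = perm[n_hold:]
    return SplitPlan(hold, [np.sort(f) for f in np.array_split(rest, folds)])
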