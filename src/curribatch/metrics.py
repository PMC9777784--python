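"""Multi-label evaluation: micro/macro precision, recall, F1, long-tail metrics.

Micro metrics pool true/false positives and false negatives over every
(example, label) cell. Macro metrics average per-label precision and recall
arithmetically over the *full* label catalog and then take the harmonic mean
of those averages — deliberately not the mean of per-label F1 scores.
Long-tail metrics restrict the micro pooling to label columns whose training
frequency falls below a threshold γ.

Any precision or recall with a zero denominator is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


def _validate(predictions: np.ndarray, gold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions)
    g = np.asarray(gold)
    if p.shape != g.shape or p.ndim != 2:
        raise ValueError(
            f"prediction and gold matrices must be aligned 2-D arrays; "
            f"got {p.shape} vs {g.shape}"
        )
    return (p != 0).astype(np.int64), (g != 0).astype(np.int64)


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


@dataclass
class MicroMacroReport:
    """Pooled confusion counts plus micro and macro rates."""

    tp: int
    fp: int
    fn: int
    p_micro: float
    r_micro: float
    f1_micro: float
    p_macro: float
    r_macro: float
    f1_macro: float
    n_labels: int

    def to_row(self) -> dict[str, float]:
        return {
            "Pmicro": self.p_micro,
            "Rmicro": self.r_micro,
            "F1micro": self.f1_micro,
            "Pmacro": self.p_macro,
            "Rmacro": self.r_macro,
            "F1macro": self.f1_macro,
        }


def micro_metrics(
    predictions: np.ndarray, gold: np.ndarray
) -> tuple[float, float, float]:
    """(Pmicro, Rmicro, F1micro) with TP/FP/FN pooled over all cells."""
    p, g = _validate(predictions, gold)
    tp = int(((p == 1) & (g == 1)).sum())
    fp = int(((p == 1) & (g == 0)).sum())
    fn = int(((p == 0) & (g == 1)).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return prec, rec, _f1(prec, rec)


def macro_f1(
    predictions: np.ndarray,
    gold: np.ndarray,
    label_catalog: Sequence[str] | None = None,
) -> tuple[float, float, float]:
    """(Pmacro, Rmacro, F1macro): per-label P and R averaged over the catalog.

    Every catalog label counts in the average (absent labels contribute 0 via
    the zero-denominator convention); F1macro is the harmonic mean of the two
    averages, not an average of per-label F1s.
    """
    p, g = _validate(predictions, gold)
    n_labels = p.shape[1] if label_catalog is None else len(label_catalog)
    if n_labels == 0:
        raise ValueError("label catalog is empty")
    if n_labels != p.shape[1]:
        raise ValueError("label catalog size must match matrix columns")
    tp = ((p == 1) & (g == 1)).sum(axis=0).astype(float)
    fp = ((p == 1) & (g == 0)).sum(axis=0).astype(float)
    fn = ((p == 0) & (g == 1)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    p_macro = float(prec.mean())
    r_macro = float(rec.mean())
    return p_macro, r_macro, _f1(p_macro, r_macro)


def micro_macro_report(
    predictions: np.ndarray,
    gold: np.ndarray,
    label_catalog: Sequence[str] | None = None,
) -> MicroMacroReport:
    p, g = _validate(predictions, gold)
    tp = int(((p == 1) & (g == 1)).sum())
    fp = int(((p == 1) & (g == 0)).sum())
    fn = int(((p == 0) & (g == 1)).sum())
    pm, rm, f1m = micro_metrics(p, g)
    pM, rM, f1M = macro_f1(p, g, label_catalog)
    return MicroMacroReport(tp, fp, fn, pm, rm, f1m, pM, rM, f1M, p.shape[1])


@dataclass
class LongTailResult:
    """Micro P/R over the long-tailed label columns only.

    ``empty`` flags the case where no label qualifies; precision and recall
    are then NaN, never silent zeros.
    """

    precision: float
    recall: float
    n_longtail_labels: int
    gamma: float

    @property
    def empty(self) -> bool:
        return self.n_longtail_labels == 0


def longtail_metrics(
    predictions: np.ndarray,
    gold: np.ndarray,
    train_label_freqs: np.ndarray,
    gamma: float,
) -> LongTailResult:
    """Micro precision/recall pooled over labels with training frequency < γ.

    ``train_label_freqs`` counts, per catalog label, the training examples
    that carry the label.
    """
    if gamma < 0:
        raise ValueError("gamma must be ≥ 0")
    p, g = _validate(predictions, gold)
    freqs = np.asarray(train_label_freqs, dtype=float)
    if freqs.shape != (p.shape[1],):
        raise ValueError("need one training frequency per label column")
    mask = freqs < gamma
    k = int(mask.sum())
    if k == 0:
        return LongTailResult(float("nan"), float("nan"), 0, gamma)
    prec, rec, _ = micro_metrics(p[:, mask], g[:, mask])
    return LongTailResult(prec, rec, k, gamma)
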