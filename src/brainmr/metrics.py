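"""Classification and segmentation metrics on the percent scale.

All rates are reported on 0-100.  AUC here is the balanced form
``(TPR + TNR)/2`` (not a ROC-curve integral), matching how two-class
screening results are usually tabulated alongside TPR/TNR.  Metrics with a
zero denominator are *undefined* and carried as ``None`` — never silently 0
— and excluded from fold means with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .core_io import BinaryMask

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
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")


@dataclass(frozen=True)
class MetricsReport:
    """Rates in percent; ``None`` marks an undefined (0/0) entry."""

    accuracy: float | None
    tpr: float | None
    tnr: float | None
    ppv: float | None
    f_score: float | None
    auc: float | None
    dsc: float | None = None   # segmentation only

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(pred: np.ndarray | BinaryMask | Sequence,
              truth: np.ndarray | BinaryMask | Sequence,
              positive=1) -> ConfusionCounts:
    """Elementwise 2x2 tally; the positive class is abnormal/tumor."""
    p = np.asarray(pred.pixels if isinstance(pred, BinaryMask) else pred)
    t = np.asarray(truth.pixels if isinstance(truth, BinaryMask) else truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    pp, tp_ = (p == positive), (t == positive)
    return ConfusionCounts(
        tp=int(np.sum(pp & tp_)),
        fp=int(np.sum(pp & ~tp_)),
        tn=int(np.sum(~pp & ~tp_)),
        fn=int(np.sum(~pp & tp_)),
    )


def _rate(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, TPR, TNR, PPV, F-score and balanced AUC from a 2x2 tally."""
    tpr = _rate(c.tp, c.tp + c.fn)
    tnr = _rate(c.tn, c.tn + c.fp)
    ppv = _rate(c.tp, c.tp + c.fp)
    acc = _rate(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn)
    if ppv is None or tpr is None or (ppv + tpr) == 0:
        f = None
    else:
        f = 2.0 * ppv * tpr / (ppv + tpr)
    auc = None if tpr is None or tnr is None else (tpr + tnr) / 2.0
    return MetricsReport(accuracy=acc, tpr=tpr, tnr=tnr, ppv=ppv, f_score=f, auc=auc)


def balanced_auc(tpr: float, tnr: float) -> float:
    """Balanced AUC = (TPR + TNR)/2, on whatever scale the rates are given."""
    return (tpr + tnr) / 2.0


def dsc(S: BinaryMask | np.ndarray, SG: BinaryMask | np.ndarray) -> float | None:
    """Dice similarity 2|S∩SG|/(|S|+|SG|) on [0,1]; None if both masks empty."""
    a = np.asarray(S.pixels if isinstance(S, BinaryMask) else S).astype(bool)
    b = np.asarray(SG.pixels if isinstance(SG, BinaryMask) else SG).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return 2.0 * int((a & b).sum()) / denom


def segmentation_metrics(S: BinaryMask, SG: BinaryMask) -> MetricsReport:
    """Pixel-level classification metrics plus DSC (in percent)."""
    c = confusion(S, SG, positive=1)
    rep = classification_metrics(c)
    d = dsc(S, SG)
    return MetricsReport(**{**rep.as_dict(), "dsc": None if d is None else 100.0 * d})


def summarize_folds(reports: Sequence[MetricsReport]) -> dict[str, tuple[float | None, float | None]]:
    """Per-metric (mean, sample SD) across folds, skipping undefined entries."""
    out: dict[str, tuple[float | None, float | None]] = {}
    for f in fields(MetricsReport):
        vals = [getattr(r, f.name) for r in reports]
        defined = [v for v in vals if v is not None]
        skipped = len(vals) - len(defined)
        if skipped and any(v is not None for v in vals):
            logger.info("metric %s undefined in %d/%d folds", f.name, skipped, len(vals))
        if not defined:
            out[f.name] = (None, None)
        else:
            mean = float(np.mean(defined))
            sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
            out[f.name] = (mean, sd)
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding matching tabulated results (2 decimals, half-up)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
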