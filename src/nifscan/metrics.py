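"""Binary performance metrics parameterized by observed class sizes.

The five metrics — sensitivity, specificity, accuracy, precision and
Matthews correlation — are written in the "redefined" form that works
directly from four counts: the number of observed positives (Np), observed
negatives (Nn), negatives misclassified as positive (here ``fp``) and
positives misclassified as negative (``fn``):

    Sn  = 1 - fn/Np
    Sp  = 1 - fp/Nn
    Ac  = 1 - (fn + fp)/(Np + Nn)
    Pre = 1 - fp/(Np - fn + fp)
    MCC = [1 - (fn/Np + fp/Nn)] / sqrt[(1 + (fp - fn)/Np)(1 + (fn - fp)/Nn)]

These are algebraically identical to the classical TP/TN/FP/FN formulas
(TP = Np - fn, TN = Nn - fp); the test suite verifies the equivalence on
random counts. Metrics with an undefined denominator are reported as NaN
and named in :attr:`MetricSet.undefined`, never silently zeroed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sn", "sp", "ac", "pre", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion summary: observed positives ``n_pos``, observed
    negatives ``n_neg``, false positives ``fp`` (negatives called positive)
    and false negatives ``fn`` (positives called negative)."""

    n_pos: int
    n_neg: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.fn > self.n_pos:
            raise ValueError("fn cannot exceed the number of observed positives")
        if self.fp > self.n_neg:
            raise ValueError("fp cannot exceed the number of observed negatives")


@dataclass(frozen=True)
class MetricSet:
    """The five metrics; NaN marks an undefined value."""

    sn: float
    sp: float
    ac: float
    pre: float
    mcc: float

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(n for n in METRIC_NAMES if math.isnan(getattr(self, n)))

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in METRIC_NAMES}


def confusion_counts(
    truth: Sequence, pred: Sequence, positive_label
) -> ConfusionCounts:
    """Tally binary confusion counts; any label other than
    ``positive_label`` counts as negative."""
    if len(truth) != len(pred):
        raise ValueError(f"truth has {len(truth)} labels but pred has {len(pred)}")
    t = np.asarray(truth, dtype=object) == positive_label
    p = np.asarray(pred, dtype=object) == positive_label
    return ConfusionCounts(
        n_pos=int(t.sum()),
        n_neg=int((~t).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Compute the five metrics from confusion counts (see module docstring)."""
    nan = float("nan")
    sn = 1.0 - c.fn / c.n_pos if c.n_pos > 0 else nan
    sp = 1.0 - c.fp / c.n_neg if c.n_neg > 0 else nan
    total = c.n_pos + c.n_neg
    ac = 1.0 - (c.fn + c.fp) / total if total > 0 else nan

    pred_pos = c.n_pos - c.fn + c.fp
    pre = 1.0 - c.fp / pred_pos if pred_pos > 0 else nan

    if c.n_pos > 0 and c.n_neg > 0:
        d1 = 1.0 + (c.fp - c.fn) / c.n_pos
        d2 = 1.0 + (c.fn - c.fp) / c.n_neg
        if d1 > 0 and d2 > 0:
            mcc = (1.0 - (c.fn / c.n_pos + c.fp / c.n_neg)) / math.sqrt(d1 * d2)
        else:
            mcc = nan
    else:
        mcc = nan
    return MetricSet(sn=sn, sp=sp, ac=ac, pre=pre, mcc=mcc)


def mean_metrics(units: Sequence[MetricSet]) -> tuple[MetricSet, MetricSet]:
    """Arithmetic mean and standard error per metric across units.

    Undefined (NaN) values are excluded metric-wise; exclusions are logged.
    Standard error = sample SD of the per-unit values / sqrt(#values).
    """
    if not units:
        raise ValueError("no metric sets to average")
    means, ses = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(u, name) for u in units], dtype=float)
        ok = vals[~np.isnan(vals)]
        n_dropped = len(vals) - len(ok)
        if n_dropped:
            logger.info("metric %s undefined in %d of %d units; excluded from average",
                        name, n_dropped, len(vals))
        if len(ok) == 0:
            means[name] = float("nan")
            ses[name] = float("nan")
        else:
            means[name] = float(ok.mean())
            ses[name] = float(ok.std(ddof=1) / math.sqrt(len(ok))) if len(ok) > 1 else 0.0
    return MetricSet(**means), MetricSet(**ses)


def roc_auc(scores: Sequence[float], truth: Sequence, positive_label) -> float:
    """Area under the ROC curve for positive-class scores (midrank ties)."""
    t = np.asarray(truth, dtype=object) == positive_label
    if t.all() or not t.any():
        raise ValueError("ROC AUC needs both classes present in truth")
    return float(roc_auc_score(t.astype(int), np.asarray(scores, dtype=float)))
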