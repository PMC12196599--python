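"""Trial-level confusion accounting and the standard detection metrics.

A *trial* is one labelled recording.  A fall trial with at least one
detector event is a true positive (multiple alerts from one trial still
count once — they are tallied separately as a multiple-alert diagnostic);
with none, a false negative.  A non-fall trial with any event is a false
positive, otherwise a true negative.  Sensitivity, specificity and accuracy
follow the usual definitions TP/(TP+FN), TN/(TN+FP) and
(TP+TN)/(TP+TN+FP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Sequence, Union

from .synthetic import FALL_LABELS

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "score_trials",
    "sensitivity",
    "specificity",
    "accuracy",
    "metrics_report",
]


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is empty (no positive / negative trials)."""


@dataclass
class ConfusionCounts:
    """Pooled TP/FP/TN/FN plus a per-activity breakdown.

    ``per_activity`` maps each label to its own four counts, so a
    per-activity table (one column per activity) can be rendered directly.
    ``multiple_alerts`` counts trials that produced more than one event.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    per_activity: dict = field(default_factory=dict)
    multiple_alerts: int = 0

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def _event_count(events: Union[int, Sequence]) -> int:
    if isinstance(events, int):
        if events < 0:
            raise ValueError("event count must be >= 0")
        return events
    return len(events)


def score_trials(results: Iterable[tuple],
                 positive_labels: Collection = FALL_LABELS
                 ) -> ConfusionCounts:
    """Tally (label, events) pairs into a :class:`ConfusionCounts`.

    ``events`` may be the detector's event list or a plain count.  Labels
    in ``positive_labels`` are ground-truth falls.  Raises ``ValueError``
    for an unlabeled trial.
    """
    c = ConfusionCounts()
    for label, events in results:
        if label is None:
            raise ValueError("unlabeled trial")
        n_events = _event_count(events)
        if n_events > 1:
            c.multiple_alerts += 1
        key = getattr(label, "value", label)
        pa = c.per_activity.setdefault(
            key, {"tp": 0, "fp": 0, "tn": 0, "fn": 0})
        if label in positive_labels or key in positive_labels:
            which = "tp" if n_events >= 1 else "fn"
        else:
            which = "fp" if n_events >= 1 else "tn"
        pa[which] += 1
        setattr(c, which, getattr(c, which) + 1)
    return c


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN): the fraction of real falls detected."""
    if c.positives == 0:
        raise UndefinedMetricError("no positive trials")
    return c.tp / c.positives


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP): the fraction of non-falls left alone."""
    if c.negatives == 0:
        raise UndefinedMetricError("no negative trials")
    return c.tn / c.negatives


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / all trials."""
    if c.total == 0:
        raise UndefinedMetricError("no trials")
    return (c.tp + c.tn) / c.total


def metrics_report(c: ConfusionCounts) -> dict:
    """Pooled metrics as display-ready values (fractions at 3 decimals)."""
    out = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
    if c.positives:
        out["sensitivity"] = round(sensitivity(c), 3)
    if c.negatives:
        out["specificity"] = round(specificity(c), 3)
    if c.total:
        out["accuracy"] = round(accuracy(c), 3)
    return out
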