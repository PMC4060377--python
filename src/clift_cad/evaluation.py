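"""Contingency tables and the four reported metrics.

Suspended well decisions are scored conservatively: a suspension counts in
the denominator of accuracy and of the rate for its own true class
(sensitivity for true positives, specificity for true negatives) but never
as a correct call, and it never enters precision. With no suspensions the
definitions reduce to the textbook ones.

All percentages are computed from exact integer counts and rounded half-up
to one decimal; rounded values are never chained.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import NEGATIVE, POSITIVE, SUSPENDED, round_half_up
from .screening import CANDIDATE_POSITIVE


@dataclass
class ContingencyTable:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0
    suspended_pos: int = 0
    suspended_neg: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn", "suspended_pos", "suspended_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn + self.suspended_pos + self.suspended_neg

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
            self.suspended_pos + other.suspended_pos,
            self.suspended_neg + other.suspended_neg,
        )


@dataclass
class MetricsReport:
    """Percentages to one decimal; ``None`` marks an undefined metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None


def tabulate(true_labels, decisions) -> ContingencyTable:
    """Cross-tabulate binary truths against binary/ternary decisions."""
    true_labels = list(true_labels)
    decisions = list(decisions)
    if len(true_labels) != len(decisions):
        raise ValueError(
            f"length mismatch: {len(true_labels)} truths vs {len(decisions)} decisions"
        )
    t = ContingencyTable()
    for truth, dec in zip(true_labels, decisions):
        if truth not in (POSITIVE, NEGATIVE):
            raise ValueError(f"true labels must be binary, got {truth!r}")
        if dec == SUSPENDED:
            if truth == POSITIVE:
                t.suspended_pos += 1
            else:
                t.suspended_neg += 1
        elif dec == POSITIVE:
            if truth == POSITIVE:
                t.tp += 1
            else:
                t.fp += 1
        elif dec == NEGATIVE:
            if truth == POSITIVE:
                t.fn += 1
            else:
                t.tn += 1
        else:
            raise ValueError(f"unrecognized decision {dec!r}")
    return t


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return round_half_up(100.0 * num / den)


def metrics(table: ContingencyTable) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision under suspension scoring."""
    return MetricsReport(
        accuracy=_pct(table.tp + table.tn, table.total),
        sensitivity=_pct(table.tp, table.tp + table.fn + table.suspended_pos),
        specificity=_pct(table.tn, table.tn + table.fp + table.suspended_neg),
        precision=_pct(table.tp, table.tp + table.fp),
    )


def threshold_step_report(true_labels, prescreen_labels) -> dict:
    """Contingency of the threshold pre-screen, with per-row percentages.

    Rows are the true classes; columns split each row by the pre-screen
    outcome (labeled positive = has candidates / labeled negative = none).
    """
    true_labels = list(true_labels)
    prescreen_labels = list(prescreen_labels)
    if len(true_labels) != len(prescreen_labels):
        raise ValueError("length mismatch between truths and prescreen labels")
    counts = {
        (POSITIVE, True): 0,
        (POSITIVE, False): 0,
        (NEGATIVE, True): 0,
        (NEGATIVE, False): 0,
    }
    for truth, pre in zip(true_labels, prescreen_labels):
        if truth not in (POSITIVE, NEGATIVE):
            raise ValueError(f"true labels must be binary, got {truth!r}")
        counts[(truth, pre == CANDIDATE_POSITIVE)] += 1
    table = ContingencyTable(
        tp=counts[(POSITIVE, True)],
        fn=counts[(POSITIVE, False)],
        fp=counts[(NEGATIVE, True)],
        tn=counts[(NEGATIVE, False)],
    )
    n_pos = table.tp + table.fn
    n_neg = table.fp + table.tn
    return {
        "table": table,
        "pos_candidate_pct": _pct(table.tp, n_pos),
        "pos_presumed_neg_pct": _pct(table.fn, n_pos),
        "neg_candidate_pct": _pct(table.fp, n_neg),
        "neg_presumed_neg_pct": _pct(table.tn, n_neg),
    }
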