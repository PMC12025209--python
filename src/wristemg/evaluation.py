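"""Accuracy and error summaries for recognition traces.

Accuracies are kept as exact rationals internally; percentage display
rounds half-up to one decimal place, and the rounded figure never feeds
back into any computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def percent(value: Fraction | float, decimals: int = 1) -> float:
    """Half-up percentage rounding for display (0.98722 -> 98.7)."""
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-decimals)
    return float((d * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AccuracyReport:
    """Per-movement and overall recognition accuracy from outcome
    counts; accuracies are exact fractions."""

    counts: dict[str, tuple[int, int]]  # movement -> (total, incorrect)
    per_movement: dict[str, Fraction]
    overall: Fraction

    def overall_percent(self) -> float:
        return percent(self.overall)

    def per_movement_percent(self) -> dict[str, float]:
        return {m: percent(a) for m, a in self.per_movement.items()}

    def __str__(self) -> str:
        lines = [
            f"{m:>6}: {t - i}/{t} correct ({percent(self.per_movement[m]):.1f}%)"
            for m, (t, i) in self.counts.items()
        ]
        lines.append(f"overall: {self.overall_percent():.1f}%")
        return "\n".join(lines)


def accuracy_from_counts(
    counts: dict[str, tuple[int, int]]
) -> AccuracyReport:
    """Exact accuracies from per-movement (total, incorrect) counts."""
    if not counts:
        raise ValueError("counts must be nonempty")
    per_movement = {}
    total = incorrect = 0
    for movement, (t, i) in counts.items():
        if not 0 <= i <= t:
            raise ValueError(
                f"{movement}: need 0 <= incorrect <= total, got ({t}, {i})"
            )
        if t == 0:
            raise ValueError(f"{movement}: total must be positive")
        per_movement[movement] = Fraction(t - i, t)
        total += t
        incorrect += i
    return AccuracyReport(
        counts=dict(counts),
        per_movement=per_movement,
        overall=Fraction(total - incorrect, total),
    )


def compare_accuracy(
    raw_trace: list[str], voted_trace: list[str], truth: list[str]
) -> tuple[float, float, float]:
    """Per-frame accuracy of the raw and voted streams against the
    truth, plus the improvement (voted minus raw)."""
    if not (len(raw_trace) == len(voted_trace) == len(truth)):
        raise ValueError(
            "raw, voted, and truth traces must have equal lengths"
        )
    if not truth:
        raise ValueError("traces must be nonempty")
    n = len(truth)
    raw_acc = sum(r == t for r, t in zip(raw_trace, truth)) / n
    voted_acc = sum(v == t for v, t in zip(voted_trace, truth)) / n
    return raw_acc, voted_acc, voted_acc - raw_acc
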