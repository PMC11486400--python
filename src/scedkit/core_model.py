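"""Domain model for concurrent multiple-baseline single-case designs.

A study consists of a small number of participants who all start a baseline
phase in the same week; the intervention is introduced staggered, one extra
baseline week per successive participant, and a short follow-up phase closes
the series.  Every measurement stream is a :class:`MeasurementSeries` keyed by
(participant, measure, side), and the measures themselves are described by a
:class:`MeasureSpec` registry entry that records the units and, crucially, the
therapeutic direction — whether an increase or a decrease counts as
improvement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


class PhaseLabel(enum.Enum):
    """Study phase, ordered in time: baseline < intervention < follow_up."""

    BASELINE = "baseline"
    INTERVENTION = "intervention"
    FOLLOW_UP = "follow_up"

    @property
    def order(self) -> int:
        return _PHASE_ORDER[self]

    @classmethod
    def parse(cls, text: str) -> "PhaseLabel":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown phase label {text!r}; expected one of "
                f"{[p.value for p in cls]}"
            ) from None


_PHASE_ORDER = {
    PhaseLabel.BASELINE: 0,
    PhaseLabel.INTERVENTION: 1,
    PhaseLabel.FOLLOW_UP: 2,
}


class Side(enum.Enum):
    """Body side of a bilateral measure; NONE for unilateral/global measures."""

    LEFT = "left"
    RIGHT = "right"
    NONE = "none"

    @classmethod
    def parse(cls, text: str) -> "Side":
        text = (text or "none").strip().lower()
        try:
            return cls(text)
        except ValueError:
            raise ValueError(f"unknown side {text!r}") from None


class Direction(enum.Enum):
    """Therapeutic direction: which sign of change is an improvement."""

    INCREASE = "increase"
    DECREASE = "decrease"

    def flipped(self) -> "Direction":
        return Direction.DECREASE if self is Direction.INCREASE else Direction.INCREASE


class MeasureFamily(enum.Enum):
    NEUROPHYSIOLOGICAL = "neurophysiological"
    CLINICAL = "clinical"


@dataclass(frozen=True)
class MeasureSpec:
    """Registry entry for one outcome measure.

    Parameters
    ----------
    name : str
        Unique identifier (e.g. ``"rmt"``, ``"cmct"``).
    units : str
        Measurement units (ms, mV, %MSO, score, s, kg).
    direction : Direction
        Whether an increase or a decrease is a clinical improvement.
    family : MeasureFamily
        Neurophysiological (TMS-derived) or clinical.
    bilateral : bool
        True when the measure is assessed separately per upper limb.
    """

    name: str
    units: str
    direction: Direction
    family: MeasureFamily
    bilateral: bool = False


def default_registry() -> dict[str, MeasureSpec]:
    """The shipped measure registry.

    Lower CMCT, MEP latency, resting motor threshold, timed gait and fatigue
    scores are improvements; higher MEP amplitude, balance, arm function,
    strength and processing-speed scores are improvements.
    """
    neuro = MeasureFamily.NEUROPHYSIOLOGICAL
    clin = MeasureFamily.CLINICAL
    inc, dec = Direction.INCREASE, Direction.DECREASE
    specs = [
        MeasureSpec("cmct", "ms", dec, neuro, bilateral=True),
        MeasureSpec("mep_amplitude", "mV", inc, neuro, bilateral=True),
        MeasureSpec("mep_latency", "ms", dec, neuro, bilateral=True),
        MeasureSpec("rmt", "%MSO", dec, neuro, bilateral=True),
        MeasureSpec("minibest", "score", inc, clin, bilateral=False),
        MeasureSpec("ssst", "s", dec, clin, bilateral=False),
        MeasureSpec("arat", "score", inc, clin, bilateral=True),
        MeasureSpec("strength", "kg", inc, clin, bilateral=True),
        MeasureSpec("sdmt", "score", inc, clin, bilateral=False),
        MeasureSpec("mfis", "score", dec, clin, bilateral=False),
    ]
    return {s.name: s for s in specs}


@dataclass(frozen=True)
class ParticipantPlan:
    """Per-participant schedule in the staggered design.

    Week indices are 1-based.  All participants start baseline at week 1; the
    baseline lasts ``baseline_weeks`` weeks, the intervention the following
    ``intervention_weeks`` weeks, and follow-up assessments happen after that.
    """

    participant_id: str
    age: float
    baseline_weeks: int
    intervention_weeks: int = 12
    n_intervention_points: int = 5
    n_followup_points: int = 3

    @property
    def intervention_start_week(self) -> int:
        return self.baseline_weeks + 1

    @property
    def intervention_end_week(self) -> int:
        return self.baseline_weeks + self.intervention_weeks


@dataclass(frozen=True)
class SeriesKey:
    participant_id: str
    measure: str
    side: Side

    def __str__(self) -> str:  # stable, used for seed derivation and sorting
        return f"{self.participant_id}/{self.measure}/{self.side.value}"


@dataclass(frozen=True)
class MeasurementPoint:
    week: int
    phase: PhaseLabel
    value: Optional[float]  # None encodes a scheduled but missed assessment

    @property
    def missing(self) -> bool:
        return self.value is None or (
            isinstance(self.value, float) and math.isnan(self.value)
        )


@dataclass
class MeasurementSeries:
    """One participant x measure x side ordered sequence of measurements.

    Missing points are kept explicitly (``value=None``) so that downstream
    statistics operate on available points only and missingness is visible in
    plots and reports rather than silently dropped.
    """

    key: SeriesKey
    points: list[MeasurementPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        weeks = [p.week for p in self.points]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(f"series {self.key}: week indices must strictly increase")
        orders = [p.phase.order for p in self.points]
        if any(b < a for a, b in zip(orders, orders[1:])):
            raise ValueError(
                f"series {self.key}: phases must be non-interleaved and in "
                "baseline < intervention < follow_up order"
            )

    def phase_points(self, phase: PhaseLabel) -> list[MeasurementPoint]:
        if not isinstance(phase, PhaseLabel):
            raise ValueError(f"unknown phase label {phase!r}")
        return [p for p in self.points if p.phase is phase]

    def n_available(self, phase: PhaseLabel) -> int:
        return sum(1 for p in self.phase_points(phase) if not p.missing)

    @property
    def analyzable(self) -> bool:
        """At least 3 non-missing points in baseline and in intervention."""
        return (
            self.n_available(PhaseLabel.BASELINE) >= 3
            and self.n_available(PhaseLabel.INTERVENTION) >= 3
        )


def phase_values(series: MeasurementSeries, phase: PhaseLabel) -> list[float]:
    """Non-missing values of one phase, in time order (may be empty)."""
    return [p.value for p in series.phase_points(phase) if not p.missing]


def phase_mean(series: MeasurementSeries, phase: PhaseLabel) -> float:
    """Arithmetic mean of a phase's available values: the phase *level*."""
    vals = phase_values(series, phase)
    if not vals:
        raise ValueError(
            f"series {series.key}: phase {phase.value!r} has no available "
            "points and cannot be analyzed"
        )
    return float(sum(vals)) / len(vals)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_design(plans: Sequence[ParticipantPlan]) -> ValidationReport:
    """Check a set of participant plans against the multiple-baseline rules.

    Violations reported: fewer than three participants, non-staggered
    baseline durations (successive baselines must increase by one week),
    and phases contributing fewer than three data points.  The concurrent
    start (all baselines begin at week 1) is inherent in the plan model.
    """
    if not plans:
        raise ValueError("at least one participant plan is required")
    report = ValidationReport()
    if len(plans) < 3:
        report.violations.append(
            f"fewer than three participants ({len(plans)}); three is the "
            "minimum for a multiple-baseline design"
        )
    ordered = sorted(plans, key=lambda p: p.baseline_weeks)
    for a, b in zip(ordered, ordered[1:]):
        if b.baseline_weeks != a.baseline_weeks + 1:
            report.violations.append(
                "baselines not staggered by one week: "
                f"{a.participant_id}={a.baseline_weeks}w, "
                f"{b.participant_id}={b.baseline_weeks}w"
            )
    for p in plans:
        if p.baseline_weeks < 3:
            report.violations.append(
                f"{p.participant_id}: baseline has {p.baseline_weeks} points "
                "(< 3 per phase)"
            )
        if p.n_intervention_points < 3:
            report.violations.append(
                f"{p.participant_id}: intervention has "
                f"{p.n_intervention_points} points (< 3 per phase)"
            )
        if p.n_followup_points < 3:
            report.violations.append(
                f"{p.participant_id}: follow-up has {p.n_followup_points} "
                "points (< 3 per phase)"
            )
    return report


# --- exercise-protocol adherence utilities -------------------------------

def session_completion_pct(completed: Iterable[int], scheduled: int = 36) -> float:
    """Group mean session-completion percentage across participants."""
    completed = list(completed)
    if not completed or scheduled <= 0:
        raise ValueError("need at least one participant and scheduled > 0")
    return 100.0 * sum(c / scheduled for c in completed) / len(completed)


def adherence_minimum(scheduled: int = 36, fraction: float = 0.75) -> int:
    """Minimum number of sessions a participant must complete (ceil)."""
    if scheduled <= 0 or not 0 < fraction <= 1:
        raise ValueError("scheduled must be positive and fraction in (0, 1]")
    return math.ceil(fraction * scheduled)


__all__ = [
    "PhaseLabel",
    "Side",
    "Direction",
    "MeasureFamily",
    "MeasureSpec",
    "default_registry",
    "ParticipantPlan",
    "SeriesKey",
    "MeasurementPoint",
    "MeasurementSeries",
    "ValidationReport",
    "phase_values",
    "phase_mean",
    "validate_design",
    "session_completion_pct",
    "adherence_minimum",
]
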