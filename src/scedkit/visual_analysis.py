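"""Six-feature visual analysis and the gate to statistical testing.

Within each phase the analysis summarises level (the phase mean), trend (an
OLS-slope classifier with a stability band), stability (share of points
within +/-15% of the phase median) and variability (share of points outside a
two-standard-deviation band).  Between baseline and intervention it
summarises the level change, overlap of intervention points with the
baseline range, immediacy (last three baseline vs first three intervention
points) and the percentage of intervention data exceeding the baseline
median in the therapeutic direction (PEM).  Consistency compares the level
direction across participants.  A series proceeds to effect estimation only
when the enabled criteria all hold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    Direction,
    MeasureSpec,
    MeasurementSeries,
    PhaseLabel,
    phase_values,
)


class Trend(enum.Enum):
    UPWARD = "upward"
    DOWNWARD = "downward"
    STABLE = "stable"


class PEMCategory(enum.Enum):
    NONE = "none"
    MODERATE = "moderate"
    HIGH = "high"


class VariabilityReference(enum.Enum):
    """Which data define the two-standard-deviation band."""

    OWN_PHASE = "own_phase"
    WHOLE_SERIES = "whole_series"
    BASELINE = "baseline"


@dataclass
class GateConfig:
    """Thresholds and switches for the visual-analysis gate.

    Defaults follow the study conventions: stability criterion met at >= 80%
    of points within +/- ``stability_band_fraction`` of the phase median
    (inclusive, because 80% is repeatedly counted as meeting the criterion);
    low variability at <= 20% of points outside the 2-SD band; zero tolerated
    overlap; PEM effect from 70%; consistency from 80% of participants
    agreeing.  ``median_abs_epsilon`` replaces a zero-width relative band
    when a phase median is 0.
    """

    stability_band_fraction: float = 0.15
    stability_threshold_pct: float = 80.0
    stability_strict: bool = False  # True: require strictly > threshold
    variability_threshold_pct: float = 20.0
    variability_reference: VariabilityReference = VariabilityReference.OWN_PHASE
    overlap_threshold_pct: float = 0.0
    pem_threshold_pct: float = 70.0
    immediacy_min_magnitude: float = 0.0
    consistency_threshold: float = 0.8
    trend_band_fraction: float = 0.15
    trend_strict_monotone: bool = False
    median_abs_epsilon: float = 0.5
    enabled_criteria: tuple[str, ...] = (
        "level",
        "trend",
        "stability",
        "variability",
        "overlap",
        "immediacy",
        "pem",
        "consistency",
    )


@dataclass
class WithinPhaseSummary:
    phase: PhaseLabel
    level: float
    trend: Trend
    stability_pct: float
    variability_pct: Optional[float]
    n_points: int


@dataclass
class BetweenPhaseSummary:
    level_change: float  # intervention level - baseline level
    level_improved: bool
    overlap_pct: float
    immediacy: bool
    immediacy_magnitude: float
    pem_pct: float
    pem_category: PEMCategory


@dataclass
class GateDecision:
    criteria: dict[str, bool]
    overall: bool
    notes: list[str] = field(default_factory=list)


def _band_halfwidth(median: float, fraction: float, abs_epsilon: float) -> float:
    """Half-width of a relative band around a median, with an absolute
    fallback when the median is zero (a zero-width band is meaningless for
    scores near zero)."""
    if median == 0:
        return abs_epsilon
    return fraction * abs(median)


def classify_trend(
    values: Sequence[float],
    stable_band_fraction: float = 0.15,
    median_abs_epsilon: float = 0.5,
    strict_monotone: bool = False,
) -> Trend:
    """Classify a phase's trend as upward, downward or stable.

    Default mode fits an OLS slope against the point index and projects the
    total change over the phase, slope * (n - 1); a projected change within
    ``stable_band_fraction`` of |phase median| is stable, otherwise the slope
    sign decides.  ``strict_monotone`` instead requires a strictly monotone
    sequence for a non-stable call.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("trend classification needs at least 3 points")
    if strict_monotone:
        diffs = np.diff(vals)
        if np.all(diffs > 0):
            return Trend.UPWARD
        if np.all(diffs < 0):
            return Trend.DOWNWARD
        return Trend.STABLE
    x = np.arange(vals.size, dtype=float)
    slope = np.polyfit(x, vals, 1)[0]
    projected = slope * (vals.size - 1)
    band = _band_halfwidth(float(np.median(vals)), stable_band_fraction,
                           median_abs_epsilon)
    if abs(projected) <= band:
        return Trend.STABLE
    return Trend.UPWARD if slope > 0 else Trend.DOWNWARD


def stability_pct(
    values: Sequence[float],
    band_fraction: float = 0.15,
    median_abs_epsilon: float = 0.5,
) -> float:
    """Percentage of points within +/- band_fraction of the phase median."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("stability needs at least 1 point")
    med = float(np.median(vals))
    half = _band_halfwidth(med, band_fraction, median_abs_epsilon)
    inside = np.sum((vals >= med - half) & (vals <= med + half))
    return 100.0 * float(inside) / vals.size


def variability_pct(
    values: Sequence[float],
    reference_values: Optional[Sequence[float]] = None,
) -> float:
    """Percentage of points outside the two-standard-deviation band.

    The band is the reference mean +/- 2 * reference SD (sample SD, ddof=1).
    By default the reference is the phase itself; pass baseline or
    whole-series values to referee against another band.
    """
    vals = np.asarray(values, dtype=float)
    ref = vals if reference_values is None else np.asarray(reference_values, float)
    if vals.size == 0:
        raise ValueError("variability needs at least 1 point")
    if ref.size < 2:
        raise ValueError("reference SD undefined with fewer than 2 points")
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0 and not np.all(vals == mean):
        # a zero-spread reference gives a zero-width band; judging other
        # values against it is meaningless
        raise ValueError("reference band degenerate: zero reference SD")
    outside = np.sum((vals < mean - 2 * sd) | (vals > mean + 2 * sd))
    return 100.0 * float(outside) / vals.size


def overlap_pct(baseline: Sequence[float], intervention: Sequence[float]) -> float:
    """Percentage of intervention points within the baseline range."""
    base = np.asarray(baseline, dtype=float)
    inter = np.asarray(intervention, dtype=float)
    if base.size == 0 or inter.size == 0:
        raise ValueError("both phases must be non-empty")
    inside = np.sum((inter >= base.min()) & (inter <= base.max()))
    return 100.0 * float(inside) / inter.size


def _improved(change: float, direction: Direction) -> bool:
    if direction is Direction.INCREASE:
        return change > 0
    return change < 0


@dataclass(frozen=True)
class ImmediacyResult:
    immediate: bool
    magnitude: float  # mean(first 3 intervention) - mean(last 3 baseline)
    flagged: bool = False  # fewer than 3 points available on a side


def immediacy(
    baseline: Sequence[float],
    intervention: Sequence[float],
    direction: Direction,
    min_magnitude: float = 0.0,
) -> ImmediacyResult:
    """Immediacy of effect: last three baseline vs first three intervention
    points.  True when the level change is in the therapeutic direction and
    exceeds ``min_magnitude`` in absolute value (default: any
    direction-consistent change)."""
    base = list(baseline)
    inter = list(intervention)
    if not base or not inter:
        raise ValueError("both phases must be non-empty")
    flagged = len(base) < 3 or len(inter) < 3
    magnitude = float(np.mean(inter[:3]) - np.mean(base[-3:]))
    ok = _improved(magnitude, direction) and abs(magnitude) > min_magnitude
    return ImmediacyResult(immediate=ok, magnitude=magnitude, flagged=flagged)


def pem(
    baseline: Sequence[float],
    intervention: Sequence[float],
    direction: Direction,
) -> tuple[float, PEMCategory]:
    """Percentage of intervention data exceeding the baseline median.

    Counts intervention points strictly better than the baseline median in
    the therapeutic direction (ties do not exceed).  Categories: < 70 none,
    70-90 moderate, > 90 high.
    """
    base = np.asarray(baseline, dtype=float)
    inter = np.asarray(intervention, dtype=float)
    if base.size == 0 or inter.size == 0:
        raise ValueError("both phases must be non-empty")
    med = float(np.median(base))
    if direction is Direction.INCREASE:
        exceeding = np.sum(inter > med)
    else:
        exceeding = np.sum(inter < med)
    pct = 100.0 * float(exceeding) / inter.size
    if pct < 70.0:
        category = PEMCategory.NONE
    elif pct <= 90.0:
        category = PEMCategory.MODERATE
    else:
        category = PEMCategory.HIGH
    return pct, category


def consistency(
    improved_flags: Sequence[bool], threshold: float = 0.8
) -> tuple[float, bool]:
    """Cross-participant consistency of the level-change direction.

    Returns the share of participants agreeing with the modal direction and
    whether that share reaches ``threshold``.  With fewer than two
    participants the criterion is not evaluable.
    """
    flags = list(improved_flags)
    if len(flags) < 2:
        raise ValueError("consistency needs at least 2 participants")
    n_true = sum(flags)
    modal_count = max(n_true, len(flags) - n_true)
    fraction = modal_count / len(flags)
    return fraction, fraction >= threshold


@dataclass
class SeriesAnalysis:
    within: dict[PhaseLabel, WithinPhaseSummary]
    between: BetweenPhaseSummary
    gate: GateDecision


def summarize_within_phase(
    series: MeasurementSeries,
    phase: PhaseLabel,
    config: GateConfig,
) -> Optional[WithinPhaseSummary]:
    vals = phase_values(series, phase)
    if len(vals) < 3:
        return None
    if config.variability_reference is VariabilityReference.OWN_PHASE:
        ref = None
    elif config.variability_reference is VariabilityReference.BASELINE:
        ref = phase_values(series, PhaseLabel.BASELINE)
    else:
        ref = [p.value for p in series.points if not p.missing]
    try:
        var_pct = variability_pct(vals, ref)
    except ValueError:
        var_pct = None
    return WithinPhaseSummary(
        phase=phase,
        level=float(np.mean(vals)),
        trend=classify_trend(
            vals,
            config.trend_band_fraction,
            config.median_abs_epsilon,
            config.trend_strict_monotone,
        ),
        stability_pct=stability_pct(
            vals, config.stability_band_fraction, config.median_abs_epsilon
        ),
        variability_pct=var_pct,
        n_points=len(vals),
    )


def summarize_between_phases(
    series: MeasurementSeries,
    spec: MeasureSpec,
    config: GateConfig,
) -> BetweenPhaseSummary:
    base = phase_values(series, PhaseLabel.BASELINE)
    inter = phase_values(series, PhaseLabel.INTERVENTION)
    level_change = float(np.mean(inter) - np.mean(base))
    pem_pct, pem_cat = pem(base, inter, spec.direction)
    imm = immediacy(base, inter, spec.direction, config.immediacy_min_magnitude)
    return BetweenPhaseSummary(
        level_change=level_change,
        level_improved=_improved(level_change, spec.direction),
        overlap_pct=overlap_pct(base, inter),
        immediacy=imm.immediate,
        immediacy_magnitude=imm.magnitude,
        pem_pct=pem_pct,
        pem_category=pem_cat,
    )


def evaluate_gate(
    series: MeasurementSeries,
    spec: MeasureSpec,
    config: Optional[GateConfig] = None,
    consistency_ok: Optional[bool] = None,
) -> SeriesAnalysis:
    """Full within/between-phase summary plus the gate decision.

    ``consistency_ok`` carries the cross-participant consistency verdict; when
    None the criterion passes vacuously with a note (it cannot be judged from
    a single series).
    """
    config = config or GateConfig()
    if not series.analyzable:
        raise ValueError(
            f"series {series.key} is not analyzable: needs >= 3 available "
            "points in baseline and intervention"
        )
    within = {}
    for phase in PhaseLabel:
        summary = summarize_within_phase(series, phase, config)
        if summary is not None:
            within[phase] = summary
    between = summarize_between_phases(series, spec, config)

    improving = Trend.UPWARD if spec.direction is Direction.INCREASE else Trend.DOWNWARD
    base_sum = within[PhaseLabel.BASELINE]
    int_sum = within[PhaseLabel.INTERVENTION]

    def stab_ok(pct: float) -> bool:
        if config.stability_strict:
            return pct > config.stability_threshold_pct
        return pct >= config.stability_threshold_pct

    def var_ok(pct: Optional[float]) -> bool:
        return pct is not None and pct <= config.variability_threshold_pct

    notes: list[str] = []
    criteria = {
        "level": between.level_improved,
        "trend": base_sum.trend is Trend.STABLE
        and (
            int_sum.trend is improving
            or (int_sum.trend is Trend.STABLE and between.level_improved)
        ),
        "stability": stab_ok(base_sum.stability_pct) and stab_ok(int_sum.stability_pct),
        "variability": var_ok(base_sum.variability_pct)
        and var_ok(int_sum.variability_pct),
        "overlap": between.overlap_pct <= config.overlap_threshold_pct,
        "immediacy": between.immediacy,
        "pem": between.pem_pct >= config.pem_threshold_pct,
    }
    if consistency_ok is None:
        criteria["consistency"] = True
        notes.append("consistency not evaluable for a single series; passed vacuously")
    else:
        criteria["consistency"] = consistency_ok
    enabled = {k: v for k, v in criteria.items() if k in config.enabled_criteria}
    overall = all(enabled.values())
    failed = sorted(k for k, v in enabled.items() if not v)
    if failed:
        notes.append("failed criteria: " + ", ".join(failed))
    gate = GateDecision(criteria=criteria, overall=overall, notes=notes)
    return SeriesAnalysis(within=within, between=between, gate=gate)


__all__ = [
    "Trend",
    "PEMCategory",
    "VariabilityReference",
    "GateConfig",
    "WithinPhaseSummary",
    "BetweenPhaseSummary",
    "GateDecision",
    "ImmediacyResult",
    "SeriesAnalysis",
    "classify_trend",
    "stability_pct",
    "variability_pct",
    "overlap_pct",
    "immediacy",
    "pem",
    "consistency",
    "summarize_within_phase",
    "summarize_between_phases",
    "evaluate_gate",
]
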