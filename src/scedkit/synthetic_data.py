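"""Synthetic multiple-baseline datasets and synthetic MEP traces.

The generator reproduces the structure the analysis assumes: five
participants who start baseline together in week 1, baselines staggered 3-7
weeks (one extra week per participant), a 12-week intervention with five
weekly assessment points starting in the third intervention week, and three
follow-up assessments at post-intervention weeks 4, 8 and 12.  Values are a
per-phase level plus iid Gaussian noise (optionally AR(1)); follow-up levels
drift back toward baseline.  Missing assessments can be injected to emulate
a participant missing individual sessions.

Shipped scenarios anchor their levels to the study's printed group means:

``rmt_effect``
    Resting motor threshold stepping 64 -> 50 %MSO (left) and 62 -> 52
    (right) with follow-up back near baseline and low noise: every series
    should pass the visual-analysis gate with complete nonoverlap.
``cmct_null_highvar``
    CMCT with no level change and noise at 15% of the level: series should
    be gated out (high variability, heavy overlap, no consistent level
    change).
``clinical_clean``
    A noiseless clinical score with a clear step: the textbook pattern of
    100% stability, zero variability, zero overlap and PEM = 100%.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    MeasureSpec,
    MeasurementPoint,
    MeasurementSeries,
    ParticipantPlan,
    PhaseLabel,
    SeriesKey,
    Side,
    default_registry,
)
from .neurophys import DEFAULT_SAMPLING_RATE, MEPTrace

DEFAULT_PARTICIPANT_IDS = ("A", "B", "C", "D", "E")
#: Table-1 style ages used when a scenario does not supply its own.
DEFAULT_AGES = (56.0, 56.0, 47.0, 52.0, 59.0)
#: Follow-up assessments at post-intervention weeks 4, 8 and 12.
FOLLOWUP_OFFSETS = (4, 8, 12)
#: Weekly intervention assessments start in the third intervention week.
INTERVENTION_ASSESSMENT_START = 3


@dataclass
class SideLevels:
    baseline: float
    intervention: float
    followup: float


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic dataset.

    ``levels`` maps a body side to its per-phase levels; ``noise_sd`` is the
    iid Gaussian noise SD in measure units (``ar1_rho`` > 0 adds serial
    dependence); ``missing_pattern`` lists (participant_id, phase, point
    index) assessments to blank out, index counted within the phase.
    """

    name: str
    measure: MeasureSpec
    levels: dict[Side, SideLevels]
    noise_sd: float = 0.0
    ar1_rho: float = 0.0
    effect_delay_points: int = 0  # 0 = immediate step at intervention onset
    missing_pattern: list[tuple[str, PhaseLabel, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for side_levels in self.levels.values():
            for attr in ("baseline", "intervention", "followup"):
                value = getattr(side_levels, attr)
                if self.measure.units == "%MSO" and not 0 < value <= 100:
                    raise ValueError(f"%MSO level {value} outside (0, 100]")
                if self.measure.units == "ms" and value <= 0:
                    raise ValueError(f"latency level {value} must be > 0 ms")


def generate_design(
    n_participants: int = 5,
    first_baseline_weeks: int = 3,
    ages: Optional[Sequence[float]] = None,
) -> list[ParticipantPlan]:
    """Staggered concurrent multiple-baseline schedule.

    Baselines of 3, 4, ... weeks (one extra per participant), all starting in
    week 1; a 12-week intervention with 5 assessment points; 3 follow-up
    points.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if ages is None:
        ages = [DEFAULT_AGES[i % len(DEFAULT_AGES)] for i in range(n_participants)]
    ids = [
        DEFAULT_PARTICIPANT_IDS[i]
        if i < len(DEFAULT_PARTICIPANT_IDS)
        else f"P{i + 1}"
        for i in range(n_participants)
    ]
    return [
        ParticipantPlan(
            participant_id=ids[i],
            age=float(ages[i]),
            baseline_weeks=first_baseline_weeks + i,
        )
        for i in range(n_participants)
    ]


def assessment_schedule(plan: ParticipantPlan) -> list[tuple[int, PhaseLabel]]:
    """(week, phase) grid of scheduled assessments for one participant."""
    weeks: list[tuple[int, PhaseLabel]] = [
        (w, PhaseLabel.BASELINE) for w in range(1, plan.baseline_weeks + 1)
    ]
    first = plan.baseline_weeks + INTERVENTION_ASSESSMENT_START
    weeks += [
        (first + i, PhaseLabel.INTERVENTION)
        for i in range(plan.n_intervention_points)
    ]
    end = plan.intervention_end_week
    weeks += [
        (end + off, PhaseLabel.FOLLOW_UP)
        for off in FOLLOWUP_OFFSETS[: plan.n_followup_points]
    ]
    return weeks


def _series_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=n)
    if rho == 0.0 or sd == 0.0:
        return eps
    out = np.empty(n)
    out[0] = eps[0]
    scale = np.sqrt(1.0 - rho**2)  # keeps the marginal SD at sd
    for i in range(1, n):
        out[i] = rho * out[i - 1] + scale * eps[i]
    return out


def generate_series(
    scenario: ScenarioSpec,
    plans: Sequence[ParticipantPlan],
    seed: int = 0,
) -> list[MeasurementSeries]:
    """Generate one MeasurementSeries per participant x side for a scenario.

    Values are phase level + noise; reproducible for a given seed.  Missing
    assessments from ``missing_pattern`` are kept as explicit None points.
    """
    series_list: list[MeasurementSeries] = []
    for p_index, plan in enumerate(plans):
        for s_index, (side, levels) in enumerate(sorted(
            scenario.levels.items(), key=lambda kv: kv[0].value
        )):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, p_index, s_index])
            )
            schedule = assessment_schedule(plan)
            noise = _series_noise(
                rng, len(schedule), scenario.noise_sd, scenario.ar1_rho
            )
            points: list[MeasurementPoint] = []
            phase_counts: dict[PhaseLabel, int] = {p: 0 for p in PhaseLabel}
            for (week, phase), eps in zip(schedule, noise):
                index_in_phase = phase_counts[phase]
                phase_counts[phase] += 1
                if phase is PhaseLabel.BASELINE:
                    level = levels.baseline
                elif phase is PhaseLabel.INTERVENTION:
                    delayed = index_in_phase < scenario.effect_delay_points
                    level = levels.baseline if delayed else levels.intervention
                else:
                    level = levels.followup
                missing = (plan.participant_id, phase, index_in_phase) in set(
                    scenario.missing_pattern
                )
                points.append(
                    MeasurementPoint(
                        week=week,
                        phase=phase,
                        value=None if missing else float(level + eps),
                    )
                )
            series_list.append(
                MeasurementSeries(
                    key=SeriesKey(plan.participant_id, scenario.measure.name, side),
                    points=points,
                )
            )
    return series_list


def generate_mep_trace(
    amplitude: float,
    onset_latency_ms: float,
    noise_sd: float = 0.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    duration_ms: float = 100.0,
    pre_stimulus_ms: float = 20.0,
    seed: int = 0,
) -> MEPTrace:
    """Synthetic EMG sweep: pre-stimulus noise, then a biphasic MEP template.

    The template is one sine cycle over ~8 ms starting at
    ``onset_latency_ms`` after the stimulus, scaled so its peak-to-peak
    amplitude equals ``amplitude`` (mV); Gaussian noise is added throughout.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    n_pre = int(round(pre_stimulus_ms * 1e-3 * sampling_rate))
    n_total = n_pre + int(round(duration_ms * 1e-3 * sampling_rate))
    onset_index = n_pre + int(round(onset_latency_ms * 1e-3 * sampling_rate))
    if onset_index >= n_total:
        raise ValueError("onset beyond the end of the trace")
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, noise_sd, size=n_total)
    response_ms = 8.0  # sharp biphasic deflection, typical APB MEP duration
    n_resp = min(int(round(response_ms * 1e-3 * sampling_rate)),
                 n_total - onset_index)
    t = np.arange(n_resp) / n_resp
    samples[onset_index : onset_index + n_resp] += (amplitude / 2.0) * np.sin(
        2.0 * np.pi * t
    )
    return MEPTrace(
        samples=samples,
        sampling_rate=sampling_rate,
        stimulus_onset_index=n_pre,
    )


# --- named scenarios ------------------------------------------------------

#: Participant-E missingness pattern: one baseline and one intervention
#: assessment skipped.
PARTICIPANT_E_MISSING = [
    ("E", PhaseLabel.BASELINE, 6),
    ("E", PhaseLabel.INTERVENTION, 3),
]


def named_scenario(name: str) -> ScenarioSpec:
    """Shipped scenario fixtures with levels anchored to printed group means."""
    registry = default_registry()
    if name == "rmt_effect":
        return ScenarioSpec(
            name="rmt_effect",
            measure=registry["rmt"],
            levels={
                Side.LEFT: SideLevels(64.0, 50.0, 65.0),
                Side.RIGHT: SideLevels(62.0, 52.0, 62.0),
            },
            noise_sd=0.8,
            missing_pattern=list(PARTICIPANT_E_MISSING),
        )
    if name == "cmct_null_highvar":
        return ScenarioSpec(
            name="cmct_null_highvar",
            measure=registry["cmct"],
            levels={
                Side.LEFT: SideLevels(10.0, 10.0, 10.0),
                Side.RIGHT: SideLevels(10.0, 10.0, 10.0),
            },
            noise_sd=1.5,  # 15% of the level: high variability, no effect
        )
    if name == "clinical_clean":
        return ScenarioSpec(
            name="clinical_clean",
            measure=registry["minibest"],
            levels={Side.NONE: SideLevels(20.0, 24.0, 21.0)},
            noise_sd=0.0,
        )
    raise ValueError(
        f"unknown scenario {name!r}; available: rmt_effect, cmct_null_highvar, "
        "clinical_clean"
    )


def scenario_with(
    base: ScenarioSpec,
    **overrides,
) -> ScenarioSpec:
    """Copy a scenario with selected fields replaced."""
    out = copy.deepcopy(base)
    for key, value in overrides.items():
        if not hasattr(out, key):
            raise AttributeError(f"ScenarioSpec has no field {key!r}")
        setattr(out, key, value)
    out.__post_init__()
    return out


__all__ = [
    "DEFAULT_PARTICIPANT_IDS",
    "DEFAULT_AGES",
    "FOLLOWUP_OFFSETS",
    "INTERVENTION_ASSESSMENT_START",
    "PARTICIPANT_E_MISSING",
    "SideLevels",
    "ScenarioSpec",
    "generate_design",
    "assessment_schedule",
    "generate_series",
    "generate_mep_trace",
    "named_scenario",
    "scenario_with",
]
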