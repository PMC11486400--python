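"""TMS-derived corticospinal excitability measures.

Central motor conduction time (CMCT) is the MEP onset latency minus the
peripheral conduction time, where the peripheral conduction time is estimated
from median-nerve stimulation as (F-wave latency + M-wave latency - 1) / 2,
in milliseconds.  MEP amplitude is the peak-to-peak voltage of the motor
evoked potential; onset latency is detected automatically by a sustained
threshold crossing of the rectified EMG relative to pre-stimulus noise (the
study scored onsets by eye; an automatic detector makes the pipeline
reproducible, and its sensitivity parameters are exposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_model import Side

#: Default amplitude/onset search window after the stimulus (ms).  Chosen to
#: exclude the stimulus artifact while covering upper-limb MEP latencies.
DEFAULT_MEP_WINDOW_MS = (15.0, 60.0)

#: Default synthetic EMG sampling rate (Hz).
DEFAULT_SAMPLING_RATE = 24_000.0


@dataclass(frozen=True)
class NerveConductionSet:
    """F-wave, M-wave and MEP latencies for one limb at one time point (ms)."""

    f_wave_latency: float
    m_wave_latency: float
    mep_latency: float

    def __post_init__(self) -> None:
        for name in ("f_wave_latency", "m_wave_latency", "mep_latency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class MEPTrace:
    """A single EMG sweep around one TMS pulse.

    ``samples`` are in mV; ``stimulus_onset_index`` marks the TMS pulse, and
    everything before it is the pre-stimulus (noise) window.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    stimulus_onset_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.stimulus_onset_index < self.samples.size:
            raise ValueError("stimulus_onset_index outside the sample range")

    def ms_to_samples(self, ms: float) -> int:
        return int(round(ms * 1e-3 * self.sampling_rate))


@dataclass(frozen=True)
class MotorThresholdRecord:
    """Resting motor threshold (%MSO) for one side at one session week."""

    rmt: float
    side: Side
    week: int

    def __post_init__(self) -> None:
        if not 0 < self.rmt <= 100:
            raise ValueError("rmt must be in (0, 100] %MSO")


@dataclass(frozen=True)
class CMCTResult:
    value: float
    degenerate: bool = False  # CMCT <= 0: flagged, not discarded


def peripheral_conduction_time(f_wave_latency: float, m_wave_latency: float) -> float:
    """Peripheral conduction time (F + M - 1) / 2, ms."""
    if f_wave_latency <= 0 or m_wave_latency <= 0:
        raise ValueError("F- and M-wave latencies must be strictly positive")
    return (f_wave_latency + m_wave_latency - 1.0) / 2.0


def central_motor_conduction_time(ncs: NerveConductionSet) -> CMCTResult:
    """CMCT = MEP latency - peripheral conduction time (ms).

    A non-positive result is physiologically degenerate; it is returned with
    ``degenerate=True`` so the visual-analysis stage can mark it.
    """
    pct = peripheral_conduction_time(ncs.f_wave_latency, ncs.m_wave_latency)
    cmct = ncs.mep_latency - pct
    return CMCTResult(value=cmct, degenerate=cmct <= 0)


def peak_to_peak_amplitude(
    trace: MEPTrace, window: tuple[float, float] = DEFAULT_MEP_WINDOW_MS
) -> float:
    """Peak-to-peak amplitude (mV) within a post-stimulus window.

    The window is given in ms after the stimulus; the amplitude is the
    maximal positive minus the maximal negative deflection, hence >= 0.
    """
    start_ms, end_ms = window
    i0 = trace.stimulus_onset_index + trace.ms_to_samples(start_ms)
    i1 = trace.stimulus_onset_index + trace.ms_to_samples(end_ms)
    i0 = max(i0, 0)
    i1 = min(i1, trace.samples.size)
    if i1 <= i0:
        raise ValueError("empty amplitude window")
    seg = trace.samples[i0:i1]
    return float(seg.max() - seg.min())


def detect_mep_onset(
    trace: MEPTrace,
    k_sd: float = 3.0,
    min_duration_ms: float = 0.5,
    window: tuple[float, float] = DEFAULT_MEP_WINDOW_MS,
) -> Optional[float]:
    """Automatic MEP onset latency (ms after stimulus), or None if absent.

    The onset is the first post-stimulus sample within ``window`` at which the
    rectified signal exceeds (pre-stimulus mean + k_sd * pre-stimulus SD)
    continuously for at least ``min_duration_ms``.  Requires >= 10
    pre-stimulus samples to estimate the noise floor.
    """
    pre = np.abs(trace.samples[: trace.stimulus_onset_index])
    if pre.size < 10:
        raise ValueError("pre-stimulus window too short (< 10 samples)")
    threshold = pre.mean() + k_sd * pre.std(ddof=0)
    i0 = trace.stimulus_onset_index + trace.ms_to_samples(window[0])
    i1 = min(trace.stimulus_onset_index + trace.ms_to_samples(window[1]),
             trace.samples.size)
    if i1 <= i0:
        raise ValueError("empty onset search window")
    above = np.abs(trace.samples[i0:i1]) > threshold
    run_needed = max(1, trace.ms_to_samples(min_duration_ms))
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= run_needed:
            onset_index = i0 + i - run_needed + 1
            return (onset_index - trace.stimulus_onset_index) / trace.sampling_rate * 1e3
    return None


@dataclass(frozen=True)
class BoutSummary:
    mean_amplitude: float
    mean_latency: Optional[float]  # None when no trace had a detectable onset
    n_used: int
    n_onset_detected: int


def summarize_mep_bout(
    traces: Sequence[MEPTrace],
    window: tuple[float, float] = DEFAULT_MEP_WINDOW_MS,
    k_sd: float = 3.0,
    min_duration_ms: float = 0.5,
) -> BoutSummary:
    """Single amplitude/latency values from a bout of suprathreshold stimuli.

    Amplitude and latency are computed per trace and then averaged.  Traces
    without a detectable onset are excluded from the latency mean but still
    counted in ``n_used``.
    """
    if not traces:
        raise ValueError("need at least one trace")
    amplitudes = [peak_to_peak_amplitude(t, window) for t in traces]
    latencies = [
        lat
        for t in traces
        if (lat := detect_mep_onset(t, k_sd, min_duration_ms, window)) is not None
    ]
    mean_lat = float(np.mean(latencies)) if latencies else None
    return BoutSummary(
        mean_amplitude=float(np.mean(amplitudes)),
        mean_latency=mean_lat,
        n_used=len(traces),
        n_onset_detected=len(latencies),
    )


@dataclass(frozen=True)
class StimulusIntensity:
    intensity: int  # %MSO
    capped: bool


def suprathreshold_intensity(rmt: float, factor: float = 1.2) -> StimulusIntensity:
    """Suprathreshold stimulation intensity: 120% of RMT, capped at 100 %MSO."""
    if not 0 < rmt <= 100:
        raise ValueError("rmt must be in (0, 100] %MSO")
    raw = factor * rmt
    intensity = int(round(raw))
    if intensity > 100:
        return StimulusIntensity(100, capped=True)
    return StimulusIntensity(intensity, capped=False)


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate, 220 - age (bpm)."""
    if not 0 < age < 120:
        raise ValueError("age must be in (0, 120) years")
    return 220.0 - age


__all__ = [
    "DEFAULT_MEP_WINDOW_MS",
    "DEFAULT_SAMPLING_RATE",
    "NerveConductionSet",
    "MEPTrace",
    "MotorThresholdRecord",
    "CMCTResult",
    "BoutSummary",
    "StimulusIntensity",
    "peripheral_conduction_time",
    "central_motor_conduction_time",
    "peak_to_peak_amplitude",
    "detect_mep_onset",
    "summarize_mep_bout",
    "suprathreshold_intensity",
    "hr_max",
]
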