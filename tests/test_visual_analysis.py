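import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scedkit import (
    Direction,
    GateConfig,
    PEMCategory,
    PhaseLabel,
    Trend,
    classify_trend,
    consistency,
    default_registry,
    evaluate_gate,
    immediacy,
    nap,
    overlap_pct,
    pem,
    stability_pct,
    variability_pct,
)
from scedkit.core_model import MeasurementPoint, MeasurementSeries, SeriesKey, Side

values_strategy = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=1, max_size=8
)


def build_series(baseline, intervention):
    points = []
    week = 1
    for phase, vals in (
        (PhaseLabel.BASELINE, baseline),
        (PhaseLabel.INTERVENTION, intervention),
    ):
        for v in vals:
            points.append(MeasurementPoint(week, phase, float(v)))
            week += 1
    return MeasurementSeries(SeriesKey("A", "rmt", Side.LEFT), points)


class TestTrend:
    def test_constant_series_is_stable(self):
        assert classify_trend([64, 64, 64, 64]) is Trend.STABLE

    def test_strictly_monotone_decrease_is_downward(self):
        assert classify_trend([14, 13, 12, 11, 10]) is Trend.DOWNWARD

    def test_small_wiggle_within_band_is_stable(self):
        assert classify_trend([10, 10.1, 9.9, 10.0, 10.05]) is Trend.STABLE

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            classify_trend([1, 2])

    def test_strict_monotone_mode(self):
        assert classify_trend([1, 2, 3], strict_monotone=True) is Trend.UPWARD
        assert classify_trend([1, 3, 2], strict_monotone=True) is Trend.STABLE


class TestStability:
    def test_constant_series_fully_stable(self):
        assert stability_pct([100, 100, 100, 100, 100]) == 100.0

    def test_outlier_outside_band_counted(self):
        # median 10, band [8.5, 11.5], 4 of 5 inside
        assert stability_pct([10, 10, 10, 10, 20]) == pytest.approx(80.0)

    @given(values_strategy, st.floats(0.1, 10.0))
    def test_scale_invariance_for_positive_gain(self, values, c):
        before = stability_pct(values)
        after = stability_pct([c * v for v in values])
        assert before == pytest.approx(after)

    @given(values_strategy)
    def test_percentage_is_multiple_of_grid(self, values):
        pct = stability_pct(values)
        assert 0.0 <= pct <= 100.0
        grid = 100.0 / len(values)
        assert pct / grid == pytest.approx(round(pct / grid), abs=1e-9)


class TestVariability:
    def test_constant_series_has_zero_variability(self):
        assert variability_pct([5, 5, 5, 5]) == 0.0

    def test_degenerate_zero_spread_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate|undefined"):
            variability_pct([0, 0, 0, 0, 10], reference_values=[0, 0, 0, 0])

    def test_single_reference_point_rejected(self):
        with pytest.raises(ValueError):
            variability_pct([1, 2, 3], reference_values=[1])

    def test_whole_series_reference_brute_force(self):
        series = [10, 10, 10, 10, 10, 30]
        mean, sd = np.mean(series), np.std(series, ddof=1)
        expected = 100.0 * sum(
            1 for v in [10, 10, 30] if abs(v - mean) > 2 * sd
        ) / 3
        got = variability_pct([10, 10, 30], reference_values=series)
        assert got == pytest.approx(expected)


class TestOverlap:
    @pytest.mark.parametrize(
        "baseline,intervention,expected",
        [
            ((60, 62, 64), (50, 51, 50, 52, 49), 0.0),
            ((60, 62, 64), (61, 63, 50, 49, 48), 40.0),
            ((60, 62, 64), (60, 62, 64), 100.0),
        ],
    )
    def test_share_of_intervention_points_in_baseline_range(
        self, baseline, intervention, expected
    ):
        assert overlap_pct(baseline, intervention) == pytest.approx(expected)

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError):
            overlap_pct([], [1, 2])


class TestImmediacy:
    def test_clear_step_in_therapeutic_direction(self):
        result = immediacy([64, 64, 64], [50, 50, 50], Direction.DECREASE)
        assert result.immediate
        assert result.magnitude == pytest.approx(-14.0)

    def test_no_change_is_not_immediate(self):
        result = immediacy([60, 60, 60], [60, 60, 60], Direction.DECREASE)
        assert not result.immediate
        assert result.magnitude == 0.0

    def test_wrong_direction_fails(self):
        result = immediacy([10, 10, 10], [8, 8, 8], Direction.INCREASE)
        assert not result.immediate

    def test_uses_last_three_and_first_three(self):
        result = immediacy(
            [99, 99, 64, 64, 64], [50, 50, 50, 99, 99], Direction.DECREASE
        )
        assert result.magnitude == pytest.approx(-14.0)


class TestPEM:
    def test_all_intervention_points_better(self):
        pct, cat = pem([64, 64, 64], [50, 50, 51, 50, 50], Direction.DECREASE)
        assert pct == 100.0 and cat is PEMCategory.HIGH

    def test_four_of_five_better_is_moderate(self):
        pct, cat = pem([64, 63, 65], [50, 65, 50, 50, 50], Direction.DECREASE)
        assert pct == 80.0 and cat is PEMCategory.MODERATE

    def test_ties_do_not_exceed_the_median(self):
        pct, _ = pem([10, 10, 10], [10, 10, 9], Direction.DECREASE)
        assert pct == pytest.approx(100.0 / 3)

    def test_below_seventy_is_no_effect(self):
        pct, cat = pem([10, 10, 10], [10, 10, 9, 11, 12], Direction.DECREASE)
        assert cat is PEMCategory.NONE


class TestConsistency:
    @pytest.mark.parametrize(
        "flags,expected_fraction,expected_ok",
        [
            ([True] * 5, 1.0, True),
            ([True, True, True, False, False], 0.6, False),
            ([True, True, True, True, False], 0.8, True),
        ],
    )
    def test_modal_agreement_fraction(self, flags, expected_fraction, expected_ok):
        fraction, ok = consistency(flags)
        assert fraction == pytest.approx(expected_fraction)
        assert ok is expected_ok

    def test_single_participant_not_evaluable(self):
        with pytest.raises(ValueError):
            consistency([True])


class TestMonotoneAndDirectionInvariance:
    @given(
        st.lists(st.integers(-50, 50), min_size=3, max_size=7).filter(
            lambda xs: len(xs) % 2 == 1  # odd: the median is an order statistic
        ),
        st.lists(st.integers(-50, 50), min_size=3, max_size=8),
    )
    def test_pem_overlap_nap_invariant_under_monotone_transform(self, base, inter):
        # strictly increasing on integers (gaps >= 3 dominate the exp term),
        # so ranks and ties are exactly preserved in float arithmetic
        transform = lambda v: math.exp(0.05 * v) + 3 * v
        tb, ti = [transform(v) for v in base], [transform(v) for v in inter]
        assert pem(base, inter, Direction.DECREASE)[0] == pytest.approx(
            pem(tb, ti, Direction.DECREASE)[0]
        )
        assert nap(base, inter, Direction.DECREASE) == pytest.approx(
            nap(tb, ti, Direction.DECREASE)
        )
        # overlap depends only on order relative to the baseline range
        assert overlap_pct(base, inter) == pytest.approx(overlap_pct(tb, ti))

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.sampled_from([Direction.INCREASE, Direction.DECREASE]),
    )
    def test_direction_symmetry_under_negation(self, base, inter, direction):
        nb, ni = [-v for v in base], [-v for v in inter]
        flipped = direction.flipped()
        assert pem(base, inter, direction)[0] == pytest.approx(
            pem(nb, ni, flipped)[0]
        )
        assert nap(base, inter, direction) == pytest.approx(nap(nb, ni, flipped))
        assert overlap_pct(base, inter) == pytest.approx(overlap_pct(nb, ni))
        assert (
            immediacy(base, inter, direction).immediate
            == immediacy(nb, ni, flipped).immediate
        )


class TestGate:
    def spec(self):
        return default_registry()["rmt"]

    def test_clean_step_passes_every_criterion(self):
        series = build_series([64, 64, 65, 64], [50, 50, 51, 50, 50])
        analysis = evaluate_gate(series, self.spec())
        assert analysis.gate.overall
        assert all(analysis.gate.criteria.values())

    def test_null_series_fails_level_pem_immediacy(self):
        series = build_series([64, 64, 65, 64], [64, 65, 64, 64, 65])
        analysis = evaluate_gate(series, self.spec())
        gate = analysis.gate
        assert not gate.overall
        assert not gate.criteria["pem"]
        assert not gate.criteria["overlap"]

    def test_single_outlier_breaks_only_stability(self):
        # one baseline outlier outside the 15% band drops stability to 75%
        # while every other criterion still holds
        series = build_series([64, 64, 90, 64], [50, 50, 51, 50, 50])
        analysis = evaluate_gate(series, self.spec())
        gate = analysis.gate
        assert not gate.criteria["stability"]
        assert gate.criteria["level"]
        assert gate.criteria["pem"]
        assert gate.criteria["immediacy"]
        assert not gate.overall

    def test_unanalyzable_series_rejected(self):
        series = build_series([64, 64], [50, 50, 50])
        with pytest.raises(ValueError, match="not analyzable"):
            evaluate_gate(series, self.spec())

    def test_consistency_verdict_feeds_through(self):
        series = build_series([64, 64, 65, 64], [50, 50, 51, 50, 50])
        analysis = evaluate_gate(series, self.spec(), consistency_ok=False)
        assert not analysis.gate.criteria["consistency"]
        assert not analysis.gate.overall

    def test_followup_summarized_but_not_gated(self):
        points = build_series([64, 64, 65, 64], [50, 50, 51, 50, 50]).points
        week = points[-1].week
        for v in (60.0, 62.0, 63.0):
            week += 1
            points.append(MeasurementPoint(week, PhaseLabel.FOLLOW_UP, v))
        series = MeasurementSeries(SeriesKey("A", "rmt", Side.LEFT), points)
        analysis = evaluate_gate(series, self.spec())
        assert PhaseLabel.FOLLOW_UP in analysis.within
        assert analysis.gate.overall  # follow-up drift does not veto the gate


class TestCleanScenarioPattern:
    def test_clinical_clean_reproduces_textbook_percentages(self, clinical_series):
        spec = default_registry()["minibest"]
        for series in clinical_series:
            analysis = evaluate_gate(series, spec)
            for phase in (PhaseLabel.BASELINE, PhaseLabel.INTERVENTION):
                w = analysis.within[phase]
                assert w.stability_pct == 100.0
                assert w.variability_pct == 0.0
            assert analysis.between.overlap_pct == 0.0
            assert analysis.between.pem_pct == 100.0
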