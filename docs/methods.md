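# Methods

This note documents the models, conventions and numerical choices behind
scedkit, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design model

A concurrent multiple-baseline design across participants: all participants
begin baseline in week 1 (week indices are 1-based); the intervention is
introduced staggered, with baselines of 3, 4, … weeks (one extra week per
successive participant); the default intervention lasts 12 weeks with five
weekly assessment points starting in the third intervention week; three
follow-up assessments fall at post-intervention weeks 4, 8 and 12. Phase
boundaries are stored explicitly per participant, never inferred from the
data. `validate_design` reports (rather than raises) violations: fewer than
three participants, baselines not staggered by one week, or any phase
contributing fewer than three points.

Missing assessments are first-class: a scheduled point with no value is kept
as an explicit gap, all statistics operate on available points only, and a
series needs at least three available points in baseline *and* intervention
to be analyzable (otherwise it is flagged, not dropped). Follow-up data are
summarised descriptively in every report but never enter the gate or the
inferential tests.

The measure registry assigns each outcome a unit, a family
(neurophysiological/clinical) and a **therapeutic direction**: decrease for
CMCT, MEP latency, resting motor threshold, timed gait and fatigue scores;
increase for MEP amplitude, balance, arm function, strength and
processing-speed scores. The registry ships as data and is overridable from
the YAML config.

## Neurophysiological measures

- Peripheral conduction time PCT = (F + M − 1)/2 ms; CMCT = MEP latency −
  PCT. A non-positive CMCT is physiologically degenerate and is returned
  flagged rather than discarded, so downstream summaries can mark it.
  CMCT + PCT = MEP latency holds exactly by construction (conservation
  identity, property-tested).
- MEP amplitude is max − min of the sweep within a post-stimulus window,
  default 15–60 ms. The window excludes the stimulus artifact; its bounds
  are configurable because no universal convention exists.
- Onset latency is detected automatically: first sample at which the
  rectified signal exceeds (pre-stimulus mean + k·SD), k = 3 by default,
  sustained for ≥ 0.5 ms. Manual visual scoring is the field's reference
  method; an explicit detector makes runs reproducible, and both k and the
  minimum duration are exposed. On noiseless synthetic sweeps the detector
  recovers the programmed onset to within one sample at 24 kHz; with a
  realistic noise floor the threshold crossing lags the true onset by
  roughly 0.1–0.2 ms (the rise time of the deflection from zero to the
  threshold), which is well inside between-session variability.
- A session's bout (default 30 suprathreshold stimuli at 120% of resting
  motor threshold, rounded to integer %MSO and capped at 100) is summarised
  by unweighted per-trace means; traces without a detectable onset are
  excluded from the latency mean but reported in the accounting. No
  artifact-exclusion rule is applied by default.
- Reporting precision: ms to 1 decimal, %MSO to integer, mV to 2 decimals.

## Visual analysis

All percentage features are exact multiples of 100/n of the relevant phase.

- **Level** is the phase mean; the level criterion asks for any change in
  the therapeutic direction (no minimum magnitude by default — a minimum is
  configurable since conventions differ).
- **Trend** fits an OLS slope against the point index and projects the total
  change over the phase, slope × (n − 1); a projection within 15% of the
  |phase median| is *stable*, otherwise the slope sign decides. Literal
  monotonicity (available as `strict_monotone`) is not the default because
  almost no noisy series is strictly monotone. The gate requires a stable
  baseline and an intervention trend that either moves in the improving
  direction or is stable with an improved level.
- **Stability**: share of points within ±15% of the phase median; criterion
  met at ≥ 80% (inclusive, since 80% is conventionally counted as meeting
  it; a strict switch exists). When the median is 0 the relative band is
  degenerate and an absolute half-width ε (default 0.5 measure units)
  is used instead.
- **Variability**: share of points outside the two-standard-deviation band
  (reference mean ± 2·SD, sample SD). The reference defaults to the phase's
  own points; whole-series and baseline references are available. Note the
  arithmetic bound: for a phase of n ≤ 5 points no point can lie more than
  (n−1)/√n < 2 sample SDs from its own mean, so own-phase variability is
  identically 0% at these sizes — published nonzero percentages necessarily
  use an external reference band, which is why the reference is
  configurable. A zero-spread reference with discrepant values raises
  rather than silently producing 0/100%.
- **Overlap**: share of intervention points inside [min, max] of baseline;
  gate threshold 0% by default.
- **Immediacy**: mean of the first three intervention points minus mean of
  the last three baseline points; true when in the therapeutic direction
  (magnitude threshold configurable, default any nonzero change). Computed
  on what is available and flagged when a side has fewer than three points.
- **PEM**: share of intervention points strictly better than the baseline
  median in the therapeutic direction; ties do not exceed. Categories:
  < 70% none, 70–90% moderate, > 90% high. PEM and overlap are rank-based
  and invariant under strictly increasing transforms *when the baseline
  median is an order statistic* (odd n); with even n the interpolated
  median is not itself rank-preserved, so the invariance property is stated
  and tested for odd baselines.
- **Consistency**: across participants for one measure and side, the share
  agreeing with the modal direction of level change; criterion at ≥ 0.8.
  With fewer than two participants it is not evaluable and passes
  vacuously with a note. It can be disabled without affecting the other
  criteria.

The gate is the conjunction of the enabled criteria (all eight by default).
A gated-out series never receives a p-value.

## Effect statistics

NAP counts improved cross-phase pairs with ties weighted ½. It equals the
tie-corrected Mann–Whitney U divided by n_A·n_B (cross-checked in the tests
against `scipy.stats.mannwhitneyu`, which is never used in the
implementation), and NAP(increase) + NAP(decrease) = 1 identically.

The randomization test treats phase labels as exchangeable within a series:
the observed values are reassigned to phases preserving the phase sizes.
The two-sided p-value is the share of reassignments whose statistic lies at
least as far from its null center (0.5 for NAP, 0 for the mean difference)
as the observed one, with the observed assignment always included, so
p > 0. Exact enumeration is used when C(n_A + n_B, n_B) ≤ 50 000 (every
series in the default design is far below this), otherwise seeded Monte
Carlo with (hits + 1)/(draws + 1). Statistic comparisons use an absolute
guard of 1e-12 so floating-point rounding cannot drop tied assignments. A
consequence of exactness at small n: with 3 baseline and 5 intervention
points the smallest attainable two-sided p is 2/C(8,3) ≈ 0.0357, which can
never survive a bilateral Bonferroni correction to 0.025 — a design floor,
not a software limitation.

Bonferroni: α_corrected = α / number of tests, with the number of tests
defaulting to the number of sides analyzed per measure (2 for bilateral
measures). A study-wide correction is a matter of choosing `n_tests` in the
caller. Monte-Carlo seeds are derived deterministically from a single
study seed and the series key (CRC32 mix, kept below 2³¹), so a full
report is reproducible while series remain independent.

Inter-assessor agreement is the share of positions where two raters differ
by at most a tolerance (default 0, pass at ≥ 0.8); validating that the
rated subset covers ≥ 20% of the condition's points is the caller's
responsibility since rating happens outside the package.

## Synthetic data

The generator emulates the *structure* the analysis assumes: staggered
concurrent baselines, per-phase levels with a step at intervention onset
(optionally delayed), iid Gaussian noise per time point (optional AR(1)
with preserved marginal SD, for stress-testing exchangeability), follow-up
levels regressing toward baseline, and explicit missing assessments (the
shipped pattern removes one baseline and one intervention point for the
last participant). It does **not** emulate: session-to-session drift,
floor/ceiling effects of bounded scores, heteroscedasticity between phases,
or rater error — so green tests on synthetic data demonstrate correctness
of the machinery under the stated model, not robustness to every real-data
pathology.

Scenario defaults are anchored to the magnitudes the workflow is designed
around: `rmt_effect` steps 64 → 50 %MSO (left) and 62 → 52 (right) with
noise SD 0.8 %MSO and follow-up at 65/62; `cmct_null_highvar` holds a
10 ms level with noise SD 1.5 ms (15%); `clinical_clean` is a noiseless
20 → 24 score step. Noise SDs are fixtures chosen to make the intended
gate outcome robust (clear pass, clear fail), not estimates of any
particular dataset. Synthetic EMG sweeps place a sharp biphasic deflection
(one 8 ms sine cycle, scaled to the requested peak-to-peak amplitude) on a
Gaussian noise floor at 24 kHz.

Identical seeds produce bit-identical datasets; generated designs always
validate cleanly.

## Problem sizes and determinism

The shipped scenarios use the full default design (5 participants, up to
13 assessment points per series), where exact enumeration tops out at
C(12,5) = 792 reassignments per series — the whole pipeline runs in
seconds. The randomization-test calibration in the acceptance tests uses
1 000 null simulations with 7 + 5 Gaussian points and the mean-difference
statistic, whose exact p-value distribution is nearly uniform at that size;
the NAP statistic's attainable p-values are coarser at small n, which makes
it the better effect descriptor but the worse calibration probe. All
randomness flows through explicit seeds; pipeline reruns with the same
input, config and seed produce byte-identical result tables.

## Known limitations

- Trend classification is a heuristic; different operationalizations of
  "monotone" can disagree near the stability band's edge.
- The within-series test is the default and conditions on the realized
  phase lengths, matching per-series effect reporting. For design-level
  inference `start_point_randomization_p` permutes the staggered onsets
  across participants (5! = 120 permutations in the default design) and
  uses the participant-mean NAP; with five participants its p-value floor
  is 1/120, so it complements rather than replaces the per-series tests.
- Consistency is reduced to the direction of level change; richer pattern
  similarity across participants is left to visual inspection.
- With ≤ 5 points per phase, own-phase variability is uninformative (see
  above) — use an external reference band if variability matters.
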