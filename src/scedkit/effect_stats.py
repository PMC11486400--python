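"""Effect estimation: NAP, randomization tests, Bonferroni, agreement.

The nonoverlap of all pairs (NAP) compares every baseline point with every
intervention point: NAP = (#pairs improved + 0.5 * #pairs tied) / (nA * nB),
where "improved" is judged in the measure's therapeutic direction.  NAP = 0.5
means chance-level overlap and NAP = 1 complete separation.

Significance comes from a randomization test under the exchangeability null:
the observed nA + nB values are reassigned to the two phases in every way
that preserves the phase sizes (exact enumeration) or in a seeded random
sample of reassignments (Monte Carlo), and the two-sided p-value is the
share of reassignments whose statistic is at least as far from its null
center (0.5 for NAP, 0 for the mean difference) as the observed one.  The
observed assignment is always counted, so p > 0.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .core_model import Direction

_EPS = 1e-12  # guards >= comparisons of float statistics against rounding


class TestScheme(enum.Enum):
    __test__ = False  # not a pytest class

    EXACT_ENUMERATION = "exact_enumeration"
    MONTE_CARLO = "monte_carlo"


class TestStatistic(enum.Enum):
    __test__ = False  # not a pytest class

    NAP = "nap"
    MEAN_DIFFERENCE = "mean_difference"


@dataclass
class EffectResult:
    nap: float
    p_value: float
    n_baseline: int
    n_intervention: int
    alpha: float
    n_tests: int
    alpha_corrected: float
    significant: bool
    test_scheme: TestScheme
    n_resamples: int  # enumerated assignments (exact) or draws (Monte Carlo)
    seed: Optional[int]


def nap(
    baseline: Sequence[float],
    intervention: Sequence[float],
    direction: Direction,
) -> float:
    """Nonoverlap of all pairs in the therapeutic direction, in [0, 1]."""
    base = np.asarray(baseline, dtype=float)
    inter = np.asarray(intervention, dtype=float)
    if base.size == 0 or inter.size == 0:
        raise ValueError("both phases must be non-empty")
    diff = inter[:, None] - base[None, :]
    if direction is Direction.INCREASE:
        improved = np.sum(diff > 0)
    else:
        improved = np.sum(diff < 0)
    ties = np.sum(diff == 0)
    return (float(improved) + 0.5 * float(ties)) / (base.size * inter.size)


def _nap_from_ranks(rank_sum_inter: float, n_base: int, n_inter: int) -> float:
    # midrank identity: U = R_inter - n_inter(n_inter+1)/2 counts
    # #(inter > base) + 0.5 * ties
    u = rank_sum_inter - n_inter * (n_inter + 1) / 2.0
    return u / (n_base * n_inter)


def randomization_p(
    baseline: Sequence[float],
    intervention: Sequence[float],
    direction: Direction,
    statistic: TestStatistic = TestStatistic.NAP,
    max_exact: int = 50_000,
    n_resamples: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[float, TestScheme, int]:
    """Two-sided within-series randomization test p-value.

    Returns ``(p_value, scheme, n)`` where ``n`` is the number of enumerated
    assignments (exact) or random draws (Monte Carlo).  Exact enumeration is
    used when C(nA + nB, nB) <= ``max_exact``; otherwise seeded Monte Carlo
    with the observed assignment added to numerator and denominator.
    """
    base = np.asarray(baseline, dtype=float)
    inter = np.asarray(intervention, dtype=float)
    if base.size == 0 or inter.size == 0:
        raise ValueError("both phases must be non-empty")
    n_base, n_inter = base.size, inter.size
    pooled = np.concatenate([base, inter])
    n_total = n_base + n_inter

    if statistic is TestStatistic.NAP:
        # rank once; any reassignment's NAP is a midrank sum over the
        # intervention indices, with the direction handled by sign
        scores = rankdata(pooled, method="average")
        if direction is Direction.DECREASE:
            scores = n_total + 1 - scores
        center = 0.5

        def stat(idx: np.ndarray) -> np.ndarray:
            return _nap_from_ranks(scores[idx].sum(axis=-1), n_base, n_inter)

    else:
        scores = pooled if direction is Direction.INCREASE else -pooled
        center = 0.0
        total = scores.sum()

        def stat(idx: np.ndarray) -> np.ndarray:
            s_inter = scores[idx].sum(axis=-1)
            # mean(intervention) - mean(baseline) from the intervention sum
            return s_inter / n_inter - (total - s_inter) / n_base

    observed = float(np.atleast_1d(stat(np.arange(n_base, n_total)[None, :]))[0])
    obs_dev = abs(observed - center)

    if comb(n_total, n_inter) <= max_exact:
        idx = np.array(
            list(combinations(range(n_total), n_inter)), dtype=np.intp
        )
        devs = np.abs(np.atleast_1d(stat(idx)) - center)
        p = float(np.sum(devs >= obs_dev - _EPS)) / idx.shape[0]
        return p, TestScheme.EXACT_ENUMERATION, idx.shape[0]

    rng = np.random.default_rng(seed)
    # each row: a uniformly random subset of size n_inter (via argsort of
    # uniform keys), i.e. a random reassignment preserving phase sizes
    keys = rng.random((n_resamples, n_total))
    idx = np.argsort(keys, axis=1)[:, :n_inter]
    devs = np.abs(np.atleast_1d(stat(idx)) - center)
    hits = int(np.sum(devs >= obs_dev - _EPS))
    p = (hits + 1) / (n_resamples + 1)
    return p, TestScheme.MONTE_CARLO, n_resamples


def start_point_randomization_p(
    series_list: Sequence,
    direction: Direction,
    max_exact: int = 50_000,
    n_resamples: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[float, TestScheme, int]:
    """Multiple-baseline randomization test over the staggered onsets.

    The design-level alternative to the within-series test: under the null
    the assignment of intervention start points to participants is
    arbitrary, so the staggered onsets are permuted across participants and
    each permutation re-labels every participant's measured sequence into
    pseudo-baseline (weeks up to the permuted boundary) and
    pseudo-intervention points.  The statistic is the participant-mean NAP;
    the two-sided p-value is the share of permutations whose mean is at
    least as far from 0.5 as the observed one (observed permutation
    included).  A pseudo-phase left empty by a permutation contributes a
    neutral 0.5.  One series per participant (same measure and side) is
    expected; follow-up points are ignored.
    """
    from math import factorial
    from .core_model import PhaseLabel  # local import avoids a cycle

    if len(series_list) < 2:
        raise ValueError("start-point randomization needs >= 2 participants")
    weeks_values = []
    boundaries = []
    for s in series_list:
        pts = [
            (p.week, p.value)
            for p in s.points
            if p.phase is not PhaseLabel.FOLLOW_UP and not p.missing
        ]
        base_weeks = [p.week for p in s.phase_points(PhaseLabel.BASELINE)]
        if not base_weeks or not pts:
            raise ValueError(f"series {s.key} has no usable points")
        weeks_values.append(pts)
        boundaries.append(max(base_weeks))

    def mean_nap(bounds: Sequence[int]) -> float:
        stats = []
        for pts, b in zip(weeks_values, bounds):
            base = [v for w, v in pts if w <= b]
            inter = [v for w, v in pts if w > b]
            stats.append(0.5 if not base or not inter else nap(base, inter, direction))
        return float(np.mean(stats))

    observed = abs(mean_nap(boundaries) - 0.5)
    n_participants = len(boundaries)
    if factorial(n_participants) <= max_exact:
        from itertools import permutations

        perms = list(permutations(boundaries))
        hits = sum(
            abs(mean_nap(perm) - 0.5) >= observed - _EPS for perm in perms
        )
        return hits / len(perms), TestScheme.EXACT_ENUMERATION, len(perms)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(boundaries)
        hits += abs(mean_nap(perm) - 0.5) >= observed - _EPS
    return (hits + 1) / (n_resamples + 1), TestScheme.MONTE_CARLO, n_resamples


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-corrected per-test alpha: alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def interassessor_agreement(
    assessor_a: Sequence[float],
    assessor_b: Sequence[float],
    tolerance: float = 0.0,
    pass_threshold: float = 0.8,
) -> tuple[float, bool]:
    """Fraction of positions where two assessors agree within ``tolerance``.

    Returns ``(fraction, passed)`` with the pass flag at >= 0.8 by default.
    The caller is responsible for checking the subset covers at least 20% of
    the condition's data points.
    """
    a = np.asarray(assessor_a, dtype=float)
    b = np.asarray(assessor_b, dtype=float)
    if a.size != b.size:
        raise ValueError("assessor sequences must have equal length")
    if a.size == 0:
        raise ValueError("agreement needs at least one shared data point")
    fraction = float(np.sum(np.abs(a - b) <= tolerance)) / a.size
    return fraction, fraction >= pass_threshold


def derive_seed(study_seed: int, series_key: str) -> int:
    """Deterministic per-series seed from a study-level seed and series key."""
    return (study_seed * 1_000_003 + zlib.crc32(series_key.encode())) % (2**31)


def analyze_measure(
    baseline: Sequence[float],
    intervention: Sequence[float],
    direction: Direction,
    gate_passed: bool,
    n_tests: int = 1,
    alpha: float = 0.05,
    statistic: TestStatistic = TestStatistic.NAP,
    max_exact: int = 50_000,
    n_resamples: int = 10_000,
    seed: Optional[int] = None,
) -> Optional[EffectResult]:
    """Effect estimation for one series, gated by the visual analysis.

    Returns None when the gate failed (no p-value is ever computed for a
    gated-out series); otherwise an :class:`EffectResult` with the NAP,
    randomization p-value and the Bonferroni verdict at alpha / n_tests.
    """
    if not gate_passed:
        return None
    nap_value = nap(baseline, intervention, direction)
    p, scheme, n = randomization_p(
        baseline,
        intervention,
        direction,
        statistic=statistic,
        max_exact=max_exact,
        n_resamples=n_resamples,
        seed=seed,
    )
    alpha_corrected = bonferroni_alpha(alpha, n_tests)
    return EffectResult(
        nap=nap_value,
        p_value=p,
        n_baseline=len(list(baseline)),
        n_intervention=len(list(intervention)),
        alpha=alpha,
        n_tests=n_tests,
        alpha_corrected=alpha_corrected,
        significant=p < alpha_corrected,
        test_scheme=scheme,
        n_resamples=n,
        seed=seed,
    )


__all__ = [
    "TestScheme",
    "TestStatistic",
    "EffectResult",
    "nap",
    "randomization_p",
    "start_point_randomization_p",
    "bonferroni_alpha",
    "interassessor_agreement",
    "derive_seed",
    "analyze_measure",
]
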