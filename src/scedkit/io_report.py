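"""Long-format CSV I/O, configuration, plotting, pipeline and reporting.

The canonical on-disk format is a long CSV with header
``participant,measure,side,week,phase,value`` (UTF-8, '.' decimal, empty
value = missed assessment).  The pipeline runs visual analysis on every
series, applies the gate, computes NAP + randomization p-values only for
gate-passing series, and writes tidy results plus a human-readable summary.
Reruns with the same input, config and seed produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core_model import (
    MeasureSpec,
    MeasurementPoint,
    MeasurementSeries,
    PhaseLabel,
    SeriesKey,
    Side,
    ValidationReport,
    default_registry,
    phase_values,
)
from .effect_stats import (
    EffectResult,
    TestStatistic,
    analyze_measure,
    derive_seed,
)
from .visual_analysis import (
    GateConfig,
    SeriesAnalysis,
    VariabilityReference,
    consistency,
    evaluate_gate,
)

CSV_COLUMNS = ["participant", "measure", "side", "week", "phase", "value"]

#: Reporting precision by unit (decimal places).
UNIT_DECIMALS = {"%MSO": 0, "ms": 1, "mV": 2, "s": 1, "score": 1, "kg": 1}
P_VALUE_DECIMALS = 4
PROPORTION_DECIMALS = 3


# --- configuration --------------------------------------------------------

@dataclass
class StatsConfig:
    alpha: float = 0.05
    statistic: TestStatistic = TestStatistic.NAP
    max_exact: int = 50_000
    n_resamples: int = 10_000


@dataclass
class PipelineConfig:
    gate: GateConfig = field(default_factory=GateConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    registry: dict[str, MeasureSpec] = field(default_factory=default_registry)


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a pipeline configuration from YAML (missing keys keep defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gate_kwargs = dict(raw.get("gate", {}))
    if "variability_reference" in gate_kwargs:
        gate_kwargs["variability_reference"] = VariabilityReference(
            gate_kwargs["variability_reference"]
        )
    if "enabled_criteria" in gate_kwargs:
        gate_kwargs["enabled_criteria"] = tuple(gate_kwargs["enabled_criteria"])
    stats_kwargs = dict(raw.get("stats", {}))
    if "statistic" in stats_kwargs:
        stats_kwargs["statistic"] = TestStatistic(stats_kwargs["statistic"])
    config = PipelineConfig(
        gate=GateConfig(**gate_kwargs),
        stats=StatsConfig(**stats_kwargs),
        seed=int(raw.get("seed", 0)),
    )
    from .core_model import Direction, MeasureFamily  # local: registry overrides

    for name, spec in (raw.get("registry") or {}).items():
        config.registry[name] = MeasureSpec(
            name=name,
            units=spec.get("units", "score"),
            direction=Direction(spec.get("direction", "increase")),
            family=MeasureFamily(spec.get("family", "clinical")),
            bilateral=bool(spec.get("bilateral", False)),
        )
    return config


def config_hash(config: PipelineConfig) -> str:
    text = repr(config)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# --- long CSV I/O ---------------------------------------------------------

def write_long_csv(series_list: Sequence[MeasurementSeries],
                   path: Union[str, Path]) -> None:
    rows = []
    for series in sorted(series_list, key=lambda s: str(s.key)):
        for p in series.points:
            rows.append(
                {
                    "participant": series.key.participant_id,
                    "measure": series.key.measure,
                    "side": series.key.side.value,
                    "week": p.week,
                    "phase": p.phase.value,
                    "value": "" if p.missing else repr(float(p.value)),
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_long_csv(
    path: Union[str, Path]
) -> tuple[list[MeasurementSeries], ValidationReport]:
    """Assemble series from a long CSV; malformed rows go to the report."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {', '.join(missing_cols)}")
    report = ValidationReport()
    grouped: dict[SeriesKey, list[MeasurementPoint]] = defaultdict(list)
    for i, row in frame.iterrows():
        try:
            phase = PhaseLabel.parse(row["phase"])
            side = Side.parse(row["side"])
            week = int(row["week"])
            value_text = row["value"].strip()
            value = None if value_text == "" else float(value_text)
        except (ValueError, TypeError) as exc:
            report.violations.append(f"row {i + 2}: {exc}")
            continue
        key = SeriesKey(row["participant"], row["measure"], side)
        grouped[key].append(MeasurementPoint(week=week, phase=phase, value=value))
    series_list = []
    for key in sorted(grouped, key=str):
        points = sorted(grouped[key], key=lambda p: p.week)
        try:
            series = MeasurementSeries(key=key, points=points)
        except ValueError as exc:
            report.violations.append(str(exc))
            continue
        if not series.analyzable:
            report.violations.append(
                f"series {key}: fewer than 3 available points in baseline or "
                "intervention; flagged as not analyzable"
            )
        series_list.append(series)
    return series_list, report


# --- study report ---------------------------------------------------------

@dataclass
class SeriesRecord:
    series: MeasurementSeries
    analysis: SeriesAnalysis
    effect: Optional[EffectResult]  # None iff the gate failed


@dataclass
class StudyReport:
    records: list[SeriesRecord]
    seed: int
    config_digest: str

    def results_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-series results table (canonical order)."""
        rows = []
        for rec in sorted(self.records, key=lambda r: str(r.series.key)):
            between = rec.analysis.between
            gate = rec.analysis.gate
            row = {
                "participant": rec.series.key.participant_id,
                "measure": rec.series.key.measure,
                "side": rec.series.key.side.value,
                "level_change": round(between.level_change, 3),
                "level_improved": between.level_improved,
                "overlap_pct": round(between.overlap_pct, 1),
                "immediacy": between.immediacy,
                "pem_pct": round(between.pem_pct, 1),
                "pem_category": between.pem_category.value,
                "gate_passed": gate.overall,
            }
            for name, ok in sorted(gate.criteria.items()):
                row[f"criterion_{name}"] = ok
            if rec.effect is not None:
                row.update(
                    nap=round(rec.effect.nap, PROPORTION_DECIMALS),
                    p_value=round(rec.effect.p_value, P_VALUE_DECIMALS),
                    alpha_corrected=rec.effect.alpha_corrected,
                    significant=rec.effect.significant,
                    test_scheme=rec.effect.test_scheme.value,
                )
            else:
                row.update(
                    nap=np.nan, p_value=np.nan, alpha_corrected=np.nan,
                    significant=pd.NA, test_scheme="",
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def phase_summary_frame(self) -> pd.DataFrame:
        """Tidy within-phase summary: one row per series x phase."""
        rows = []
        for rec in sorted(self.records, key=lambda r: str(r.series.key)):
            for phase, w in rec.analysis.within.items():
                rows.append(
                    {
                        "participant": rec.series.key.participant_id,
                        "measure": rec.series.key.measure,
                        "side": rec.series.key.side.value,
                        "phase": phase.value,
                        "level": round(w.level, 3),
                        "trend": w.trend.value,
                        "stability_pct": round(w.stability_pct, 1),
                        "variability_pct": (
                            np.nan if w.variability_pct is None
                            else round(w.variability_pct, 1)
                        ),
                        "n_points": w.n_points,
                    }
                )
        return pd.DataFrame(rows)


def group_phase_means(
    report: StudyReport, registry: Optional[dict[str, MeasureSpec]] = None
) -> pd.DataFrame:
    """Group means per measure x side x phase.

    The group mean is the mean over participants of the per-participant
    phase means, rounded to the measure's reporting precision.
    """
    registry = registry or default_registry()
    acc: dict[tuple[str, str, str], list[float]] = defaultdict(list)
    for rec in report.records:
        for phase, w in rec.analysis.within.items():
            key = (rec.series.key.measure, rec.series.key.side.value, phase.value)
            acc[key].append(w.level)
    rows = []
    for (measure, side, phase), levels in sorted(acc.items()):
        units = registry[measure].units if measure in registry else "score"
        decimals = UNIT_DECIMALS.get(units, 2)
        mean = round(float(np.mean(levels)), decimals)
        if decimals == 0:
            mean = int(mean)
        rows.append(
            {
                "measure": measure,
                "side": side,
                "phase": phase,
                "group_mean": mean,
                "n_participants": len(levels),
            }
        )
    return pd.DataFrame(rows)


# --- pipeline -------------------------------------------------------------

def analyze_study(
    series_list: Sequence[MeasurementSeries],
    config: Optional[PipelineConfig] = None,
) -> StudyReport:
    """Visual analysis -> gate -> (gated) effect statistics for every series.

    Consistency is computed across participants within each measure x side
    from the direction of the level change, then attached to each series'
    gate.  ``n_tests`` for the Bonferroni correction is the number of sides
    analyzed for the measure (2 for bilateral measures).
    """
    config = config or PipelineConfig()
    analyzable = [s for s in series_list if s.analyzable]
    if not analyzable:
        raise ValueError("no analyzable series in input")

    # first pass: between-phase level direction per series
    prelim: dict[SeriesKey, SeriesAnalysis] = {
        s.key: evaluate_gate(s, _spec_for(s, config), config.gate)
        for s in analyzable
    }
    # consistency across participants per measure x side
    by_condition: dict[tuple[str, Side], list[SeriesKey]] = defaultdict(list)
    for s in analyzable:
        by_condition[(s.key.measure, s.key.side)].append(s.key)
    consistency_ok: dict[SeriesKey, Optional[bool]] = {}
    for keys in by_condition.values():
        flags = [prelim[k].between.level_improved for k in keys]
        if len(flags) < 2:
            verdict: Optional[bool] = None
        else:
            _, verdict = consistency(flags, config.gate.consistency_threshold)
        for k in keys:
            consistency_ok[k] = verdict

    # Bonferroni n_tests: how many sides of the measure are tested
    sides_per_measure = {
        m: len({s.key.side for s in analyzable if s.key.measure == m})
        for m in {s.key.measure for s in analyzable}
    }

    records = []
    for s in analyzable:
        spec = _spec_for(s, config)
        analysis = evaluate_gate(s, spec, config.gate, consistency_ok[s.key])
        base = phase_values(s, PhaseLabel.BASELINE)
        inter = phase_values(s, PhaseLabel.INTERVENTION)
        effect = analyze_measure(
            base,
            inter,
            spec.direction,
            gate_passed=analysis.gate.overall,
            n_tests=sides_per_measure[s.key.measure],
            alpha=config.stats.alpha,
            statistic=config.stats.statistic,
            max_exact=config.stats.max_exact,
            n_resamples=config.stats.n_resamples,
            seed=derive_seed(config.seed, str(s.key)),
        )
        records.append(SeriesRecord(series=s, analysis=analysis, effect=effect))
    return StudyReport(
        records=records, seed=config.seed, config_digest=config_hash(config)
    )


def _spec_for(series: MeasurementSeries, config: PipelineConfig) -> MeasureSpec:
    name = series.key.measure
    if name in config.registry:
        return config.registry[name]
    raise KeyError(
        f"measure {name!r} not in the registry; add it via config overrides"
    )


def run_pipeline(
    series_list: Sequence[MeasurementSeries],
    outdir: Union[str, Path],
    config: Optional[PipelineConfig] = None,
    make_figures: bool = False,
) -> StudyReport:
    """End-to-end run writing results CSV/JSON and a summary to ``outdir``."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = analyze_study(series_list, config)

    results = report.results_frame()
    results.to_csv(outdir / "results.csv", index=False)
    report.phase_summary_frame().to_csv(outdir / "phase_summaries.csv", index=False)
    group_phase_means(report, config.registry).to_csv(
        outdir / "group_phase_means.csv", index=False
    )
    payload = {
        "seed": report.seed,
        "config": report.config_digest,
        "series": json.loads(results.to_json(orient="records")),
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2,
                                                    sort_keys=True))
    (outdir / "summary.md").write_text(render_summary(report))
    if make_figures:
        for measure in sorted({r.series.key.measure for r in report.records}):
            plot_measure(report, measure, outdir / f"fig_{measure}")
    return report


def render_summary(report: StudyReport) -> str:
    """Human-readable run summary with per-series gate rationale."""
    lines = [
        "# Study analysis summary",
        "",
        f"- seed: {report.seed}",
        f"- config: {report.config_digest}",
        f"- series analyzed: {len(report.records)}",
        "",
    ]
    for rec in sorted(report.records, key=lambda r: str(r.series.key)):
        gate = rec.analysis.gate
        status = "PASSED" if gate.overall else "gated out"
        lines.append(f"## {rec.series.key} — {status}")
        between = rec.analysis.between
        lines.append(
            f"- level change {between.level_change:+.3f}, "
            f"overlap {between.overlap_pct:.0f}%, PEM {between.pem_pct:.0f}% "
            f"({between.pem_category.value})"
        )
        for note in gate.notes:
            lines.append(f"- {note}")
        if rec.effect is not None:
            e = rec.effect
            lines.append(
                f"- NAP = {e.nap:.3f}, p = {e.p_value:.4f} "
                f"({e.test_scheme.value}, n = {e.n_resamples}), "
                f"alpha_corrected = {e.alpha_corrected:.4f}, "
                f"significant = {e.significant}"
            )
        else:
            lines.append("- no statistical test (visual-analysis gate not met)")
        lines.append("")
    return "\n".join(lines)


# --- plotting -------------------------------------------------------------

def plot_measure(
    report: StudyReport,
    measure: str,
    outpath: Union[str, Path],
    config: Optional[GateConfig] = None,
) -> None:
    """Multiple-baseline panel figure for one measure.

    One row per participant, one column per side.  Each phase shows a grey
    +/-15%-of-median stability band and a solid mean line; the baseline
    median extends dashed across the intervention phase (the PEM reference);
    vertical lines separate phases; missed assessments are marked with an
    asterisk at the scheduled week.  Writes SVG and PNG.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or GateConfig()
    records = [r for r in report.records if r.series.key.measure == measure]
    if not records:
        raise ValueError(f"no series for measure {measure!r}")
    participants = sorted({r.series.key.participant_id for r in records})
    sides = sorted({r.series.key.side for r in records}, key=lambda s: s.value)
    fig, axes = plt.subplots(
        len(participants),
        len(sides),
        figsize=(4.5 * len(sides), 1.8 * len(participants)),
        squeeze=False,
        sharex=True,
    )
    by_key = {(r.series.key.participant_id, r.series.key.side): r for r in records}
    for i, pid in enumerate(participants):
        for j, side in enumerate(sides):
            ax = axes[i][j]
            rec = by_key.get((pid, side))
            if rec is None:
                ax.axis("off")
                continue
            _plot_series_panel(ax, rec, config)
            if i == 0:
                ax.set_title(side.value)
            if j == 0:
                ax.set_ylabel(pid)
    fig.suptitle(measure)
    fig.supxlabel("week")
    fig.tight_layout()
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    for ext in ("svg", "png"):
        fig.savefig(outpath.with_suffix(f".{ext}"), dpi=120)
    plt.close(fig)


def _plot_series_panel(ax, rec: SeriesRecord, config: GateConfig) -> None:
    series = rec.series
    phases = [p for p in PhaseLabel if series.phase_points(p)]
    baseline_median = None
    for phase in phases:
        pts = series.phase_points(phase)
        weeks = [p.week for p in pts if not p.missing]
        vals = [p.value for p in pts if not p.missing]
        if vals:
            med = float(np.median(vals))
            half = config.stability_band_fraction * abs(med)
            if half == 0:
                half = config.median_abs_epsilon  # degenerate band: epsilon
            w0, w1 = pts[0].week - 0.4, pts[-1].week + 0.4
            ax.fill_between([w0, w1], med - half, med + half,
                            color="0.85", zorder=0)
            ax.hlines(float(np.mean(vals)), w0, w1, color="black", lw=1.2)
            if phase is PhaseLabel.BASELINE:
                baseline_median = (med, w0)
            elif phase is PhaseLabel.INTERVENTION and baseline_median:
                ax.hlines(baseline_median[0], w0, w1, color="black",
                          lw=1.0, linestyle="--")
        ax.plot(weeks, vals, "o-", ms=3, lw=1, color="tab:blue")
        for p in pts:
            if p.missing:
                ax.annotate("*", (p.week, ax.get_ylim()[0]), ha="center",
                            fontsize=11)
        if phase is not phases[-1]:
            boundary = pts[-1].week + 0.5
            ax.axvline(boundary, color="black", lw=0.8)


__all__ = [
    "CSV_COLUMNS",
    "StatsConfig",
    "PipelineConfig",
    "load_config",
    "config_hash",
    "write_long_csv",
    "read_long_csv",
    "SeriesRecord",
    "StudyReport",
    "group_phase_means",
    "analyze_study",
    "run_pipeline",
    "render_summary",
    "plot_measure",
]
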