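"""Group comparison across fish, metrics and sections.

Every fish on the plate becomes a :class:`FishRecord` holding its traces,
bouts, stimulus responses and group label.  Sections (possibly
overlapping) slice the run into analysis windows; each metric is computed
independently within each section, giving a fish x (section.metric) table.

For each metric the groups are compared with a Kruskal-Wallis one-way
ANOVA on ranks, and the effect size is the strictly standardized mean
difference,

    SSMD = (mean1 - mean2) / sqrt(var1 + var2),

whose value is 0 under no effect and antisymmetric under group swap.
Run-level summaries mirror screening practice: the number of metrics with
p < 0.05 and the peak position of a Gaussian kernel density estimate of
the SSMD distribution (both near 0 / 5% for null comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import kinematics
from .formats import CentroidTrace, EventCommand, MotionTrace, SectionsSpec
from .kinematics import Bout, BoutParams
from .responses import ResponseEvent

__all__ = [
    "FishRecord",
    "ComparisonResult",
    "apply_sections",
    "metric_table",
    "kruskal_wallis",
    "ssmd",
    "ssmd_summary",
    "SsmdSummary",
    "compare_groups",
    "baseline_mixed_model",
]


@dataclass
class FishRecord:
    """One animal: traces, derived events, metrics and its group label."""

    well_id: str
    group: str
    motion: MotionTrace | None = None
    centroid: CentroidTrace | None = None
    well_size: tuple[float, float] | None = None
    bouts: list[Bout] = field(default_factory=list)
    #: (event, scored response) pairs from high-speed clips
    responses: list[tuple[EventCommand, ResponseEvent]] = field(default_factory=list)
    #: section name -> {metric name -> value}
    processed: dict[str, dict[str, float]] = field(default_factory=dict)


def _time_section_metrics(
    rec: FishRecord,
    start_s: float,
    end_s: float,
    params: BoutParams,
    sleep_min_quiescence_s: float,
) -> dict[str, float]:
    if rec.motion is None or rec.centroid is None:
        return {}
    end_s = min(end_s, rec.motion.t0 + rec.motion.duration_s)
    if end_s <= start_s:
        return {}
    motion = rec.motion.slice_time(start_s, end_s)
    centroid = rec.centroid.slice_time(start_s, end_s + 1.0 / rec.centroid.fps)
    if len(centroid) != len(motion) + 1:
        # trim/extend guard at run boundaries
        pts = centroid.points[:len(motion) + 1]
        if len(pts) < len(motion) + 1:
            motion = MotionTrace(motion.values[:len(pts) - 1], motion.fps,
                                 motion.t0)
        centroid = CentroidTrace(pts, centroid.fps, centroid.t0)
    span = end_s - start_s
    bouts = kinematics.detect_bouts(motion, centroid, params)
    out = kinematics.bout_summary_metrics(
        bouts, span, centroid=centroid, well_size=rec.well_size, params=params
    )
    out.update(kinematics.sleep_wake_metrics(
        bouts, span, motion.fps, sleep_min_quiescence_s
    ))
    return out


def _event_section_metrics(
    rec: FishRecord,
    section,
) -> dict[str, float]:
    selected = [
        (e, r) for e, r in rec.responses
        if section.contains_time(e.scheduled_time)
        and (not section.event_selector
             or section.event_selector in (e.raw or ""))
    ]
    if not selected:
        return {}
    resps = [r for _, r in selected]
    responded = [r for r in resps if r.responded]
    out = {
        "response_frequency": len(responded) / len(resps),
        "n_events": float(len(resps)),
    }
    if responded:
        out.update({
            "response_latency_ms": float(np.mean([r.latency_ms for r in responded])),
            "response_distance_px": float(np.mean([r.distance_px for r in responded])),
            "response_displacement_px": float(
                np.mean([r.displacement_px for r in responded])),
            "response_delta_pixels": float(
                np.mean([r.cumulative_delta_pixels for r in responded])),
            "response_velocity_px_s": float(
                np.mean([r.mean_velocity_px_s for r in responded])),
        })
    return out


def apply_sections(
    records: Sequence[FishRecord],
    sections: SectionsSpec,
    bout_params: BoutParams | None = None,
    sleep_min_quiescence_s: float = 60.0,
) -> None:
    """Compute every metric within every section, per fish (in place).

    Time sections get bout/sleep/position metrics from the slow-speed
    traces; event sections get response metrics from high-speed clips
    whose events fall inside the window (and match the selector).
    Overlapping sections each receive the full shared data; an empty
    section yields an empty metric map, not an error.
    """
    bout_params = bout_params or BoutParams()
    for rec in records:
        for sec in sections:
            if sec.kind == "time":
                m = _time_section_metrics(
                    rec, sec.start_s, sec.end_s, bout_params,
                    sleep_min_quiescence_s,
                )
            else:
                m = _event_section_metrics(rec, sec)
            rec.processed[sec.name] = m


def metric_table(records: Sequence[FishRecord]) -> pd.DataFrame:
    """Flatten processed metrics into a fish x ``section.metric`` table.

    Index is well id; a ``group`` column carries the label.  Metrics a
    fish lacks are NaN.
    """
    rows = []
    for rec in records:
        row: dict[str, float | str] = {"group": rec.group}
        for sec_name, metrics in rec.processed.items():
            for m, v in metrics.items():
                row[f"{sec_name}.{m}"] = v
        rows.append(pd.Series(row, name=rec.well_id))
    return pd.DataFrame(rows)


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis one-way ANOVA on ranks (tie-corrected).

    Returns (H, p) with p from the chi-square approximation.  Requires at
    least two non-empty groups; an empty group is an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if len(a) == 0:
            raise ValueError(f"group {i} is empty")
    if all(np.all(a == arrays[0][0]) for a in arrays):
        return 0.0, 1.0  # scipy raises on all-identical data
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def ssmd(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """Strictly standardized mean difference.

    ``(mean1 - mean2) / sqrt(var1 + var2)`` with unbiased sample
    variances.  Degenerate cases: both variances zero with equal means
    -> 0 (no effect); zero total variance with unequal means -> signed
    infinity.  Antisymmetric under argument swap.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    m1, m2 = a.mean(), b.mean()
    v1 = a.var(ddof=1) if len(a) > 1 else 0.0
    v2 = b.var(ddof=1) if len(b) > 1 else 0.0
    denom = math.sqrt(v1 + v2)
    if denom == 0:
        if m1 == m2:
            return 0.0
        return math.copysign(float("inf"), m1 - m2)
    return float((m1 - m2) / denom)


@dataclass
class SsmdSummary:
    """Run-level summary of a multi-metric comparison."""

    kde_grid: np.ndarray
    kde_density: np.ndarray
    peak: float
    n_p_below_05: int
    n_metrics: int


def ssmd_summary(
    ssmds: Sequence[float],
    p_values: Sequence[float] | None = None,
    grid_points: int = 512,
) -> SsmdSummary:
    """KDE peak of the SSMD distribution plus the p < 0.05 count.

    Uses a Gaussian KDE with Scott's-rule bandwidth evaluated on a
    ``grid_points``-point grid spanning the data range extended by three
    bandwidths; the peak is the grid argmax.  Non-finite SSMDs (from
    zero-variance metrics) are dropped before density estimation.
    Invariant under metric reordering.
    """
    arr = np.asarray(ssmds, dtype=float)
    finite = arr[np.isfinite(arr)]
    if len(finite) == 0:
        raise ValueError("no finite SSMD values")
    n_p = 0 if p_values is None else int(np.sum(np.asarray(p_values) < 0.05))
    if np.ptp(finite) == 0:
        v = float(finite[0])
        grid = np.linspace(v - 1, v + 1, grid_points)
        dens = np.zeros(grid_points)
        dens[np.argmin(np.abs(grid - v))] = 1.0
        return SsmdSummary(grid, dens, v, n_p, len(arr))
    kde = stats.gaussian_kde(finite)  # Scott's rule by default
    bw = kde.factor * finite.std(ddof=1)
    grid = np.linspace(finite.min() - 3 * bw, finite.max() + 3 * bw, grid_points)
    dens = kde(grid)
    peak = float(grid[int(np.argmax(dens))])
    return SsmdSummary(grid, dens, peak, n_p, len(arr))


@dataclass
class ComparisonResult:
    """Per-metric statistics and run-level summary of a group comparison."""

    table: pd.DataFrame          # index metric; group means, H, p, SSMD
    summary: SsmdSummary
    groups: tuple[str, ...]


def compare_groups(
    metrics: pd.DataFrame,
    group_col: str = "group",
    groups: Sequence[str] | None = None,
    bh_correction: bool = False,
) -> ComparisonResult:
    """Compare groups metric by metric.

    ``metrics`` is a fish x metric table with a group-label column (as
    produced by :func:`metric_table`).  For every numeric metric with at
    least two observations per group, computes per-group means, the
    Kruskal-Wallis (H, p) and the SSMD of the first group against the
    second.  Raw p-values are reported by default, matching screening
    practice of counting uncorrected p < 0.05; ``bh_correction`` adds a
    Benjamini-Hochberg ``q`` column without changing the count.
    """
    if groups is None:
        groups = sorted(metrics[group_col].dropna().unique().tolist())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for col in metrics.columns:
        if col == group_col:
            continue
        series = pd.to_numeric(metrics[col], errors="coerce")
        samples = [series[metrics[group_col] == g].dropna().to_numpy()
                   for g in groups]
        if any(len(s) < 2 for s in samples):
            continue
        if np.ptp(np.concatenate(samples)) == 0:
            continue  # constant metric carries no information
        h, p = kruskal_wallis(*samples)
        row = {"metric": col, "H": h, "p": p,
               "ssmd": ssmd(samples[0], samples[1])}
        for g, s in zip(groups, samples):
            row[f"mean_{g}"] = float(np.mean(s))
            row[f"n_{g}"] = len(s)
        rows.append(row)
    if not rows:
        raise ValueError("no comparable metrics found")
    table = pd.DataFrame(rows).set_index("metric")
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    summary = ssmd_summary(table["ssmd"], table["p"])
    return ComparisonResult(table=table, summary=summary, groups=tuple(groups))


def baseline_mixed_model(
    binned: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    fish_col: str = "fish_id",
    time_col: str = "time_bin",
) -> tuple[float, float]:
    """Linear mixed model for baseline activity with a time component.

    Model: value ~ group + time-bin (both fixed) with a per-fish random
    intercept, fitted by REML.  Returns the fixed-effect estimate of the
    second group level versus the first and its p-value.  With a single
    time bin the time term drops and the model collapses to a group
    comparison of means.
    """
    import statsmodels.formula.api as smf

    df = binned.dropna(subset=[value_col]).copy()
    if df[group_col].nunique() < 2:
        raise ValueError("need two group levels")
    terms = [f"C({group_col})"]
    if df[time_col].nunique() > 1:
        terms.append(f"C({time_col})")
    formula = f"{value_col} ~ " + " + ".join(terms)
    model = smf.mixedlm(formula, df, groups=df[fish_col])
    fit = model.fit(reml=True)
    levels = sorted(df[group_col].unique())
    name = f"C({group_col})[T.{levels[1]}]"
    return float(fit.params[name]), float(fit.pvalues[name])
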