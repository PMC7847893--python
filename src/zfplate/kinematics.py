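"""Slow-speed kinematics: bout detection, bout metrics, sleep/wake, binning.

A *bout* is a discrete episode of swimming delimited by quiescence.  Bouts
are gated on the delta-pixel motion trace — a maximal run of frames with
motion strictly above a noise threshold — and measured with the centroid
trace (distance, displacement, velocity).  Runs separated by less than a
merge gap are fused, then runs shorter than a minimum length are dropped.

Motion value ``i`` describes the change between centroid frames ``i`` and
``i + 1``, so a bout over motion frames ``[s, e)`` is measured on centroid
frames ``s .. e`` inclusive.  Missing centroid frames are linearly
interpolated here (never at the tracking layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formats import CentroidTrace, MotionTrace

__all__ = [
    "Bout",
    "BoutParams",
    "BinnedSeries",
    "detect_bouts",
    "bout_summary_metrics",
    "sleep_wake_metrics",
    "bin_series",
]


@dataclass
class Bout:
    """One detected movement episode.

    Frame indices are motion-trace indices, half-open ``[start, end)``.
    Distance is the summed centroid step length; displacement the
    straight-line start-to-end length, so displacement <= distance.
    """

    start_frame: int
    end_frame: int
    duration_s: float
    distance_px: float
    displacement_px: float
    mean_velocity_px_s: float
    peak_velocity_px_s: float
    delta_pixel_sum: int

    def __post_init__(self) -> None:
        assert self.end_frame > self.start_frame
        assert self.displacement_px <= self.distance_px + 1e-9


@dataclass
class BoutParams:
    """Bout-detection thresholds for 30-fps slow-speed data.

    Motion gating uses a strict ``>`` comparison.  ``center_fraction_defn``
    is the fraction of well area defining the concentric "well-center"
    region for the thigmotaxis metric (0.5 = area-balanced null).
    """

    motion_on_threshold: float = 2.0
    min_bout_frames: int = 2
    merge_gap_frames: int = 3
    center_fraction_defn: float = 0.5

    def __post_init__(self) -> None:
        if self.motion_on_threshold <= 0 or self.min_bout_frames <= 0 \
                or self.merge_gap_frames <= 0:
            raise ValueError("bout parameters must be positive")
        if not 0 < self.center_fraction_defn <= 1:
            raise ValueError("center_fraction_defn must be in (0, 1]")


@dataclass
class BinnedSeries:
    """Per-bin aggregates of a metric over fixed-width time bins."""

    metric: str
    bin_width_s: float
    values: np.ndarray
    bin_starts_s: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def _runs_above(binary: np.ndarray) -> list[tuple[int, int]]:
    """Half-open maximal runs of True."""
    if not binary.any():
        return []
    padded = np.concatenate([[0], binary.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def merge_runs(runs: list[tuple[int, int]], merge_gap: int) -> list[tuple[int, int]]:
    """Fuse consecutive runs whose separating gap is < ``merge_gap`` frames."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


def detect_bouts(
    motion: MotionTrace,
    centroid: CentroidTrace,
    params: BoutParams | None = None,
) -> list[Bout]:
    """Detect bouts from an aligned (motion, centroid) trace pair.

    Traces must share fps and t0, with ``len(centroid) == len(motion) + 1``
    (one motion value per consecutive frame pair).
    """
    params = params or BoutParams()
    if motion.fps != centroid.fps or not math.isclose(motion.t0, centroid.t0):
        raise ValueError("motion and centroid traces are misaligned (fps/t0)")
    if len(centroid) != len(motion) + 1:
        raise ValueError(
            f"expected len(centroid) == len(motion) + 1, got "
            f"{len(centroid)} vs {len(motion)}"
        )

    active = motion.values > params.motion_on_threshold
    runs = merge_runs(_runs_above(active), params.merge_gap_frames)
    runs = [(s, e) for s, e in runs if e - s >= params.min_bout_frames]

    pts = centroid.interpolated()
    fps = motion.fps
    bouts: list[Bout] = []
    for s, e in runs:
        seg = pts[s:e + 1]  # centroid frames s..e inclusive
        steps = np.linalg.norm(np.diff(seg, axis=0), axis=1)
        if np.isnan(steps).any():  # all-missing centroid trace
            steps = np.zeros_like(steps)
            seg = np.zeros((e - s + 1, 2))
        distance = float(steps.sum())
        displacement = float(np.linalg.norm(seg[-1] - seg[0]))
        duration = (e - s) / fps
        bouts.append(Bout(
            start_frame=s,
            end_frame=e,
            duration_s=duration,
            distance_px=distance,
            displacement_px=min(displacement, distance),
            mean_velocity_px_s=distance / duration,
            peak_velocity_px_s=float(steps.max()) * fps if len(steps) else 0.0,
            delta_pixel_sum=int(motion.values[s:e].sum()),
        ))
    return bouts


def _center_region(well_w: float, well_h: float, area_fraction: float):
    """Concentric rectangle holding ``area_fraction`` of the well area."""
    k = math.sqrt(area_fraction)
    cw, ch = k * well_w, k * well_h
    x0 = (well_w - cw) / 2
    y0 = (well_h - ch) / 2
    return x0, y0, x0 + cw, y0 + ch


def bout_summary_metrics(
    bouts: list[Bout],
    span_s: float,
    centroid: CentroidTrace | None = None,
    well_size: tuple[float, float] | None = None,
    params: BoutParams | None = None,
) -> dict[str, float]:
    """Section-level activity summary.

    Returns bout frequency (bouts/min), active fraction, total/mean
    distance, mean velocity (distance per active second) and — when a
    centroid trace and well size are supplied — the fraction of tracked
    time spent in the concentric well-center region.
    """
    params = params or BoutParams()
    if span_s <= 0:
        raise ValueError("span must be positive")
    total_dur = sum(b.duration_s for b in bouts)
    total_dist = sum(b.distance_px for b in bouts)
    metrics = {
        "bout_frequency_per_min": len(bouts) / (span_s / 60.0),
        "active_fraction": total_dur / span_s,
        "total_distance_px": total_dist,
        "mean_bout_distance_px": total_dist / len(bouts) if bouts else 0.0,
        "mean_bout_duration_s": total_dur / len(bouts) if bouts else 0.0,
        "mean_velocity_px_s": total_dist / total_dur if total_dur > 0 else 0.0,
    }
    if centroid is not None and well_size is not None:
        x0, y0, x1, y1 = _center_region(*well_size, params.center_fraction_defn)
        pts = centroid.points
        good = ~np.isnan(pts).any(axis=1)
        if good.any():
            inside = (
                (pts[good, 0] >= x0) & (pts[good, 0] < x1)
                & (pts[good, 1] >= y0) & (pts[good, 1] < y1)
            )
            metrics["center_fraction"] = float(inside.mean())
        else:
            metrics["center_fraction"] = float("nan")
    return metrics


def sleep_wake_metrics(
    bouts: list[Bout],
    span_s: float,
    fps: float,
    sleep_min_quiescence_s: float = 60.0,
) -> dict[str, float]:
    """Sleep bouts and waking activity over a section.

    A sleep bout is a continuous quiescent interval (between movement
    bouts, or at either end of the section) lasting at least
    ``sleep_min_quiescence_s`` (default 60 s, the standard larval-sleep
    criterion).  Waking activity is active time per awake minute.
    """
    if span_s <= 0:
        raise ValueError("span must be positive")
    edges: list[tuple[float, float]] = []
    t = 0.0
    for b in bouts:
        start = b.start_frame / fps
        if start > t:
            edges.append((t, start))
        t = max(t, b.end_frame / fps)
    if span_s > t:
        edges.append((t, span_s))
    sleep = [(a, b) for a, b in edges if b - a >= sleep_min_quiescence_s]
    sleep_total = sum(b - a for a, b in sleep)
    awake_s = span_s - sleep_total
    active_s = sum(b.duration_s for b in bouts)
    return {
        "sleep_bout_count": float(len(sleep)),
        "sleep_total_s": sleep_total,
        "sleep_fraction": sleep_total / span_s,
        "waking_activity_s_per_min": (
            active_s / (awake_s / 60.0) if awake_s > 0 else 0.0
        ),
    }


def bin_series(
    values: np.ndarray,
    fps: float,
    bin_width_s: float,
    t0: float = 0.0,
    reduce: str = "mean",
    metric: str = "series",
) -> BinnedSeries:
    """Aggregate a per-frame series into fixed-width time bins.

    ``reduce="sum"`` conserves the grand total exactly (the last bin may be
    partial); ``reduce="mean"`` is the time-weighted average, i.e. the bin
    sum divided by the number of frames in the bin.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if bin_width_s <= 0 or fps <= 0:
        raise ValueError("bin_width_s and fps must be positive")
    span = len(values) / fps
    n_bins = int(math.ceil(span / bin_width_s - 1e-12))
    frame_bin = np.minimum(
        (np.arange(len(values)) / fps / bin_width_s).astype(int), n_bins - 1
    )
    sums = np.bincount(frame_bin, weights=values, minlength=n_bins)
    counts = np.bincount(frame_bin, minlength=n_bins)
    if reduce == "sum":
        out = sums
    elif reduce == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(counts > 0, sums / counts, np.nan)
    else:
        raise ValueError(f"unknown reduce {reduce!r}")
    starts = t0 + np.arange(n_bins) * bin_width_s
    return BinnedSeries(metric=metric, bin_width_s=bin_width_s,
                        values=out, bin_starts_s=starts)
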