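"""Ground-truthed synthetic plate experiments.

Real runs come off acquisition hardware; this module replaces the rig
with generators whose statistical structure matches what the analyses
assume, with exact ground truth retained at every level:

* **spontaneous swimming** — a two-state renewal process per fish:
  exponential inter-bout intervals (rate differing between day and
  night), lognormal bout durations, and a correlated random walk within
  bouts that reflects off the well walls.  Bout boundaries in the ground
  truth are frame-accurate.
* **stimulus responses** — Bernoulli trials with a four-parameter
  logistic response probability in log10 intensity, per-modality latency
  distributions, a multiplicative prepulse-inhibition factor on prepulse
  trials, and an exponential habituation decay over repeated stimuli.
* **rendering** — high-speed clips drawn as an ellipse fish (oriented
  along its motion) over a noisy flat background, for exercising the
  tracker; pixel-accurate masks are retained.

Every generator is a pure function of (spec, seed): the same seed always
reproduces the same experiment.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .formats import (
    CentroidTrace,
    EventCommand,
    MotionTrace,
    Roi,
    RoiSet,
    Section,
    SectionsSpec,
    parse_event_string,
    write_centroid_trace,
    write_events_file,
    write_motion_trace,
    write_rois,
    write_sections,
)
from .tracking import FrameStack

__all__ = [
    "SyntheticSpec",
    "GroundTruthBout",
    "simulate_fish_trace",
    "simulate_event_responses",
    "simulate_response_clip_traces",
    "simulate_spontaneous_clip_traces",
    "render_clip",
    "simulate_experiment",
    "acoustic_battery",
]

#: the standard 12-intensity acoustic battery (transducer drive amplitudes)
ACOUSTIC_AMPLITUDES = (0.0005, 0.001, 0.003, 0.0075, 0.01, 0.03,
                       0.06, 0.075, 0.1, 0.3, 0.5, 1.0)


@dataclass
class SyntheticSpec:
    """All knobs of the synthetic experiment.

    Defaults describe a plausible wild-type larva at 5 dpf in a 96-well
    format well: ~15 bouts/min by day and ~3 by night, 0.2-0.4 s bouts,
    and acoustic response probability rising from ~2% to ~95% with an
    EC50 of 13.17 stimulus-power units by day and 31.43 by night (night
    arousal threshold higher).  Clips render at 285 fps for 1 s; slow
    traces at 30 fps.  ``seed`` is mandatory: generation is deterministic.
    """

    seed: int
    n_wells: int = 24
    well_size: tuple[int, int] = (48, 48)
    fps_slow: float = 30.0
    fps_high: float = 285.0
    clip_duration_s: float = 1.0
    # spontaneous swimming
    day_bout_rate_per_min: float = 15.0
    night_bout_rate_per_min: float = 3.0
    bout_duration_log_mean: float = math.log(0.3)
    bout_duration_log_sd: float = 0.35
    bout_speed_px_s: float = 25.0
    turn_sd_deg: float = 25.0
    min_gap_frames: int = 5
    min_bout_frames: int = 3
    active_delta_px_mean: float = 20.0
    # responses; stimulus power = amplitude_a * amplitude_to_power, so the
    # a0.0005..a1 battery spans powers 0.5..1000 on the log axis
    amplitude_to_power: float = 1000.0
    acoustic_ec50: float = 13.17
    acoustic_ec50_night: float = 31.43
    hill_slope: float = 1.5
    p_floor: float = 0.02
    p_ceiling: float = 0.95
    visual_ec50: float = 50.0
    acoustic_latency_log_ms: float = math.log(15.0)
    acoustic_latency_sd: float = 0.4
    visual_latency_log_ms: float = math.log(250.0)
    visual_latency_sd: float = 0.3
    ppi_factor: float = 0.5
    habituation_tau_trials: float = 20.0
    # rendering
    background_level: int = 200
    fish_level: int = 80
    fish_axes_px: tuple[float, float] = (4.0, 2.0)
    imaging_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("day_bout_rate_per_min", "night_bout_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_floor", "p_ceiling", "ppi_factor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent generator for a named sub-stream of the seed."""
        return np.random.default_rng([self.seed, *stream])

    def response_p(self, intensity: float, modality: str = "acoustic",
                   night: bool = False) -> float:
        """Logistic response probability at a stimulus intensity."""
        if modality == "acoustic":
            ec50 = self.acoustic_ec50_night if night else self.acoustic_ec50
        else:
            ec50 = self.visual_ec50
        x = math.log10(intensity)
        return self.p_floor + (self.p_ceiling - self.p_floor) / (
            1.0 + 10.0 ** (self.hill_slope * (math.log10(ec50) - x))
        )


@dataclass
class GroundTruthBout:
    """Frame-accurate bout in the generated trace (motion-frame indexing,
    half-open)."""

    start_frame: int
    end_frame: int


def simulate_fish_trace(
    spec: SyntheticSpec,
    duration_s: float,
    rng: np.random.Generator,
    night_windows: list[tuple[float, float]] | None = None,
    bout_rate_per_min: float | None = None,
) -> tuple[MotionTrace, CentroidTrace, list[GroundTruthBout]]:
    """One fish's slow-speed traces plus the exact bout list.

    Bouts arrive as a renewal process whose rate follows the light
    schedule (``night_windows`` in run seconds), with a hard minimum
    inter-bout gap and minimum bout length in frames so that the ground
    truth is recoverable exactly by the detector at default settings.
    Quiescent frames carry zero delta pixels; active frames draw Poisson
    counts well above the detection floor.
    """
    fps = spec.fps_slow
    n_centroid = int(round(duration_s * fps)) + 1
    n_motion = n_centroid - 1
    night_windows = night_windows or []

    def rate_at(t: float) -> float:
        if bout_rate_per_min is not None:
            return bout_rate_per_min
        for a, b in night_windows:
            if a <= t < b:
                return spec.night_bout_rate_per_min
        return spec.day_bout_rate_per_min

    # --- bout schedule (frame-accurate) -----------------------------------
    bouts: list[GroundTruthBout] = []
    frame = 0
    while frame < n_motion:
        r = rate_at(frame / fps) / 60.0  # per second
        if r <= 0:
            break
        gap_s = rng.exponential(1.0 / r)
        gap_f = max(int(round(gap_s * fps)), spec.min_gap_frames)
        start = frame + gap_f
        dur_s = rng.lognormal(spec.bout_duration_log_mean,
                              spec.bout_duration_log_sd)
        dur_f = max(int(round(dur_s * fps)), spec.min_bout_frames)
        end = start + dur_f
        if end > n_motion:
            break
        bouts.append(GroundTruthBout(start, end))
        frame = end

    # --- traces ------------------------------------------------------------
    motion = np.zeros(n_motion, dtype=np.int64)
    pts = np.zeros((n_centroid, 2))
    w, h = spec.well_size
    margin = 2.0
    pos = np.array([rng.uniform(margin, w - margin),
                    rng.uniform(margin, h - margin)])
    heading = rng.uniform(-math.pi, math.pi)
    pts[0] = pos
    active = np.zeros(n_motion, dtype=bool)
    for b in bouts:
        active[b.start_frame:b.end_frame] = True
    step_len = spec.bout_speed_px_s / fps
    for i in range(n_motion):
        if active[i]:
            heading += math.radians(rng.normal(0.0, spec.turn_sd_deg))
            step = step_len * max(rng.lognormal(0.0, 0.3), 0.1)
            cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
            # reflect off well walls
            for k, lim in enumerate((w, h)):
                if cand[k] < margin:
                    cand[k] = 2 * margin - cand[k]
                    heading = math.pi - heading if k == 0 else -heading
                elif cand[k] > lim - margin:
                    cand[k] = 2 * (lim - margin) - cand[k]
                    heading = math.pi - heading if k == 0 else -heading
            pos = np.clip(cand, margin, [w - margin, h - margin])
            motion[i] = max(int(rng.poisson(spec.active_delta_px_mean)), 3)
        pts[i + 1] = pos
    return (
        MotionTrace(motion, fps=fps),
        CentroidTrace(pts, fps=fps),
        bouts,
    )


def simulate_event_responses(
    spec: SyntheticSpec,
    events: list[EventCommand],
    rng: np.random.Generator,
    night_windows: list[tuple[float, float]] | None = None,
    response_scale: float = 1.0,
) -> list[dict]:
    """Ground-truth trial outcomes for a battery of stimulus events.

    Each event draws Bernoulli(p) with the logistic response model of the
    spec; prepulse (two-delay) acoustic events multiply p by the PPI
    factor; repeated identical stimuli decay exponentially with the
    habituation time constant.  ``response_scale`` scales p overall (for
    implanting group effects).  Returns one record per event:
    ``{event, responded, latency_ms, is_ppi, prepulse_responded}``.
    """
    night_windows = night_windows or []
    seen_counts: dict[str, int] = {}
    out: list[dict] = []
    for ev in events:
        night = any(a <= ev.scheduled_time < b for a, b in night_windows)
        modality = ev.modality
        if modality in ("none",):
            out.append(dict(event=ev, responded=False, latency_ms=float("nan"),
                            is_ppi=False, prepulse_responded=False))
            continue
        if modality in ("acoustic", "mixed"):
            intensity = ev.amplitude_a * spec.amplitude_to_power
            mod = "acoustic"
        else:
            intensity = abs(250 - (ev.light_b or 250)) or 1e-6
            mod = "visual"
        p = spec.response_p(max(intensity, 1e-12), mod, night=night)
        is_ppi = mod == "acoustic" and len(ev.delays_D) >= 2
        prepulse_responded = False
        if is_ppi:
            p *= spec.ppi_factor
            prepulse_responded = bool(rng.random() < 0.05)
        key = ev.raw or ev.to_string()
        k = seen_counts.get(key, 0)
        seen_counts[key] = k + 1
        if spec.habituation_tau_trials > 0:
            p *= math.exp(-k / spec.habituation_tau_trials) \
                if spec.habituation_tau_trials < float("inf") else 1.0
        p = min(max(p * response_scale, 0.0), 1.0)
        responded = bool(rng.random() < p)
        if responded:
            if mod == "acoustic":
                lat = rng.lognormal(spec.acoustic_latency_log_ms,
                                    spec.acoustic_latency_sd)
            else:
                lat = rng.lognormal(spec.visual_latency_log_ms,
                                    spec.visual_latency_sd)
        else:
            lat = float("nan")
        out.append(dict(event=ev, responded=responded, latency_ms=lat,
                        is_ppi=is_ppi, prepulse_responded=prepulse_responded))
    return out


def simulate_response_clip_traces(
    spec: SyntheticSpec,
    responded: bool,
    latency_ms: float,
    rng: np.random.Generator,
    onset_frame: int = 0,
    turn_total_deg: float = 0.0,
) -> tuple[MotionTrace, CentroidTrace, np.ndarray]:
    """High-speed (285 fps, 1 s) traces for one stimulus presentation.

    A responding fish starts a burst ``latency_ms`` after the stimulus
    onset: ~12 frames of fast movement with the requested total signed
    turn (0 for a straight escape dash), high delta pixels during the
    burst.  Returns (motion, centroid, ground-truth trajectory).
    """
    fps = spec.fps_high
    n_centroid = int(round(spec.clip_duration_s * fps)) + 1
    n_motion = n_centroid - 1
    w, h = spec.well_size
    pts = np.zeros((n_centroid, 2))
    motion = np.zeros(n_motion, dtype=np.int64)
    pos = np.array([w / 2.0, h / 2.0]) + rng.normal(0, 1.5, size=2)
    heading = rng.uniform(-math.pi, math.pi)
    pts[0] = pos
    burst_frames = 12
    start = None
    if responded:
        start = onset_frame + int(round(latency_ms / 1000.0 * fps))
        start = min(start, n_motion - burst_frames)
    margin = 2.0
    for i in range(n_motion):
        in_burst = responded and start is not None and start <= i < start + burst_frames
        if in_burst:
            heading += math.radians(turn_total_deg / burst_frames)
            step = 2.0 * max(rng.lognormal(0.0, 0.2), 0.3)
            cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
            for k, lim in enumerate((w, h)):
                if cand[k] < margin or cand[k] > lim - margin:
                    heading = math.pi - heading if k == 0 else -heading
                    cand[k] = np.clip(cand[k], margin, lim - margin)
            pos = cand
            motion[i] = max(int(rng.poisson(15.0)), 4)
        pts[i + 1] = pos
    return MotionTrace(motion, fps=fps), CentroidTrace(pts, fps=fps), pts


def simulate_spontaneous_clip_traces(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    p_move: float = 0.3,
) -> tuple[MotionTrace, CentroidTrace, np.ndarray]:
    """High-speed traces of a fish receiving no stimulus.

    Most clips are still; with probability ``p_move`` the fish performs
    one routine swim bout (slow, gently turning — nothing like an escape
    burst) at a random time.  Used to validate that startle-response
    filters stay silent on spontaneous movement.
    """
    fps = spec.fps_high
    n_centroid = int(round(spec.clip_duration_s * fps)) + 1
    n_motion = n_centroid - 1
    w, h = spec.well_size
    margin = 6.0
    # interior start: a routine bout is short enough not to reach a wall
    pos = np.array([rng.uniform(w * 0.3, w * 0.7),
                    rng.uniform(h * 0.3, h * 0.7)])
    pts = np.tile(pos, (n_centroid, 1))
    motion = np.zeros(n_motion, dtype=np.int64)
    if rng.random() < p_move:
        dur = int(rng.integers(6, 15))
        start = int(rng.integers(0, n_motion - dur))
        heading = rng.uniform(-math.pi, math.pi)
        turn_per_frame = math.radians(rng.normal(0.0, spec.turn_sd_deg)) / dur
        for i in range(start, start + dur):
            heading += turn_per_frame
            step = 1.2 * max(rng.lognormal(0.0, 0.2), 0.3)
            cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
            pos = np.clip(cand, margin, [w - margin, h - margin])
            motion[i] = max(int(rng.poisson(8.0)), 4)
            pts[i + 1:] = pos
    return MotionTrace(motion, fps=fps), CentroidTrace(pts, fps=fps), pts


def render_clip(
    trajectory: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    headings: np.ndarray | None = None,
) -> tuple[FrameStack, np.ndarray]:
    """Render a trajectory as a high-speed clip of one well.

    The fish is a dark ellipse (axes from the spec) on a
    flat background with Gaussian imaging noise; a ``NaN`` row in the
    trajectory renders an empty frame.  Returns the stack and the boolean
    fish mask per frame (pixel-level ground truth).
    """
    from skimage.draw import ellipse

    w, h = spec.well_size
    n = len(trajectory)
    frames = np.empty((n, h, w), dtype=np.uint8)
    masks = np.zeros((n, h, w), dtype=bool)
    a, b = spec.fish_axes_px
    for i, (x, y) in enumerate(np.asarray(trajectory, dtype=float)):
        bg = np.full((h, w), float(spec.background_level))
        if not (math.isnan(x) or math.isnan(y)):
            if headings is not None:
                rot = headings[i]
            elif i + 1 < n and not np.isnan(trajectory[i + 1]).any():
                d = trajectory[i + 1] - trajectory[i]
                rot = math.atan2(d[1], d[0]) if np.linalg.norm(d) > 1e-6 else 0.0
            else:
                rot = 0.0
            rr, cc = ellipse(y, x, b, a, shape=(h, w), rotation=-rot)
            bg[rr, cc] = spec.fish_level
            masks[i, rr, cc] = True
        # sensor noise applies to fish and background alike, so neither
        # occupies a single intensity bin in the per-pixel histogram
        bg += rng.normal(0.0, spec.imaging_noise_sd, (h, w))
        frames[i] = np.clip(bg, 0, 255).astype(np.uint8)
    return FrameStack(frames, fps=spec.fps_high), masks


def acoustic_battery(
    n_repeats: int,
    interval_s: float = 120.0,
    amplitudes: tuple[float, ...] = ACOUSTIC_AMPLITUDES,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> list[EventCommand]:
    """The standard dose-response battery: every amplitude ``n_repeats``
    times in randomized order at fixed intervals (default 2 min)."""
    order = list(amplitudes) * n_repeats
    if rng is not None:
        perm = rng.permutation(len(order))
        order = [order[i] for i in perm]
    events = []
    for i, a in enumerate(order):
        s = f"a{a}f625d20"
        events.append(parse_event_string(s, scheduled_time=t0 + i * interval_s))
    return events


@dataclass
class SimulatedExperiment:
    """Paths and ground truth of one on-disk synthetic dataset."""

    root: Path
    rois_path: Path
    events_path: Path
    sections_path: Path
    platemap_path: Path
    manifest_path: Path
    manifest: dict


def simulate_experiment(
    spec: SyntheticSpec,
    out_dir: str | Path,
    duration_s: float = 600.0,
    groups: dict[str, float] | None = None,
    events: list[EventCommand] | None = None,
    sections: SectionsSpec | None = None,
    night_windows: list[tuple[float, float]] | None = None,
    bout_rate_scales: dict[str, float] | None = None,
) -> SimulatedExperiment:
    """Write a complete, byte-valid synthetic dataset to ``out_dir``.

    ``groups`` maps group label -> response-probability scale (1.0 =
    baseline); wells alternate between groups column-interleaved, the
    standard plate layout for two-group screens.  ``bout_rate_scales``
    scales the spontaneous bout rate per group (for implanted baseline
    effects).  Slow traces, one high-speed trace pair per (well, event),
    ROI/events/sections/plate-map files and a ground-truth manifest are
    written; the dataset is a pure function of ``spec.seed``.
    """
    out = Path(out_dir)
    (out / "slow").mkdir(parents=True, exist_ok=True)
    (out / "hs").mkdir(exist_ok=True)
    groups = groups or {"group1": 1.0, "group2": 1.0}
    group_names = list(groups)
    bout_rate_scales = bout_rate_scales or {}

    n = spec.n_wells
    cols = max(int(math.ceil(math.sqrt(n * 1.5))), 1)
    rows = int(math.ceil(n / cols))
    rois = RoiSet.grid(rows=rows, cols=cols, well_width=spec.well_size[0],
                       well_height=spec.well_size[1],
                       plate_format=f"{n}-well synthetic")
    rois = RoiSet(rois.rois[:n], plate_format=rois.plate_format)

    if events is None:
        ev_rng = spec.rng(0)
        events = acoustic_battery(n_repeats=2, interval_s=60.0, rng=ev_rng,
                                  t0=30.0)
        events = [e for e in events if e.scheduled_time < duration_s - 1]
    if sections is None:
        sections = SectionsSpec([
            Section("baseline", 0.0, duration_s, "time"),
            Section("acoustic_all", 0.0, duration_s, "event"),
        ])

    # column-interleaved plate map
    platemap: dict[str, str] = {}
    for idx, roi in enumerate(rois):
        col = idx % cols
        platemap[roi.well_id] = group_names[col % len(group_names)]

    manifest: dict = {
        "seed": spec.seed,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "duration_s": duration_s,
        "groups": groups,
        "bout_rate_scales": bout_rate_scales,
        "night_windows": [list(w) for w in (night_windows or [])],
        "wells": {},
    }

    for idx, roi in enumerate(rois):
        gname = platemap[roi.well_id]
        rscale = groups[gname]
        bscale = bout_rate_scales.get(gname, 1.0)
        rng = spec.rng(1, idx)
        rate = spec.day_bout_rate_per_min * bscale
        motion, centroid, truth_bouts = simulate_fish_trace(
            spec, duration_s, rng,
            night_windows=night_windows,
            bout_rate_per_min=rate if (bscale != 1.0 or not night_windows)
            else None,
        )
        write_motion_trace(out / "slow" / f"{roi.well_id}_motion.csv", motion)
        write_centroid_trace(out / "slow" / f"{roi.well_id}_centroid.csv",
                             centroid)
        ev_rng = spec.rng(2, idx)
        trials = simulate_event_responses(
            spec, events, ev_rng, night_windows=night_windows,
            response_scale=rscale,
        )
        clip_rng = spec.rng(3, idx)
        well_truth = {"group": gname,
                      "bouts": [[b.start_frame, b.end_frame]
                                for b in truth_bouts],
                      "trials": []}
        for j, tr in enumerate(trials):
            mod = tr["event"].modality
            turn = 0.0
            if tr["responded"]:
                turn = float(clip_rng.normal(120.0, 30.0)) \
                    if mod == "visual" else float(clip_rng.normal(0.0, 20.0))
            m, c, _ = simulate_response_clip_traces(
                spec, tr["responded"],
                tr["latency_ms"] if tr["responded"] else 0.0,
                clip_rng, turn_total_deg=turn,
            )
            stem = f"{roi.well_id}_ev{j:03d}"
            write_motion_trace(out / "hs" / f"{stem}_motion.csv", m)
            write_centroid_trace(out / "hs" / f"{stem}_centroid.csv", c)
            well_truth["trials"].append({
                "event_index": j,
                "time_s": tr["event"].scheduled_time,
                "responded": tr["responded"],
                "latency_ms": None if math.isnan(tr["latency_ms"])
                else tr["latency_ms"],
                "is_ppi": tr["is_ppi"],
                "prepulse_responded": tr["prepulse_responded"],
            })
        manifest["wells"][roi.well_id] = well_truth

    write_rois(out / "rois.csv", rois)
    write_events_file(out / "events.csv", events)
    write_sections(out / "sections.csv", sections)
    with (out / "platemap.csv").open("w") as fh:
        fh.write("well_id,group\n")
        for wid, g in platemap.items():
            fh.write(f"{wid},{g}\n")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return SimulatedExperiment(
        root=out,
        rois_path=out / "rois.csv",
        events_path=out / "events.csv",
        sections_path=out / "sections.csv",
        platemap_path=out / "platemap.csv",
        manifest_path=manifest_path,
        manifest=manifest,
    )
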