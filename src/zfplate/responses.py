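"""Stimulus-response detection and classification on 285-fps clips.

A response to a stimulus is scored inside a modality-dependent window
after stimulus onset.  Two independent rules can trigger a response:

* **distance rule** — the centroid moves more than ``distance_threshold_px``
  (0.9 px) per frame for at least ``distance_frames`` (2) consecutive
  frame steps;
* **delta-pixel rule** — the motion trace exceeds
  ``delta_pixel_threshold`` (3.0) for at least ``delta_pixel_frames`` (3)
  consecutive frames.

Thresholds use strict ``>``; run lengths use ``>=``.  Latency is the first
frame (relative to onset) of the earliest qualifying run under either rule.

Bulk responses are further filtered into putative response types:
*C-bends* (the fast acoustic startle, short latency and high velocity) by
cumulative delta pixels and mean velocity, and *O-bends* (the slower,
large-turn dark-flash response) by latency window and the magnitude of the
summed signed heading change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats import CentroidTrace, EventCommand, MotionTrace

__all__ = [
    "ResponseParams",
    "ResponseFilters",
    "ResponseEvent",
    "stimulus_onset_frame",
    "detect_response",
    "heading_angle_sum",
    "classify_c_bend",
    "classify_o_bend",
    "classify_response",
]

#: response windows in frames after onset, by stimulus modality
DEFAULT_WINDOWS = {"acoustic": 100, "visual": None, "mixed": None, "none": None}


@dataclass
class ResponseParams:
    """Response-scoring thresholds.

    Defaults are the standard operating values for 285-fps clips:
    0.9 px movement over >= 2 frames, or 3.0 delta pixels over >= 3
    frames.  ``response_window_frames`` maps modality to the number of
    frames scored after onset (``None`` = to the end of the clip; acoustic
    startles are scored in the first 100 frames, ~350 ms, while dark-flash
    responses may occur anywhere in the clip).
    """

    distance_threshold_px: float = 0.9
    delta_pixel_threshold: float = 3.0
    distance_frames: int = 2
    delta_pixel_frames: int = 3
    response_window_frames: dict | None = None
    heading_min_step_px: float = 0.25

    def __post_init__(self) -> None:
        if min(self.distance_threshold_px, self.delta_pixel_threshold,
               self.distance_frames, self.delta_pixel_frames) <= 0:
            raise ValueError("response parameters must be positive")
        if self.response_window_frames is None:
            self.response_window_frames = dict(DEFAULT_WINDOWS)

    def window_for(self, modality: str, n_frames: int) -> int:
        w = self.response_window_frames.get(modality, None)
        return n_frames if w is None else int(w)


@dataclass
class ResponseFilters:
    """Cutoffs separating putative C-bends and O-bends from bulk responses.

    All comparisons are inclusive (``>=``, and latency within a closed
    interval).  Defaults were calibrated on simulated clips and are
    expected to be re-tuned per rig.
    """

    c_dp_min: float = 75.0
    c_vel_min: float = 40.0
    o_lat_min_frames: int = 43
    o_lat_max_frames: int = 285
    o_angle_min_deg: float = 90.0


@dataclass
class ResponseEvent:
    """Scored outcome of one stimulus presentation for one fish."""

    responded: bool
    latency_frames: int = -1
    latency_ms: float = float("nan")
    distance_px: float = 0.0
    displacement_px: float = 0.0
    cumulative_delta_pixels: int = 0
    mean_velocity_px_s: float = 0.0
    heading_angle_sum_deg: float = 0.0
    classification: str = "none"

    def __post_init__(self) -> None:
        if self.responded and self.latency_frames < 0:
            raise ValueError("responded event must have latency >= 0")


def stimulus_onset_frame(event: EventCommand, fps: float) -> int:
    """Frame of stimulus onset within the clip.

    The first delay in the command string positions the stimulus inside
    the 1-s recording; with no delay the stimulus is taken to fire at
    frame 0.  For paired-stimulus (prepulse) commands the last delay marks
    the strong stimulus; callers scoring the prepulse itself should pass
    an explicit onset to :func:`detect_response`.
    """
    if not event.delays_D:
        return 0
    return int(round(event.delays_D[-1] / 1000.0 * fps))


def _qualifying_runs(values: np.ndarray, threshold: float, min_len: int) -> int:
    """First index of a run of >= min_len values strictly above threshold,
    or -1."""
    above = values > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_len:
            return i - min_len + 1
    return -1


def detect_response(
    motion: MotionTrace,
    centroid: CentroidTrace,
    event: EventCommand,
    params: ResponseParams | None = None,
    onset_frame: int | None = None,
) -> ResponseEvent:
    """Score one stimulus presentation from a high-speed clip's traces.

    Kinematic metrics (distance, displacement, cumulative delta pixels,
    velocity, heading-angle sum) are computed from the first qualifying
    frame to the end of the response window.  A clip shorter than the
    window triggers a truncated-window warning and is scored on the
    available frames.
    """
    params = params or ResponseParams()
    if motion.fps != centroid.fps:
        raise ValueError("motion and centroid traces are misaligned (fps)")
    onset = stimulus_onset_frame(event, motion.fps) if onset_frame is None \
        else int(onset_frame)
    window = params.window_for(event.modality, len(motion))
    end = onset + window
    if end > len(motion):
        warnings.warn(
            f"clip shorter than response window ({len(motion)} < {end} frames); "
            "scoring truncated window", stacklevel=2,
        )
        end = len(motion)
    if onset >= len(motion):
        return ResponseEvent(responded=False)

    pts = centroid.interpolated()
    # step i is the movement between centroid frames i and i+1, matching
    # the indexing of motion value i
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    win_motion = motion.values[onset:end].astype(float)
    win_steps = steps[onset:min(end, len(steps))]
    if np.isnan(win_steps).any():
        win_steps = np.zeros(0)

    lat_dist = _qualifying_runs(win_steps, params.distance_threshold_px,
                                params.distance_frames)
    lat_dp = _qualifying_runs(win_motion, params.delta_pixel_threshold,
                              params.delta_pixel_frames)
    latencies = [l for l in (lat_dist, lat_dp) if l >= 0]
    if not latencies:
        return ResponseEvent(responded=False)

    latency = min(latencies)
    seg0 = onset + latency
    seg_pts = pts[seg0:end + 1]
    seg_steps = np.linalg.norm(np.diff(seg_pts, axis=0), axis=1)
    if np.isnan(seg_steps).any():
        seg_steps = np.zeros_like(seg_steps)
        seg_pts = np.zeros((len(seg_pts), 2))
    distance = float(seg_steps.sum())
    displacement = float(np.linalg.norm(seg_pts[-1] - seg_pts[0])) \
        if len(seg_pts) else 0.0
    seg_dur = max(end - seg0, 1) / motion.fps
    return ResponseEvent(
        responded=True,
        latency_frames=latency,
        latency_ms=latency / motion.fps * 1000.0,
        distance_px=distance,
        displacement_px=min(displacement, distance),
        cumulative_delta_pixels=int(motion.values[seg0:end].sum()),
        mean_velocity_px_s=distance / seg_dur,
        heading_angle_sum_deg=heading_angle_sum(
            seg_pts, min_step_px=params.heading_min_step_px
        ),
    )


def heading_angle_sum(points: np.ndarray, min_step_px: float = 0.25) -> float:
    """Signed sum of successive heading changes along a trajectory, degrees.

    Headings come from consecutive displacement vectors; steps shorter
    than ``min_step_px`` are skipped as positional noise.  Each turn is
    the signed angle between successive kept headings, wrapped to
    (-180, 180]; a straight path sums to 0, a full counterclockwise loop
    to +360 minus the final closing turn.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    vecs = np.diff(pts, axis=0)
    lengths = np.linalg.norm(vecs, axis=1)
    vecs = vecs[lengths >= min_step_px]
    if len(vecs) < 2:
        return 0.0
    headings = np.degrees(np.arctan2(vecs[:, 1], vecs[:, 0]))
    turns = np.diff(headings)
    turns = (turns + 180.0) % 360.0 - 180.0
    turns[turns == -180.0] = 180.0  # wrap to (-180, 180]
    return float(turns.sum())


def classify_c_bend(resp: ResponseEvent,
                    filters: ResponseFilters | None = None) -> bool:
    """Putative C-bend: responded with both high cumulative delta pixels
    and high mean velocity (inclusive cutoffs)."""
    filters = filters or ResponseFilters()
    return bool(
        resp.responded
        and resp.cumulative_delta_pixels >= filters.c_dp_min
        and resp.mean_velocity_px_s >= filters.c_vel_min
    )


def classify_o_bend(resp: ResponseEvent,
                    filters: ResponseFilters | None = None) -> bool:
    """Putative O-bend: responded within the dark-flash latency window
    with a large summed heading change (inclusive cutoffs)."""
    filters = filters or ResponseFilters()
    return bool(
        resp.responded
        and filters.o_lat_min_frames <= resp.latency_frames
        <= filters.o_lat_max_frames
        and abs(resp.heading_angle_sum_deg) >= filters.o_angle_min_deg
    )


def classify_response(resp: ResponseEvent,
                      filters: ResponseFilters | None = None) -> str:
    """Assign ``none`` / ``putative_C_bend`` / ``putative_O_bend`` / ``other``.

    A response passing both filters is labelled a C-bend (the faster,
    more stereotyped movement dominates).
    """
    if not resp.responded:
        return "none"
    if classify_c_bend(resp, filters):
        return "putative_C_bend"
    if classify_o_bend(resp, filters):
        return "putative_O_bend"
    return "other"
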