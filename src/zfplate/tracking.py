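"""High-speed clip tracking: mode-image background subtraction and centroids.

Each 1-s, 285-fps clip is reduced to a per-well pair of traces: a
:class:`~zfplate.formats.MotionTrace` of delta-pixel counts and a
:class:`~zfplate.formats.CentroidTrace` of fish positions.  The background
of a clip is estimated as the per-pixel *mode* across frames — the fish is
small and moving, so for each pixel the modal intensity is the empty-well
intensity — and the fish is segmented frame by frame as the largest
connected component of the absolute difference from that mode image.

Movies are read either from a directory of ordered grayscale PNG/TIFF
frames (the canonical interchange format here) or from an AVI when the
runtime has a codec plugin able to decode it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .formats import CentroidTrace, FormatError, MotionTrace, Roi, RoiSet

__all__ = [
    "FrameStack",
    "TrackingParams",
    "compute_mode_image",
    "segment_fish",
    "frame_delta_pixels",
    "track_clip",
]


@dataclass
class FrameStack:
    """An ordered stack of same-size grayscale uint8 frames."""

    frames: np.ndarray  # (n, h, w) uint8
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError("frame stack must be (n_frames, height, width)")
        if self.frames.dtype != np.uint8:
            raise FormatError(f"frames must be uint8, got {self.frames.dtype}")
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of one frame."""
        return self.frames.shape[1:]

    @classmethod
    def from_directory(cls, path: str | Path, fps: float = 285.0) -> "FrameStack":
        """Load a clip from a directory of lexically ordered image frames."""
        import imageio.v3 as iio

        path = Path(path)
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FormatError(f"no image frames found in {path}")
        frames = []
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # RGB(A) -> luma
                img = img[..., :3].mean(axis=-1)
            frames.append(np.asarray(img, dtype=np.uint8))
        stack = np.stack(frames)
        return cls(stack, fps=fps)

    @classmethod
    def from_avi(cls, path: str | Path, fps: float = 285.0) -> "FrameStack":
        """Load a clip from an AVI movie, if a decoding plugin is available."""
        import imageio.v3 as iio

        path = Path(path)
        try:
            frames = iio.imread(path, index=None)
        except Exception as e:  # codec availability varies by install
            raise FormatError(
                f"cannot decode movie {path}: {e}. Install an imageio ffmpeg "
                "plugin or supply the clip as a frame directory."
            ) from e
        frames = np.asarray(frames)
        if frames.ndim == 4:
            frames = frames[..., :3].mean(axis=-1)
        return cls(frames.astype(np.uint8), fps=fps)

    @classmethod
    def load(cls, path: str | Path, fps: float = 285.0) -> "FrameStack":
        path = Path(path)
        if path.is_dir():
            return cls.from_directory(path, fps=fps)
        return cls.from_avi(path, fps=fps)


@dataclass
class TrackingParams:
    """Free parameters of segmentation and motion counting.

    ``intensity_diff_threshold`` is the uint8 noise floor applied both to
    background-vs-frame differences (segmentation) and frame-vs-frame
    differences (delta pixels); comparisons are strict (``> threshold``).
    ``min_blob_area`` discards speckle components; ``mode_sample_stride``
    subsamples frames when estimating the mode image.
    """

    intensity_diff_threshold: int = 12
    min_blob_area: int = 4
    mode_sample_stride: int = 1

    def __post_init__(self) -> None:
        if self.intensity_diff_threshold <= 0:
            raise ValueError("intensity_diff_threshold must be positive")
        if self.min_blob_area <= 0:
            raise ValueError("min_blob_area must be positive")
        if self.mode_sample_stride <= 0:
            raise ValueError("mode_sample_stride must be positive")


def compute_mode_image(stack: FrameStack, stride: int | None = None) -> np.ndarray:
    """Per-pixel modal intensity across (stride-sampled) frames.

    Ties are broken toward the lowest intensity among the tied values.
    Returns a uint8 image of the stack's frame shape.
    """
    stride = 1 if stride is None else int(stride)
    if stride <= 0:
        raise ValueError("stride must be positive")
    frames = stack.frames[::stride]
    if frames.shape[0] == 0:
        raise ValueError("no frames sampled for mode computation")
    h, w = frames.shape[1:]
    counts = np.zeros((256, h, w), dtype=np.int32)
    rows, cols = np.indices((h, w))
    for frame in frames:
        np.add.at(counts, (frame, rows, cols), 1)
    # argmax returns the first maximal bin, i.e. the lowest tied intensity
    return counts.argmax(axis=0).astype(np.uint8)


_EIGHT_CONN = np.ones((3, 3), dtype=int)


def _component_stats(mask: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    return labels, n


def segment_fish(
    frame: np.ndarray,
    mode_image: np.ndarray,
    roi: Roi,
    params: TrackingParams,
) -> tuple[tuple[float, float] | None, int, np.ndarray]:
    """Segment the fish in one ROI of one frame.

    Thresholds ``|frame - mode|`` (so the fish may be darker or brighter
    than the background), keeps 8-connected components of at least
    ``min_blob_area`` pixels, and selects the largest (ties broken by the
    smallest ``(y, x)`` top-left bounding-box corner).  Returns
    ``(centroid, blob_area, mask)`` where ``centroid`` is the unweighted
    mean of member-pixel coordinates as ROI-relative ``(x, y)``, or
    ``None`` when no component qualifies (an empty-looking well is a
    value, not an error).
    """
    if frame.shape != mode_image.shape:
        raise ValueError("frame and mode image differ in shape")
    ys, xs = roi.slices()
    sub = frame[ys, xs].astype(np.int16)
    bg = mode_image[ys, xs].astype(np.int16)
    mask = np.abs(sub - bg) > params.intensity_diff_threshold

    labels, n = _component_stats(mask)
    if n == 0:
        return None, 0, mask
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= params.min_blob_area) + 1
    if len(keep) == 0:
        return None, 0, np.zeros_like(mask)
    best_area = areas[keep - 1].max()
    tied = keep[areas[keep - 1] == best_area]
    if len(tied) > 1:
        corners = []
        for lab in tied:
            rr, cc = np.nonzero(labels == lab)
            corners.append((rr.min(), cc.min()))
        tied = [lab for _, lab in sorted(zip(corners, tied))]
    chosen = int(tied[0])
    blob = labels == chosen
    rr, cc = np.nonzero(blob)
    centroid = (float(cc.mean()), float(rr.mean()))  # (x, y), ROI-relative
    return centroid, int(best_area), blob


def frame_delta_pixels(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    roi: Roi,
    params: TrackingParams,
) -> int:
    """Count ROI pixels whose intensity changes by strictly more than the
    noise floor between consecutive frames."""
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames differ in shape")
    ys, xs = roi.slices()
    diff = np.abs(frame_t1[ys, xs].astype(np.int16) - frame_t[ys, xs].astype(np.int16))
    return int(np.count_nonzero(diff > params.intensity_diff_threshold))


def track_clip(
    stack: FrameStack,
    rois: RoiSet | Roi,
    params: TrackingParams | None = None,
) -> dict[str, tuple[MotionTrace, CentroidTrace]]:
    """Track every ROI of a clip.

    Returns an ordered ``{well_id: (MotionTrace, CentroidTrace)}`` map.
    The centroid trace has one point per frame (NaN where no fish was
    found); the motion trace has ``n_frames - 1`` values.  Tracking is a
    deterministic function of the input bytes.
    """
    params = params or TrackingParams()
    if isinstance(rois, Roi):
        rois = RoiSet([rois], plate_format="single")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to compute motion")
    rois.validate_against_frame(stack.shape)
    mode_img = compute_mode_image(stack, stride=params.mode_sample_stride)

    out: dict[str, tuple[MotionTrace, CentroidTrace]] = {}
    for roi in rois:
        pts = np.full((stack.n_frames, 2), np.nan)
        motion = np.zeros(stack.n_frames - 1, dtype=np.int64)
        for i, frame in enumerate(stack.frames):
            centroid, _, _ = segment_fish(frame, mode_img, roi, params)
            if centroid is not None:
                pts[i] = centroid
            if i > 0:
                motion[i - 1] = frame_delta_pixels(
                    stack.frames[i - 1], frame, roi, params
                )
        out[roi.well_id] = (
            MotionTrace(motion, fps=stack.fps),
            CentroidTrace(pts, fps=stack.fps),
        )
    return out
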