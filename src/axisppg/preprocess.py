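"""From raw video + label stream to network-ready windows.

The pipeline is: per-frame face localisation (pluggable detector with a
carry-forward fallback), crop + bilinear resize to a square input, label
resampling to the video frame rate, and non-overlapping slicing into
``T``-frame windows with aligned length-``T`` targets.

No trained frontal-face detector ships with the package; the detector
surface accepts ``fixed`` (a known bounding box, the natural choice for
synthetic clips), ``full_frame``, or ``intensity`` — a brightness-based
region finder that boxes the dominant bright blob, which is exactly what the
synthetic ellipse is.  Any object with a ``detect(frame) -> BBox | None``
method plugs in the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthetic import GroundTruthPPG, VideoClip

__all__ = [
    "BBox", "WindowedSample", "FixedDetector", "FullFrameDetector",
    "IntensityDetector", "make_detector", "detect_face_bbox", "crop_resize",
    "resample_labels", "window_clip", "preprocess_clip",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BBox:
    """0-based, half-open pixel box."""

    left: int
    top: int
    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("BBox width/height must be positive")

    def clipped(self, frame_h: int, frame_w: int) -> "BBox":
        left = max(0, min(self.left, frame_w - 1))
        top = max(0, min(self.top, frame_h - 1))
        right = max(left + 1, min(self.left + self.width, frame_w))
        bottom = max(top + 1, min(self.top + self.height, frame_h))
        return BBox(left, top, right - left, bottom - top)


@dataclass(frozen=True)
class WindowedSample:
    video: np.ndarray   # (3, T, H, W) in [0, 1]
    target: np.ndarray  # (T,)
    fps: float

    def __post_init__(self):
        if self.video.ndim != 4 or self.video.shape[0] != 3:
            raise ValueError("video must be (3, T, H, W)")
        if len(self.target) != self.video.shape[1]:
            raise ValueError("target length must equal T")


class FixedDetector:
    def __init__(self, bbox: BBox):
        self.bbox = bbox

    def detect(self, frame: np.ndarray) -> BBox:
        return self.bbox


class FullFrameDetector:
    def detect(self, frame: np.ndarray) -> BBox:
        h, w = frame.shape[:2]
        return BBox(0, 0, w, h)


class IntensityDetector:
    """Box the dominant bright region (pixels above a luminance threshold)."""

    def __init__(self, rel_threshold: float = 0.5, min_pixels: int = 16):
        self.rel_threshold = rel_threshold
        self.min_pixels = min_pixels

    def detect(self, frame: np.ndarray) -> BBox | None:
        luma = frame.mean(axis=-1) if frame.ndim == 3 else frame
        lo, hi = luma.min(), luma.max()
        if hi - lo < 1e-6:
            return None
        mask = luma >= lo + self.rel_threshold * (hi - lo)
        if mask.sum() < self.min_pixels:
            return None
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        return BBox(int(cols[0]), int(rows[0]),
                    int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1))


def make_detector(kind: str = "intensity", bbox: BBox | None = None):
    if kind == "fixed":
        if bbox is None:
            raise ValueError("fixed detector needs a bbox")
        return FixedDetector(bbox)
    if kind == "full_frame":
        return FullFrameDetector()
    if kind == "intensity":
        return IntensityDetector()
    raise ValueError(f"unknown detector kind: {kind}")


def detect_face_bbox(frame: np.ndarray, detector, last_bbox: BBox | None = None) -> BBox:
    """Run the detector with the fallback contract.

    Detection failure returns ``last_bbox`` if one exists, otherwise the full
    frame.  The returned box is clipped to the frame.
    """
    h, w = frame.shape[:2]
    bbox = detector.detect(frame)
    if bbox is None:
        bbox = last_bbox if last_bbox is not None else BBox(0, 0, w, h)
    return bbox.clipped(h, w)


def crop_resize(frame: np.ndarray, bbox: BBox, size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Bilinear-resized crop; intensities stay in [0, 1]."""
    h, w = frame.shape[:2]
    bbox = bbox.clipped(h, w)
    crop = frame[bbox.top:bbox.top + bbox.height, bbox.left:bbox.left + bbox.width]
    if crop.shape[0] == size[0] and crop.shape[1] == size[1]:
        return crop.astype(float)
    out_shape = size + crop.shape[2:]
    out = _sk_resize(crop.astype(float), out_shape, order=1,
                     anti_aliasing=False, preserve_range=True, mode="edge")
    return np.clip(out, 0.0, 1.0)


def resample_labels(signal: np.ndarray, src_rate: float, dst_rate: float) -> np.ndarray:
    """Linear interpolation onto the destination rate's sample grid.

    Output length is ``floor(duration * dst_rate)`` with
    ``duration = len(signal) / src_rate``; both grids start at t = 0.
    """
    if src_rate <= 0 or dst_rate <= 0:
        raise ValueError("rates must be positive")
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise ValueError("labels must be finite")
    if src_rate == dst_rate:
        return signal.copy()
    duration = len(signal) / src_rate
    n_out = int(np.floor(duration * dst_rate))
    t_src = np.arange(len(signal)) / src_rate
    t_dst = np.arange(n_out) / dst_rate
    return np.interp(t_dst, t_src, signal)


def window_clip(frames: np.ndarray, labels: np.ndarray, fps: float,
                T: int = 32, stride: int | None = None) -> list[WindowedSample]:
    """Cut aligned frames/labels into consecutive ``T``-frame windows.

    ``frames`` is (N, H, W, 3) already cropped/resized; ``labels`` must be at
    video rate.  Trailing excess of either stream is truncated; windows are
    non-overlapping by default (``stride = T``), the remainder shorter than
    ``T`` is dropped.  Each sample's target is the matching label slice.
    """
    stride = stride or T
    n = min(len(frames), len(labels))
    if n < T:
        logger.warning("window_clip: %d frames < window length %d; no windows", n, T)
        return []
    samples = []
    for start in range(0, n - T + 1, stride):
        win = frames[start:start + T]
        samples.append(WindowedSample(
            video=np.ascontiguousarray(win.transpose(3, 0, 1, 2)),
            target=np.asarray(labels[start:start + T], dtype=float),
            fps=fps))
    return samples


def standardize(signal: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance copy (safe for constant input)."""
    signal = np.asarray(signal, dtype=float)
    sd = signal.std()
    if sd == 0:
        return np.zeros_like(signal)
    return (signal - signal.mean()) / sd


def preprocess_clip(clip: VideoClip, labels: GroundTruthPPG, *,
                    T: int = 32, size: int = 128, stride: int | None = None,
                    detector="intensity", fixed_bbox: BBox | None = None,
                    standardize_targets: bool = True) -> list[WindowedSample]:
    """Full pipeline for one clip: detect, crop, resize, resample, window.

    Per-window targets are standardised by default — the Pearson loss is
    scale-invariant but the spectral amplitude term is not, and a fixed
    target scale makes it well-posed.  Pass ``standardize_targets=False``
    for raw label slices.
    """
    if isinstance(detector, str):
        detector = make_detector(detector, fixed_bbox)
    processed = np.empty((clip.n_frames, size, size, 3), dtype=float)
    last: BBox | None = None
    for k in range(clip.n_frames):
        last = detect_face_bbox(clip.frames[k], detector, last)
        processed[k] = crop_resize(clip.frames[k], last, (size, size))
    labels_fps = resample_labels(labels.samples, labels.rate, clip.fps)
    samples = window_clip(processed, labels_fps, clip.fps, T=T, stride=stride)
    if standardize_targets:
        samples = [WindowedSample(s.video, standardize(s.target), s.fps) for s in samples]
    return samples
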