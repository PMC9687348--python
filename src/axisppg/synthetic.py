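"""Seeded synthetic facial-video generator with an embedded ground-truth PPG.

Real rPPG corpora pair an RGB face video with a contact-PPG label stream
recorded at its own rate.  This module emulates that structure at desk scale:
an elliptical "skin" region whose colour is modulated, channel-wise, by a
synthetic pulse waveform, over a darker static background, with optional
per-pixel noise, small region translation per frame and a slow multiplicative
illumination drift.  The generator is fully deterministic given its seed, and
the planted signal is exactly recoverable from the region mean when noise is
off — which is what makes every downstream stage testable without any
dataset download.

The beat template is a sum of Gaussian bumps: a systolic peak, a diastolic
peak, and a notch dip between them — the three landmarks of a PPG beat.  It
is a morphological stand-in, not a haemodynamic model: it gives the waveform
a realistic harmonic structure (including the low-frequency notch content
the spectral loss cares about) without simulating pressure dynamics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PPGTemplate", "SyntheticSpec", "VideoClip", "GroundTruthPPG",
    "make_ppg_template", "synthesize_ppg", "synthesize_face_video",
    "make_dataset", "save_clip", "load_clip",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PPGTemplate:
    """One-beat waveform shape; positions and widths are beat-period fractions."""

    systolic_amp: float = 1.0
    systolic_pos: float = 0.22
    notch_depth: float = 0.20
    diastolic_amp: float = 0.45
    diastolic_pos: float = 0.48
    widths: tuple[float, float, float] = (0.13, 0.05, 0.12)  # systolic, notch, diastolic

    def __post_init__(self):
        if not (0.0 <= self.systolic_pos < 1.0 and 0.0 <= self.diastolic_pos < 1.0):
            raise ValueError("peak positions must lie in [0, 1)")
        if self.diastolic_pos <= self.systolic_pos:
            raise ValueError("diastolic_pos must exceed systolic_pos")
        if min(self.systolic_amp, self.diastolic_amp) < 0 or self.notch_depth < 0:
            raise ValueError("amplitudes must be >= 0")
        if min(self.widths) <= 0:
            raise ValueError("widths must be positive")

    @property
    def notch_pos(self) -> float:
        return 0.5 * (self.systolic_pos + self.diastolic_pos)

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        """Evaluate the (unnormalised) template at beat phase in [0, 1)."""
        phase = np.asarray(phase, dtype=float)

        def bump(pos, width):
            # wrapped Gaussian so the waveform is periodic in phase
            d = phase - pos
            d = d - np.round(d)
            return np.exp(-0.5 * (d / width) ** 2)

        ws, wn, wd = self.widths
        return (self.systolic_amp * bump(self.systolic_pos, ws)
                + self.diastolic_amp * bump(self.diastolic_pos, wd)
                - self.notch_depth * bump(self.notch_pos, wn))


def make_ppg_template(params: PPGTemplate | None = None, n_points: int = 100) -> np.ndarray:
    """Sample one beat of the template on ``n_points`` phases; min shifted to 0."""
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    params = params or PPGTemplate()
    wave = params(np.arange(n_points) / n_points)
    return wave - wave.min()


@dataclass(frozen=True)
class GroundTruthPPG:
    samples: np.ndarray
    rate: float

    def __post_init__(self):
        if not np.isfinite(self.samples).all():
            raise ValueError("PPG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class VideoClip:
    frames: np.ndarray  # (T_total, H, W, 3) in [0, 1]
    fps: float

    def __post_init__(self):
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be (T, H, W, 3)")
        if self.frames.min() < 0.0 or self.frames.max() > 1.0:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic clip."""

    hr_bpm: float = 72.0
    hrv_sd: float = 0.02          # beat-period jitter SD (s)
    fps: float = 20.0
    duration_s: float = 10.0
    height: int = 64
    width: int = 64
    roi_center: tuple[float, float] | None = None   # (row, col); default frame centre
    roi_semi_axes: tuple[float, float] | None = None  # default (0.3 H, 0.25 W)
    base_color: tuple[float, float, float] = (0.55, 0.45, 0.40)
    pulse_amp: tuple[float, float, float] = (0.02, 0.05, 0.03)  # green largest
    noise_sd: float = 0.01
    motion_jitter_px: int = 1
    illum_drift_amp: float = 0.05
    illum_drift_hz: float = 0.05   # < 0.1 Hz: lands in the ULF/VLF bands
    background_dim: float = 0.4
    template: PPGTemplate = field(default_factory=PPGTemplate)
    seed: int = 0

    def __post_init__(self):
        if not (40.0 <= self.hr_bpm <= 240.0):
            raise ValueError("hr_bpm must lie in [40, 240]")
        if self.fps <= 2.0 * self.hr_bpm / 60.0:
            raise ValueError("fps violates Nyquist for the requested heart rate")
        peak = max(b + a for b, a in zip(self.base_color, self.pulse_amp))
        if peak > 1.0 or min(self.base_color) < 0.0:
            raise ValueError("base_color + pulse_amp must stay within [0, 1]")

    def roi_params(self) -> tuple[tuple[float, float], tuple[float, float]]:
        center = self.roi_center or (self.height / 2.0, self.width / 2.0)
        semi = self.roi_semi_axes or (0.3 * self.height, 0.25 * self.width)
        return center, semi


def synthesize_ppg(hr_bpm: float, hrv_sd: float, duration_s: float, rate: float,
                   template: PPGTemplate | None = None, seed: int = 0) -> GroundTruthPPG:
    """Concatenate template beats with jittered periods into a sampled trace.

    Each beat period is drawn as ``60/hr_bpm + N(0, hrv_sd^2)``; a draw at or
    below zero is clipped to 0.25 s with a logged warning.  The trace is the
    template evaluated at the running beat phase, so ``hrv_sd = 0`` gives an
    exactly periodic signal.
    """
    if hr_bpm <= 0 or duration_s <= 0 or rate <= 0:
        raise ValueError("hr_bpm, duration_s and rate must be positive")
    template = template or PPGTemplate()
    rng = np.random.default_rng(seed)
    mean_period = 60.0 / hr_bpm
    n_samples = round(duration_s * rate)

    boundaries = [0.0]
    while boundaries[-1] < duration_s:
        period = mean_period + (rng.normal(0.0, hrv_sd) if hrv_sd > 0 else 0.0)
        if period <= 0:
            logger.warning("synthesize_ppg: drew non-positive beat period; clipping to 0.25 s")
            period = 0.25
        boundaries.append(boundaries[-1] + period)
    boundaries = np.asarray(boundaries)

    t = np.arange(n_samples) / rate
    beat_idx = np.searchsorted(boundaries, t, side="right") - 1
    starts = boundaries[beat_idx]
    periods = boundaries[beat_idx + 1] - starts
    phase = (t - starts) / periods
    wave = template(phase)
    wave = wave - wave.min()
    return GroundTruthPPG(samples=wave, rate=rate)


def _ellipse_mask(height: int, width: int, center, semi_axes,
                  shift: tuple[int, int] = (0, 0)) -> np.ndarray:
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = center[0] + shift[0], center[1] + shift[1]
    ay, ax = semi_axes
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def synthesize_face_video(spec: SyntheticSpec) -> tuple[VideoClip, GroundTruthPPG, np.ndarray]:
    """Render a clip: pulsatile ellipse on a dimmed background.

    Returns ``(clip, ppg, roi_mask)`` where ``ppg`` is sampled at the video
    frame rate and ``roi_mask`` marks the un-jittered ellipse.  Inside the
    (per-frame jittered) ellipse the colour is
    ``(base + pulse_amp * normalised_ppg(t)) * drift(t)`` channel-wise; noise
    is added last and the result clipped to [0, 1].
    """
    ppg = synthesize_ppg(spec.hr_bpm, spec.hrv_sd, spec.duration_s, spec.fps,
                         spec.template, seed=spec.seed)
    n_frames = round(spec.duration_s * spec.fps)
    wave = ppg.samples
    span = wave.max() - wave.min()
    norm = (wave - wave.min()) / span if span > 0 else np.zeros_like(wave)

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xFACE)))
    center, semi = spec.roi_params()
    roi_mask = _ellipse_mask(spec.height, spec.width, center, semi)

    base = np.asarray(spec.base_color, dtype=float)
    amp = np.asarray(spec.pulse_amp, dtype=float)
    background = np.clip(base * spec.background_dim, 0.0, 1.0)
    t = np.arange(n_frames) / spec.fps
    drift = 1.0 + spec.illum_drift_amp * np.sin(2.0 * np.pi * spec.illum_drift_hz * t)

    frames = np.empty((n_frames, spec.height, spec.width, 3), dtype=float)
    for k in range(n_frames):
        if spec.motion_jitter_px > 0:
            shift = tuple(rng.integers(-spec.motion_jitter_px, spec.motion_jitter_px + 1, 2))
        else:
            shift = (0, 0)
        mask = roi_mask if shift == (0, 0) else _ellipse_mask(
            spec.height, spec.width, center, semi, shift)
        frame = np.broadcast_to(background, (spec.height, spec.width, 3)).copy()
        frame[mask] = (base + amp * norm[k]) * drift[k]
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, frame.shape)
        frames[k] = frame
    np.clip(frames, 0.0, 1.0, out=frames)
    return VideoClip(frames=frames, fps=spec.fps), ppg, roi_mask


def make_dataset(n_clips: int, spec_ranges: dict | None = None, seed: int = 0,
                 **fixed) -> tuple[list[tuple[VideoClip, GroundTruthPPG, np.ndarray]],
                                   list[dict]]:
    """Generate ``n_clips`` clips with per-clip parameters sampled uniformly.

    ``spec_ranges`` maps :class:`SyntheticSpec` field names to ``(lo, hi)``
    ranges (e.g. ``{"hr_bpm": (60, 120)}``); ``fixed`` overrides any other
    spec field for all clips.  Returns the clips and a metadata record per
    clip (true HR and the clip seed), all reproducible from ``seed``.
    """
    if n_clips < 1:
        raise ValueError("n_clips must be >= 1")
    spec_ranges = spec_ranges or {}
    for name, (lo, hi) in spec_ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
    clip_seeds = np.random.SeedSequence(seed).generate_state(n_clips) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xDA7A)))
    clips, meta = [], []
    for i in range(n_clips):
        sampled = {name: float(rng.uniform(lo, hi))
                   for name, (lo, hi) in spec_ranges.items()}
        spec = SyntheticSpec(**{**fixed, **sampled, "seed": int(clip_seeds[i])})
        clips.append(synthesize_face_video(spec))
        meta.append({"clip": i, "hr_bpm": spec.hr_bpm, "seed": spec.seed,
                     "fps": spec.fps, "duration_s": spec.duration_s})
    return clips, meta


# ---- writers ------------------------------------------------------------


def save_clip(out_dir: str | Path, name: str, clip: VideoClip, ppg: GroundTruthPPG,
              roi_mask: np.ndarray, meta: dict | None = None) -> None:
    """Write a clip as NPZ frames, two-column CSV labels, JSON sidecar, NPZ mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / f"{name}_video.npz",
                        frames=clip.frames.astype(np.float32), fps=clip.fps)
    times = np.arange(len(ppg.samples)) / ppg.rate
    np.savetxt(out / f"{name}_ppg.csv",
               np.column_stack([times, ppg.samples]),
               delimiter=",", header="time_s,value", comments="")
    sidecar = {"rate": ppg.rate, **(meta or {})}
    (out / f"{name}_ppg.json").write_text(json.dumps(sidecar, indent=2))
    np.savez_compressed(out / f"{name}_mask.npz", mask=roi_mask)


def load_clip(out_dir: str | Path, name: str) -> tuple[VideoClip, GroundTruthPPG, np.ndarray]:
    out = Path(out_dir)
    vid = np.load(out / f"{name}_video.npz")
    clip = VideoClip(frames=vid["frames"].astype(float), fps=float(vid["fps"]))
    table = np.loadtxt(out / f"{name}_ppg.csv", delimiter=",", skiprows=1)
    sidecar = json.loads((out / f"{name}_ppg.json").read_text())
    ppg = GroundTruthPPG(samples=table[:, 1], rate=float(sidecar["rate"]))
    mask = np.load(out / f"{name}_mask.npz")["mask"].astype(bool)
    return clip, ppg, mask
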