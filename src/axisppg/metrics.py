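"""Evaluation protocol: heart-rate extraction and error metrics, plus two
small clinical utilities (frequency-band labels and the early-warning score).

Heart rate is read off a PPG-like signal spectrally: sliding windows are
detrended, Hann-tapered, zero-padded and Fourier-transformed, and the peak
frequency inside a physiological band becomes the per-window beats-per-minute
estimate.  HR-MAE and HR-RMSE compare two such series elementwise; the
Pearson R of an evaluation concatenates each subject's windows into one
signal first and correlates the whole thing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

__all__ = [
    "HRSeries", "VitalsRecord", "bandpass_filter", "estimate_hr_series",
    "hr_mae", "hr_rmse", "pearson_r_concat", "ews_score", "classify_band",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HRSeries:
    bpm: np.ndarray
    window_s: float
    stride_s: float

    def __len__(self):
        return len(self.bpm)


def bandpass_filter(signal: np.ndarray, fs: float, low_hz: float = 0.5,
                    high_hz: float = 4.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; clips the band below Nyquist."""
    nyq = fs / 2.0
    high = min(high_hz, 0.99 * nyq)
    sos = sp_signal.butter(order, [low_hz, high], btype="bandpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def estimate_hr_series(signal: np.ndarray, fs: float, window_s: float = 10.0,
                       stride_s: float = 1.0, band: tuple[float, float] = (0.66, 3.0),
                       bandpass: bool = False,
                       subharmonic_ratio: float = 0.5) -> HRSeries:
    """Per-window spectral heart-rate estimates in beats per minute.

    Each window is detrended, Hann-windowed and zero-padded so the bin width
    is below 1 bpm; the peak in ``band`` gives ``60 * f_peak``.  Pulse
    waveforms carry strong harmonics, so the raw spectral peak can land on a
    multiple of the beat frequency; if an in-band subharmonic (peak/2 or
    peak/3) carries at least ``subharmonic_ratio`` of the peak amplitude the
    lowest such frequency is taken as the fundamental
    (``subharmonic_ratio=None`` disables this).  A window with no in-band
    energy yields NaN (excluded downstream).  A signal shorter than one
    window returns an empty series with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    win = int(round(window_s * fs))
    step = int(round(stride_s * fs))
    if len(signal) < win:
        logger.warning("estimate_hr_series: signal shorter than one window")
        return HRSeries(np.empty(0), window_s, stride_s)
    if bandpass:
        signal = bandpass_filter(signal, fs)
    nfft = _next_pow2(max(win, int(60 * fs)))  # bin width fs/nfft*60 < 1 bpm
    taper = np.hanning(win)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    n_windows = (len(signal) - win) // step + 1
    bpm = np.full(n_windows, np.nan)
    for k in range(n_windows):
        seg = sp_signal.detrend(signal[k * step:k * step + win])
        spec = np.abs(np.fft.rfft(seg * taper, n=nfft))
        # a flat window leaves only round-off in the band: no estimate
        if spec[in_band].max() <= 1e-10 * max(1.0, np.abs(seg).sum()):
            continue
        peak = np.flatnonzero(in_band)[np.argmax(spec[in_band])]
        if subharmonic_ratio is not None:
            half_bin = max(1, nfft // (2 * int(60 * fs)))  # ~0.5 bpm search slack
            for div in (3, 2):
                cand = peak // div
                lo, hi = max(cand - half_bin, 0), cand + half_bin + 1
                if freqs[cand] >= band[0] and \
                        spec[lo:hi].max() >= subharmonic_ratio * spec[peak]:
                    peak = lo + int(np.argmax(spec[lo:hi]))
                    break
        bpm[k] = 60.0 * freqs[peak]
    return HRSeries(bpm, window_s, stride_s)


def _paired(inf: HRSeries | np.ndarray, target: HRSeries | np.ndarray):
    a = np.asarray(inf.bpm if isinstance(inf, HRSeries) else inf, dtype=float)
    b = np.asarray(target.bpm if isinstance(target, HRSeries) else target, dtype=float)
    if len(a) != len(b):
        raise ValueError("HR series lengths differ")
    keep = np.isfinite(a) & np.isfinite(b)
    if not keep.any():
        raise ValueError("no comparable HR pairs")
    return a[keep], b[keep]


def hr_mae(inf, target) -> float:
    """Mean absolute HR difference in bpm (NaN pairs dropped)."""
    a, b = _paired(inf, target)
    return float(np.mean(np.abs(a - b)))


def hr_rmse(inf, target) -> float:
    """Root-mean-square HR difference in bpm (NaN pairs dropped)."""
    a, b = _paired(inf, target)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson_r_concat(per_person: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Pearson r over per-person concatenated (gt, inference) signals.

    Each entry is one person's ``(gt, inf)`` pair, windows already in
    temporal order; all persons are concatenated into two long signals and a
    single correlation is computed.
    """
    gts, infs = [], []
    for gt, inf in per_person:
        gt, inf = np.asarray(gt, float), np.asarray(inf, float)
        if gt.shape != inf.shape:
            raise ValueError("per-person gt/inf lengths differ")
        gts.append(gt)
        infs.append(inf)
    gt_all, inf_all = np.concatenate(gts), np.concatenate(infs)
    if np.ptp(gt_all) == 0 or np.ptp(inf_all) == 0:
        raise ValueError("constant concatenated signal; correlation undefined")
    return float(sp_stats.pearsonr(gt_all, inf_all)[0])


# ---- clinical utilities -------------------------------------------------


@dataclass(frozen=True)
class VitalsRecord:
    heart_rate: float          # bpm
    systolic_bp: float         # mmHg
    respiratory_rate: float    # breaths/min
    temperature: float         # deg C
    consciousness: str         # alert | voice | pain | unresponsive

    def __post_init__(self):
        if min(self.heart_rate, self.systolic_bp, self.respiratory_rate,
               self.temperature) <= 0:
            raise ValueError("vitals must be positive")


# Score bands, inclusive (lo, hi) with None = unbounded; lower edges inclusive.
_EWS_BANDS: dict[str, list[tuple[int, float | None, float | None]]] = {
    "heart_rate": [(0, 51, 100), (1, 40, 50), (1, 101, 110),
                   (2, None, 39), (2, 111, 130), (3, 131, None)],
    "systolic_bp": [(0, 101, 160), (1, 81, 100), (1, 161, 200),
                    (2, 70, 80), (2, 201, None), (3, None, 69)],
    "respiratory_rate": [(0, 9, 14), (1, 15, 20), (2, None, 8),
                         (2, 21, 30), (3, 31, None)],
    "temperature": [(0, 36.1, 37.5), (1, 35.0, 36.0), (1, 37.5001, None),
                    (2, None, 34.9999)],
}

_CONSCIOUSNESS = {"alert": 0, "voice": 1, "pain": 2, "unresponsive": 3}


def _band_score(name: str, value: float) -> int:
    bands = _EWS_BANDS[name]
    for score, lo, hi in bands:
        if (lo is None or value >= lo) and (hi is None or value <= hi):
            return score
    # gap between bands (non-integer boundary values): nearest band wins
    logger.warning("ews_score: %s=%.3g falls between bands; using nearest", name, value)
    best, dist = 0, np.inf
    for score, lo, hi in bands:
        edges = [e for e in (lo, hi) if e is not None]
        d = min(abs(value - e) for e in edges)
        if d < dist:
            best, dist = score, d
    return best


def ews_score(v: VitalsRecord) -> tuple[int, dict[str, int]]:
    """Early-warning score: banded sub-scores of the vitals, summed.

    Band boundaries are inclusive on the lower edge; temperature has no
    score-3 band.  Returns ``(total, sub_scores)``.
    """
    c = v.consciousness.lower()
    if c not in _CONSCIOUSNESS:
        raise ValueError(f"unknown consciousness level: {v.consciousness!r}")
    sub = {
        "heart_rate": _band_score("heart_rate", v.heart_rate),
        "systolic_bp": _band_score("systolic_bp", v.systolic_bp),
        "respiratory_rate": _band_score("respiratory_rate", v.respiratory_rate),
        "temperature": _band_score("temperature", v.temperature),
        "consciousness": _CONSCIOUSNESS[c],
    }
    return sum(sub.values()), sub


def classify_band(freq_hz: float) -> str:
    """PPG frequency-band label: ULF / VLF / LF / HF / out_of_range.

    ULF <= 0.003 Hz; VLF 0.033-0.04; LF 0.04-0.15; HF 0.15-0.4 (lower edge
    inclusive, upper edge exclusive at shared boundaries; the gap between
    ULF and VLF is unassigned).
    """
    if freq_hz < 0:
        raise ValueError("frequency must be >= 0")
    if freq_hz <= 0.003:
        return "ULF"
    if 0.033 <= freq_hz < 0.04:
        return "VLF"
    if 0.04 <= freq_hz < 0.15:
        return "LF"
    if 0.15 <= freq_hz <= 0.4:
        return "HF"
    return "out_of_range"
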