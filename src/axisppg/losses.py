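"""Training objectives for waveform regression.

Two losses drive the network toward the reference pulse signal:

* the **negative-Pearson loss**, ``1 - r`` with ``r`` the Pearson correlation
  in its sum form — scale- and offset-invariant, it teaches the trend and the
  peak positions;
* the **spectral (FFT) loss**, the L1 distance between one-sided DFT
  amplitude vectors plus the L1 distance between (wrapped) phase vectors — it
  penalises differences band by band and pushes the low-frequency waveform
  detail (the dicrotic notch region) into the prediction.

Conventions, fixed and documented here because the oracles in the test suite
depend on them: the DFT is the one-sided, *unnormalised* transform with bins
``k = 0 .. floor(T/2)``; phase differences are wrapped into ``(-pi, pi]``
before the norm; a batch of signals contributes the mean of per-signal
losses.
"""

from __future__ import annotations

import logging

import numpy as np

from .autograd import Tensor, as_tensor, atan2

__all__ = [
    "neg_pearson_loss", "fft_loss", "combined_loss", "one_sided_spectrum",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _as_batch(x) -> Tensor:
    t = as_tensor(x)
    if t.ndim == 1:
        t = t.reshape(1, t.shape[0])
    if t.ndim != 2:
        raise ValueError("signals must be 1-D or (batch, T)")
    return t


def _check_pair(gt: Tensor, inf: Tensor) -> int:
    if gt.shape != inf.shape:
        raise ValueError(f"signal shapes differ: {gt.shape} vs {inf.shape}")
    n = gt.shape[-1]
    if n < 4:
        raise ValueError("signals must have length >= 4")
    if not (np.isfinite(gt.data).all() and np.isfinite(inf.data).all()):
        raise ValueError("signals must be finite")
    return n


def neg_pearson_loss(gt, inf) -> Tensor:
    """``1 - r`` with Pearson ``r`` in sum form; scalar (mean over batch).

    A constant signal leaves the correlation undefined; the epsilon-guarded
    denominator then yields a loss of 1 with a zero gradient, and a warning
    is logged.
    """
    gt, inf = _as_batch(gt), _as_batch(inf)
    n = _check_pair(gt, inf)
    if np.ptp(gt.data, axis=-1).min() == 0 or np.ptp(inf.data, axis=-1).min() == 0:
        logger.warning("neg_pearson_loss: constant signal, correlation undefined; returning 1")
    sx = gt.sum(axis=-1)
    sy = inf.sum(axis=-1)
    sxy = (gt * inf).sum(axis=-1)
    sxx = (gt * gt).sum(axis=-1)
    syy = (inf * inf).sum(axis=-1)
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy) + _EPS).sqrt()
    r = num / den
    return (1.0 - r).mean()


def _dft_matrices(n: int) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(n // 2 + 1)
    t = np.arange(n)
    ang = 2.0 * np.pi * np.outer(t, k) / n
    return np.cos(ang), np.sin(ang)


def one_sided_spectrum(x) -> tuple[Tensor, Tensor]:
    """Amplitude and phase of the one-sided unnormalised DFT.

    Returns ``(A, P)`` with ``floor(T/2)+1`` bins each; ``A >= 0`` and
    ``P`` in ``(-pi, pi]``.  Differentiable; the amplitude is guarded at
    zero-energy bins.
    """
    x = _as_batch(x)
    n = x.shape[-1]
    cosm, sinm = _dft_matrices(n)
    dtype = x.data.dtype
    re = x @ Tensor(cosm.astype(dtype))
    im = -(x @ Tensor(sinm.astype(dtype)))
    amp = (re * re + im * im + 1e-24).sqrt()
    # phase of a numerically-empty bin is defined as 0: the raw atan2 of
    # round-off residuals would be an arbitrary angle
    rel = 1e-6 if dtype == np.float32 else 1e-10
    floor = max(np.finfo(dtype).tiny, rel * float(amp.data.max()))
    alive = (amp.data > floor).astype(dtype)
    phase = atan2(im, re) * Tensor(alive)
    return amp, phase


def fft_loss(gt, inf, phase_amp_threshold: float | None = None) -> Tensor:
    """L1 amplitude distance plus L1 wrapped-phase distance of the spectra.

    ``phase_amp_threshold``, if given, masks the phase term to bins where the
    reference amplitude exceeds the threshold (phase at empty bins is noise);
    the default compares every bin.
    """
    gt, inf = _as_batch(gt), _as_batch(inf)
    _check_pair(gt, inf)
    a_gt, p_gt = one_sided_spectrum(gt)
    a_inf, p_inf = one_sided_spectrum(inf)
    amp_term = (a_gt - a_inf).abs().sum(axis=-1)
    d = p_gt - p_inf
    wrapped = atan2(d.sin(), d.cos())
    phase_abs = wrapped.abs()
    if phase_amp_threshold is not None:
        mask = (a_gt.data > phase_amp_threshold).astype(float)
        phase_term = (phase_abs * Tensor(mask)).sum(axis=-1)
    else:
        phase_term = phase_abs.sum(axis=-1)
    return (amp_term + phase_term).mean()


def combined_loss(gt, inf, w_pearson: float = 1.0, w_fft: float = 1.0,
                  phase_amp_threshold: float | None = None):
    """Weighted sum of the two losses.

    Returns ``(total, parts)`` where ``total`` is a differentiable scalar and
    ``parts`` maps each sub-loss name to its float value for logging.
    """
    if w_pearson < 0 or w_fft < 0:
        raise ValueError("loss weights must be >= 0")
    if w_pearson == 0 and w_fft == 0:
        raise ValueError("at least one loss weight must be positive")
    parts: dict[str, float] = {}
    total = Tensor(0.0)
    if w_pearson > 0:
        lp = neg_pearson_loss(gt, inf)
        parts["neg_pearson"] = lp.item()
        total = total + w_pearson * lp
    else:
        parts["neg_pearson"] = neg_pearson_loss(gt, inf).item()
    if w_fft > 0:
        lf = fft_loss(gt, inf, phase_amp_threshold)
        parts["fft"] = lf.item()
        total = total + w_fft * lf
    else:
        parts["fft"] = fft_loss(gt, inf, phase_amp_threshold).item()
    return total, parts
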