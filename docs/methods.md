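# Methods

## The estimation problem

Remote photoplethysmography (rPPG) recovers the blood-volume-pulse signal
from ordinary camera video of skin: each heartbeat changes the blood volume
in the superficial vasculature and hence the fraction of light the skin
reflects, most strongly in the green channel.  Given a facial video
`X ∈ R^{B×3×T×H×W}` and a co-registered contact-PPG label stream, the task
is to regress a length-`T` pulse waveform per window and, downstream, the
heart rate.

## Network

The network treats the three video axes symmetrically.  For each axis
`n ∈ {T, H, W}` the tensor is reshaped so that axis becomes the batch
dimension and the remaining two span a 2-D image; the axis stream is then

1. **2-D feature block** — two 3×3 convolutions with stride 2 and padding 1
   (ReLU after each), quartering both spatial dimensions and keeping the
   channel count `C` unchanged;
2. **spatio-temporal translator** — a pure reshape laying the per-slice
   features out as a map whose rows index the position along the projected
   axis and whose columns index flattened space (the STMap layout used
   throughout the rPPG literature);
3. **spatio-temporal feature block** — a MaxViT-style unit (a residual
   convolutional pair, windowed *block* self-attention inside non-overlapping
   tiles, then *grid* attention across tiles, pre-LayerNorm, single head by
   default) followed by a CBAM-style spatial-attention gate (channel max+mean
   pool → two 3×3 convolutions → sigmoid mask, multiplied elementwise);
4. **tail** — adaptive average pooling of the map columns to 16 bins;
   the T-axis feature is reshaped to `(B, C, T, 4, 4)` while the H/W features
   become `(B, C, 4, D, 4)` and are trilinearly interpolated onto
   `(T, 4, 4)` before mixing.

A **feature mixer** combines the three axis features into one attentive
`(B, C, T, 4, 4)` tensor.  Ten algebraic cases are implemented (⊙ is the
Hadamard product, `@` a batched 4×4 matrix product over the trailing dims):

| case | formula             | case | formula            |
|------|---------------------|------|--------------------|
| 1    | (E_W @ E_H) ⊙ E_T + E_T | 6 | (E_W + E_H) ⊙ E_T |
| 2    | E_T                 | 7    | E_W ⊙ E_T          |
| 3    | E_W ⊙ E_T + E_T     | 8    | E_H ⊙ E_T          |
| 4    | E_H ⊙ E_T + E_T     | 9    | E_W                |
| 5    | (E_W + E_H) ⊙ E_T + E_T | 10 | E_H              |

(all non-T features interpolated first; in case 1 the interpolation precedes
the matrix product because the raw H/W shapes are incompatible).

The **decoder** reshapes the mixed feature to a `(T, 16)` map, applies a 3×3
convolution mapping the `C` channels to `T` channels, averages over the 16
spatial columns, adds a residual pair of 1-D convolutions, and collapses to
one channel: a `(B, T)` signal.

Design points that were genuinely open and how they were fixed:

* channel width stays at `C = 3` through every convolution (configurable);
  that keeps the whole network at ~9 k parameters / ~35 kB fp32;
* attention windows default to 8×8; maps whose sides are not multiples are
  zero-padded and cropped back;
* ReLU after convolutions, LayerNorm inside attention, Kaiming-uniform
  initialisation from one seed;
* decoder kernels are 3×3 / width-3 with padding 1.

Because the decoder maps *channels to time indices*, each output sample owns
its own filter; a constant-in-time clip therefore still yields a structured
output signal.  The meaningful temporal-sensitivity property — and the one
the tests assert — is that frame shuffling changes the output of a dynamic
clip but leaves a static clip's output exactly unchanged.

## Losses

With `g` the reference and `y` the prediction (both length `T`):

* **negative Pearson**: `1 − r(g, y)` with `r` computed in sum form; scale-
  and offset-invariant.  Constant inputs make `r` undefined: an epsilon in
  the denominator returns loss 1 with zero gradient and a logged warning.
* **spectral (FFT) loss**: `‖A_g − A_y‖₁ + ‖P_g − P_y‖₁` on the one-sided
  *unnormalised* DFT (bins `0 .. ⌊T/2⌋`); phase differences are wrapped into
  `(−π, π]`, and the phase of a numerically-empty bin is defined as 0.  The
  convention is fixed because the test oracles depend on it.

Per-window targets are standardised (zero mean, unit variance) by default:
the Pearson term is scale-invariant but the spectral amplitude term is not,
and a fixed target scale makes it well-posed.

The combined objective is `w_p · L_pearson + w_f · L_fft`.  The function
defaults to `w_p = w_f = 1`; the *training* default for `w_f` is `1/T`,
because the unnormalised DFT amplitude of a standardised window grows
linearly with `T`, so at 1:1 the spectral term (≈70 at `T = 32`) drowns the
Pearson term (≤ 2) and training collapses to matching the average spectrum
without ever learning correlation.  `1/T` puts the two terms on a common
scale; pass `w_fft=1.0` for the strict 1:1 sum.

## Heart-rate read-out and metrics

HR is read spectrally: 10 s sliding windows with 1 s stride ("per-second"
cadence) are detrended, Hann-tapered and zero-padded so the bin width is
below 1 bpm; the peak inside 0.66–3.0 Hz (40–180 bpm) gives the estimate.
Pulse waveforms are harmonic-rich, so the raw in-band argmax can land on
2× or 3× the beat frequency; if an in-band subharmonic of the peak carries
at least half the peak amplitude, the lowest such frequency is taken as the
fundamental.  Predicted signals are band-passed (0.5–4 Hz Butterworth,
order 4, zero-phase) before HR extraction.  HR-MAE and HR-RMSE compare two
HR series elementwise after dropping NaN pairs.  The Pearson R of an
evaluation concatenates each subject's (here: each clip's) windows into one
signal and correlates the whole concatenation; R is reported on both raw
and band-passed predictions.

Two small clinical utilities accompany the metrics: a frequency-band
classifier (ULF ≤ 0.003 Hz; VLF 0.033–0.04; LF 0.04–0.15; HF 0.15–0.4;
lower edges inclusive, the ULF–VLF gap deliberately unassigned) and an
early-warning score that sums banded sub-scores of heart rate, systolic
blood pressure, respiratory rate, temperature and consciousness; band
boundaries are inclusive on the lower edge and temperature has no score-3
band.

## Synthetic data generator

The generator emulates the structure of rPPG corpora — RGB video plus a
label stream at its own rate — without rendering faces.  A beat template is
a sum of wrapped Gaussians: systolic peak (amplitude 1.0 at phase 0.22,
width 0.13 of the period), diastolic peak (0.45 at 0.48, width 0.12) and a
notch dip (0.20, width 0.05) centred between them.  These widths were chosen
so the waveform keeps the two-peaks-plus-notch morphology *and* its
fundamental Fourier component dominates every harmonic by ~2.7×, matching
real PPG harmonic ratios; with a much spikier beat the 2nd/3rd harmonics
rival the fundamental and the dominant spectral bin no longer equals the
heart rate, which breaks the generator's own construction contract.

Beats are concatenated with per-beat periods `60/HR + N(0, σ²)` (periods
clipped at 0.25 s with a warning), and the sampled trace modulates the
colour of an elliptical region channel-wise (`base + amp · ppg(t)`, green
amplitude largest at 0.05) over a dimmed static background.  Optional
nuisances: per-pixel Gaussian noise (σ = 0.01), ±1 px per-frame region
translation, and a slow multiplicative illumination drift (amplitude 0.05 at
0.05 Hz — inside the ULF/VLF bands, separable from HR).  Everything is
deterministic given the seed.

What the generator does *not* model: photorealistic skin, head pose, skin
tones, specular reflections, compression artifacts.  Passing tests
therefore demonstrate that the pipeline recovers a spatially-localised,
colour-coded pulse from video under noise, drift and jitter — not that it
performs on real faces.

## The recovery experiment

`run_synthetic_recovery` is the package's end-to-end experiment.  The quick
profile uses 48 training clips and 12 held-out clips at 32×32 px, 16 fps,
12 s, HR ~ U(54, 150) bpm; mixer case 6 with the combined loss; Adam at
lr 1e-3, batch 16, 40 epochs, 80:20 train/validation split with the
best-validation weights retained.  These problem sizes are the package's
chosen desk-scale operating point; the full profile (128×128, 160 clips) is
the same experiment at native resolution.  Evaluation concatenates each
held-out clip's windows, reports HR-MAE / HR-RMSE / R, re-trains the same
configuration on targets permuted across windows as a negative control, and
computes the median ROI relevance concentration (mean |gradient × input|
inside the planted ellipse over outside) of the trained model.

## Numerical and implementation notes

* All learnable computation runs on a small reverse-mode autodiff engine
  over numpy written for this package (`axisppg.autograd`, `axisppg.nn`);
  the network runs in float32, losses and metrics in the precision of their
  inputs (float64 in the tests).
* Convolutions are im2col + matmul; adaptive pooling and trilinear
  interpolation are matrix products with fixed weight matrices, so they are
  differentiable for free.
* Epsilon-rule LRP is implemented for plain Linear/Conv/ReLU chains and is
  conservative on bias-free chains; through attention blocks LRP is not
  well defined, so `relevance_map(method="eps_lrp")` on the full network
  falls back to gradient × input with a warning.
* Determinism: one seed drives data generation, weight init, the
  train/validation split and batch order; identical configuration implies
  bit-identical training.

## Known limitations

* No trained frontal-face detector is bundled; the detector surface accepts
  `fixed`, `full_frame`, `intensity` (a brightness-based region finder
  adequate for the synthetic clips) or any object with a
  `detect(frame) -> BBox | None` method.
* The quick profile's 32×32 inputs under-use the attention windows compared
  with the native 128×128 configuration.
* Single-axis mixers (cases 9/10) are supported but known to train poorly;
  they are exercised for robustness only.
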