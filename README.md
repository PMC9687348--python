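# axisppg

Axis-projection network for remote photoplethysmography (rPPG): estimate a
pulse waveform — and from it the heart rate — from facial video, without
touching the subject.

Each heartbeat subtly changes how much light skin reflects.  `axisppg`
regresses the pulse signal from an RGB video window `X ∈ R^{3×T×H×W}` by
extracting features three times, once per axis: the tensor is reshaped so
that T, H or W in turn becomes the batch dimension, a two-convolution block
and a MaxViT-style attention layer (with a spatial-attention gate) process
the resulting spatio-temporal map, and one of **ten feature mixers**
(Hadamard products, sums, a batched 4×4 matrix product, residual adds)
combines the three axis features into a single attentive `(C, T, 4, 4)`
tensor that a small decoder turns into a length-`T` PPG.  Training uses the
combined **negative-Pearson + spectral (FFT amplitude/phase) loss**;
evaluation reports **HR-MAE**, **HR-RMSE** and the **Pearson R** of
per-subject concatenated signals.

Everything runs on one CPU: the package ships a seeded synthetic
pulsatile-video generator (an elliptical "skin" region whose colour is
modulated by a morphologically realistic beat template with systolic peak,
dicrotic notch and diastolic peak), so the full pipeline — simulation,
preprocessing, training, evaluation, pixel attribution — is testable
without downloading any dataset.  The neural network and its training loop
run on a compact reverse-mode autodiff engine over numpy included in the
package.

## Worked example

The end-to-end experiment — generate clips, train, evaluate held-out HR
recovery with a shuffled-label negative control and an attribution check —
is one call (about ten minutes on one CPU):

```python
from axisppg import run_synthetic_recovery

report = run_synthetic_recovery("quick", seed=0)
print({"hr_mae": report.hr_mae, "hr_rmse": report.hr_rmse, "r": report.r,
       "control_hr_mae": report.control_hr_mae,
       "roi_concentration_median": report.roi_concentration_median})
```

which prints (seed 0):

```
{'hr_mae': 0.234375, 'hr_rmse': 0.46875, 'r': 0.9321949294302522,
 'control_hr_mae': 41.901041666666664,
 'roi_concentration_median': 2.4268784287144403}
```

Read: on 12 held-out clips with heart rates drawn from 54–150 bpm, the
per-second heart rate recovered from the predicted pulse is within 0.23 bpm
of the reference on average, the predicted waveform correlates at r = 0.93
with the planted pulse (windows concatenated per clip), the same network
trained on shuffled labels is off by 42 bpm (so the signal is learned, not
memorised), and the trained model's pixel relevance is 2.4× denser inside
the pulsatile region than outside it.  The lower-level surface
(`make_dataset`, `preprocess_clip`, `train`, `evaluate`) exposes each of
those stages separately; note that at this desk scale the network needs the
full quick-profile data volume (48 clips, 40 epochs) before the correlation
term starts to drop — much smaller runs stay near chance.

A command-line interface mirrors the pipeline stages:

```bash
axisppg simulate --n-clips 8 --hr-min 60 --hr-max 120 --size 32x32 --seed 0 --out data/
axisppg train --data-dir data/ --seed 0 --out runs/exp1
axisppg evaluate --checkpoint runs/exp1/model.npz --data-dir data/ --out runs/exp1/report.json
axisppg recovery --profile quick --seed 0 --out runs/recovery
```

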