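# semgait

**Surface-EMG gait phase recognition and continuous joint-angle prediction
with a multi-branch CNN–GRU network.**

Lower-limb exoskeletons and rehabilitation robots need to decode the user's
motion intention in real time. Surface electromyography (sEMG) leads actual
limb movement, so it is the natural control signal — but mapping 8 channels
of noisy sEMG to *both* a discrete walking gait phase and continuous joint
angles is a hard multi-task learning problem. `semgait` implements a full
pipeline for this problem:

* a **synthetic gait-session generator** (8-channel sEMG with
  phase-dependent muscle activation, plantar footswitch traces, smooth
  hip/knee/ankle trajectories, 50 Hz mains interference) so the whole
  pipeline is testable without human recordings;
* **preprocessing**: second-order Butterworth 20–300 Hz band-pass and
  49–51 Hz band-stop filters (zero-phase), per-channel zero
  standardization, and footswitch thresholding that converts plantar
  pressure into the four-phase gait label stream
  SW → IC → MSt → TSt;
* **feature extraction** per 320-sample window: the classical 5×8
  time-domain matrix (WL, MAV, VAR, RMS, ZC per channel) and a 9×9×8
  Hann/64-point/hop-32 STFT spectrogram (0–187.5 Hz retained);
* a **three-branch network** — 1-D CNN + 3-layer GRU over the raw window,
  2-D CNN over the spectrogram, 3-layer GRU over the time-domain matrix —
  fused and split into a 4-way softmax gait head and a 3-output linear
  angle head, trained jointly with `CE + 0.1·MSE`. The layers
  (convolutions, pooling, GRU, dense) are implemented in NumPy with
  analytic gradients, each verified against finite differences;
* **evaluation**: 80/20 cycle-grouped split, per-phase precision,
  macro/micro precision & sensitivity (PMAP/PMIP/PMAS/PMIS), per-joint
  RMSE, zero-lag cross-correlation and relative error.

See `docs/methods.md` for the signal model, architecture arithmetic and all
numerical conventions.

## Worked example

```python
from semgait.config import PipelineConfig
from semgait.cli import run_e2e

report, history = run_e2e(PipelineConfig().with_seed(1))
print(f"gait accuracy      {report.accuracy:.2f} %")
print(f"per-phase precision {report.per_class_precision.round(2)} %  (SW, IC, TSt, MSt)")
print(f"joint RMSE         {report.per_joint_rmse.round(2)} deg  (hip, knee, ankle)")
print(f"joint xcorr        {report.per_joint_xcorr.round(3)}")
```

This simulates 200 gait cycles (300,000 samples at 1.5 kHz), preprocesses
and labels them, extracts ~1,870 windows, trains the network for 40 epochs
(~3 minutes on one CPU core) and scores the held-out 20% of cycles.
Output with seed 1:

```
gait accuracy      94.43 %
per-phase precision [97.96 94.67 91.25 90.67] %  (SW, IC, TSt, MSt)
joint RMSE         [2.42 4.78 2.  ] deg  (hip, knee, ankle)
joint xcorr        [0.988 0.966 0.974]
```

Gait accuracy of ~94% against a 25% chance level shows the network
recovers the phase structure the generator encodes; the knee, with the
largest range of motion (57°), carries the largest angle error. The same
run is available from the shell:

```bash
semgait e2e --seed 1 --out results/run1 --verbose   # writes report.json,
                                                    # traces.csv, curves.csv
```

Stage-wise commands (`semgait simulate / preprocess / featurize / train /
evaluate`) exchange HDF5 containers and write a manifest (config hash, seed,
versions, stage counts) next to every artifact.

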