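# Methods

`semgait` implements a complete, testable pipeline for recognizing the
walking gait phase and predicting lower-limb joint angles from 8-channel
surface EMG (sEMG). Because no public dataset of synchronized sEMG, plantar
pressure and joint-angle recordings exists for this setup, the package ships
a synthetic session generator that emulates the statistical structure the
pipeline assumes; the generator is first-class, tested code, and every
downstream stage is validated against it.

## The signal model

A walking session is a periodic sequence of four gait phases in temporal
order

    SW (swing) -> IC (initial contact) -> MSt (mid stance) -> TSt (terminal stance)

Integer codes follow the S0..S3 reporting convention (SW=0, IC=1, TSt=2,
MSt=3). Default phase fractions are 40/20/20/20% of the cycle — swing
occupies roughly 40% of a normal gait cycle, and the three stance
sub-phases split the rest evenly. Cycle duration defaults to 1 s (cadence of
brisk treadmill walking at ~4 km/h) with ±5% multiplicative per-cycle
jitter, renormalized so an n-cycle session has exactly
`round(n · duration · fs)` samples at fs = 1500 Hz.

**sEMG.** Each of the 8 channels (RF, VLO, VMO, BF, ST, TIA, LGA, MGA) is a
band-limited Gaussian carrier, amplitude-modulated by a phase-dependent
activation envelope:

    x_c(t) = e_c(t) · g_c(t) + a_mains · sin(2π·50·t + φ_c) + ε_c(t)

where `g_c` is white Gaussian noise band-passed to 20–150 Hz (the dominant
physiological sEMG band) and normalized to unit RMS, `e_c(t)` is the entry
of the 8×4 activation matrix for the current phase smoothed with a
raised-cosine (Hann) kernel spanning 10% of the mean phase length (real EMG
amplitude transitions are gradual), `a_mains` (default 0.05) injects 50 Hz
interference, and `ε_c` is white measurement noise (SD 0.05). The default
activation matrix encodes the physiology: thigh muscles (RF..ST, amplitudes
0.6–0.9) are strong in SW and IC when the hip and knee are driven; calf
muscles (TIA, LGA, MGA) carry IC/MSt/TSt, peaking in stance. Entries are
deliberately distinct across channels so the envelope vector is informative
about cycle position. Units are arbitrary mV-scale — standardization removes
scale downstream.

**Plantar pressure.** Eight switch channels (heel, 5th metatarsal, 1st
metatarsal, big toe; right foot then left). Right-foot contact per phase:
SW none; IC heel only; MSt heel + both metatarsals; TSt metatarsals + toe
without heel. The left foot repeats the pattern shifted by half a cycle.
Each on/off edge is jittered (Gaussian, SD 10 ms) and Gaussian amplitude
noise (SD 0.05) is added, so label recovery by thresholding is non-trivial;
a `noiseless()` helper switches both off for exact round-trip checks.

**Joint angles.** Hip, knee and ankle follow two-harmonic Fourier series of
the normalized cycle position, affinely mapped so their extremes touch the
configured ranges of motion — hip −15°…30°, knee −12°…45°, ankle −20°…8°.
Harmonic placement encodes standard kinematics (hip flexion peaks in late
swing, knee flexion mid-swing, ankle dorsiflexion in late stance) and is
perturbed slightly per session so realizations differ across seeds while
remaining range-bound. An `angle_amplitude` scale (0 → constant mid-range)
supports degenerate tests. Trajectories are phase-locked to the jittered
cycles, mirroring motion-capture angles synchronized to footswitches.

What the generator does **not** model: motor-unit physiology (no MUAP
shapes, recruitment or firing statistics), electrode lift/motion artifacts,
inter-subject variability, fatigue drift, or crosstalk between electrode
sites. Within a phase interior the envelope is flat, so the network resolves
cycle position mainly from phase boundaries visible inside a window.
Passing tests therefore demonstrate that the pipeline recovers the structure
this model encodes — not that the architecture would reach the same scores
on human recordings.

## Preprocessing

Second-order Butterworth filters: 20–300 Hz band-pass, then 49–51 Hz
band-stop (the order matters only marginally; the two nearly commute and the
band-pass-first order is fixed and documented). Offline processing uses
zero-phase forward–backward filtering (scipy `sosfiltfilt`, odd-reflection
padding), which cancels phase lag and squares the magnitude response; a
causal single-pass mode is exposed for streaming. Tests validate measured
tone attenuation against the analytic |H(f)| (squared for the double pass)
within 2%.

Standardization is per channel per recording, (x−mean)/SD with the **N−1
(sample) denominator** — that convention is the contract, asserted by the
two-point example [0,2] → ±1/√2. A zero-variance channel raises an error
naming the channel.

Pressure is moving-average smoothed (20 ms window, shrinking at edges) and
thresholded at 50% of each channel's 95th percentile (robust to amplitude
noise; the percentile ignores spikes). The contact pattern of the four
right-foot switches maps to the phase via the table above, then a 50 ms
minimum-phase-duration debounce absorbs short flickers into the preceding
run. On noiseless synthetic pressure the round trip recovers ≥99% of
samples; residual disagreement comes from smoothing-induced edge shifts.

## Features

Windows are 320 samples (213 ms) with 160-sample stride and majority-vote
gait labels; the regression target is the angle at the window's **final**
sample (predicting the current state). 320 is the unique window length for
which the 64-point/32-hop STFT yields exactly 9 frames, matching the
9×9×8 retained tensor.

Per channel and window, five classical time-domain features are stacked
into a 5×8 matrix (row order WL, MAV, VAR, RMS, ZC): waveform length
Σ|Δy|, mean |y|, sample variance (N−1), RMS, and the count of sign changes
whose step exceeds a threshold ε (default 0.01 ≈ 1% of the unit SD after
standardization). All five are pinned to brute-force loop oracles at 1e-10
relative tolerance.

The spectrogram uses periodic-Hann 64-point frames at hop 32: 33 one-sided
bins spanning 0–750 Hz; the lowest 9 rows (0–187.5 Hz, bin width
23.4375 Hz) are retained because most sEMG energy lies below ~200 Hz.
Magnitude is linear by default (`log1p` optional). A Parseval check ties
spectrogram energy to Hann-windowed time-domain energy; a pure tone at a bin
center lands 2/3 of its energy in that bin (the exact Hann share) and ≥99%
within ±1 bin.

## Network

Three branches, each matched to its input type, all authored in
`semgait.nn` (NumPy layers with analytic gradients, verified against central
finite differences):

* **Time series.** Two valid 1-D convolutions (kernel 3, stride 1, no
  padding — the convolution sum's index range implies valid convolution),
  each ReLU + max-pool 2: 320 → 318 → 159 → 157 → 78 steps; then a
  three-layer GRU (hidden 64) whose final hidden state is the embedding.
* **Spectrogram.** One valid 2-D convolution (3×3, stride 2): 9×9 → 4×4
  maps, ReLU, 2×2 max pool → 2×2, flattened.
* **Time-domain matrix.** A three-layer GRU over 5 steps of 8-dim inputs
  (feature rows as time steps, channels as dimensions).

Embeddings are concatenated (timeseries, spectrogram, timedomain) and fed
to two fully separate heads (Dense 128 → ReLU → output): a 4-way softmax
gait classifier and a 3-output linear angle regressor in degrees (targets
unnormalized, so reported RMSE is directly in degrees). Defaults: conv1d
32/64 kernels, conv2d 32, GRU hidden 64, FC 128 — sized to train the
default study in a few minutes on one CPU core. ReLU is used wherever the
nonlinearity is unspecified; pooling is max. Depth of the spectrogram
branch is configurable; one conv block is the default.

Training: Adam (lr 1e-3), batch 64, 40 epochs, multi-task loss
CE + λ·MSE with λ = 0.1 (balances O(1) cross-entropy against squared-degree
errors of order 10² early in training). A 10% carve-out of the training side
is scored every epoch (total loss + gait accuracy — the standard progress
curves); the best-validation-loss weights are restored at the end. All
randomness (init, shuffling, carve-out) derives from explicit seeds, so a
fixed seed reproduces curves exactly.

## Evaluation protocol

80/20 split, grouped by gait cycle by default: windows overlap, so a random
window split would leak near-duplicates across the split; whole cycles go
to one side. Classification: per-class precision, accuracy, and the
macro/micro averaged precision and sensitivity suite (PMAP/PMIP/PMAS/PMIS;
the "macro average accuracy" label used in this literature is implemented
as macro-averaged precision, matching the metric table row names). Micro
precision = micro sensitivity = accuracy identically in single-label
multiclass; the implementation is checked against a brute-force oracle on
1,000 random confusion matrices exactly, and against scikit-learn on label
streams. A class never predicted gets precision 0 with a warning.

Regression: per-joint RMSE (degrees), zero-lag Pearson cross-correlation
(the conventional choice when no alignment lag is expected), and relative
error = RMSE / observed true range of motion × 100 (the denominator is a
package convention; no standard definition exists for this quantity).

## Study scale and headline gates

The default synthetic study — 200 cycles (300 k samples, ~1870 windows),
40 epochs — trains in ~3 minutes on one CPU core. Repo gates on it (not
claims about real data): held-out gait accuracy ≥85% (chance 25%),
per-joint RMSE ≤5°, per-joint cross-correlation ≥0.90. With the default
seed the run reaches ~94% accuracy, 2.4/4.8/2.0° hip/knee/ankle RMSE and
xcorr ≥0.96. The knee, with the largest range of motion (57°), dominates
angle error; the irreducible floor comes from windows that sit wholly inside
a phase's flat envelope interior, where cycle position is only partly
observable.

## Numerical and degenerate-input choices

* Filter cutoffs at or above Nyquist, non-positive cycle counts, phase
  fractions not summing to 1 (tolerance 1e-9), activation entries outside
  [0,1], and carrier bands above Nyquist are configuration errors; NaN
  signals and zero-variance channels are data errors.
* Max-pool layers drop a trailing odd sample; valid convolutions never pad.
* GRU gate order is (reset, update, candidate) with a separate bias on the
  hidden candidate term, so the reset gate multiplies the biased hidden
  contribution.
* Debounce absorbs short runs left-to-right into the preceding run; the
  first run, if short, joins its successor.
* Angle range mapping uses a 20001-point grid to locate trajectory extremes
  and clips residual grid error (≤1e-7°) so samples never leave the range.
* Ties in majority vote labels resolve to the lowest phase code
  (`argmax` on counts).

## Known limitations

* The generator's phase-conditional stationarity makes classification easier
  than on real sEMG, where envelopes drift within phases and across fatigue.
* Single-subject, single-session regime: no domain shift, no electrode
  re-placement variability.
* The NumPy network trains on one core; the implementation favors clarity
  and exactness (checked gradients) over large-scale speed.
* Left-foot switches are generated but unused by labeling (the right leg is
  the instrumented side).
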