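# Methods

`rowkinetics` estimates the forces and segment powers a rower produces, from
kinematic-only sensors, with a sequence-to-sequence LSTM. This note records
the model, the biomechanical target definitions, the synthetic-data
generator that stands in for instrumented training data, and the numerical
and design choices a maintainer should know about.

## Problem and target quantities

Rowing telemetry systems measure forces at the foot stretcher and at the
handle (ergometer) or oarlock gates (boat), from which coaches derive power
profiles and technique determinants. The package's estimator replaces the
force sensors: it maps kinematic channels (cable-sensor positions on the
ergometer; oar angles, GPS boat velocity and body-worn IMU streams on the
boat) to six target sequences per rowing cycle:

* `Ff_x` — horizontal foot-stretcher force (N),
* `Fh_x` — handle chain tension (ergometer) or summed port+starboard
  propulsive gate force (boat) (N),
* `Ph_x` — handle power (W),
* `Pa`, `Pt`, `Pl` — arm, trunk and leg segment powers (W).

On the ergometer, with handle/chest/seat positions `Xh, Xc, Xs`, the segment
kinematics are the arm length `Xa = Xh − Xc`, trunk opening `Xt = Xc − Xs`
and leg extension `Xs`; powers follow Kleshnev's decomposition
`Ph_x = Vh·Fh_x`, `Pa = Va·Fh_x`, `Pt = Vt·Fh_x`, `Pl = Vl·Ff_x`. By
construction `Va + Vt + Vl = Vh`, so `Pa + Pt + Pl = Ph_x` whenever the same
force acts at handle and feet — a closure identity the tests assert.

On the boat, the power transferred to each oar is
`Ph = (Fh_x·li·cosθ + Fh_y·li·sinθ)·θ̇` with inner lever `li` (default
0.88 m, a typical scull inboard; the per-boat rigging value can be supplied),
summed over sides. Segment velocities come from the body IMUs: the trunk
velocity is the difference between the thoracic and pelvis IMU horizontal
velocities, and the leg velocity is the pelvis IMU velocity corrected for
pelvis tilt, `Vl = V_Ip − l_Ip·θ̇_Ip·cos θ_Ip` with `l_Ip = 0.15` m
(pelvis-sensor-to-seat distance, identical for all subjects). Then
`Pl = Ff_x·Vl`, `Pt = Fh_x·Vt`, and the arm power is the residual of the
rower's power balance, `Pa = Ph + (Ff_x − Fh_x)·V_boat − Pt − Pl`.

A note on the trunk-velocity definition: the source expression for the boat
trunk velocity types as a *product* of two IMU velocities, which is
dimensionally inconsistent for a velocity; it is implemented here as the
difference `V_It − V_Ip`, consistent with the ergometer trunk-opening
derivative and with the structure of the leg-velocity expression.

IMU horizontal velocities are obtained by trapezoidal time-integration of the
free acceleration followed by a zero-phase 2nd-order Butterworth high-pass at
0.1 Hz to remove drift — the same treatment applied to the GPS velocity for
synchronization. A stream must span at least three filter settling times
(30 s at 0.1 Hz) to be integrated.

## Preprocessing

* **Synchronization.** The GPS/gate logger and the wireless body IMUs run on
  independent clocks. The lag is found by normalized cross-correlation of
  the high-passed GPS boat velocity with the velocity integrated from the
  boat-mounted IMU acceleration, within a ±5 s window. Two details matter
  for quasi-periodic rowing signals, whose correlation has near-equal peaks
  one stroke period apart: a fixed-length core window of the IMU signal is
  slid inside the GPS signal, so every candidate lag compares equal-length
  windows (per-window norms computed exactly) and only the cycle-to-cycle
  jitter decides between period aliases; and the core is trimmed by the
  high-pass settling time (~10 s at 0.1 Hz) so the position-locked filter
  edge transients of both signals stay outside every compared window. The
  correlation at the chosen lag must exceed 0.5 or synchronization fails
  loudly. Planted offsets of up to ±2 s are recovered within one sample at
  100 Hz.
* **Segmentation.** Cycles are cut on the handle position (ergometer) or
  starboard oar angle (boat): maxima are finish events, minima catches;
  cycles run finish-to-finish with the intervening minimum as the catch.
  Peak finding requires a prominence of 20% of the channel range and a
  spacing of at least 1.2 s (50 strokes/min); cycles outside 1.2–6 s are
  discarded. These peak-detection parameters are package choices.
* **Effective drive phase.** Detected per cycle from the measured handle/gate
  force with the rowing-telemetry convention: onset when the force exceeds
  20 kgf, offset when it falls below 10 kgf. Thresholds are held internally
  in newtons (196.2 / 98.1 N, g = 9.81 m/s²).
* **Differentiation.** Central finite differences with one-sided edges
  (`np.gradient`); for noisy measured sessions an optional zero-phase
  low-pass (default 8 Hz in the pipeline) precedes differencing — stroke
  content lives below ~5 Hz, so this suppresses difference-amplified sensor
  noise without touching the waveform.
* **Artifacts.** Cycles containing NaNs or any sample with |z| > 6 (session-
  level statistics) in a required channel are dropped; this rule is a
  package choice.

## The estimator

Architecture (fixed stack): sequence input (nI) → dense (nI→nI) → one LSTM
layer → dropout → dense (→6), with a per-timestep mean-squared-error
objective. nI is 16 on the ergometer and 18 on the boat (see below). The
LSTM layer for nI = 16 and 500 units has 4·((16+500)·500 + 500) = 1,034,000
parameters. Because no deep-learning framework is part of the dependency
set, the network — forward pass, backpropagation through time, Adam, and
inverted dropout — is implemented directly in NumPy (`rowkinetics.nn`),
with fused gate matrices and float32 training arithmetic; gradients are
validated against central finite differences in the test suite.

Training: Adam at learning rate 1e-3, minibatch 32, early stopping when 20
epochs pass without any decrease of the validation full-cycle RMSE
(normalized units), returning the best-epoch weights; epoch cap 10,000 by
default. Cycles are variable-length sequences in absolute time; minibatches
are padded with the loss masked on pad frames (states run forward, so
padding cannot contaminate real frames). Batches are assembled
length-sorted with jittered ties to limit padding waste — a performance
choice with no semantic effect.

Features (16 ergometer / 18 boat): positions of handle/chest/seat; segment
velocities and accelerations (ergometer); oar angular velocity, boat
velocity and acceleration, the three IMU horizontal velocities, and the
first principal component of each IMU's 3-axis acceleration and angular
rate (boat); plus per-cycle scalars — height, mass, previous/current drive
durations, previous-stroke maximum handle speed and the time from that
maximum to the current catch (a flywheel spin-down proxy) on the ergometer,
previous-cycle mean/max boat speed on the boat. Scalars enter the sequence
model broadcast as constant channels, the simplest mechanism that preserves
the stated channel counts. PCA for the 1PCA channels is fitted per IMU per
session, sign-fixed by a positive loading on the sensor's forward axis. No
measured force or power may appear among the features; a name blacklist
enforces this.

Normalization: per-channel z-scores for features *and* targets, fitted on
training cycles only; predictions are de-normalized before any metric.
Splits: random by cycle, stratified by subject (80/20), or
leave-one-subject-out where the held-out subject is also the early-stopping
validation set. The random hyperparameter search draws LSTM units
log-uniformly in [10, 500] and dropout from {0, 5%, 10%}, scoring trials by
the mean de-normalized drive-phase MAE over the six targets.

## Evaluation

Errors are computed over the effective drive phase, linearly interpolated to
a 50-frame grid per cycle:

* `MAE = (1/CT) Σ_c Σ_t |y − ŷ|`, and `cMAE = (1/CT) Σ_t |Σ_c (y − ŷ)|` —
  the error of the cycle-averaged curve on the same scale, so cMAE ≤ MAE
  always. Both are normalized to percent by the mean measured curve value
  over the drive grid, pooled over validation cycles per target.
* The drive window used for both measured and estimated sequences is the one
  detected from the *measured* force, so the two curves always share a
  window.
* Technique determinants over the entire catch-to-finish phase (not the
  threshold window): T2P (peak instant, % of phase; plateau peaks resolve to
  the first maximal index), M2P (100·mean/max), WR (100·area before the
  peak / total area, trapezoidal).
* Discrimination accuracies via two-sample pooled-variance t-tests at
  α = 0.05 (a Welch option exists): intra-subject accuracy `As` is the
  fraction of subjects whose measured and estimated determinant means are
  indistinguishable; inter-subject accuracy `Ap` is the fraction of subject
  pairs where the measured-vs-measured and estimated-vs-estimated decisions
  agree. Technique discrimination is assessed on the segment-power
  determinants (T2P/M2P/WR of `Pa`, `Pt`, `Pl`), the quantities coaches use
  for legs–trunk–arms sequencing; no multiple-testing correction is applied
  across the pair matrix.

## Synthetic data generator

No public dataset of instrumented rowing sessions exists, so the generator
is first-class: it emulates what the estimator needs to be tested against,
with exactly known kinetics.

* **Waveforms.** Within the drive, the handle (or stroke) velocity is a
  warped raised cosine `v(u) = sin²(π u^k)` on drive fraction `u`, with
  `k = ln½ / ln p` so the velocity peaks at the subject's
  `force_peak_position` `p`. Positions are its monotone integral; the
  recovery mirrors the drive in time. Segment velocities are smooth
  bump-weighted shares of the handle velocity with ordered centres
  (legs < trunk < arms), so segments engage sequentially in the drive and
  return in reverse order in the recovery.
* **Forces tied to kinematics.** The handle/gate force is
  `gain · max(V, 0)^1.5`, with the gain calibrated so a nominal cycle peaks
  at the subject's `peak_force_N` (itself scaled with body mass). Kinematic
  inputs therefore *carry* the force information — without this, learning
  recovery tests would be vacuous — and forces vanish identically during
  the recovery (handle force ≤ 5% of the cycle peak there, exactly 0 on
  clean signals). The foot force is a subject-specific multiple of the
  handle force; part of that multiplier is deliberately unobservable from
  kinematics, which is one honest source of the leave-one-subject-out
  generalization gap.
* **Technique controllability.** `force_peak_position p` maps to a measured
  force T2P of ~100·p (verified within ±3 points on clean data); subject
  draws spread `p` over [0.26, 0.46] while per-cycle jitter moves it by
  SD 0.004, so between-subject technique differences dominate within-subject
  variability by design. An optional `arm_negative_power_flag` inserts a
  mid-drive negative arm-velocity lobe (balanced by the trunk), reproducing
  the "negative arm power" technical-fault pattern.
* **Subjects.** Anthropometry is drawn near competitive-sculler cohort
  statistics (≈1.85 m ± 5 cm, ≈79 ± 7 kg); stroke rates near 20 strokes/min
  (ergometer analysis condition) and 32.5 strokes/min (boat). Per-cycle
  jitter: duration ±3%, amplitude ±5% (clipped Gaussians), on by default.
* **Ground truth.** `true_targets` are *defined* as the kinetics pipeline
  applied to the noise-free streams; emitted streams add per-channel
  Gaussian noise (ergometer chain tension clipped at 0 — the strain gauge
  is unidirectional). With `noise_sd = 0` a recomputation from the emitted
  streams therefore reproduces the truth to float precision, and measured
  targets built from noisy streams differ from the truth the way processed
  measurements do.
* **Boat specifics.** Oar angles sweep ~1.6 rad with the catch at the
  minimum; gate forces split per side with a small port/starboard asymmetry
  and a lateral component at 35% of the propulsive one; the boat velocity
  fluctuates ±7% within the cycle around ~4.6 m/s, slowest near the catch;
  IMU accelerations are the derivatives of the constructed segment
  velocities, so drift-free integration recovers them; `imu_delay_s` shifts
  all IMU streams against the GPS/gate logger by whole samples to exercise
  synchronization (truth always corresponds to the aligned streams).
* **What the generator does not emulate:** hydrodynamics and blade–water
  interaction, flywheel dynamics, within-session fatigue or drift,
  wireless packet loss, sensor-placement differences between subjects, and
  vertical/lateral force components. Passing recovery tests therefore shows
  the pipeline and estimator are sound on data of this structure, not that
  the trained network transfers to real rowers.

## Benchmark problem sizes

The default synthetic ergometer benchmark is 12 subjects × 80 cycles at
20 strokes/min, simulated at 50 Hz — the stroke signal lives well below
10 Hz, so 50 Hz preserves the waveform content while keeping desk-scale
training times; the generator's native rates (150 Hz ergometer, 100 Hz
boat) remain the defaults elsewhere. The benchmark model uses 64 LSTM units
with an epoch cap of 120 for the 80/20 split and 25 per leave-one-out fold
(the held-out-subject error is dominated by the generalization gap, not by
late-epoch refinement). The acceptance script runs a further-reduced
configuration (10 subjects × 64 cycles, 100/20 epochs) for the same reason.

On this benchmark the split model reaches a mean drive-phase MAE_norm of a
few percent with the arm power the hardest target (smallest magnitude,
largest relative error), leave-one-out error is several times larger, and
segment-power technique discrimination exceeds 90% — the same qualitative
pattern reported for the instrumented human dataset the method was
developed on, which is not publicly available and whose exact error tables
are therefore out of reach of this package.

## Numerical choices and degenerate inputs

* Index convention 0-based, half-open `[start, end)` everywhere.
* Plateau peaks: argmax ties resolve to the first index (deterministic; note
  this makes T2P of plateaued leg-power curves sensitive to small changes).
* Zero-variance feature channels normalize with std replaced by 1 (warning);
  all-zero or non-positive curves raise `no_peak` in determinants; a drive
  window needs ≥ 2 samples to interpolate; the force never reaching the
  onset threshold raises `no_drive_detected`, never reaching the offset
  threshold ends the drive at the cycle end with a warning.
* Determinism: every stochastic component (subject sampling, cycle jitter,
  measurement noise, weight init, batch shuffling, dropout) draws from
  seeded generators; identical seeds reproduce identical sessions,
  training histories and weights on a fixed platform.
* Forget-gate biases initialize at 1 (standard practice so memory persists
  early in training); other weights are Glorot-uniform.

## Known limitations

* The LSTM is trained and evaluated on phenomenological synthetic data; no
  claim is made about accuracy on real instrumented sessions.
* The leave-one-out epoch cap trades a slightly pessimistic fold error for
  tractable runtimes; the split-vs-LOOV ordering is insensitive to it.
* The boat arm power, as a balance residual, inherits every upstream error
  and can dip negative mid-drive even without the technical-fault flag.
* Gap-filling of dropped IMU packets beyond short linear interpolation, and
  real-time inference, are out of scope.
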