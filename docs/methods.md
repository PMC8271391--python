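# Methods

This note records the modelling choices behind `imugait`: what is simulated,
how, with which defaults, and what the synthetic experiments do and do not
demonstrate.

## Virtual-IMU simulation

A segment pose is a uniformly sampled sequence of unit quaternions
(body→global, Hamilton convention, scalar-first) plus origin positions in a
z-up global frame. Sequences are hemisphere-corrected (consecutive dot
products ≥ 0) so finite differences act on a continuous representative of
the double-covered rotation group.

- **Gyroscope**: `ω = 2 · vec(q* ⊗ q̇)`, the body-frame angular rate from the
  quaternion derivative. `q̇` uses central differences with second-order
  one-sided stencils at the endpoints.
- **Accelerometer**: specific force `f = Rᵀ(p̈ − g)` with
  `g = (0, 0, −9.81) m/s²`. Gravity is included because that is what a
  physical accelerometer reports (a static sensor reads +1 g upward), and
  because placement fitting against measured signals would otherwise be
  biased by a constant 9.81 m/s² discrepancy. `p̈` uses second-order central
  differences (`(2, −5, 4, −1)/dt²` at the ends).

Both estimators converge at O(dt²) against analytic motions (verified by
the dt-halving test), and the gyroscope agrees with an independent
rotation-matrix estimator (`skew(RᵀṘ)` by finite differences) to ~1e-6 rad/s
on gently curved paths sampled at 5 kHz. Spline differentiation was
deliberately avoided: plain stencils have a provable convergence order and
no smoothing bias.

**Placement fitting** recovers the rigid sensor-to-segment transform
(3 translation + 3 rotation-vector parameters) by bounded least squares
(trust-region reflective) on the stacked accelerometer and gyroscope
residuals, gyro weighted by a configurable factor (default 1). On noiseless
synthetic walking data it recovers placements to well under 1 mm / 0.1°
from initial guesses 5 cm / 10° away; with additive noise the residual
approaches the injected noise floor. The optimizer is deterministic given
the initial guess. The augmentation step replays one motion trial under
every placement set in a library, producing `|library|` simulated 5-sensor
trials in library order.

**Joint decomposition** uses intrinsic Cardan angles in a configurable
order, default Z (flexion-extension) – X (ab-adduction) – Y
(internal-external rotation), consistent with lower-limb conventions in
biomechanics. Angles are unwrapped over time; frames whose middle angle
comes within 1° of ±90° are flagged as gimbal-proximal. Walking kinematics
stay far from that singularity.

## Synthetic cohort

The generator emulates the study conditions the pipeline is designed for:
a cohort of ~116 walkers (defaults configurable) at self-selected speeds of
0.8–2.0 m/s, five sensor sites (pelvis, bilateral thigh and shank), and a
subset of subjects (23 at full scale) carrying physical sensors with
subject-specific placements that double as the augmentation library.

- **Anthropometrics**: mass ~ N(72.5, 11.9²) kg, height ~ N(1.73, 0.09²) m,
  truncated to [40, 120] kg and [1.4, 2.1] m; segment lengths as fixed
  height fractions (pelvis width 0.15 h, thigh 0.245 h, shank 0.246 h).
- **Joint angles**: each of the 18 channels (6 joints × 3 components) is a
  4-harmonic Fourier series over the stride cycle with subject-specific
  amplitudes (±15% around physiologic templates) and phases. Templates give
  hip flexion ≈ 40° range, knee flexion ≈ 60°, and enforce
  sagittal > frontal > transverse ranges, mirroring the small non-sagittal
  ranges of motion in walking. Left channels are phase-shifted by half a
  stride. Stride period is `(0.6 + 0.4 v)/v` s — cadence rises monotonically
  with speed.
- **Poses**: the pelvis advances in a straight line with small sinusoidal
  vertical/lateral oscillation and axial sway; thigh and shank orientations
  compose the pelvis pose with the commanded hip and knee Cardan rotations,
  so extracting joint angles from the generated poses returns the commanded
  curves to 1e-6° (a closed-loop identity used throughout the tests).
- **Moments**: stance-phase templates — exactly zero at foot contact and
  outside stance, a double-hump `sin(πτ) − β sin(2πτ)` shape for sagittal
  channels, single-hump for the others — scaled per subject and stored
  normalised by `m·g·h` (dimensionless). These are plausible-shaped
  surrogate targets, not inverse-dynamics solutions.
- **Measured IMU noise**: additive white Gaussian noise
  (σ_accel = 0.2 m/s², σ_gyro = 0.02 rad/s) plus a per-trial constant bias
  (SD 0.05 m/s² / 0.005 rad/s); no drift. Defaults are configurable and can
  be zeroed for closed-loop experiments.

What passing tests on this cohort show: the simulation, preprocessing,
training and evaluation machinery is internally consistent and can learn
the motion-to-kinematics mapping across unseen subjects. What they do not
show: performance on real gait, which adds soft-tissue artefact,
marker/model error, richer inter-subject variability, non-stationary sensor
noise and real inverse-dynamics moments.

## Preprocessing

- **Filtering**: zero-phase (forward–backward) Butterworth low-pass;
  4th order / 6 Hz for optically derived curves, 1st order / 5 Hz for IMU
  channels.
- **Synchronization**: integer-lag normalized cross-correlation of gyro
  magnitudes; ties break toward the smallest |lag|. Positive lag = second
  series delayed.
- **Time normalization**: linear interpolation onto 101 points spanning the
  phase window inclusive — step (contact→contact) for kinematics, stance
  (contact→toe-off) for kinetics. Linear interpolation preserves endpoints
  and monotone segments.
- **Moment normalization**: `M / (m · 9.81 · h)`, with the exact inverse
  provided.
- **Ensemble sanity filter** (`ci_filter`): each curve is scored by the mean
  robust z-magnitude over all channel/time points, with the pointwise
  ensemble median and 1.4826·MAD as center and scale. A curve is excluded
  when its score exceeds the analytic level-quantile (default 0.95) of the
  score under a Gaussian null (half-normal mean, CLT across points). Under
  i.i.d. Gaussian perturbations this excludes ≈ 5% of samples; because the
  robust statistics barely move when the flagged tail is removed, filtering
  the kept set again excludes almost nothing (near-idempotence). Both the
  statistic and the cut are configurable.
- **Channel order** (a frozen contract — trained weights depend on it):
  sensors pelvis, thigh_L, thigh_R, shank_L, shank_R; accelerometer before
  gyroscope; axes x, y, z. Targets: joints hip_L, hip_R, knee_L, knee_R,
  ankle_L, ankle_R × flexion, abduction, rotation.
- **Layouts**: flat `n × 3030` / `n × 1818` (channel-major, time
  fastest-varying); sequence `n × 30 × 101` / `n × 18 × 101`; image — the
  native 10 × 101 × 3 grid (rows = 5 sensors × {accel, gyro}, colour
  channels = x/y/z axes) min–max scaled to [0, 1] per colour channel and
  bilinearly interpolated to 224 × 224 × 3. Pixel range [0, 1] and bilinear
  interpolation are this package's choices among reasonable options.
- **Scalers**: per-feature standardization (flat/sequence) or min–max
  (image), fitted on the training partition only and carried with the
  tensors; constant features map to zero. Inverse transforms are exact.

## Networks and training

The three families map layouts to the 18 joint curves: MLP (two dense
hidden layers, linear 18·101 output), LSTM (two stacked recurrent layers,
per-timestep linear read-out), CNN (five convolution blocks — kernels
7/5/3/3/3, pooling after blocks 1, 2 and 5 — then two dense layers). The
`cnn_frozen_conv` variant freezes the convolution/pooling stack at its
seeded random initialization and trains only the dense head, isolating the
contribution of the learned convolutional features.

Published-scale hyperparameters (widths 6000–4000 etc.) are mirrored in
`configs/`. Training minimizes mean absolute error with Adam (β₁ = 0.9,
β₂ = 0.999), batch size 64, 40 epochs cap, early stopping when the
validation loss fails to improve for 5 consecutive epochs (patience 0 stops
at the first plateau), best-epoch weights restored. The optimizer, batch
size and initialization (Glorot-uniform dense/LSTM, He-normal
convolutions, forget-gate bias 1) are package choices exposed in the spec
object. Everything is float64 and single-threaded, so runs are
bit-reproducible given a seed.

**Desk-scale profile** (`desk_scale_spec` / `--scale`): widths divided by
~100 (MLP 60–40, CNN head 30–60; LSTM hidden sizes stay at 32–32 because
they are already small), image side 32, dropout off, and learning rates
adapted to the smaller nets (MLP 3e-4, LSTM 3e-3, CNN 1e-3). The standard
desk experiment — 8 noiseless subjects, 2 with measured IMU, 2 trials each —
trains any family in seconds on one CPU and reaches held-out mean
per-channel correlation ≥ 0.9.

**Hyperband** samples widths and learning rate log-uniformly and dropout
uniformly within configurable bounds and allocates epochs by successive
halving (η = 3). The returned winner is checked to lie strictly inside the
bounds; a boundary winner raises, signalling the bounds should be widened.

## Evaluation

- **nRMSE** = RMSE / (max − min of the ground-truth series), computed per
  trial and channel, then averaged over trials; comparable across kinematic
  and kinetic channels but offset-sensitive and harsh on small-range
  channels. Constant-truth channels are flagged NaN and excluded from
  aggregates.
- **Pearson r**: shape agreement, offset/scale-blind; aggregated by the
  median over folds/trials.
- **LOSO**: one fold per subject with measured-IMU trials; the fold trains
  on all other subjects' simulated (placement-augmented) and measured
  samples and tests on the held-out subject's measured trials. Scalers and
  the image encoder are refitted inside each fold on its training partition
  only. Whether a subject's *placements* appear in the augmentation library
  is independent of the motion-subject disjointness that the protocol
  audits enforce.
- **Improvement tables**: `100 · (nRMSE_base − nRMSE_other)/nRMSE_base` on
  fold-mean nRMSE per channel (ratio of fold means, fixed and documented
  because either order is defensible); positive = improvement over the
  baseline.

## Numerical notes and limitations

- Endpoint stencils keep differentiation second-order but are the noisiest
  frames; phase windows in practice exclude trial boundaries.
- The finite-difference comparisons between independent estimators need
  gentle, densely sampled paths (the two O(dt²) errors differ in their
  constants); oracle tests sample at 5 kHz.
- `fit_placement` is a local optimizer: it assumes an initial guess within
  a few cm / ~10° (met by design in the emulated protocol, where nominal
  mounting sites are known). A coarse rotation grid can be layered on top
  for cold starts.
- The LSTM consumes the same 101-point normalized sequences as the other
  families; variable-length inference is out of scope.
- True transfer learning for the frozen-convolution CNN would require an
  external pretrained weight file; the shipped variant uses a seeded random
  convolution stack, which preserves the architecture and freezing
  mechanics but not pretrained features.
- Moments are template surrogates; no ground-reaction forces or muscle
  modelling. No magnetometer, soft-tissue artefact or sensor-fusion
  orientation estimation is simulated.
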