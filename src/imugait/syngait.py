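"""Synthetic gait-cohort generator.

Emulates a level-walking mocap cohort so the whole pipeline — virtual-IMU
simulation, placement augmentation, preprocessing and network training — can
be exercised without access to a motion-capture dataset.  The emulated study
conditions: ~116 subjects walking at self-selected speeds of 0.8–2.0 m/s,
five sensor sites (pelvis, bilateral thigh and shank), and a subset of
subjects ("flagged") carrying ground-truth sensors with subject-specific
placements.  Anthropometrics are drawn from Gaussians with mean mass 72.5 kg
(SD 11.9) and height 1.73 m (SD 0.09), truncated to physiologic bounds.

Joint-angle curves are truncated Fourier series over the stride cycle (4
harmonics) with subject-specific coefficients; this gives full parametric
control and physiologic ranges (hip flexion ≈ 40° range, knee ≈ 60°,
sagittal > frontal > transverse) without external templates.  Joint-moment
curves are stance-phase templates (zero at foot contact, double-hump sagittal
shape) scaled by body mass·g·height and stored in normalized units.  Segment
poses are built by forward kinematics from the angle curves over a
straight-line pelvis path with small sinusoidal vertical/lateral oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quat
from .rigid import (
    SEGMENTS,
    IMUSignal,
    PoseSequence,
    SensorPlacement,
    augment,
    cardan_to_quat,
    simulate_imu,
)

JOINTS = ("hip_L", "hip_R", "knee_L", "knee_R", "ankle_L", "ankle_R")
COMPONENTS = ("flexion", "abduction", "rotation")
#: 18 target channels, joint-major then component ("hip_L_flexion", ...).
CHANNELS = tuple(f"{j}_{c}" for j in JOINTS for c in COMPONENTS)

SPEED_RANGE = (0.8, 2.0)
DEFAULT_RATE = 100.0
STANCE_FRACTION = 0.6

# Per-component Fourier priors: (mean offset, harmonic amplitudes deg).
# Sagittal amplitudes dominate, transverse are smallest, mirroring the small
# non-sagittal ranges of motion in walking gait.
_ANGLE_PRIORS = {
    ("hip", "flexion"): (10.0, (20.0, 5.0, 2.0, 1.0)),
    ("hip", "abduction"): (2.0, (5.0, 2.0, 1.0, 0.5)),
    ("hip", "rotation"): (1.0, (3.0, 1.5, 0.8, 0.3)),
    ("knee", "flexion"): (20.0, (25.0, 12.0, 4.0, 1.5)),
    ("knee", "abduction"): (1.0, (4.0, 1.5, 0.8, 0.3)),
    ("knee", "rotation"): (1.0, (2.5, 1.2, 0.5, 0.2)),
    ("ankle", "flexion"): (0.0, (10.0, 6.0, 2.0, 1.0)),
    ("ankle", "abduction"): (1.0, (3.5, 1.5, 0.6, 0.3)),
    ("ankle", "rotation"): (0.5, (2.0, 1.0, 0.4, 0.2)),
}

# Stance-template harmonic weights for normalized joint moments (dimensionless
# after mass·g·height normalization).
_MOMENT_SCALE = {
    "flexion": 0.08,
    "abduction": 0.04,
    "rotation": 0.015,
}


@dataclass
class SubjectSpec:
    """Sampled virtual participant: anthropometrics, per-joint gait
    coefficients and the subject's own sensor placements."""

    subject_id: str
    mass: float
    height: float
    segment_lengths: dict[str, float]
    gait_coeffs: dict[str, np.ndarray]  # channel -> (a0, a1..a4, phi1..phi4)
    has_ground_truth_sensors: bool
    placements: dict[str, SensorPlacement]
    seed: int

    def __post_init__(self) -> None:
        if not 40.0 <= self.mass <= 120.0:
            raise ValueError("mass outside [40, 120] kg")
        if not 1.4 <= self.height <= 2.1:
            raise ValueError("height outside [1.4, 2.1] m")
        for name, length in self.segment_lengths.items():
            if not 0.0 < length < self.height:
                raise ValueError(f"invalid segment length {name}={length}")


@dataclass
class GaitTrial:
    """One walking trial: 18-channel angle and normalized moment curves, gait
    events and the per-segment pose sequences the curves were generated from."""

    subject_id: str
    speed: float
    rate: float
    joint_angles: np.ndarray  # (18, n) degrees
    joint_moments: np.ndarray  # (18, n) normalized (M / (m g h))
    events: dict[str, dict[str, list[int]]]  # side -> {contact, toe_off}
    segment_poses: dict[str, PoseSequence]

    def __post_init__(self) -> None:
        if not SPEED_RANGE[0] <= self.speed <= SPEED_RANGE[1]:
            raise ValueError(f"speed {self.speed} outside {SPEED_RANGE}")
        for side in self.events.values():
            for idx in side.values():
                if np.any(np.diff(idx) <= 0):
                    raise ValueError("event indices must be strictly increasing")


@dataclass
class StudyBundle:
    """The generated study: cohort, source trials, measured-IMU trials for
    flagged subjects, and the placement-library augmented IMU trials."""

    cohort: list[SubjectSpec]
    trials: list[GaitTrial]
    measured_imu: dict[tuple[str, int], dict[str, IMUSignal]]
    augmented: list[dict]  # {trial_index, placement_subject, imu}
    placement_library: dict[str, dict[str, SensorPlacement]] = field(
        default_factory=dict
    )

    @property
    def augmentation_factor(self) -> float:
        if not self.trials:
            return 0.0
        return len(self.augmented) / len(self.trials)


def _sample_placements(rng: np.random.Generator) -> dict[str, SensorPlacement]:
    """Subject-specific sensor mounting: a few cm of translation and up to
    ~10° of mounting misalignment per site."""
    out = {}
    for seg in SEGMENTS:
        t = rng.normal(0.0, 0.02, 3)
        axis = rng.normal(size=3)
        angle = rng.normal(0.0, np.deg2rad(5.0))
        out[seg] = SensorPlacement(
            seg, offset_t=np.clip(t, -0.08, 0.08), offset_q=quat.from_axis_angle(axis, angle)
        )
    return out


def sample_cohort(
    n_subjects: int, n_ground_truth: int, seed: int
) -> list[SubjectSpec]:
    """Draw a cohort of virtual participants.

    Exactly ``n_ground_truth`` subjects are flagged as carrying ground-truth
    sensors.  Deterministic given the seed.
    """
    if n_ground_truth > n_subjects:
        raise ValueError("n_ground_truth cannot exceed n_subjects")
    rng = np.random.default_rng(seed)
    flagged = set(rng.choice(n_subjects, size=n_ground_truth, replace=False).tolist())
    cohort = []
    for i in range(n_subjects):
        mass = float(np.clip(rng.normal(72.5, 11.9), 40.0, 120.0))
        height = float(np.clip(rng.normal(1.73, 0.09), 1.4, 2.1))
        seg_len = {
            "pelvis_width": 0.15 * height,
            "thigh": 0.245 * height,
            "shank": 0.246 * height,
        }
        coeffs = {}
        for ch in CHANNELS:
            joint = ch.split("_")[0]
            comp = ch.rsplit("_", 1)[1]
            a0, amps = _ANGLE_PRIORS[(joint, comp)]
            amp = np.array(amps) * rng.uniform(0.85, 1.15, 4)
            phi = rng.normal(0.0, 0.25, 4)
            coeffs[ch] = np.concatenate([[rng.normal(a0, 2.0)], amp, phi])
        cohort.append(
            SubjectSpec(
                subject_id=f"S{i:03d}",
                mass=mass,
                height=height,
                segment_lengths=seg_len,
                gait_coeffs=coeffs,
                has_ground_truth_sensors=i in flagged,
                placements=_sample_placements(rng),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cohort


def stride_period(speed: float) -> float:
    """Stride duration in seconds; decreases monotonically with speed
    (stride length grows sub-linearly with speed)."""
    stride_length = 0.6 + 0.4 * speed
    return stride_length / speed


def synth_joint_angles(
    subject: SubjectSpec,
    speed: float,
    n_strides: int = 2,
    rate: float = DEFAULT_RATE,
) -> tuple[np.ndarray, dict]:
    """18-channel joint-angle curves plus gait events for a trial.

    Each channel is a 4-harmonic Fourier series over the stride cycle with the
    subject's own coefficients; left-side channels are phase shifted by half a
    stride.  Events: per-side foot contacts at stride boundaries and toe-offs
    at 60% of the stride cycle (stance fraction).
    """
    if not SPEED_RANGE[0] <= speed <= SPEED_RANGE[1]:
        raise ValueError(f"speed {speed} outside configured range {SPEED_RANGE}")
    period = stride_period(speed)
    n = int(round(n_strides * period * rate)) + 1
    t = np.arange(n) / rate
    phase = t / period  # stride fraction, right side reference
    angles = np.empty((len(CHANNELS), n))
    for k, ch in enumerate(CHANNELS):
        c = subject.gait_coeffs[ch]
        ph = phase + (0.5 if ch.split("_")[1].startswith("L") else 0.0)
        a0, amps, phis = c[0], c[1:5], c[5:9]
        val = a0 * np.ones(n)
        for h in range(4):
            val += amps[h] * np.cos(2 * np.pi * (h + 1) * ph + phis[h])
        angles[k] = val
    events: dict[str, dict[str, list[int]]] = {}
    for side, offset in (("R", 0.0), ("L", 0.5)):
        contacts = [
            int(round((s + offset) * period * rate))
            for s in range(n_strides + 1)
            if (s + offset) * period * rate <= n - 1
        ]
        toe_offs = [
            int(round((s + offset + STANCE_FRACTION) * period * rate))
            for s in range(n_strides + 1)
            if (s + offset + STANCE_FRACTION) * period * rate <= n - 1
        ]
        events[side] = {"contact": contacts, "toe_off": toe_offs}
    return angles, events


def _pelvis_path(
    n: int, rate: float, speed: float, height: float, period: float
) -> PoseSequence:
    """Straight-line progression along +x with small vertical/lateral
    sinusoidal oscillation at step frequency; identity orientation plus a
    slight sinusoidal axial sway."""
    t = np.arange(n) / rate
    x = speed * t
    y = 0.01 * np.sin(2 * np.pi * t / period)
    z = 0.53 * height + 0.015 * np.sin(4 * np.pi * t / period)
    origins = np.column_stack([x, y, z])
    sway = np.deg2rad(2.0) * np.sin(2 * np.pi * t / period)
    orientations = quat.from_axis_angle(np.array([0.0, 0.0, 1.0]), sway)
    return PoseSequence(rate=rate, orientations=orientations, origins=origins)


def forward_kinematics(
    angles: np.ndarray,
    subject: SubjectSpec,
    pelvis_path: PoseSequence,
) -> dict[str, PoseSequence]:
    """Build segment pose sequences from joint-angle curves.

    Thigh orientation = pelvis ⊗ hip rotation (Cardan composition in the
    configured order); shank = thigh ⊗ knee rotation.  Origins chain along the
    distal (−z) axis by the subject's segment lengths, starting from hip
    joints offset laterally by half the pelvis width.
    """
    n = len(pelvis_path)
    if angles.shape != (len(CHANNELS), n):
        raise ValueError(
            f"angles shape {angles.shape} incompatible with pelvis path length {n}"
        )
    rate = pelvis_path.rate
    half_w = subject.segment_lengths["pelvis_width"] / 2.0
    poses: dict[str, PoseSequence] = {"pelvis": pelvis_path}
    for side, sign in (("L", 1.0), ("R", -1.0)):
        hip_idx = [CHANNELS.index(f"hip_{side}_{c}") for c in COMPONENTS]
        knee_idx = [CHANNELS.index(f"knee_{side}_{c}") for c in COMPONENTS]
        q_hip = cardan_to_quat(angles[hip_idx].T)
        q_knee = cardan_to_quat(angles[knee_idx].T)
        q_thigh = quat.qmult(pelvis_path.orientations, q_hip)
        q_shank = quat.qmult(q_thigh, q_knee)
        hip_origin = pelvis_path.origins + quat.qrotate(
            pelvis_path.orientations, np.array([0.0, sign * half_w, 0.0])
        )
        knee_origin = hip_origin + quat.qrotate(
            q_thigh, np.array([0.0, 0.0, -subject.segment_lengths["thigh"]])
        )
        poses[f"thigh_{side}"] = PoseSequence(rate, q_thigh, hip_origin)
        poses[f"shank_{side}"] = PoseSequence(rate, q_shank, knee_origin)
    return poses


def synth_moments(
    subject: SubjectSpec,
    angles: np.ndarray,
    events: dict,
    rate: float = DEFAULT_RATE,
) -> np.ndarray:
    """Normalized joint-moment curves: stance-phase templates, zero outside
    stance and exactly zero at foot contact.

    Sagittal channels get a characteristic double-hump shape
    (sin(πτ) − β sin(2πτ) over stance fraction τ); non-sagittal channels a
    single hump with smaller magnitude.  Curves are stored normalized by
    mass·g·height, so the normalized shape is subject-scale invariant while
    the implied unnormalized moment scales with mass × height.
    """
    n = angles.shape[1]
    rng = np.random.default_rng(subject.seed + 101)
    mods = {ch: rng.uniform(0.8, 1.2) for ch in CHANNELS}
    betas = {ch: rng.uniform(0.3, 0.6) for ch in CHANNELS}
    moments = np.zeros((len(CHANNELS), n))
    for k, ch in enumerate(CHANNELS):
        side = ch.split("_")[1]
        comp = ch.rsplit("_", 1)[1]
        scale = _MOMENT_SCALE[comp] * mods[ch]
        ev = events[side]
        for c in ev["contact"]:
            offs = [to for to in ev["toe_off"] if to > c]
            if not offs:
                continue
            to = offs[0]
            tau = np.linspace(0.0, 1.0, to - c + 1)
            if comp == "flexion":
                shape = np.sin(np.pi * tau) - betas[ch] * np.sin(2 * np.pi * tau)
            else:
                shape = np.sin(np.pi * tau)
            moments[k, c : to + 1] = scale * shape
    return moments


def make_trial(
    subject: SubjectSpec, speed: float, n_strides: int = 2, rate: float = DEFAULT_RATE
) -> GaitTrial:
    """Generate one complete trial (angles, events, poses, moments)."""
    angles, events = synth_joint_angles(subject, speed, n_strides, rate)
    period = stride_period(speed)
    pelvis = _pelvis_path(angles.shape[1], rate, speed, subject.height, period)
    poses = forward_kinematics(angles, subject, pelvis)
    moments = synth_moments(subject, angles, events, rate)
    return GaitTrial(
        subject_id=subject.subject_id,
        speed=speed,
        rate=rate,
        joint_angles=angles,
        joint_moments=moments,
        events=events,
        segment_poses=poses,
    )


@dataclass
class NoiseConfig:
    """Additive measurement-noise model for 'measured' IMU trials: white
    Gaussian noise plus a per-trial constant bias per channel."""

    sigma_accel: float = 0.2  # m/s²
    sigma_gyro: float = 0.02  # rad/s
    bias_accel: float = 0.05  # m/s², SD of per-trial constant bias
    bias_gyro: float = 0.005  # rad/s

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0)


def _noisy(sig: IMUSignal, cfg: NoiseConfig, rng: np.random.Generator) -> IMUSignal:
    a = sig.accel + rng.normal(0, cfg.sigma_accel, sig.accel.shape)
    g = sig.gyro + rng.normal(0, cfg.sigma_gyro, sig.gyro.shape)
    a = a + rng.normal(0, cfg.bias_accel, 3) if cfg.bias_accel else a
    g = g + rng.normal(0, cfg.bias_gyro, 3) if cfg.bias_gyro else g
    return IMUSignal(rate=sig.rate, accel=a, gyro=g)


def make_dataset(
    cohort: list[SubjectSpec],
    trials_per_subject: int = 3,
    noise_config: NoiseConfig | None = None,
    seed: int = 0,
    n_strides: int = 2,
    rate: float = DEFAULT_RATE,
) -> StudyBundle:
    """Assemble the full study bundle.

    For every subject and trial: poses, angles, moments.  Flagged subjects
    additionally get "measured" IMU trials — their own placements simulated
    plus configured noise and bias.  The placement library is the set of
    flagged subjects' placements; every library entry is applied to every
    source trial, so the augmented count is |library| × |trials|.
    """
    noise_config = noise_config or NoiseConfig()
    rng = np.random.default_rng(seed)
    trials: list[GaitTrial] = []
    measured: dict[tuple[str, int], dict[str, IMUSignal]] = {}
    library = {
        s.subject_id: s.placements for s in cohort if s.has_ground_truth_sensors
    }
    for subject in cohort:
        speeds = rng.uniform(SPEED_RANGE[0], SPEED_RANGE[1], trials_per_subject)
        for j, speed in enumerate(speeds):
            trial = make_trial(subject, float(speed), n_strides, rate)
            trial_index = len(trials)
            trials.append(trial)
            if subject.has_ground_truth_sensors:
                measured[(subject.subject_id, trial_index)] = {
                    seg: _noisy(
                        simulate_imu(trial.segment_poses[seg], subject.placements[seg]),
                        noise_config,
                        rng,
                    )
                    for seg in SEGMENTS
                }
    augmented = []
    if library:
        for ti, trial in enumerate(trials):
            sims = augment(trial.segment_poses, list(library.values()))
            for pid, imu in zip(library.keys(), sims):
                augmented.append(
                    {"trial_index": ti, "placement_subject": pid, "imu": imu}
                )
    return StudyBundle(
        cohort=cohort,
        trials=trials,
        measured_imu=measured,
        augmented=augmented,
        placement_library=library,
    )
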