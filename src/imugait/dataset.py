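"""From study bundle to network samples.

Applies the conditioning chain (zero-lag Butterworth filtering, phase
windowing, time normalization) to every simulated and measured IMU trial in a
:class:`~imugait.syngait.StudyBundle` and produces :class:`Sample` objects
ready for tensor assembly.  Kinematic targets are normalized over the step
phase (right-foot contact to next contact); kinetic targets over the stance
phase (contact to toe-off); the inputs use the same window as their targets.
"""

from __future__ import annotations

import numpy as np

from .preprocess import N_POINTS, Sample, imu_trial_matrix, time_normalize, zero_lag_butter
from .syngait import GaitTrial, StudyBundle

OPTICAL_FILTER = (4, 6.0)  # order, cutoff Hz (zero-lag, optical-derived curves)
IMU_FILTER = (1, 5.0)  # order, cutoff Hz (zero-lag, inertial channels)


def trial_window(trial: GaitTrial, target: str) -> tuple[int, int]:
    """Phase window of a trial: step (kinematics) or stance (kinetics),
    referenced to the right foot."""
    ev = trial.events["R"]
    c0 = ev["contact"][0]
    if target == "angles":
        if len(ev["contact"]) < 2:
            raise ValueError("trial too short: no full step")
        return c0, ev["contact"][1]
    if target == "moments":
        toe = [t for t in ev["toe_off"] if t > c0]
        if not toe:
            raise ValueError("trial too short: no stance phase")
        return c0, toe[0]
    raise ValueError(f"unknown target {target!r}")


def _target_curves(trial: GaitTrial, target: str) -> np.ndarray:
    y = trial.joint_angles if target == "angles" else trial.joint_moments
    return zero_lag_butter(y, OPTICAL_FILTER[0], OPTICAL_FILTER[1], trial.rate)


def make_sample(
    trial: GaitTrial,
    imu: dict,
    placement_label: str,
    trial_index: int,
    target: str = "angles",
    n_points: int = N_POINTS,
) -> Sample:
    """Condition one (trial, IMU realisation) pair into a network sample."""
    x = zero_lag_butter(
        imu_trial_matrix(imu), IMU_FILTER[0], IMU_FILTER[1], trial.rate
    )
    y = _target_curves(trial, target)
    start, end = trial_window(trial, target)
    return Sample(
        x=time_normalize(x, start, end, n_points),
        y=time_normalize(y, start, end, n_points),
        index=(trial.subject_id, trial_index, placement_label),
    )


def build_samples(
    bundle: StudyBundle,
    target: str = "angles",
    n_points: int = N_POINTS,
    include_augmented: bool = True,
    include_measured: bool = True,
) -> list[Sample]:
    """All samples of a bundle: augmented (simulated under the placement
    library) and measured-IMU trials.  The placement field of the sample
    index is the placement-donor subject id, or ``"measured"``."""
    samples: list[Sample] = []
    if include_augmented:
        for entry in bundle.augmented:
            trial = bundle.trials[entry["trial_index"]]
            samples.append(
                make_sample(
                    trial,
                    entry["imu"],
                    entry["placement_subject"],
                    entry["trial_index"],
                    target,
                    n_points,
                )
            )
    if include_measured:
        for (subject_id, trial_index), imu in bundle.measured_imu.items():
            trial = bundle.trials[trial_index]
            samples.append(
                make_sample(trial, imu, "measured", trial_index, target, n_points)
            )
    return samples


def split_by_subject(
    samples: list[Sample], test_subjects: set[str]
) -> tuple[list[Sample], list[Sample]]:
    """Partition samples so no test subject's trials (measured or simulated)
    reach the training side."""
    train = [s for s in samples if s.index[0] not in test_subjects]
    test = [s for s in samples if s.index[0] in test_subjects]
    return train, test
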