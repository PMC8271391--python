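"""Rigid-body pose sequences and the virtual-IMU simulator.

A segment's motion is a :class:`PoseSequence` — a uniformly sampled series of
unit quaternions (body->global) and origin positions (metres, global frame).
A :class:`SensorPlacement` is the rigid sensor-to-segment transform; composing
it with a segment pose gives the sensor pose, from which the simulator derives

* angular rate ``ω = 2 · vec(q* ⊗ q̇)`` (body frame, rad/s), with the
  quaternion derivative taken by central differences, and
* specific force ``f = Rᵀ (p̈ − g)`` (sensor frame, m/s²), with the second
  derivative of the sensor origin by central differences and gravity
  ``g = (0, 0, −9.81)`` in a z-up global frame — the quantity a real
  accelerometer reports.

Differentiation uses second-order stencils throughout (one-sided at the
endpoints), so both signals converge at O(dt²) against analytic motions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import quat

logger = logging.getLogger(__name__)

GRAVITY = np.array([0.0, 0.0, -9.81])
SEGMENTS = ("pelvis", "thigh_L", "thigh_R", "shank_L", "shank_R")

#: Intrinsic Cardan sequence for lower-limb joint decomposition:
#: flexion–extension (z), ab-adduction (x), internal–external rotation (y).
CARDAN_ORDER = "ZXY"


@dataclass
class PoseSequence:
    """Uniformly sampled rigid-body pose path.

    Parameters
    ----------
    rate : float
        Sampling rate, Hz.
    orientations : (n, 4) ndarray
        Unit quaternions, scalar-first, body->global.
    origins : (n, 3) ndarray
        Body origin in the global frame, metres.
    """

    rate: float
    orientations: np.ndarray
    origins: np.ndarray

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.origins = np.asarray(self.origins, dtype=float)
        if len(self.orientations) != len(self.origins):
            raise ValueError("orientations and origins length mismatch")
        if len(self.orientations) < 3:
            raise ValueError("a pose sequence needs at least 3 frames")
        if not (np.isfinite(self.orientations).all() and np.isfinite(self.origins).all()):
            raise ValueError("non-finite pose values")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            warnings.warn("non-unit quaternions in pose sequence; normalizing")
            self.orientations = self.orientations / norms[:, None]
        self.orientations = quat.hemisphere_correct(self.orientations)

    def __len__(self) -> int:
        return len(self.orientations)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclass(frozen=True)
class SensorPlacement:
    """Rigid sensor-to-segment offset: translation in the segment frame plus a
    segment->sensor rotation quaternion."""

    segment_id: str
    offset_t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    offset_q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "offset_t", np.asarray(self.offset_t, dtype=float))
        object.__setattr__(
            self, "offset_q", quat.canonicalize(quat.qnormalize(self.offset_q))
        )
        if self.segment_id not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment_id!r}")
        if np.linalg.norm(self.offset_t) > 0.5:
            raise ValueError("sensor offset exceeds 0.5 m")


@dataclass
class IMUSignal:
    """Tri-axial specific force (m/s²) and angular rate (rad/s), sensor frame."""

    rate: float
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape != self.gyro.shape:
            raise ValueError("accel and gyro must have the same shape")
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise ValueError("non-finite IMU values")

    def __len__(self) -> int:
        return len(self.accel)

    def as_matrix(self) -> np.ndarray:
        """Stack to a (6, n) channel matrix (ax ay az gx gy gz)."""
        return np.vstack([self.accel.T, self.gyro.T])


def _ddt(x: np.ndarray, dt: float) -> np.ndarray:
    """First derivative, central differences, second-order one-sided ends."""
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2 * dt)
    d[0] = (-3 * x[0] + 4 * x[1] - x[2]) / (2 * dt)
    d[-1] = (3 * x[-1] - 4 * x[-2] + x[-3]) / (2 * dt)
    return d


def _d2dt2(x: np.ndarray, dt: float) -> np.ndarray:
    """Second derivative, central differences, second-order one-sided ends."""
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt**2
    if len(x) >= 4:
        d[0] = (2 * x[0] - 5 * x[1] + 4 * x[2] - x[3]) / dt**2
        d[-1] = (2 * x[-1] - 5 * x[-2] + 4 * x[-3] - x[-4]) / dt**2
    else:
        d[0] = d[1]
        d[-1] = d[-2]
    return d


def angular_rate(pose: PoseSequence) -> np.ndarray:
    """Body-frame angular rate from the quaternion derivative.

    ω(t) = 2 · vec( q*(t) ⊗ q̇(t) ), rad/s; same length as the input.
    """
    q = pose.orientations
    qdot = _ddt(q, pose.dt)
    return 2.0 * quat.qmult(quat.qconj(q), qdot)[:, 1:]


def sensor_pose(segment: PoseSequence, placement: SensorPlacement) -> PoseSequence:
    """Compose a segment pose with a rigid sensor placement.

    q_s = q_seg ⊗ offset_q;  p_s = p_seg + R(q_seg) · offset_t.
    """
    q_s = quat.qmult(segment.orientations, placement.offset_q)
    p_s = segment.origins + quat.qrotate(segment.orientations, placement.offset_t)
    return PoseSequence(rate=segment.rate, orientations=q_s, origins=p_s)


def simulate_accel(sensor: PoseSequence, g_vec: np.ndarray = GRAVITY) -> np.ndarray:
    """Specific force in the sensor frame: f = R(q)ᵀ · (p̈ − g)."""
    p_dd = _d2dt2(sensor.origins, sensor.dt)
    # Rᵀ v == rotation of v by the conjugate quaternion (global->body)
    return quat.qrotate(quat.qconj(sensor.orientations), p_dd - np.asarray(g_vec, float))


def simulate_imu(
    segment: PoseSequence,
    placement: SensorPlacement,
    g_vec: np.ndarray = GRAVITY,
) -> IMUSignal:
    """Full virtual-IMU simulation: placement composition then accel/gyro."""
    s = sensor_pose(segment, placement)
    return IMUSignal(rate=s.rate, accel=simulate_accel(s, g_vec), gyro=angular_rate(s))


def relative_orientation(parent: PoseSequence, child: PoseSequence) -> np.ndarray:
    """Per-frame joint quaternion q_rel = q_parent* ⊗ q_child, hemisphere
    corrected across frames."""
    if len(parent) != len(child):
        raise ValueError("parent and child sequences differ in length")
    q_rel = quat.qmult(quat.qconj(parent.orientations), child.orientations)
    return quat.hemisphere_correct(q_rel)


def cardan_angles(
    q_rel: np.ndarray, order: str = CARDAN_ORDER, gimbal_tol_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Intrinsic Cardan decomposition of joint quaternions, degrees.

    Returns ``(angles, gimbal_flags)`` where ``angles`` is (n, 3) unwrapped to
    be continuous across frames and ``gimbal_flags`` marks frames whose middle
    angle lies within ``gimbal_tol_deg`` of ±90° (near the Cardan singularity,
    where the decomposition is ill-conditioned; scipy's degenerate-case
    formula is used at exact lock).
    """
    q_rel = np.atleast_2d(np.asarray(q_rel, dtype=float))
    quat.assert_unit(q_rel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at exact gimbal lock
        ang = quat.to_scipy(q_rel).as_euler(order, degrees=True)
    ang = np.unwrap(ang, axis=0, period=360.0)
    gimbal = np.abs(np.abs(ang[:, 1]) - 90.0) < gimbal_tol_deg
    return ang, gimbal


def cardan_to_quat(angles_deg: np.ndarray, order: str = CARDAN_ORDER) -> np.ndarray:
    """Inverse of :func:`cardan_angles` (composition of elemental rotations)."""
    r = Rotation.from_euler(order, np.atleast_2d(angles_deg), degrees=True)
    return quat.from_scipy(r)


# ---------------------------------------------------------------------------
# sensor-to-segment placement fitting and placement-library augmentation


@dataclass
class PlacementFit:
    """Result of :func:`fit_placement`: recovered placement, final mean-squared
    residual and optimizer convergence flag."""

    placement: SensorPlacement
    residual: float
    converged: bool


def fit_placement(
    segment: PoseSequence,
    measured: IMUSignal,
    init: SensorPlacement,
    gyro_weight: float = 1.0,
    g_vec: np.ndarray = GRAVITY,
) -> PlacementFit:
    """Recover the sensor-to-segment transform from measured IMU data.

    Minimizes the mean squared discrepancy between the simulated and measured
    accelerometer and gyroscope channels over the 6 placement parameters
    (translation + rotation vector), by bounded local least squares from the
    given initial guess.  Gyro channels are weighted by ``gyro_weight``.
    Deterministic given the initial guess.
    """
    if len(measured) != len(segment):
        raise ValueError("measured signal and segment pose must be time-aligned")
    if abs(measured.rate - segment.rate) > 1e-9:
        raise ValueError("measured signal and segment pose rate mismatch")

    sqrt_w = np.sqrt(gyro_weight)

    def pack(p: SensorPlacement) -> np.ndarray:
        rv = quat.to_scipy(p.offset_q).as_rotvec()
        return np.concatenate([p.offset_t, rv])

    def unpack(x: np.ndarray) -> SensorPlacement:
        q = quat.from_scipy(Rotation.from_rotvec(x[3:]))
        return SensorPlacement(init.segment_id, offset_t=x[:3], offset_q=q)

    def residuals(x: np.ndarray) -> np.ndarray:
        sim = simulate_imu(segment, unpack(x), g_vec)
        return np.concatenate(
            [
                (sim.accel - measured.accel).ravel(),
                sqrt_w * (sim.gyro - measured.gyro).ravel(),
            ]
        )

    x0 = pack(init)
    bounds = (
        np.concatenate([x0[:3] - 0.2, x0[3:] - 0.6]),
        np.concatenate([x0[:3] + 0.2, x0[3:] + 0.6]),
    )
    sol = least_squares(residuals, x0, bounds=bounds, xtol=1e-12, ftol=1e-12)
    n = residuals(sol.x).size
    fit = PlacementFit(
        placement=unpack(sol.x),
        residual=2.0 * sol.cost / n,  # mean squared residual per channel sample
        converged=bool(sol.status > 0),
    )
    if not fit.converged:
        logger.warning("placement optimization did not converge; returning best iterate")
    return fit


def augment(
    trial_segments: dict[str, PoseSequence],
    library: list[dict[str, SensorPlacement]],
    g_vec: np.ndarray = GRAVITY,
) -> list[dict[str, IMUSignal]]:
    """Simulate one 5-sensor IMU trial per placement set in the library.

    Replaying a single motion trial under many sensor placements widens the
    training distribution (placement augmentation); the output count equals
    the library size, in library order.
    """
    if not library:
        raise ValueError("placement library is empty")
    out = []
    for pset in library:
        missing = set(SEGMENTS) - set(pset)
        if missing:
            raise ValueError(f"placement set missing segments: {sorted(missing)}")
        out.append(
            {
                seg: simulate_imu(trial_segments[seg], pset[seg], g_vec)
                for seg in SEGMENTS
            }
        )
    return out
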