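"""Signal conditioning and dataset-tensor assembly.

Pipeline steps between raw trials and network-ready tensors:

* zero-lag Butterworth low-pass filtering (4th order / 6 Hz for optical-
  derived curves, 1st order / 5 Hz for IMU channels, both forward–backward);
* cross-correlation lag synchronization of IMU and optical streams;
* time normalization of every curve onto a fixed number of points (101) over
  a gait phase — step (contact to contact) for kinematics, stance (contact to
  toe-off) for kinetics;
* moment normalization by body weight × height (M / (m·g·h));
* an ensemble sanity filter that drops curves outside a 95% band;
* assembly of the three network-specific layouts (flat matrix, rank-3
  sequence tensor, RGB-image tensor) plus train-partition-only scalers.

Channel order is a frozen contract: sensors (pelvis, thigh_L, thigh_R,
shank_L, shank_R), accelerometer before gyroscope, axes x, y, z — 30 input
channels; 18 output channels as in :data:`imugait.syngait.CHANNELS`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import norm
from skimage.transform import resize

from .rigid import SEGMENTS, IMUSignal

#: Frozen 30-channel input order (sensor-major; accel before gyro; x, y, z).
INPUT_CHANNELS = tuple(
    f"{seg}_{kind}_{ax}"
    for seg in SEGMENTS
    for kind in ("accel", "gyro")
    for ax in ("x", "y", "z")
)

N_POINTS = 101
IMAGE_SIDE = 224

# ---------------------------------------------------------------------------
# filtering / synchronization / normalization


def zero_lag_butter(
    x: np.ndarray, order: int, cutoff_hz: float, rate_hz: float
) -> np.ndarray:
    """Forward–backward (zero-phase) Butterworth low-pass along the last axis.

    The forward–backward pass doubles the effective order but cancels the
    phase delay, so filtered peaks stay aligned with the raw signal.
    """
    if cutoff_hz >= rate_hz / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def sync_lag(a: np.ndarray, b: np.ndarray, max_lag: int) -> int:
    """Integer lag of ``b`` relative to ``a`` maximizing normalized
    cross-correlation; ties break toward the smallest ``|lag|``.

    Intended for gyroscope-magnitude channels of two recordings of the same
    motion.  Positive lag means ``b`` is delayed by that many samples.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 * max_lag or len(b) < 2 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input; cannot synchronize")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = az[: len(az) - lag], bz[lag:lag + len(az) - lag]
        else:
            x, y = az[-lag:], bz[: len(bz) + lag]
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        scores[i] = float(np.dot(x, y) / n) if n else -np.inf
    best = scores.max()
    candidates = lags[np.isclose(scores, best, rtol=0, atol=1e-12)]
    return int(candidates[np.argmin(np.abs(candidates))])


def time_normalize(
    x: np.ndarray, start: int, end: int, n_points: int = N_POINTS
) -> np.ndarray:
    """Resample ``x[..., start:end]`` onto ``n_points`` equally spaced samples
    spanning [start, end] inclusive, by linear interpolation.

    Endpoints are preserved exactly; linear interpolation also preserves
    monotone segments.
    """
    x = np.asarray(x, dtype=float)
    if not (0 <= start < end < x.shape[-1]):
        raise ValueError(f"degenerate window [{start}, {end}]")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    src = np.arange(start, end + 1)
    dst = np.linspace(start, end, n_points)
    if x.ndim == 1:
        return np.interp(dst, src, x[start : end + 1])
    flat = x.reshape(-1, x.shape[-1])
    out = np.stack([np.interp(dst, src, row[start : end + 1]) for row in flat])
    return out.reshape(*x.shape[:-1], n_points)


G = 9.81


def moment_normalize(moments: np.ndarray, mass: float, height: float) -> np.ndarray:
    """Normalize joint moments (N·m) by body weight × height: M / (m·g·h)."""
    if mass <= 0 or height <= 0:
        raise ValueError("mass and height must be positive")
    return np.asarray(moments, dtype=float) / (mass * G * height)


def moment_denormalize(moments: np.ndarray, mass: float, height: float) -> np.ndarray:
    """Inverse of :func:`moment_normalize`."""
    if mass <= 0 or height <= 0:
        raise ValueError("mass and height must be positive")
    return np.asarray(moments, dtype=float) * (mass * G * height)


# ---------------------------------------------------------------------------
# ensemble sanity filter


@dataclass
class CIFilterReport:
    kept: list[int]
    excluded: list[int]
    scores: np.ndarray
    threshold: float


def ci_filter(samples: np.ndarray, level: float = 0.95) -> CIFilterReport:
    """Exclude curves that fall outside the ensemble's confidence band.

    Each sample (shape ``(n_samples, ...)``, remaining axes channels × time)
    is scored by the mean robust z-score magnitude over all points, where the
    pointwise center and scale are the ensemble median and 1.4826·MAD.  A
    sample is excluded when its score exceeds the ``level``-quantile of the
    score's Gaussian-null distribution (half-normal mean, CLT over the number
    of points).  Robust statistics keep the filter nearly idempotent: the
    kept set re-scores almost unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for the ensemble filter")
    flat = samples.reshape(n, -1)
    center = np.median(flat, axis=0)
    mad = np.median(np.abs(flat - center), axis=0)
    scale = 1.4826 * mad
    ok = scale > 0
    if not ok.any():
        warnings.warn("zero spread everywhere; no samples excluded")
        return CIFilterReport(list(range(n)), [], np.zeros(n), np.inf)
    z = np.abs(flat[:, ok] - center[ok]) / scale[ok]
    scores = z.mean(axis=1)
    n_pts = ok.sum()
    # Null: score is the mean of n_pts half-normal variates
    mu = np.sqrt(2 / np.pi)
    sd = np.sqrt(1 - 2 / np.pi) / np.sqrt(n_pts)
    threshold = float(mu + norm.ppf(level) * sd)
    excluded = np.flatnonzero(scores > threshold)
    kept = np.flatnonzero(scores <= threshold)
    return CIFilterReport(kept.tolist(), excluded.tolist(), scores, threshold)


# ---------------------------------------------------------------------------
# tensor assembly


@dataclass
class Sample:
    """One network sample: a 30×T input matrix, an 18×T target matrix and the
    (subject, trial, placement) provenance index."""

    x: np.ndarray  # (30, n_points)
    y: np.ndarray  # (18, n_points)
    index: tuple  # (subject_id, trial, placement)


@dataclass
class Scaler:
    """Per-feature affine scaler: standardization (flat/sequence layouts) or
    min–max to [0, 1] (image layout).  Fitted on the training partition only;
    constant features map to 0 without division by zero."""

    kind: str  # "standard" | "minmax"
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, X: np.ndarray, axes: tuple[int, ...]) -> "Scaler":
        if self.kind == "standard":
            self.center = X.mean(axis=axes, keepdims=True)
            s = X.std(axis=axes, keepdims=True)
        elif self.kind == "minmax":
            self.center = X.min(axis=axes, keepdims=True)
            s = X.max(axis=axes, keepdims=True) - self.center
        else:
            raise ValueError(f"unknown scaler kind {self.kind!r}")
        self.scale = np.where(s == 0, 1.0, s)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.center is None:
            raise RuntimeError("scaler not fitted")
        return (X - self.center) / self.scale

    def inverse(self, X: np.ndarray) -> np.ndarray:
        if self.center is None:
            raise RuntimeError("scaler not fitted")
        return X * self.scale + self.center


@dataclass
class DatasetTensors:
    """A network-ready dataset in one of the three layouts."""

    layout: str  # "flat" | "sequence" | "image"
    X: np.ndarray
    Y: np.ndarray
    sample_index: list[tuple]
    x_scaler: Scaler | None = None
    y_scaler: Scaler | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_index)


def imu_trial_matrix(imu: dict[str, IMUSignal]) -> np.ndarray:
    """Stack a 5-sensor IMU trial to the frozen 30×n channel matrix."""
    rows = []
    for seg in SEGMENTS:
        sig = imu[seg]
        rows.append(sig.accel.T)
        rows.append(sig.gyro.T)
    return np.vstack(rows)


def _stack(samples: list[Sample]) -> tuple[np.ndarray, np.ndarray, list]:
    if not samples:
        raise ValueError("no samples to assemble")
    n_pts = samples[0].x.shape[1]
    for s in samples:
        if s.x.shape != (len(INPUT_CHANNELS), n_pts) or s.y.shape[1] != n_pts:
            raise ValueError("inconsistent sample shapes; time-normalize first")
    X = np.stack([s.x for s in samples])
    Y = np.stack([s.y for s in samples])
    return X, Y, [s.index for s in samples]


def assemble_sequence(samples: list[Sample]) -> DatasetTensors:
    """Rank-3 layout: X [n × 30 × T], Y [n × 18 × T]."""
    X, Y, idx = _stack(samples)
    return DatasetTensors("sequence", X, Y, idx)


def assemble_flat(samples: list[Sample]) -> DatasetTensors:
    """Flat layout: channels concatenated (channel-major, time fastest):
    X [n × 30·T], Y [n × 18·T]."""
    X, Y, idx = _stack(samples)
    return DatasetTensors(
        "flat", X.reshape(len(idx), -1), Y.reshape(len(idx), -1), idx
    )


def flat_to_sequence(X: np.ndarray, n_channels: int) -> np.ndarray:
    """Undo :func:`assemble_flat`'s concatenation."""
    n = X.shape[0]
    return X.reshape(n, n_channels, -1)


def native_image_grid(samples: list[Sample]) -> np.ndarray:
    """Native-resolution image encoding before interpolation:
    [n × 10 × T × 3] with rows = 5 sensors × {accel, gyro} and RGB channels =
    the x/y/z signal axes."""
    X, _, _ = _stack(samples)
    n, _, n_pts = X.shape
    return X.reshape(n, 10, 3, n_pts).transpose(0, 1, 3, 2)


def assemble_image(
    samples: list[Sample],
    side: int = IMAGE_SIDE,
    scaler: Scaler | None = None,
) -> DatasetTensors:
    """Image layout: the native 10×T×3 grid min–max scaled to [0, 1] per RGB
    channel and bilinearly interpolated to ``side × side × 3``.

    ``scaler`` must be the scaler fitted on the training partition when
    assembling validation/test data; when omitted, a new scaler is fitted on
    these samples (training partition).
    """
    grid = native_image_grid(samples)
    if scaler is None:
        scaler = Scaler("minmax").fit(grid, axes=(0, 1, 2))
    grid = scaler.transform(grid)
    n = grid.shape[0]
    imgs = np.empty((n, side, side, 3))
    for i in range(n):
        imgs[i] = resize(
            grid[i], (side, side, 3), order=1, mode="edge", anti_aliasing=False
        )
    _, Y, idx = _stack(samples)
    return DatasetTensors("image", imgs, Y.reshape(n, -1), idx, x_scaler=scaler)


def fit_scalers(train: DatasetTensors) -> DatasetTensors:
    """Fit X/Y scalers on a training partition and return the scaled tensors.

    flat and sequence layouts use per-feature standardization; the image
    layout's X is already min–max scaled at assembly, so only Y is fitted.
    """
    t = DatasetTensors(train.layout, train.X, train.Y, train.sample_index,
                       train.x_scaler, train.y_scaler)
    if t.layout in ("flat", "sequence"):
        t.x_scaler = Scaler("standard").fit(t.X, axes=(0,))
        t.X = t.x_scaler.transform(t.X)
    t.y_scaler = Scaler("standard").fit(t.Y, axes=(0,))
    t.Y = t.y_scaler.transform(t.Y)
    return t


def apply_scalers(tensors: DatasetTensors, fitted: DatasetTensors) -> DatasetTensors:
    """Apply a training partition's scalers to another partition."""
    X = tensors.X
    if fitted.x_scaler is not None and tensors.layout in ("flat", "sequence"):
        X = fitted.x_scaler.transform(X)
    if fitted.y_scaler is None:
        raise RuntimeError("training scalers not fitted")
    Y = fitted.y_scaler.transform(tensors.Y)
    return DatasetTensors(
        tensors.layout, X, Y, tensors.sample_index, fitted.x_scaler, fitted.y_scaler
    )
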