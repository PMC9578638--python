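"""Extended Kalman filter for per-segment angular kinematics.

The state x = [theta, omega, alpha] evolves under a constant-jerk-free
kinematic chain (F integrates alpha into omega into theta over one sample
period) with additive Gaussian process noise Q, and is observed through
the nonlinear planar sensor model h(x) of :mod:`sit2stand.forward_model`
with measurement noise R.  The filter is run independently for the shank
and the back, each from its own (ax, ay, gyr_z) stream.

Default noise covariances (for sampling period dt, gravity g):

    Q = diag[(dt/2)^2, (0.1*dt)^2, 0.04^2]
    R = diag[(g/10)^2, (g/10)^2,  0.005^2]

The small gyro variance makes the angular-velocity estimate track the
gyroscope closely while the accelerometer channels anchor the absolute
angle through gravity, removing the drift a pure gyro integration would
accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import InvalidArgumentError, NumericalError
from .forward_model import (
    GRAVITY,
    AngularState,
    PlanarMeasurement,
    SensorGeometry,
    measurement_jacobian,
    predict_measurement,
)

Placement = Literal["shank", "back"]

# Samples assumed static at trial start, used to initialize theta from the
# gravity direction (trials begin seated and still).
_N_INIT_STATIC = 25


@dataclass(frozen=True)
class EkfConfig:
    """Filter configuration: sampling period, noise covariances, and the
    initial state/covariance."""

    dt: float
    F: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    x0: AngularState = field(default_factory=lambda: AngularState(0.0, 0.0, 0.0))
    P0: np.ndarray = field(default_factory=lambda: np.diag([0.1**2, 0.1**2, 0.5**2]))

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise InvalidArgumentError(f"dt must be positive, got {self.dt!r}")
        for name in ("Q", "R", "P0"):
            m = getattr(self, name)
            if m.shape != (3, 3):
                raise InvalidArgumentError(f"{name} must be 3x3")
            if not np.allclose(m, m.T):
                raise InvalidArgumentError(f"{name} must be symmetric")
            if np.any(np.diag(m) < 0):
                raise InvalidArgumentError(f"{name} diagonal must be non-negative")


def make_default_config(dt: float = 0.02, gravity: float = GRAVITY) -> EkfConfig:
    """Build the standard filter configuration for sampling period ``dt``."""
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidArgumentError(f"dt must be positive, got {dt!r}")
    F = np.array([[1.0, dt, dt**2 / 2.0], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    Q = np.diag([(dt / 2.0) ** 2, (0.1 * dt) ** 2, 0.04**2])
    R = np.diag([(gravity / 10.0) ** 2, (gravity / 10.0) ** 2, 0.005**2])
    return EkfConfig(dt=dt, F=F, Q=Q, R=R)


@dataclass
class InertialStream:
    """One mounted sensor's time-synchronized 6-axis record.

    Channels are SI (m/s^2, rad/s) on a uniform time base.  Only ax, ay and
    gz enter the planar model; az, gx, gy are carried through I/O untouched.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    placement: Placement
    geometry: SensorGeometry

    def __post_init__(self) -> None:
        arrays = [self.t, self.ax, self.ay, self.az, self.gx, self.gy, self.gz]
        n = len(self.t)
        if any(len(a) != n for a in arrays):
            raise InvalidArgumentError("all channels must have equal length")
        if n >= 2:
            steps = np.diff(self.t)
            dt = np.median(steps)
            if dt <= 0 or np.any(np.abs(steps - dt) > 0.1 * dt):
                raise InvalidArgumentError(
                    "timestamps must be uniformly spaced within 10%; resample at ingest"
                )
        for a in arrays:
            if not np.isfinite(a).all():
                raise InvalidArgumentError("stream contains non-finite values")
        if self.placement not in ("shank", "back"):
            raise InvalidArgumentError(f"placement must be 'shank' or 'back', got {self.placement!r}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class SegmentKinematics:
    """Angular kinematics time series for one segment (S, T or B)."""

    segment: Literal["S", "T", "B"]
    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("theta", "omega", "alpha"):
            a = getattr(self, name)
            if len(a) != n:
                raise InvalidArgumentError("kinematic channels must have equal length")
            if not np.isfinite(a).all():
                raise InvalidArgumentError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.t)


def ekf_step(
    state_mean: AngularState,
    state_cov: np.ndarray,
    z: PlanarMeasurement,
    cfg: EkfConfig,
    geom: SensorGeometry,
) -> tuple[AngularState, np.ndarray]:
    """One predict/update cycle of the filter.

    Predict propagates the mean through F and inflates the covariance by Q;
    update linearizes h at the predicted mean and applies the Joseph-form
    covariance update, which keeps P symmetric positive semi-definite in
    floating point.
    """
    F, Q, R = cfg.F, cfg.Q, cfg.R
    # Predict
    x_pred = F @ state_mean.as_vector()
    P_pred = F @ state_cov @ F.T + Q
    pred_state = AngularState.from_vector(x_pred)
    # Update
    H = measurement_jacobian(pred_state, geom)
    z_pred = predict_measurement(pred_state, geom).as_vector()
    innovation = z.as_vector() - z_pred
    S = H @ P_pred @ H.T + R
    try:
        K = np.linalg.solve(S, H @ P_pred).T
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"singular innovation covariance (cond issue): S diag {np.diag(S)}"
        ) from exc
    x_post = x_pred + K @ innovation
    IKH = np.eye(3) - K @ H
    P_post = IKH @ P_pred @ IKH.T + K @ R @ K.T
    P_post = (P_post + P_post.T) / 2.0
    return AngularState.from_vector(x_post), P_post


def initial_state(stream: InertialStream, n_static: int = _N_INIT_STATIC) -> AngularState:
    """Initial angle from the gravity direction over the first static samples.

    With the segment at rest, (ax, ay) is gravity rotated by theta, so
    theta0 = atan2(mean ax, mean ay); omega0 = alpha0 = 0.
    """
    n = min(n_static, len(stream))
    theta0 = float(np.arctan2(np.mean(stream.ax[:n]), np.mean(stream.ay[:n])))
    return AngularState(theta0, 0.0, 0.0)


def estimate_segment_kinematics(stream: InertialStream, cfg: EkfConfig | None = None) -> SegmentKinematics:
    """Run the filter over a stream, returning one state per sample.

    The segment label is 'S' for a shank-mounted sensor and 'B' for a
    back-mounted one.
    """
    if len(stream) < 10:
        raise InvalidArgumentError(f"stream too short ({len(stream)} samples; need >= 10)")
    if cfg is None:
        cfg = make_default_config(stream.dt)
    geom = stream.geometry
    mean = initial_state(stream)
    cov = cfg.P0.copy()

    n = len(stream)
    theta = np.empty(n)
    omega = np.empty(n)
    alpha = np.empty(n)
    for i in range(n):
        z = PlanarMeasurement(float(stream.ax[i]), float(stream.ay[i]), float(stream.gz[i]))
        mean, cov = ekf_step(mean, cov, z, cfg, geom)
        theta[i], omega[i], alpha[i] = mean.theta, mean.omega, mean.alpha

    segment = "S" if stream.placement == "shank" else "B"
    return SegmentKinematics(segment=segment, t=stream.t.copy(), theta=theta, omega=omega, alpha=alpha)
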