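"""Planar forward model of a single pivoting body segment.

A segment (shank or back) is modelled as a rigid link pivoting about a
fixed joint (ankle or hip) in the sagittal plane, with an inertial sensor
mounted at distance ``L`` along the link.  Given the segment's angular
state (angle from vertical ``theta``, angular velocity ``omega``, angular
acceleration ``alpha``), the accelerometer's in-plane axes see gravity
rotated into the sensor frame plus the tangential and centripetal
accelerations of the mount point, while the gyroscope's out-of-plane axis
reads the angular rate directly:

    ax    = g*sin(theta) - L*alpha
    ay    = g*cos(theta) - L*omega**2
    gyr_z = omega

Joint translation is neglected: the ankle is on the ground throughout a
sit-to-stand, and the same approximation is applied to the hip so the back
can be treated with the identical one-link model.

All quantities are SI (metres, radians, seconds).  This module is pure
computation: the EKF uses it as the measurement function h(x) and its
Jacobian, and the synthetic-data generator uses it to render ground-truth
kinematics into sensor streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

GRAVITY = 9.81
"""Standard gravity, m/s^2."""


@dataclass(frozen=True)
class AngularState:
    """Angular state of one segment: angle from vertical (rad), angular
    velocity (rad/s) and angular acceleration (rad/s^2)."""

    theta: float
    omega: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("theta", "omega", "alpha"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidArgumentError(f"AngularState.{name} must be finite, got {v!r}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.theta, self.omega, self.alpha], dtype=float)

    @staticmethod
    def from_vector(x: np.ndarray) -> "AngularState":
        return AngularState(float(x[0]), float(x[1]), float(x[2]))


@dataclass(frozen=True)
class SensorGeometry:
    """Sensor mounting: distance ``L`` (m) from the pivot joint along the
    segment, and local gravity (m/s^2)."""

    L: float
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L) and self.L > 0):
            raise InvalidArgumentError(f"SensorGeometry.L must be positive, got {self.L!r}")
        if not (np.isfinite(self.gravity) and self.gravity > 0):
            raise InvalidArgumentError(
                f"SensorGeometry.gravity must be positive, got {self.gravity!r}"
            )


@dataclass(frozen=True)
class PlanarMeasurement:
    """In-plane sensor reading: accelerometer x/y (m/s^2) and gyroscope z
    (rad/s)."""

    ax: float
    ay: float
    gyr_z: float

    def __post_init__(self) -> None:
        for name in ("ax", "ay", "gyr_z"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidArgumentError(f"PlanarMeasurement.{name} must be finite, got {v!r}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.ax, self.ay, self.gyr_z], dtype=float)


def predict_measurement(state: AngularState, geom: SensorGeometry) -> PlanarMeasurement:
    """Expected sensor reading for a segment in the given angular state.

    Gravity projects onto the sensor axes through the segment angle; the
    mount point at radius L contributes the tangential term L*alpha on x
    and the centripetal term L*omega^2 on y; the gyro z-axis reads omega.
    """
    g, L = geom.gravity, geom.L
    ax = g * np.sin(state.theta) - L * state.alpha
    ay = g * np.cos(state.theta) - L * state.omega**2
    return PlanarMeasurement(float(ax), float(ay), float(state.omega))


def measurement_jacobian(state: AngularState, geom: SensorGeometry) -> np.ndarray:
    """3x3 Jacobian of :func:`predict_measurement` w.r.t. [theta, omega, alpha].

    Needed to linearize the measurement function inside the EKF update.
    """
    g, L = geom.gravity, geom.L
    return np.array(
        [
            [g * np.cos(state.theta), 0.0, -L],
            [-g * np.sin(state.theta), -2.0 * L * state.omega, 0.0],
            [0.0, 1.0, 0.0],
        ]
    )


def predict_measurement_array(
    theta: np.ndarray, omega: np.ndarray, alpha: np.ndarray, geom: SensorGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized forward model over whole kinematic series.

    Returns (ax, ay, gyr_z) arrays; used by the synthetic-data renderer.
    """
    theta = np.asarray(theta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if not (np.isfinite(theta).all() and np.isfinite(omega).all() and np.isfinite(alpha).all()):
        raise InvalidArgumentError("kinematic series must be finite")
    g, L = geom.gravity, geom.L
    ax = g * np.sin(theta) - L * alpha
    ay = g * np.cos(theta) - L * omega**2
    return ax, ay, omega.copy()
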