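"""Thigh kinematics without a thigh sensor.

The thigh angle is pinned by posture in the stationary states — about 90
degrees seated, 0 degrees standing — and the transition between them is
modelled as a logistic sigmoid in time, the activation of a single neuron
whose weight ``w`` sets the transition speed, bias ``b`` its centre, gain
``G`` the angular range, and whose direction input ``x`` (the tier-2
classification result) selects the rising (stand-to-sit, x=0) or falling
(sit-to-stand, x=1) branch:

    theta_T(t) = G * exp(x * (-w (t - b))) / (1 + exp(-w (t - b)))

Both branches sum to G at every t, so sit-to-stand and stand-to-sit are
exact time mirrors — the symmetry assumption under which a single fitted
``w`` serves both directions.  The sigmoid is smooth, so angular velocity
and acceleration come from its closed-form derivatives; both are zero in
the stationary states.

``w`` and ``b`` are in sample units: ``t`` is the sample index within the
transition window and ``b`` its midpoint, so ``w`` reads "per sample"
(0.135 per sample at 50 Hz is a typical adult transition).  Velocity and
acceleration are converted to per-second units through the sampling
period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .ekf import SegmentKinematics
from .errors import InvalidArgumentError, StructuralError
from .segmentation import Episode

DEFAULT_W = 0.135
"""Default transition-speed parameter, per sample at 50 Hz."""

GAIN = np.pi / 2
"""Default gain: thigh sweeps a quarter turn between sitting and standing."""


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic transition parameters: speed w in [0, 1] per time-unit,
    centre b (time-units), gain G (rad), direction x (0 = stand_to_sit,
    1 = sit_to_stand)."""

    w: float
    b: float
    G: float = GAIN
    x: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise InvalidArgumentError(f"w must be in [0, 1], got {self.w!r}")
        if not self.G > 0:
            raise InvalidArgumentError(f"G must be positive, got {self.G!r}")
        if self.x not in (0, 1):
            raise InvalidArgumentError(f"x must be 0 or 1, got {self.x!r}")


def sigmoid_angle(t: np.ndarray | float, p: SigmoidParams) -> np.ndarray | float:
    """Thigh angle at time(s) t: the rising logistic for x=0, its mirror
    1 - sigma for x=1, scaled by G."""
    s = expit(p.w * (np.asarray(t, dtype=float) - p.b))
    out = p.G * (1.0 - s) if p.x == 1 else p.G * s
    return float(out) if np.isscalar(t) else out


def sigmoid_velocity(t: np.ndarray | float, p: SigmoidParams) -> np.ndarray | float:
    """First derivative of :func:`sigmoid_angle` w.r.t. t (rad per
    time-unit): +/- G*w*s*(1-s), peaking at G*w/4 at the centre."""
    s = expit(p.w * (np.asarray(t, dtype=float) - p.b))
    sign = -1.0 if p.x == 1 else 1.0
    out = sign * p.G * p.w * s * (1.0 - s)
    return float(out) if np.isscalar(t) else out


def sigmoid_acceleration(t: np.ndarray | float, p: SigmoidParams) -> np.ndarray | float:
    """Second derivative of :func:`sigmoid_angle` w.r.t. t (rad per
    time-unit^2); zero at the centre (inflection)."""
    s = expit(p.w * (np.asarray(t, dtype=float) - p.b))
    sign = -1.0 if p.x == 1 else 1.0
    out = sign * p.G * p.w**2 * s * (1.0 - s) * (1.0 - 2.0 * s)
    return float(out) if np.isscalar(t) else out


def fit_transition_speed(
    segments: list[tuple[np.ndarray, np.ndarray, int]],
    G: float = GAIN,
) -> float:
    """Fit the shared transition speed w in [0, 1] to reference thigh angles.

    Each segment is (t, reference theta_T, direction x) with t in the same
    time-units as w (samples by default) and theta_T in radians; b is fixed
    at each segment's midpoint.  Minimizes the pooled RMSE over all
    segments by bounded scalar least squares.
    """
    if not segments:
        raise InvalidArgumentError("need at least one transition segment to fit w")
    prepared = []
    for t, ref, x in segments:
        t = np.asarray(t, dtype=float)
        ref = np.asarray(ref, dtype=float)
        if len(t) != len(ref) or len(t) == 0:
            raise InvalidArgumentError("segment times and angles must be equal-length, non-empty")
        prepared.append((t, ref, (t[0] + t[-1]) / 2.0, int(x)))

    def pooled_rmse(w: float) -> float:
        sq = 0.0
        n = 0
        for t, ref, b, x in prepared:
            pred = sigmoid_angle(t, SigmoidParams(w=w, b=b, G=G, x=x))
            sq += float(np.sum((pred - ref) ** 2))
            n += len(t)
        return np.sqrt(sq / n)

    res = minimize_scalar(pooled_rmse, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def reconstruct_thigh(
    episodes: list[Episode],
    n_samples: int,
    dt: float,
    w: float = DEFAULT_W,
    G: float = GAIN,
) -> SegmentKinematics:
    """Assemble the full thigh kinematic series from labeled episodes.

    Sitting: theta = G (90 deg), omega = alpha = 0.  Standing: all zero.
    Transitions: the sigmoid family with b at the episode's sample-span
    midpoint and the direction from the label; omega and alpha are the
    analytic derivatives converted to per-second units.
    """
    if not episodes or episodes[0].start != 0 or episodes[-1].end != n_samples or any(
        a.end != b.start for a, b in zip(episodes, episodes[1:])
    ):
        raise InvalidArgumentError("episodes must partition [0, n_samples)")
    theta = np.empty(n_samples)
    omega = np.zeros(n_samples)
    alpha = np.zeros(n_samples)
    for ep in episodes:
        sl = slice(ep.start, ep.end)
        if ep.label == "sit":
            theta[sl] = G
        elif ep.label == "stand":
            theta[sl] = 0.0
        elif ep.label in ("sit_to_stand", "stand_to_sit"):
            idx = np.arange(ep.start, ep.end, dtype=float)
            b = (ep.start + ep.end - 1) / 2.0
            p = SigmoidParams(w=w, b=b, G=G, x=1 if ep.label == "sit_to_stand" else 0)
            theta[sl] = sigmoid_angle(idx, p)
            # derivatives are per-sample; rescale to per-second
            omega[sl] = sigmoid_velocity(idx, p) / dt
            alpha[sl] = sigmoid_acceleration(idx, p) / dt**2
        else:
            raise StructuralError(f"unlabeled episode [{ep.start}, {ep.end}): {ep.label!r}")
    t = np.arange(n_samples) * dt
    return SegmentKinematics(segment="T", t=t, theta=theta, omega=omega, alpha=alpha)
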