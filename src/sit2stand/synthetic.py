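"""Synthetic sit-to-stand trials with known ground truth.

The generator emulates multi-cycle sit<->stand trials as recorded by two
body-worn inertial sensors: piecewise ground-truth kinematics for the
shank, thigh and back (stationary postures joined by smooth sigmoid-shaped
transitions), rendered into noisy accelerometer/gyroscope streams through
the planar forward model.  Because both the true kinematics and the true
state labels are known, every pipeline stage can be scored without any
recorded data.

Transitions use a *finite-support* logistic: the standard logistic
restricted to the transition window and affinely rescaled so the endpoints
meet the flanking postures exactly.  The shape parameter ``k`` sets how
bell-shaped the velocity profile is; at the default k=2.5 the segment is
already moving at roughly a third of peak velocity one sample into the
transition, matching the fairly abrupt initiation of real sit-to-stand
movements, while the interior remains smooth and sigmoid-like.

Stationary segments are never perfectly still: the truth carries a small
slow postural sway plus the ubiquitous 8-12 Hz physiological micro-tremor
(two incommensurate sinusoids per segment, independent phases), because
even healthy quiet stance and sitting show both.  Standing angles default
to a few hundredths of a radian rather than exactly zero — quiet stance
keeps the shank slightly inclined and a strapped sensor always carries a
small mounting tilt.  Cohort presets add the group phenomenology of older
and parkinsonian movers: longer and more variable transitions, a
mid-transition pause (velocity clamped to zero halfway), and a slower,
larger rest tremor on the stationary angular velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .ekf import InertialStream, SegmentKinematics
from .errors import InvalidArgumentError
from .forward_model import GRAVITY, SensorGeometry, predict_measurement_array
from .segmentation import Episode
from .thigh_reconstruction import (
    SigmoidParams,
    sigmoid_acceleration,
    sigmoid_angle,
    sigmoid_velocity,
)

Group = str  # "YH" | "OH" | "PwP"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated trial; defaults emulate a younger healthy
    adult performing unhurried cycles at 50 Hz."""

    seed: int = 0
    n_cycles: int = 3
    dt: float = 0.02
    sit_duration: float = 4.0          # s, mean stationary sit
    stand_duration: float = 4.0        # s, mean stationary stand
    sit_to_stand_duration: float = 1.44  # s, mean rise time
    stand_to_sit_duration: float = 1.55  # s, mean descent time
    duration_jitter_sd: float = 0.15   # s, per-episode SD around the means
    sitting_theta_S: float = 0.25      # rad, shank tucked back while seated
    sitting_theta_B: float = 0.18      # rad, back tilt seated
    sitting_theta_T: float = np.pi / 2  # rad, thigh horizontal seated
    standing_theta_S: float = 0.12     # rad, shank lean + mount tilt standing
    standing_theta_B: float = 0.08
    standing_theta_T: float = 0.0
    transition_shape_k: float = 1.0    # finite-support logistic steepness (shank/back)
    thigh_w: float = 0.135             # per-sample logistic speed of the thigh
    sway_amplitude: float = 0.002      # rad, slow postural sway angle amplitude
    sway_frequency: float = 0.3        # Hz, sway base frequency
    physio_tremor_amplitude: float = 0.006  # rad/s, 8-12 Hz physiological tremor
    physio_tremor_frequency: float = 9.5    # Hz
    pause_probability: float = 0.0     # chance of a mid-transition pause
    pause_duration: float = 0.15       # s, brief mid-transition pause length
    pause_velocity_fraction: float = 0.25  # residual speed during the pause
    tremor_amplitude: float = 0.0      # rad/s, pathological rest tremor on omega
    tremor_frequency: float = 5.0      # Hz
    accel_noise_sd: float = 0.05       # m/s^2 per accelerometer channel
    gyro_noise_sd: float = 0.005       # rad/s per gyroscope channel
    L_S: float = 0.25                  # m, shank sensor above the ankle
    L_B: float = 0.18                  # m, back sensor above the hip
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        for name in (
            "dt", "sit_duration", "stand_duration", "sit_to_stand_duration",
            "stand_to_sit_duration", "pause_duration", "L_S", "L_B", "gravity",
            "transition_shape_k",
        ):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"SimulationConfig.{name} must be positive")
        for name in ("pause_probability", "pause_velocity_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidArgumentError(f"SimulationConfig.{name} must be in [0, 1]")
        for name in ("duration_jitter_sd", "sway_amplitude", "tremor_amplitude",
                     "physio_tremor_amplitude", "accel_noise_sd", "gyro_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"SimulationConfig.{name} must be non-negative")
        if self.n_cycles < 1:
            raise InvalidArgumentError("SimulationConfig.n_cycles must be >= 1")


@dataclass
class SimulatedTrial:
    """Ground truth plus rendered sensor streams for one trial."""

    truth: dict[str, SegmentKinematics]          # keys "S", "T", "B"
    labels: np.ndarray                           # per-sample four-state labels
    episodes: list[Episode]                      # true labeled episodes
    streams: dict[str, InertialStream]           # keys "shank", "back"
    config: SimulationConfig


_POSTURES = {  # (sit value, stand value) per segment attribute
    "S": ("sitting_theta_S", "standing_theta_S"),
    "T": ("sitting_theta_T", "standing_theta_T"),
    "B": ("sitting_theta_B", "standing_theta_B"),
}


_EASE_SAMPLES = 3  # ~60 ms at 50 Hz: velocity ramps on/off over this many samples


def _band_noise(
    rng: np.random.Generator, n: int, dt: float, band: tuple[float, float],
    rms: float, rms_of: str = "omega",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band-limited Gaussian wobble as consistent (theta, omega, alpha).

    White noise is masked to ``band`` (Hz) in the frequency domain to give
    the angular-velocity process; angle and angular acceleration follow by
    spectral integration/differentiation, so the triplet is exactly
    consistent.  ``rms`` fixes the RMS of ``omega`` (rad/s) or of ``theta``
    (rad) per ``rms_of``.
    """
    freqs = np.fft.rfftfreq(n, dt)
    spec = np.fft.rfft(rng.standard_normal(n))
    mask = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    spec = np.where(mask, spec, 0.0)
    omega = np.fft.irfft(spec, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.fft.irfft(np.where(mask, spec / (2j * np.pi * freqs), 0.0), n)
    alpha = np.fft.irfft(spec * (2j * np.pi * freqs), n)
    ref = omega if rms_of == "omega" else theta
    denom = float(np.std(ref))
    scale = rms / denom if denom > 0 else 0.0
    return theta * scale, omega * scale, alpha * scale


def _shape(tau: np.ndarray, k: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transition shape f: [0,1] -> [0,1] with f(0)=0, f(1)=1.

    A finite-support logistic (steepness k) whose velocity profile is
    eased on with a short raised-cosine ramp — a limb cannot jump to speed
    instantaneously — while the terminus stays sharp, as both transitions
    end abruptly (knee lock standing up, chair contact sitting down).
    Returns (f, df/dtau, d2f/dtau2); the eased profile is integrated
    numerically on the tau grid.
    """
    u = 2.0 * k * (tau - 0.5)
    lo, hi = expit(-k), expit(k)
    s = expit(u)
    df = 2.0 * k * s * (1.0 - s) / (hi - lo)
    n = len(tau)
    r = min(_EASE_SAMPLES, max(0, (n - 1) // 2))
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(1, r + 1)) / (r + 1)))
        df[:r] *= ramp
    # integrate back to f, renormalizing so the endpoints meet exactly
    f = np.concatenate([[0.0], np.cumsum((df[1:] + df[:-1]) / 2.0 * np.diff(tau))])
    f /= f[-1]
    df /= np.trapezoid(df, tau)
    d2f = np.gradient(df, tau)
    return f, df, d2f


def _episode_plan(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Sequence of (label, n_samples, n_pause_samples) for the whole trial:
    sit, SiSt, stand, StSi per cycle, closing with a final sit."""
    def n_of(mean: float) -> int:
        d = max(0.5, rng.normal(mean, cfg.duration_jitter_sd))
        return max(10, int(round(d / cfg.dt)))

    plan: list[tuple[str, int, int]] = []
    for _ in range(cfg.n_cycles):
        plan.append(("sit", n_of(cfg.sit_duration), 0))
        pause = n_of(cfg.pause_duration) if rng.random() < cfg.pause_probability else 0
        plan.append(("sit_to_stand", n_of(cfg.sit_to_stand_duration), pause))
        plan.append(("stand", n_of(cfg.stand_duration), 0))
        pause = n_of(cfg.pause_duration) if rng.random() < cfg.pause_probability else 0
        plan.append(("stand_to_sit", n_of(cfg.stand_to_sit_duration), pause))
    plan.append(("sit", n_of(cfg.sit_duration), 0))
    return plan


def simulate_truth(
    cfg: SimulationConfig,
) -> tuple[dict[str, SegmentKinematics], np.ndarray, list[Episode]]:
    """Generate ground-truth kinematics, per-sample labels and episodes.

    Deterministic in ``cfg.seed``.  The thigh is exactly at its posture
    angles in stationary states (horizontal seated, vertical standing);
    shank and back additionally carry the configured postural sway, and the
    cohort presets may add stationary tremor.
    """
    rng = np.random.default_rng(cfg.seed)
    plan = _episode_plan(cfg, rng)
    n_total = sum(n + n_pause for _, n, n_pause in plan)

    segs = {s: {"theta": [], "omega": [], "alpha": []} for s in ("S", "T", "B")}
    labels: list[str] = []
    episodes: list[Episode] = []
    cursor = 0
    # Involuntary wobble per segment over the whole trial, as consistent
    # (theta, omega, alpha) band-noise processes: slow postural sway, the
    # ubiquitous 8-12 Hz physiological tremor, and (when configured) a
    # slower pathological rest tremor.
    wobble: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for s in ("S", "B"):
        th = np.zeros(n_total)
        om = np.zeros(n_total)
        al = np.zeros(n_total)
        for band, rms, rms_of in (
            ((0.3 * cfg.sway_frequency, 1.7 * cfg.sway_frequency),
             cfg.sway_amplitude, "theta"),
            ((0.75 * cfg.physio_tremor_frequency, 1.35 * cfg.physio_tremor_frequency),
             cfg.physio_tremor_amplitude, "omega"),
            ((0.8 * cfg.tremor_frequency, 1.2 * cfg.tremor_frequency),
             cfg.tremor_amplitude, "omega"),
        ):
            if rms > 0:
                t_, o_, a_ = _band_noise(rng, n_total, cfg.dt, band, rms, rms_of)
                th += t_
                om += o_
                al += a_
        wobble[s] = (th, om, al)

    for label, n, n_pause in plan:
        stationary = label in ("sit", "stand")
        if stationary:
            sl = slice(cursor, cursor + n)
            for s in ("S", "T", "B"):
                sit_v = getattr(cfg, _POSTURES[s][0])
                stand_v = getattr(cfg, _POSTURES[s][1])
                base = sit_v if label == "sit" else stand_v
                theta = np.full(n, base)
                omega = np.zeros(n)
                alpha = np.zeros(n)
                if s in ("S", "B"):
                    wt, wo, wa = wobble[s]
                    theta = theta + wt[sl]
                    omega = omega + wo[sl]
                    alpha = alpha + wa[sl]
                segs[s]["theta"].append(theta)
                segs[s]["omega"].append(omega)
                segs[s]["alpha"].append(alpha)
            total = n
        else:
            total = n + n_pause
            tau = np.linspace(0.0, 1.0, total)
            f, df, d2f = _shape(tau, cfg.transition_shape_k)
            if n_pause > 0:
                # A pause is a deep velocity notch at the transition
                # midpoint: the mover slows to a small fraction of local
                # speed rather than freezing outright (residual motion never
                # quite vanishes), then completes the movement.
                center = (total - 1) / 2.0
                sigma = max(n_pause / 2.0, 1.0)
                notch = 1.0 - (1.0 - cfg.pause_velocity_fraction) * np.exp(
                    -0.5 * ((np.arange(total) - center) / sigma) ** 2
                )
                df = df * notch
                f = np.concatenate(
                    [[0.0], np.cumsum((df[1:] + df[:-1]) / 2.0 * np.diff(tau))]
                )
                df = df / f[-1]
                f = f / f[-1]
                d2f = np.gradient(df, tau)
            span = (total - 1) * cfg.dt
            # Shank and back move monotonically between their postures along
            # the eased finite-support logistic (see the methods note for why
            # the trunk's real flexion excursion is not modelled).  The thigh
            # follows the plain logistic family in sample units — its motion
            # is temporally concentrated between seat-off and full extension,
            # and this is the trajectory family the reconstruction stage
            # assumes.
            idx = np.arange(total, dtype=float)
            thigh_p = SigmoidParams(
                w=cfg.thigh_w, b=(total - 1) / 2.0, G=cfg.sitting_theta_T,
                x=1 if label == "sit_to_stand" else 0,
            )
            for s in ("S", "T", "B"):
                sit_v = getattr(cfg, _POSTURES[s][0])
                stand_v = getattr(cfg, _POSTURES[s][1])
                a, b = (sit_v, stand_v) if label == "sit_to_stand" else (stand_v, sit_v)
                if s == "T":
                    theta = np.asarray(sigmoid_angle(idx, thigh_p))
                    omega = np.asarray(sigmoid_velocity(idx, thigh_p)) / cfg.dt
                    alpha = np.asarray(sigmoid_acceleration(idx, thigh_p)) / cfg.dt**2
                else:
                    theta = a + (b - a) * f
                    omega = (b - a) * df / span
                    alpha = (b - a) * d2f / span**2
                segs[s]["theta"].append(theta)
                segs[s]["omega"].append(omega)
                segs[s]["alpha"].append(alpha)
        labels.extend([label] * total)
        episodes.append(Episode(cursor, cursor + total, label))
        cursor += total

    n_total = cursor
    t = np.arange(n_total) * cfg.dt
    truth = {
        s: SegmentKinematics(
            segment=s,  # type: ignore[arg-type]
            t=t,
            theta=np.concatenate(segs[s]["theta"]),
            omega=np.concatenate(segs[s]["omega"]),
            alpha=np.concatenate(segs[s]["alpha"]),
        )
        for s in ("S", "T", "B")
    }
    return truth, np.array(labels, dtype=str), episodes


def truth_to_streams(
    truth: dict[str, SegmentKinematics], cfg: SimulationConfig
) -> dict[str, InertialStream]:
    """Render ground truth into the two sensor streams via the forward
    model, adding independent Gaussian noise per channel.

    Noise draws come from a dedicated substream of ``cfg.seed`` so the
    truth and its noisy rendering stay individually reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    out: dict[str, InertialStream] = {}
    for placement, seg, L in (("shank", "S", cfg.L_S), ("back", "B", cfg.L_B)):
        kin = truth[seg]
        geom = SensorGeometry(L=L, gravity=cfg.gravity)
        ax, ay, gz = predict_measurement_array(kin.theta, kin.omega, kin.alpha, geom)
        n = len(kin)
        a_sd, g_sd = cfg.accel_noise_sd, cfg.gyro_noise_sd
        out[placement] = InertialStream(
            t=kin.t.copy(),
            ax=ax + rng.normal(0, a_sd, n) if a_sd > 0 else ax,
            ay=ay + rng.normal(0, a_sd, n) if a_sd > 0 else ay,
            az=rng.normal(0, a_sd, n) if a_sd > 0 else np.zeros(n),
            gx=rng.normal(0, g_sd, n) if g_sd > 0 else np.zeros(n),
            gy=rng.normal(0, g_sd, n) if g_sd > 0 else np.zeros(n),
            gz=gz + rng.normal(0, g_sd, n) if g_sd > 0 else gz,
            placement=placement,  # type: ignore[arg-type]
            geometry=geom,
        )
    return out


def simulate_trial(cfg: SimulationConfig) -> SimulatedTrial:
    """One full trial: truth, labels and rendered streams."""
    truth, labels, episodes = simulate_truth(cfg)
    streams = truth_to_streams(truth, cfg)
    return SimulatedTrial(truth=truth, labels=labels, episodes=episodes,
                          streams=streams, config=cfg)


# Cohort presets: (SiSt mean, StSi mean, between-participant SD,
# within-trial SD, pause probability, tremor amplitude rad/s)
_GROUP_PRESETS: dict[str, dict] = {
    "YH": dict(sist=1.44, stsi=1.55, between_sd=0.25, within_sd=0.15,
               pause_probability=0.0, tremor_amplitude=0.0),
    "OH": dict(sist=1.80, stsi=1.77, between_sd=0.40, within_sd=0.25,
               pause_probability=0.5, tremor_amplitude=0.0),
    "PwP": dict(sist=2.29, stsi=2.18, between_sd=0.90, within_sd=0.35,
                pause_probability=0.7, tremor_amplitude=0.02),
}


def group_config(
    group: Group, participant_seed: int, rng: np.random.Generator,
    base: SimulationConfig | None = None,
) -> SimulationConfig:
    """Draw one participant's trial configuration around the group preset."""
    if group not in _GROUP_PRESETS:
        raise InvalidArgumentError(f"unknown group {group!r}; expected YH, OH or PwP")
    p = _GROUP_PRESETS[group]
    base = base if base is not None else SimulationConfig()
    sist = float(np.clip(rng.normal(p["sist"], p["between_sd"]), 0.7, 6.0))
    stsi = float(np.clip(rng.normal(p["stsi"], p["between_sd"]), 0.7, 6.0))
    return replace(
        base,
        seed=participant_seed,
        sit_to_stand_duration=sist,
        stand_to_sit_duration=stsi,
        duration_jitter_sd=p["within_sd"],
        pause_probability=p["pause_probability"],
        tremor_amplitude=p["tremor_amplitude"],
        # Individual posture habits.  The seated-vs-standing angle difference
        # is drawn with a physical floor: bent knees force the shank back by
        # several degrees when seated, and sitters slouch or recline relative
        # to their stance, which the back-mounted sensor reads as extra tilt.
        **_posture_draw(base, rng),
    )


def _posture_draw(base: SimulationConfig, rng: np.random.Generator) -> dict[str, float]:
    standing_S = float(np.clip(rng.normal(base.standing_theta_S, 0.015), 0.03, 0.25))
    standing_B = float(np.clip(rng.normal(base.standing_theta_B, 0.015), 0.02, 0.2))
    delta_S = max(0.10, rng.normal(base.sitting_theta_S - base.standing_theta_S, 0.03))
    delta_B = max(0.06, rng.normal(base.sitting_theta_B - base.standing_theta_B, 0.03))
    return {
        "standing_theta_S": standing_S,
        "standing_theta_B": standing_B,
        "sitting_theta_S": standing_S + delta_S,
        "sitting_theta_B": standing_B + delta_B,
    }


def simulate_cohort(
    group: Group,
    n_participants: int,
    seed: int = 0,
    base: SimulationConfig | None = None,
) -> list[SimulatedTrial]:
    """Simulate one trial per participant for a YH/OH/PwP-like cohort.

    Per-participant randomness derives from (seed, participant index), so
    cohorts are reproducible and order-independent.
    """
    if n_participants < 1:
        raise InvalidArgumentError("n_participants must be >= 1")
    trials = []
    for i in range(n_participants):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        participant_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        cfg = group_config(group, participant_seed, rng, base=base)
        trials.append(simulate_trial(cfg))
    return trials
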