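"""Evaluation battery: agreement with reference kinematics and group
statistics.

Agreement between estimated and reference kinematics is quantified two
ways: the normalised root-mean-squared error (RMSE divided by the
reference range, so a unitless fraction comparable across angle, velocity
and acceleration), and Bland–Altman analysis (mean difference, SD of the
differences, and the share of points within the mean +/- 2 SD limits).
Group-level comparisons of transition durations and postures use the
two-sided Mann–Whitney U test with Bonferroni correction over the three
pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np
from scipy.stats import mannwhitneyu

from .ekf import SegmentKinematics
from .errors import DegenerateDataError, InsufficientDataError, InvalidArgumentError
from .segmentation import Episode

NormMode = Literal["range", "mean", "sd"]


@dataclass(frozen=True)
class AgreementReport:
    """NRMSE per kinematic channel plus Bland–Altman statistics for the
    angle channel of one segment."""

    nrmse_theta: float
    nrmse_omega: float
    nrmse_alpha: float
    ba_mean_diff: float
    ba_sd: float
    ba_pct_within: float


@dataclass
class TimingSummary:
    """Transition durations (s) grouped by transition class."""

    durations: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, label: str) -> float:
        return float(np.mean(self.durations[label]))

    def sd(self, label: str) -> float:
        return float(np.std(self.durations[label], ddof=1))


def nrmse(estimated: np.ndarray, reference: np.ndarray, mode: NormMode = "range") -> float:
    """RMSE between the series, normalised by the reference range (default),
    mean magnitude, or SD."""
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise InvalidArgumentError(f"length mismatch: {est.shape} vs {ref.shape}")
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    if mode == "range":
        denom = float(np.max(ref) - np.min(ref))
    elif mode == "mean":
        denom = float(np.abs(np.mean(ref)))
    elif mode == "sd":
        denom = float(np.std(ref, ddof=1))
    else:
        raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
    if denom == 0.0:
        raise DegenerateDataError("reference series is constant; NRMSE undefined")
    return rmse / denom


def bland_altman(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Bland–Altman agreement of two paired series.

    Returns (mean difference, sample SD of differences, percentage of
    points with |d - mean| <= 2 SD; boundary counts as within).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise InvalidArgumentError(f"need >= 2 paired samples, got {len(a)}")
    d = a - b
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    within = np.abs(d - mean_diff) <= 2.0 * sd
    return mean_diff, sd, 100.0 * float(np.mean(within))


def agreement_report(est: SegmentKinematics, ref: SegmentKinematics,
                     mode: NormMode = "range") -> AgreementReport:
    """Full agreement report for one segment: channel-wise NRMSE and
    Bland–Altman on the angle."""
    md, sd, pct = bland_altman(est.theta, ref.theta)
    return AgreementReport(
        nrmse_theta=nrmse(est.theta, ref.theta, mode),
        nrmse_omega=nrmse(est.omega, ref.omega, mode),
        nrmse_alpha=nrmse(est.alpha, ref.alpha, mode),
        ba_mean_diff=md,
        ba_sd=sd,
        ba_pct_within=pct,
    )


def transition_timings(episodes: list[Episode], dt: float) -> TimingSummary:
    """Durations of the transition episodes, in seconds, keyed by class.
    A trial with no transitions yields an empty summary."""
    summary = TimingSummary()
    for ep in episodes:
        if ep.label in ("sit_to_stand", "stand_to_sit", "transition"):
            summary.durations.setdefault(ep.label, []).append(ep.n_samples * dt)
    return summary


def group_compare(
    samples_by_group: dict[str, list[float]], n_comparisons: int = 3
) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Mann–Whitney U tests with Bonferroni correction.

    The exact null distribution is used when both groups have <= 20
    observations, the tie-corrected normal approximation otherwise.
    Corrected p-values are clamped at 1.
    """
    for name, vals in samples_by_group.items():
        if len(vals) < 2:
            raise InsufficientDataError(f"group {name!r} has < 2 samples")
    out: dict[tuple[str, str], float] = {}
    for g1, g2 in combinations(samples_by_group, 2):
        a, b = samples_by_group[g1], samples_by_group[g2]
        method = "exact" if (len(a) <= 20 and len(b) <= 20) else "asymptotic"
        try:
            res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:
            # exact method refuses ties; fall back to the tie-corrected normal
            res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        out[(g1, g2)] = min(1.0, float(res.pvalue) * n_comparisons)
    return out


def posture_summary(
    episodes: list[Episode], shank: SegmentKinematics, back: SegmentKinematics
) -> dict[str, dict[str, float]]:
    """Mean shank and back angles (rad) over all samples of each stationary
    class present in the trial; absent classes are simply omitted."""
    out: dict[str, dict[str, float]] = {}
    for state in ("sit", "stand"):
        idx = np.concatenate(
            [np.arange(ep.start, ep.end) for ep in episodes if ep.label == state]
        ) if any(ep.label == state for ep in episodes) else None
        if idx is not None and len(idx):
            out[state] = {
                "theta_S": float(np.mean(shank.theta[idx])),
                "theta_B": float(np.mean(back.theta[idx])),
            }
    return out


def resample_normalized(y: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Linearly resample a series onto n_points over normalized time [0, 1]."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise InvalidArgumentError("need >= 2 samples to resample")
    x = np.linspace(0.0, 1.0, len(y))
    return np.interp(np.linspace(0.0, 1.0, n_points), x, y)


def grand_average_profiles(
    episodes_by_trial: list[tuple[list[Episode], SegmentKinematics]],
    label: str,
    channel: str = "omega",
    n_points: int = 101,
) -> np.ndarray:
    """Pointwise mean curve of one kinematic channel over all episodes with
    the given label, each time-normalized to [0, 1] by linear interpolation.

    ``episodes_by_trial`` pairs each trial's labeled episodes with the
    kinematics of the segment of interest.
    """
    curves = []
    for episodes, kin in episodes_by_trial:
        series = getattr(kin, channel)
        for ep in episodes:
            if ep.label == label and ep.n_samples >= 2:
                curves.append(resample_normalized(series[ep.start : ep.end], n_points))
    if not curves:
        raise DegenerateDataError(f"no {label!r} episodes to average")
    return np.mean(curves, axis=0)
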