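"""Tier-1 classifier: split a trial into stationary and transition episodes.

A one-dimensional feature is built from the estimated shank and back
kinematics: the product theta_S * omega_S * theta_B * omega_B, rectified
and smoothed with a 5-sample forward moving average.  Because omega is
zero at rest and theta_S is near zero while standing, the product is close
to zero in the stationary states and large during transitions, so a simple
threshold separates the two.  The threshold itself is data-driven: the
right edge of the first histogram bin of the feature's peak values, with
the bin width set by Scott's rule, so stationary-noise peaks land in the
first bin and transition peaks beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ekf import SegmentKinematics
from .errors import DegenerateDataError, InvalidArgumentError

EpisodeLabel = Literal["sit", "stand", "sit_to_stand", "stand_to_sit", "stationary", "transition"]


@dataclass(frozen=True)
class FeatureSeries:
    """Non-negative scalar feature per sample, same length as the input."""

    t: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.value):
            raise InvalidArgumentError("t and value must have equal length")
        if np.any(self.value < 0):
            raise InvalidArgumentError("feature values must be non-negative")

    def __len__(self) -> int:
        return len(self.value)


@dataclass
class Episode:
    """Half-open sample interval [start, end) with a state label."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InvalidArgumentError(f"episode must be non-empty: [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def to_dict(self, dt: float | None = None) -> dict:
        d = {"start": self.start, "end": self.end, "label": self.label}
        if dt is not None:
            d["start_s"] = self.start * dt
            d["end_s"] = self.end * dt
        return d


def moving_average_forward(x: np.ndarray, window: int) -> np.ndarray:
    """Forward moving average y_t = mean(x[t : t+window]), truncated at the
    tail so the last windows average over fewer samples."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < window:
        raise InvalidArgumentError(f"series of length {n} shorter than window {window}")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    ends = np.minimum(np.arange(n) + window, n)
    starts = np.arange(n)
    return (csum[ends] - csum[starts]) / (ends - starts)


def build_feature(
    shank: SegmentKinematics,
    back: SegmentKinematics,
    window: int = 5,
    composition: Literal["product", "sum_of_products"] = "product",
) -> FeatureSeries:
    """Build the smoothed stationary-vs-transition feature.

    ``product`` (default): MA(|theta_S*omega_S*theta_B*omega_B|).
    ``sum_of_products``:   MA(|theta_S*omega_S| + |theta_B*omega_B|),
    kept as an alternative reading of the feature construction.
    """
    if len(shank) != len(back):
        raise InvalidArgumentError("shank and back kinematics must have equal length")
    if composition == "product":
        raw = np.abs(shank.theta * shank.omega * back.theta * back.omega)
    elif composition == "sum_of_products":
        raw = np.abs(shank.theta * shank.omega) + np.abs(back.theta * back.omega)
    else:
        raise InvalidArgumentError(f"unknown composition {composition!r}")
    return FeatureSeries(t=shank.t.copy(), value=moving_average_forward(raw, window))


def find_peaks(feature: FeatureSeries | np.ndarray) -> list[float]:
    """Values at strict interior local maxima; a flat plateau flanked by
    lower values contributes one peak at its start.  Endpoints excluded."""
    v = feature.value if isinstance(feature, FeatureSeries) else np.asarray(feature, dtype=float)
    if len(v) == 0:
        raise InvalidArgumentError("empty feature series")
    peaks: list[float] = []
    i = 1
    n = len(v)
    while i < n - 1:
        if v[i] > v[i - 1]:
            # scan a potential plateau starting at i
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                peaks.append(float(v[i]))
            i = j + 1
        else:
            i += 1
    return peaks


def scott_threshold(peaks: list[float]) -> float:
    """Classification threshold = right edge of the first histogram bin of
    the peak values, with Scott's-rule bin width h = 3.49*sd*m^(-1/3) and
    bins anchored at zero (the feature is non-negative).

    The first bin collects the near-zero stationary peaks, so its right
    edge — simply h with zero anchoring — separates them from transition
    peaks.
    """
    p = np.asarray(peaks, dtype=float)
    if len(p) < 2:
        raise DegenerateDataError(
            f"need >= 2 peaks to set a threshold, got {len(p)}: no transitions detected"
        )
    sd = float(np.std(p, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("peak values have zero spread: no transitions detected")
    return 3.49 * sd * len(p) ** (-1.0 / 3.0)


def classify_stationary_transition(feature: FeatureSeries, threshold: float) -> np.ndarray:
    """Per-sample binary labels: True = transition (value strictly above the
    threshold), False = stationary."""
    if not threshold > 0:
        raise InvalidArgumentError(f"threshold must be positive, got {threshold!r}")
    return feature.value > threshold


def correct_spurious(labels: np.ndarray) -> np.ndarray:
    """Flip isolated misclassifications: any maximal run of one or two
    samples whose neighbours on both sides carry the opposite class takes
    that class.  Applied repeatedly until no such run remains."""
    out = np.asarray(labels, dtype=bool).copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(out)
        for k, (s, e) in enumerate(runs):
            if e - s <= 2 and 0 < k < len(runs) - 1:
                out[s:e] = ~out[s]
                changed = True
                break  # run boundaries shifted; recompute
    return out


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal constant runs as half-open (start, end) pairs."""
    n = len(labels)
    if n == 0:
        return []
    boundaries = np.flatnonzero(np.diff(labels.astype(np.int8))) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    return list(zip(starts.tolist(), ends.tolist()))


def segment_episodes(labels: np.ndarray) -> list[Episode]:
    """Turn per-sample binary labels into a partition of [0, N) into
    alternating stationary/transition episodes."""
    labels = np.asarray(labels, dtype=bool)
    if len(labels) == 0:
        raise InvalidArgumentError("empty label vector")
    return [
        Episode(s, e, "transition" if labels[s] else "stationary") for s, e in _runs(labels)
    ]


def segment_trial(
    shank: SegmentKinematics,
    back: SegmentKinematics,
    window: int = 5,
    composition: Literal["product", "sum_of_products"] = "product",
) -> tuple[list[Episode], float]:
    """Full tier-1 pass: feature, threshold, classification, spurious
    correction, episode extraction.  Returns (episodes, threshold).

    Raises :class:`DegenerateDataError` when the trial contains no
    detectable transitions.
    """
    feature = build_feature(shank, back, window=window, composition=composition)
    peaks = find_peaks(feature)
    threshold = scott_threshold(peaks)
    labels = correct_spurious(classify_stationary_transition(feature, threshold))
    return segment_episodes(labels), threshold
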