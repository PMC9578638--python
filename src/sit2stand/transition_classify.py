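"""Tier-2 classifier: name the transitions, then the stationary states.

Each transition episode is summarized by four features — the least-squares
slopes of omega_S and omega_B over the episode, and the net change of
theta_S and theta_B across it.  Sit-to-stand and stand-to-sit produce
mirrored feature vectors (the shank swings one way standing up and back
the other sitting down), so k-means with k=2 on the standardized features
separates them without any training data; as few as two transitions in a
trial suffice.  Cluster identities are assigned post hoc: standing pins
the shank near vertical, so the cluster whose mean net shank-angle change
is lower is sit-to-stand.  Stationary episodes then inherit their label
from the preceding transition (after sit-to-stand one is standing; after
stand-to-sit, sitting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .ekf import SegmentKinematics
from .errors import InsufficientDataError, InvalidArgumentError, StructuralError
from .segmentation import Episode

# Reference-label thresholds on the thigh angle (degrees): above the first
# -> sitting, below the second -> standing, otherwise in transition.
SIT_THIGH_DEG = 70.0
STAND_THIGH_DEG = 20.0


@dataclass(frozen=True)
class TransitionFeatures:
    """4-D descriptor of one transition episode."""

    slope_omega_S: float  # rad/s per second
    slope_omega_B: float
    dtheta_S: float  # rad, end minus start
    dtheta_B: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.slope_omega_S, self.slope_omega_B, self.dtheta_S, self.dtheta_B], dtype=float
        )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def transition_features(
    ep: Episode, shank: SegmentKinematics, back: SegmentKinematics
) -> TransitionFeatures:
    """Compute the 4-D feature vector for one transition episode."""
    if ep.n_samples < 3:
        raise InvalidArgumentError(
            f"transition episode too short ({ep.n_samples} samples; need >= 3)"
        )
    sl = slice(ep.start, ep.end)
    t = shank.t[sl]
    return TransitionFeatures(
        slope_omega_S=_ols_slope(t, shank.omega[sl]),
        slope_omega_B=_ols_slope(t, back.omega[sl]),
        dtheta_S=float(shank.theta[ep.end - 1] - shank.theta[ep.start]),
        dtheta_B=float(back.theta[ep.end - 1] - back.theta[ep.start]),
    )


def cluster_transitions(feats: list[TransitionFeatures], seed: int = 0) -> list[str]:
    """Label each transition episode sit_to_stand / stand_to_sit.

    k-means (k=2, 10 restarts, fixed seed) on z-scored features; the
    cluster with the lower mean net shank-angle change is sit_to_stand.
    With exactly two episodes each forms its own cluster.
    """
    if len(feats) < 2:
        raise InsufficientDataError(
            f"need >= 2 transition episodes to cluster, got {len(feats)}"
        )
    X = np.array([f.as_vector() for f in feats])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if len(feats) == 2:
        assign = np.array([0, 1])
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed, tol=1e-6)
        assign = km.fit_predict(Z)
        if len(np.unique(assign)) < 2:  # pathological: all points identical
            raise InsufficientDataError("k-means collapsed to a single cluster")
    mean_dtheta_S = [X[assign == c, 2].mean() for c in (0, 1)]
    sist_cluster = int(np.argmin(mean_dtheta_S))
    return ["sit_to_stand" if a == sist_cluster else "stand_to_sit" for a in assign]


_AFTER = {"sit_to_stand": "stand", "stand_to_sit": "sit"}
_BEFORE = {"sit_to_stand": "sit", "stand_to_sit": "stand"}


def label_stationary(episodes: list[Episode]) -> list[Episode]:
    """Resolve stationary episodes to sit/stand from the flanking
    transitions.

    A stationary episode takes the end state of the previous transition;
    the leading episode (no predecessor) takes the origin state of the
    transition that follows it.  A trial with no transitions at all cannot
    be resolved and raises :class:`StructuralError`.
    """
    labels = [ep.label for ep in episodes]
    for a, b in zip(labels, labels[1:]):
        a_trans = a in _AFTER or a == "transition"
        b_trans = b in _AFTER or b == "transition"
        if a_trans and b_trans:
            raise StructuralError("two adjacent transition episodes: alternation violated")
    if not any(lab in _AFTER for lab in labels):
        raise StructuralError(
            "no labeled transitions: stationary states cannot be resolved"
        )
    out: list[Episode] = []
    prev_transition: str | None = None
    for i, ep in enumerate(episodes):
        if ep.label in _AFTER:
            prev_transition = ep.label
            out.append(Episode(ep.start, ep.end, ep.label))
        elif ep.label in ("stationary", "sit", "stand"):
            if prev_transition is not None:
                out.append(Episode(ep.start, ep.end, _AFTER[prev_transition]))
            else:
                nxt = next((e.label for e in episodes[i + 1 :] if e.label in _BEFORE), None)
                assert nxt is not None  # guaranteed by the any() check above
                out.append(Episode(ep.start, ep.end, _BEFORE[nxt]))
        else:
            raise StructuralError(f"unlabeled transition episode at [{ep.start}, {ep.end})")
    return out


def classify_episodes(
    episodes: list[Episode],
    shank: SegmentKinematics,
    back: SegmentKinematics,
    seed: int = 0,
) -> list[Episode]:
    """Full tier-2 pass over tier-1 episodes: feature extraction, k-means
    labeling of transitions, then stationary resolution."""
    trans_idx = [i for i, ep in enumerate(episodes) if ep.label == "transition"]
    feats = [transition_features(episodes[i], shank, back) for i in trans_idx]
    names = cluster_transitions(feats, seed=seed)
    labeled = [Episode(ep.start, ep.end, ep.label) for ep in episodes]
    for i, name in zip(trans_idx, names):
        labeled[i] = Episode(labeled[i].start, labeled[i].end, name)
    return label_stationary(labeled)


def episodes_to_sample_labels(episodes: list[Episode], n_samples: int) -> np.ndarray:
    """Expand labeled episodes into a per-sample label array of length
    ``n_samples``."""
    out = np.empty(n_samples, dtype=object)
    for ep in episodes:
        out[ep.start : ep.end] = ep.label
    if (out == None).any():  # noqa: E711 — object-array sentinel check
        raise InvalidArgumentError("episodes do not cover [0, n_samples)")
    return out.astype(str)


def classification_accuracy(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Percentage of samples whose four-state label matches the reference."""
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.shape != reference.shape:
        raise InvalidArgumentError(
            f"label vectors differ in length: {predicted.shape} vs {reference.shape}"
        )
    return 100.0 * float(np.mean(predicted == reference))


def derive_reference_labels(
    ref_thigh: SegmentKinematics,
    sit_deg: float = SIT_THIGH_DEG,
    stand_deg: float = STAND_THIGH_DEG,
) -> np.ndarray:
    """Four-state labels from a reference thigh-angle series.

    The thigh is horizontal (~90 deg) seated and vertical (~0 deg) standing,
    so thresholds on theta_T mark the states; samples between the
    thresholds are transitions, with the direction taken from the local
    trend of theta_T (falling -> sit_to_stand).
    """
    theta_deg = np.degrees(ref_thigh.theta)
    n = len(theta_deg)
    labels = np.empty(n, dtype=object)
    labels[theta_deg > sit_deg] = "sit"
    labels[theta_deg < stand_deg] = "stand"
    in_transition = (theta_deg >= stand_deg) & (theta_deg <= sit_deg)
    # direction per maximal transition run: falling thigh angle = standing up
    i = 0
    while i < n:
        if in_transition[i]:
            j = i
            while j + 1 < n and in_transition[j + 1]:
                j += 1
            before = theta_deg[i - 1] if i > 0 else theta_deg[i]
            after = theta_deg[j + 1] if j + 1 < n else theta_deg[j]
            labels[i : j + 1] = "sit_to_stand" if after < before else "stand_to_sit"
            i = j + 1
        else:
            i += 1
    return labels.astype(str)
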