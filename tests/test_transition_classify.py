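"""Tier-2 classification: episode features, k-means vs exhaustive oracle,
stationary-state resolution, accuracy scoring."""

from itertools import combinations

import numpy as np
import pytest

from sit2stand import (
    Episode,
    InsufficientDataError,
    InvalidArgumentError,
    SegmentKinematics,
    StructuralError,
    TransitionFeatures,
    classification_accuracy,
    classify_episodes,
    cluster_transitions,
    derive_reference_labels,
    label_stationary,
    simulate_trial,
    transition_features,
)
from sit2stand import SimulationConfig
from sit2stand.ekf import estimate_segment_kinematics
from sit2stand.transition_classify import episodes_to_sample_labels


def _kin(theta, omega, seg="S"):
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    return SegmentKinematics(segment=seg, t=np.arange(n) * 0.02, theta=theta,
                             omega=np.asarray(omega, dtype=float), alpha=np.zeros(n))


class TestTransitionFeatures:
    def test_ols_slope_closed_form(self):
        # omega = [0, 0.1, 0.2, 0.3] at dt = 0.02 s -> slope 5.0 rad/s^2,
        # cross-checked against the normal-equations solution
        om = np.array([0.0, 0.1, 0.2, 0.3])
        shank = _kin(np.zeros(4), om)
        back = _kin(np.zeros(4), np.zeros(4), "B")
        f = transition_features(Episode(0, 4, "transition"), shank, back)
        assert f.slope_omega_S == pytest.approx(5.0)
        t = np.arange(4) * 0.02
        X = np.column_stack([np.ones(4), t])
        beta = np.linalg.solve(X.T @ X, X.T @ om)
        assert f.slope_omega_S == pytest.approx(beta[1])

    def test_constant_omega_gives_zero_slope_and_dtheta_from_endpoints(self):
        shank = _kin([0.3, 0.2, 0.1, 0.3], np.full(4, 0.7))
        back = _kin(np.zeros(4), np.zeros(4), "B")
        f = transition_features(Episode(0, 4, "transition"), shank, back)
        assert f.slope_omega_S == pytest.approx(0.0)
        assert f.dtheta_S == pytest.approx(0.0)  # identical endpoints

    def test_short_episode_rejected(self):
        shank = _kin(np.zeros(5), np.zeros(5))
        with pytest.raises(InvalidArgumentError):
            transition_features(Episode(0, 2, "transition"), shank, shank)


def brute_force_min_sse_bipartition(Z):
    """Exhaustive minimum within-cluster sum of squares over all proper
    bipartitions of the points."""
    n = len(Z)
    best, best_sets = np.inf, None
    idx = set(range(n))
    for r in range(1, n // 2 + 1):
        for left in combinations(range(n), r):
            right = tuple(sorted(idx - set(left)))
            sse = sum(
                float(((Z[list(grp)] - Z[list(grp)].mean(axis=0)) ** 2).sum())
                for grp in (left, right)
            )
            if sse < best - 1e-12:
                best, best_sets = sse, (left, right)
    return best, best_sets


class TestClustering:
    def test_mirrored_pair_gets_one_label_each(self):
        v = np.array([1.0, 0.5, -0.4, -0.3])
        feats = [TransitionFeatures(*v), TransitionFeatures(*(-v))]
        labels = cluster_transitions(feats, seed=0)
        assert sorted(labels) == ["sit_to_stand", "stand_to_sit"]
        # the episode with the lower net shank-angle change (dtheta_S = -0.4)
        # is the rise
        assert labels[0] == "sit_to_stand"

    def test_alternating_cohort_matches_generator_truth(self):
        trial = simulate_trial(SimulationConfig(seed=3, n_cycles=3,
                                                accel_noise_sd=0.0, gyro_noise_sd=0.0))
        shank = estimate_segment_kinematics(trial.streams["shank"])
        back = estimate_segment_kinematics(trial.streams["back"])
        eps = [Episode(e.start, e.end, "transition") for e in trial.episodes
               if "_to_" in e.label]
        feats = [transition_features(e, shank, back) for e in eps]
        got = cluster_transitions(feats, seed=0)
        truth = [e.label for e in trial.episodes if "_to_" in e.label]
        assert got == truth  # strictly alternating SiSt/StSi

    def test_partition_matches_exhaustive_min_sse(self, rng):
        for n in (4, 5, 6):
            X = rng.normal(size=(n, 4))
            feats = [TransitionFeatures(*row) for row in X]
            labels = cluster_transitions(feats, seed=0)
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            _, (left, right) = brute_force_min_sse_bipartition((X - mu) / sd)
            got_left = tuple(i for i, lab in enumerate(labels) if lab == labels[left[0]])
            assert got_left in (left, right)

    def test_order_permutation_invariance(self, rng):
        X = rng.normal(size=(6, 4))
        feats = [TransitionFeatures(*row) for row in X]
        labels = cluster_transitions(feats, seed=0)
        perm = [3, 1, 5, 0, 2, 4]
        labels_p = cluster_transitions([feats[i] for i in perm], seed=0)
        assert [labels[i] for i in perm] == labels_p

    def test_single_episode_rejected(self):
        with pytest.raises(InsufficientDataError):
            cluster_transitions([TransitionFeatures(0, 0, 0, 0)], seed=0)


class TestLabelStationary:
    def test_after_rise_comes_standing(self):
        eps = [Episode(0, 5, "stationary"), Episode(5, 10, "sit_to_stand"),
               Episode(10, 15, "stationary")]
        got = [e.label for e in label_stationary(eps)]
        assert got == ["sit", "sit_to_stand", "stand"]

    def test_after_descent_comes_sitting(self):
        eps = [Episode(0, 5, "stationary"), Episode(5, 10, "stand_to_sit"),
               Episode(10, 15, "stationary")]
        got = [e.label for e in label_stationary(eps)]
        assert got == ["stand", "stand_to_sit", "sit"]

    def test_lone_stationary_cannot_be_resolved(self):
        with pytest.raises(StructuralError):
            label_stationary([Episode(0, 10, "stationary")])

    def test_adjacent_transitions_rejected(self):
        eps = [Episode(0, 5, "sit_to_stand"), Episode(5, 10, "stand_to_sit")]
        with pytest.raises(StructuralError):
            label_stationary(eps)

    def test_full_tier2_respects_state_machine(self, clean_trial):
        shank = estimate_segment_kinematics(clean_trial.streams["shank"])
        back = estimate_segment_kinematics(clean_trial.streams["back"])
        from sit2stand.segmentation import segment_trial

        raw, _ = segment_trial(shank, back)
        labeled = classify_episodes(raw, shank, back, seed=0)
        allowed = {
            "sit": {"sit_to_stand"}, "sit_to_stand": {"stand"},
            "stand": {"stand_to_sit"}, "stand_to_sit": {"sit"},
        }
        for a, b in zip(labeled, labeled[1:]):
            assert b.label in allowed[a.label], (a.label, b.label)


class TestAccuracyScoring:
    def test_identical_and_half_matching(self):
        a = np.array(["sit", "sit", "stand", "stand"])
        assert classification_accuracy(a, a) == 100.0
        b = np.array(["sit", "sit", "sit", "sit"])
        assert classification_accuracy(a, b) == 50.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classification_accuracy(np.array(["sit"]), np.array(["sit", "sit"]))

    def test_jittered_boundaries_stay_above_95pct(self, clean_trial):
        truth = clean_trial.labels
        jittered = truth.copy()
        rng = np.random.default_rng(0)
        for ep in clean_trial.episodes:
            shift = rng.integers(-3, 4)
            if shift > 0:
                jittered[ep.start : ep.start + shift] = truth[max(0, ep.start - 1)]
            elif shift < 0:
                jittered[ep.start + shift : ep.start] = truth[ep.start]
        assert classification_accuracy(jittered, truth) >= 95.0


class TestReferenceLabels:
    def test_constant_extremes(self):
        n = 10
        sit = _kin(np.full(n, np.radians(90.0)), np.zeros(n), "T")
        stand = _kin(np.zeros(n), np.zeros(n), "T")
        assert (derive_reference_labels(sit) == "sit").all()
        assert (derive_reference_labels(stand) == "stand").all()

    def test_monotone_ramp_boundaries_at_threshold_crossings(self):
        theta_deg = np.linspace(90.0, 0.0, 91)  # one degree per sample
        kin = _kin(np.radians(theta_deg), np.zeros(91), "T")
        labels = derive_reference_labels(kin)
        assert (labels[theta_deg > 70] == "sit").all()
        assert (labels[(theta_deg <= 70) & (theta_deg >= 20)] == "sit_to_stand").all()
        assert (labels[theta_deg < 20] == "stand").all()


def test_sample_label_expansion_requires_full_cover():
    eps = [Episode(0, 3, "sit"), Episode(3, 5, "sit_to_stand")]
    labels = episodes_to_sample_labels(eps, 5)
    assert labels.tolist() == ["sit"] * 3 + ["sit_to_stand"] * 2
    with pytest.raises(InvalidArgumentError):
        episodes_to_sample_labels(eps, 6)
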