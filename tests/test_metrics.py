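"""Agreement metrics and group statistics, each against an independent
route: hand computation, closed forms, Monte Carlo, exact enumeration."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from sit2stand import (
    DegenerateDataError,
    Episode,
    InsufficientDataError,
    InvalidArgumentError,
    SegmentKinematics,
    bland_altman,
    grand_average_profiles,
    group_compare,
    nrmse,
    posture_summary,
    transition_timings,
)
from sit2stand.metrics import resample_normalized


class TestNrmse:
    def test_identical_series_is_zero(self, rng):
        x = rng.normal(size=100)
        assert nrmse(x, x) == 0.0

    def test_hand_example(self):
        assert nrmse([0.5, 1.5], [0.0, 1.0]) == pytest.approx(0.5)

    def test_constant_offset_closed_form(self, rng):
        ref = rng.normal(size=200)
        c = 0.37
        expected = c / (ref.max() - ref.min())
        assert nrmse(ref + c, ref) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        ref = rng.normal(size=50)
        est = ref + rng.normal(0, 0.1, 50)
        assert nrmse(3.7 * est, 3.7 * ref) == pytest.approx(nrmse(est, ref))
        assert nrmse(-2.0 * est, -2.0 * ref) == pytest.approx(nrmse(est, ref))

    def test_constant_reference_rejected(self):
        with pytest.raises(DegenerateDataError):
            nrmse([1.0, 2.0], [3.0, 3.0])


class TestBlandAltman:
    def test_identical_series(self, rng):
        x = rng.normal(size=50)
        md, sd, pct = bland_altman(x, x)
        assert (md, sd, pct) == (0.0, 0.0, 100.0)

    def test_constant_offset_boundary_counts_within(self, rng):
        x = rng.integers(-8, 8, size=50).astype(float) / 4.0  # exact in binary
        md, sd, pct = bland_altman(x + 3.0, x)
        assert md == pytest.approx(3.0)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert pct == 100.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=80), rng.normal(size=80)
        md_ab, sd_ab, _ = bland_altman(a, b)
        md_ba, sd_ba, _ = bland_altman(b, a)
        assert md_ab == pytest.approx(-md_ba)
        assert sd_ab == pytest.approx(sd_ba)

    def test_normal_differences_two_sigma_mass(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=10_000)
        b = np.zeros(10_000)
        _, _, pct = bland_altman(a, b)
        assert pct == pytest.approx(95.4, abs=1.0)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bland_altman([1.0], [2.0])


class TestTimings:
    def test_duration_arithmetic(self):
        eps = [Episode(0, 100, "sit"), Episode(100, 172, "sit_to_stand"),
               Episode(172, 300, "stand")]
        summary = transition_timings(eps, dt=0.02)
        assert summary.durations["sit_to_stand"] == [pytest.approx(1.44)]

    def test_no_transitions_gives_empty_summary(self):
        assert transition_timings([Episode(0, 10, "sit")], 0.02).durations == {}

    def test_generator_durations_recovered(self, clean_trial):
        summary = transition_timings(clean_trial.episodes, clean_trial.config.dt)
        mean_sist = np.mean(summary.durations["sit_to_stand"])
        assert mean_sist == pytest.approx(clean_trial.config.sit_to_stand_duration, abs=0.3)


def exact_mannwhitney_p(a, b):
    """Two-sided exact p by full enumeration of all C(n+m, n) rank
    assignments (no ties)."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    total = comb(n + m, n)
    all_ranks = np.arange(1, n + m + 1)
    count = 0
    for first in combinations(range(n + m), n):
        u = all_ranks[list(first)].sum() - n * (n + 1) / 2
        if min(u, n * m - u) <= min(u_obs, n * m - u_obs):
            count += 1
    return count / total


class TestGroupCompare:
    def test_exact_p_matches_enumeration(self, rng):
        for n, m in ((3, 3), (4, 5), (6, 4), (8, 8)):
            a = rng.normal(0, 1, n)
            b = rng.normal(1, 1, m)
            res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.pvalue == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_separated_tiny_groups(self):
        out = group_compare({"A": [1.0, 2, 3], "B": [10.0, 11, 12]}, n_comparisons=1)
        # most extreme arrangement of C(6,3)=20: two-sided exact p = 2/20
        assert out[("A", "B")] == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        out = group_compare({"A": [1.0, 2, 3], "B": [1.0, 2, 3]})
        assert out[("A", "B")] == 1.0

    def test_bonferroni_clamped_at_one(self, rng):
        a = rng.normal(size=10).tolist()
        b = (np.array(a) + 0.01).tolist()
        out = group_compare({"A": a, "B": b}, n_comparisons=50)
        assert out[("A", "B")] <= 1.0

    def test_three_groups_give_three_pairs(self, rng):
        groups = {g: rng.normal(i, 1, 8).tolist() for i, g in enumerate("XYZ")}
        out = group_compare(groups)
        assert set(out) == {("X", "Y"), ("X", "Z"), ("Y", "Z")}

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_compare({"A": [1.0], "B": [1.0, 2.0]})


class TestPostureSummary:
    @staticmethod
    def _kin(theta, seg="S"):
        n = len(theta)
        return SegmentKinematics(segment=seg, t=np.arange(n) * 0.02,
                                 theta=np.asarray(theta, float),
                                 omega=np.zeros(n), alpha=np.zeros(n))

    def test_constant_angles_recovered(self):
        eps = [Episode(0, 5, "sit"), Episode(5, 8, "sit_to_stand"), Episode(8, 12, "stand")]
        shank = self._kin([0.25] * 5 + [0.2] * 3 + [0.1] * 4)
        back = self._kin([0.18] * 5 + [0.1] * 3 + [0.05] * 4, "B")
        out = posture_summary(eps, shank, back)
        assert out["sit"]["theta_S"] == pytest.approx(0.25)
        assert out["stand"]["theta_B"] == pytest.approx(0.05)

    def test_absent_class_omitted(self):
        eps = [Episode(0, 5, "stand")]
        shank = self._kin([0.1] * 5)
        back = self._kin([0.05] * 5, "B")
        assert "sit" not in posture_summary(eps, shank, back)


class TestGrandAverage:
    @staticmethod
    def _kin(omega):
        n = len(omega)
        return SegmentKinematics(segment="S", t=np.arange(n) * 0.02,
                                 theta=np.zeros(n), omega=np.asarray(omega, float),
                                 alpha=np.zeros(n))

    def test_single_transition_returns_its_resampled_curve(self):
        om = np.sin(np.linspace(0, np.pi, 60))
        kin = self._kin(om)
        eps = [Episode(0, 60, "sit_to_stand")]
        curve = grand_average_profiles([(eps, kin)], "sit_to_stand", "omega", 101)
        assert np.allclose(curve, resample_normalized(om, 101))

    def test_two_identical_shapes_of_different_length_average_to_same(self):
        short = np.sin(np.linspace(0, np.pi, 40))
        long = np.sin(np.linspace(0, np.pi, 160))
        kin = self._kin(np.concatenate([short, long]))
        eps = [Episode(0, 40, "sit_to_stand"), Episode(40, 200, "sit_to_stand")]
        curve = grand_average_profiles([(eps, kin)], "sit_to_stand", "omega", 101)
        assert np.allclose(curve, np.sin(np.linspace(0, np.pi, 101)), atol=1e-3)

    def test_linear_ramp_survives_resampling_exactly(self):
        ramp = np.linspace(-1.0, 2.0, 73)
        assert np.allclose(resample_normalized(ramp, 101),
                           np.linspace(-1.0, 2.0, 101), atol=1e-9)

    def test_missing_label_rejected(self):
        kin = self._kin(np.zeros(10))
        with pytest.raises(DegenerateDataError):
            grand_average_profiles([([Episode(0, 10, "sit")], kin)], "sit_to_stand")
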