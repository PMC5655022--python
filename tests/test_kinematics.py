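"""Unit and oracle tests for the shared signal operators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from playmetrics import kinematics as kin
from playmetrics.kinematics import PlanarPath, SummaryStats


def path_of(*pts):
    return PlanarPath.from_samples([(float(i), float(x), float(y)) for i, (x, y) in enumerate(pts)])


class TestPathLength:
    def test_single_segment(self):
        assert kin.path_length(path_of((0, 0), (3, 4))) == pytest.approx(5.0)

    def test_single_point(self):
        assert kin.path_length(path_of((0, 0))) == 0.0

    def test_unit_segments(self):
        assert kin.path_length(path_of((0, 0), (1, 0), (1, 1), (2, 1))) == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            PlanarPath.from_samples([])


class TestPathEfficiency:
    def test_straight(self):
        assert kin.path_efficiency(path_of((0, 0), (1, 1))) == 1.0

    def test_backtrack(self):
        assert kin.path_efficiency(path_of((0, 0), (2, 0), (1, 0))) == pytest.approx(1 / 3)

    def test_l_shape(self):
        assert kin.path_efficiency(path_of((0, 0), (0, 5), (5, 5))) == pytest.approx(
            math.sqrt(50) / 10
        )

    def test_single_point_is_one(self):
        assert kin.path_efficiency(path_of((0, 0))) == 1.0

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_bounded(self, pts):
        assert 0.0 <= kin.path_efficiency(path_of(*pts)) <= 1.0

    def test_collinear_forward_is_one(self):
        p = path_of((0, 0), (1, 1), (2, 2), (3, 3))
        assert kin.path_efficiency(p) == pytest.approx(1.0)


class TestSegmentSpeedStats:
    def test_two_segments(self):
        p = PlanarPath.from_samples([(0, 0, 0), (1, 1, 0), (2, 4, 0)])
        s = kin.segment_speed_stats(p)
        assert (s.mean, s.min, s.max, s.median) == (2.0, 1.0, 3.0, 2.0)

    def test_constant_speed(self):
        p = PlanarPath.from_samples([(t, t, 0.0) for t in range(5)])
        s = kin.segment_speed_stats(p)
        assert s.mean == s.min == s.max == s.median == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kin.segment_speed_stats(path_of((0, 0)))

    def test_zero_dt_skipped(self):
        p = PlanarPath.from_samples([(0, 0, 0), (0, 1, 0), (1, 2, 0)])
        speeds = kin.segment_speeds(p)
        assert list(speeds) == [1.0]

    def test_random_path_matches_loop_oracle(self, rng):
        pts = rng.random((100, 2))
        ts = np.cumsum(rng.uniform(0.01, 0.2, 100))
        p = PlanarPath(t=ts, x=pts[:, 0], y=pts[:, 1])
        # independent brute-force oracle
        speeds = []
        for i in range(99):
            d = math.hypot(pts[i + 1, 0] - pts[i, 0], pts[i + 1, 1] - pts[i, 1])
            speeds.append(d / (ts[i + 1] - ts[i]))
        s = kin.segment_speed_stats(p)
        assert s.mean == pytest.approx(np.mean(speeds))
        assert s.sd == pytest.approx(np.std(speeds, ddof=1))
        assert s.min == pytest.approx(np.min(speeds))
        assert s.max == pytest.approx(np.max(speeds))
        assert s.median == pytest.approx(np.median(speeds))


def brute_force_episodes(t, angles, threshold):
    """Direct per-sample scan: maximal runs with angle > threshold."""
    runs = []
    current = None
    for i in range(len(t)):
        if angles[i] > threshold:
            if current is None:
                current = [i, i]
            else:
                current[1] = i
        elif current is not None:
            runs.append(tuple(current))
            current = None
    if current is not None:
        runs.append(tuple(current))
    return runs


class TestTiltEpisodes:
    def test_flat_series(self):
        t = np.linspace(0, 2, 50)
        assert kin.detect_tilt_episodes(t, np.zeros(50), "forward", 0.175) == []

    def test_constant_forward_pitch(self):
        t = np.linspace(0, 2, 50)
        pitch = np.full(50, -0.3)
        angles = kin.signed_angle(np.zeros(50), pitch, "forward")
        eps = kin.detect_tilt_episodes(t, angles, "forward", 0.175)
        assert len(eps) == 1
        assert eps[0].t_start == 0.0
        assert eps[0].t_end == 2.0
        assert eps[0].peak == pytest.approx(0.3)

    def test_sine_against_dense_oracle(self):
        t = np.arange(0, 2, 0.01)
        pitch = -0.4 * np.sin(2 * np.pi * t)
        angles = kin.signed_angle(np.zeros_like(t), pitch, "forward")
        eps = kin.detect_tilt_episodes(t, angles, "forward", 0.2)
        assert len(eps) == 2
        # dense 1 kHz brute-force scan
        td = np.arange(0, 2, 0.001)
        dense = brute_force_episodes(td, 0.4 * np.sin(2 * np.pi * td), 0.2)
        assert len(dense) == 2
        for ep, (i, j) in zip(eps, dense):
            assert ep.t_start == pytest.approx(td[i], abs=0.011)
            assert ep.t_end == pytest.approx(td[j], abs=0.011)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 80))
            t = np.cumsum(rng.uniform(0.01, 0.1, n))
            angles = rng.normal(0, 0.2, n)
            eps = kin.detect_tilt_episodes(t, angles, "left", 0.175)
            runs = brute_force_episodes(t, angles, 0.175)
            assert len(eps) == len(runs)
            for ep, (i, j) in zip(eps, runs):
                assert ep.t_start == t[i] and ep.t_end == t[j]
                assert ep.peak == pytest.approx(np.max(angles[i : j + 1]))

    def test_episodes_disjoint(self, rng):
        t = np.cumsum(rng.uniform(0.01, 0.1, 200))
        angles = rng.normal(0, 0.25, 200)
        eps = kin.detect_tilt_episodes(t, angles, "right", 0.175)
        for a, b in zip(eps, eps[1:]):
            assert a.t_end < b.t_start
        assert sum(e.duration for e in eps) <= t[-1] - t[0]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            kin.detect_tilt_episodes([], [], "forward", 0.175)


class TestTiltFeatures:
    def test_no_episodes(self):
        f = kin.tilt_features([], 10.0)
        assert f["fraction"] == 0.0 and f["rate"] == 0.0

    def test_full_coverage(self):
        ep = kin.TiltEpisode("forward", 0.0, 10.0, 0.3, 2)
        assert kin.tilt_features([ep], 10.0)["fraction"] == 1.0

    def test_three_episodes(self):
        eps = [kin.TiltEpisode("forward", i * 3.0, i * 3.0 + 1.0, 0.3, 0) for i in range(3)]
        f = kin.tilt_features(eps, 10.0)
        assert f["fraction"] == pytest.approx(0.3)
        assert f["rate"] == pytest.approx(0.3)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            kin.tilt_features([], 0.0)


class TestOscillationCount:
    def test_monotone(self):
        assert kin.oscillation_count([1, 2, 3, 4]) == 0

    def test_zigzag(self):
        assert kin.oscillation_count([0, 1, 0, 1, 0]) == 3

    def test_plateau_collapse(self):
        assert kin.oscillation_count([0, 1, 1, 0]) == 1

    def test_random_walk_matches_oracle(self, rng):
        vals = np.cumsum(rng.normal(0, 1, 200))
        # direct-definition oracle after plateau collapse
        collapsed = [vals[0]]
        for v in vals[1:]:
            if v != collapsed[-1]:
                collapsed.append(v)
        count = 0
        for i in range(1, len(collapsed) - 1):
            if (collapsed[i] - collapsed[i - 1]) * (collapsed[i + 1] - collapsed[i]) < 0:
                count += 1
        assert kin.oscillation_count(vals) == count

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=50))
    def test_invariant_under_monotone_transform(self, vals):
        # exact strictly monotone transform (no precision collapse)
        transformed = [2.0 * v for v in vals]
        assert kin.oscillation_count(vals) == kin.oscillation_count(transformed)


class TestSignChangeRate:
    def test_all_positive(self):
        assert kin.sign_change_rate([1, 2, 3], 5.0) == 0.0

    def test_alternating(self):
        assert kin.sign_change_rate([1, -1, 1, -1, 1], 2.0) == 2.0

    def test_zero_skipped(self):
        assert kin.sign_change_rate([1, 0, -1], 1.0) == 1.0

    def test_zero_does_not_reset(self):
        assert kin.sign_change_rate([1, 0, 1], 1.0) == 0.0

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=60),
        st.floats(0.1, 10, allow_nan=False),
    )
    def test_invariant_under_positive_scaling(self, vals, scale):
        assert kin.sign_change_rate(vals, 2.0) == kin.sign_change_rate(
            [v * scale for v in vals], 2.0
        )

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            kin.sign_change_rate([1, -1], 0.0)


class TestExceedanceFraction:
    def test_all_below(self):
        t = np.linspace(0, 1, 20)
        assert kin.exceedance_fraction(t, np.full(20, 0.01), 0.15) == 0.0

    def test_all_above(self):
        t = np.linspace(0, 1, 20)
        assert kin.exceedance_fraction(t, np.full(20, 0.5), 0.15) == 1.0

    def test_square_wave_half(self):
        t = np.arange(0, 10, 0.01)
        vals = np.where((t % 2) < 1, 0.5, 0.0)
        frac = kin.exceedance_fraction(t, vals, 0.15)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_negative_values_count(self):
        t = np.linspace(0, 1, 10)
        assert kin.exceedance_fraction(t, np.full(10, -0.5), 0.15) == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kin.exceedance_fraction([0.0], [1.0], 0.15)


class TestReactionTimes:
    def test_simple_match(self):
        assert kin.reaction_times([1.0], [1.35], 2.0) == [pytest.approx(0.35)]

    def test_missed(self):
        assert kin.reaction_times([1.0], [4.0], 2.0) == [None]

    def test_greedy_two(self):
        rts = kin.reaction_times([1.0, 3.0], [1.2, 3.5], 2.0)
        assert rts == [pytest.approx(0.2), pytest.approx(0.5)]

    def test_tap_consumed(self):
        rts = kin.reaction_times([1.0, 1.5], [1.6], 2.0)
        assert rts[0] == pytest.approx(0.6)
        assert rts[1] is None

    def test_tap_at_onset_excluded(self):
        assert kin.reaction_times([1.0], [1.0], 2.0) == [None]

    def test_negative_window(self):
        with pytest.raises(ValueError):
            kin.reaction_times([1.0], [1.2], -1.0)


class TestSummaryStats:
    def test_single_value(self):
        s = SummaryStats.from_values([3.0])
        assert s.mean == s.min == s.max == s.median == 3.0
        assert s.sd == 0.0

    def test_ordering_invariant(self, rng):
        vals = rng.normal(0, 1, 50)
        s = SummaryStats.from_values(vals)
        assert s.min <= s.median <= s.max
        assert s.sd >= 0
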