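import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackmigrate.features import (
    compute_feature_table,
    confinement_ratio,
    default_registry,
    diameter_stats,
    directional_change_count,
    directional_change_stats,
    duration,
    gyration_tensor_features,
    mean_straight_line_speed,
    net_displacement,
    path_length,
    speed_stats,
    velocity_average,
)
from trackmigrate.simulate import CohortConfig, MotionConfig, gen_cohort
from trackmigrate.track_io import Track


def test_registry_has_exactly_48_unique_descriptors():
    reg = default_registry()
    names = [d.name for d in reg]
    assert len(names) == 48 and len(set(names)) == 48
    classes = {d.feature_class for d in reg}
    assert "partition" in classes and "rdp_simplification" in classes


class TestPathNetDuration:
    def test_three_four_five(self):
        t = Track("t", [0, 1, 2], [[0, 0], [3, 4], [6, 8]])
        assert path_length(t) == pytest.approx(10.0)
        assert net_displacement(t) == pytest.approx(10.0)

    def test_closed_loop_net_zero(self, square_track):
        assert net_displacement(square_track) == pytest.approx(0.0)

    def test_13_frames_span_240_min(self):
        t = Track("t", np.arange(13), np.column_stack([np.arange(13.0), np.zeros(13)]))
        assert duration(t) == pytest.approx(240.0)


class TestDiameter:
    def test_unit_square(self, square_track):
        dmax, _, _ = diameter_stats(square_track)
        assert dmax == pytest.approx(np.sqrt(2))

    def test_two_points(self):
        t = Track("t", [0, 1], [[0, 0], [5, 0]])
        dmax, dmean, dmed = diameter_stats(t)
        assert dmax == dmean == dmed == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, random_track_factory):
        t = random_track_factory(7, n=20)
        dists = [
            np.hypot(*(t.xy[i] - t.xy[j]))
            for i in range(t.n_points)
            for j in range(i + 1, t.n_points)
        ]
        dmax, dmean, dmed = diameter_stats(t)
        assert dmax == pytest.approx(max(dists))
        assert dmean == pytest.approx(np.mean(dists))
        assert dmed == pytest.approx(np.median(dists))


class TestSpeed:
    def test_constant_steps(self):
        t = Track("t", np.arange(5), np.column_stack([2.0 * np.arange(5), np.zeros(5)]))
        mean, med, std, mn, mx = speed_stats(t)
        assert mean == pytest.approx(0.1) and std == pytest.approx(0.0)

    def test_mixed_steps(self):
        t = Track("t", [0, 1, 2], [[0, 0], [2, 0], [6, 0]])
        mean, med, std, mn, mx = speed_stats(t)
        assert (mean, mn, mx) == pytest.approx((0.15, 0.1, 0.2))

    def test_gap_uses_actual_dt(self):
        t = Track("t", [0, 2], [[0, 0], [4, 0]])
        assert speed_stats(t)[0] == pytest.approx(0.1)  # 4 µm over 40 min


class TestDirectionalChange:
    def test_straight_line(self, straight_track):
        assert directional_change_stats(straight_track) == pytest.approx((0, 0, 0, 0))
        assert directional_change_count(straight_track) == pytest.approx((0, 0, 0))

    def test_square_all_right_angles(self, square_track):
        mean, med, std, mx = directional_change_stats(square_track)
        assert mean == med == mx == pytest.approx(90.0)
        p20, p45, p90 = directional_change_count(square_track)
        assert (p20, p45) == (1.0, 1.0)
        assert p90 == 0.0  # strict inequality at the threshold

    def test_reversal_is_180(self):
        t = Track("t", [0, 1, 2], [[0, 0], [1, 0], [0, 0]])
        assert directional_change_stats(t)[3] == pytest.approx(180.0)

    def test_degenerate_two_points(self):
        t = Track("t", [0, 1], [[0, 0], [1, 0]])
        assert directional_change_stats(t) == (0.0, 0.0, 0.0, 0.0)


class TestVelocityAverage:
    def test_ballistic_along_x(self):
        t = Track("t", np.arange(5), np.column_stack([2.0 * np.arange(5), np.zeros(5)]))
        assert velocity_average(t) == pytest.approx((0.1, 0.0))

    def test_closed_loop_convention(self, square_track):
        assert velocity_average(square_track) == (0.0, 0.0)

    def test_l_path(self, l_track):
        mag, ang = velocity_average(l_track)
        assert mag == pytest.approx(0.125)
        assert ang == pytest.approx(np.degrees(np.arctan2(4, 3)))


class TestGyration:
    def test_collinear(self):
        t = Track("t", np.arange(4), np.column_stack([np.arange(4.0), np.zeros(4)]))
        radius, major, minor, asph, orient = gyration_tensor_features(t)
        assert minor == pytest.approx(0.0, abs=1e-9)
        assert asph == pytest.approx(1.0)
        assert orient == pytest.approx(0.0)

    def test_symmetric_four_points(self):
        t = Track("t", np.arange(4), [[1, 1], [-1, 1], [-1, -1], [1, -1]])
        radius, major, minor, asph, _ = gyration_tensor_features(t)
        assert radius == pytest.approx(np.sqrt(2))
        assert major == minor == pytest.approx(2.0)
        assert asph == pytest.approx(0.0)

    def test_eigenvalues_match_covariance_oracle(self, random_track_factory):
        t = random_track_factory(11, n=30)
        cov = np.cov(t.xy.T, ddof=0)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        _, major, minor, _, _ = gyration_tensor_features(t)
        assert major == pytest.approx(2 * np.sqrt(lam[0]), rel=1e-9)
        assert minor == pytest.approx(2 * np.sqrt(lam[1]), rel=1e-9)


class TestConfinement:
    def test_straight(self, straight_track):
        assert confinement_ratio(straight_track) == pytest.approx(1.0)

    def test_l_path(self, l_track):
        assert confinement_ratio(l_track) == pytest.approx(5 / 7)

    def test_closed_loop(self, square_track):
        assert confinement_ratio(square_track) == pytest.approx(0.0)

    def test_straight_line_speed(self, l_track):
        assert mean_straight_line_speed(l_track) == pytest.approx(5 / 40)


@pytest.fixture(scope="module")
def cohort():
    cfg = CohortConfig(
        groups={"control": [(MotionConfig(model="saltatory", n_frames=40), 5)]},
        seed=21,
    )
    ts, _ = gen_cohort(cfg)
    return ts


class TestFeatureTable:
    def test_exactly_48_descriptors_no_missing(self, cohort):
        table = compute_feature_table(cohort)
        assert len(table.feature_names) == 48
        assert not table.values().isna().any().any()

    def test_row_order_invariant(self, cohort):
        table = compute_feature_table(cohort)
        reversed_set = cohort.subset(list(reversed(cohort.track_ids())))
        table2 = compute_feature_table(reversed_set)
        assert table.data.sort_index().equals(table2.data.sort_index())

    def test_identical_tracks_identical_rows(self, cohort):
        src = next(iter(cohort))
        from trackmigrate.track_io import Track, TrackSet

        twins = TrackSet()
        for tid in ("a", "b"):
            twins.add(Track(tid, src.frames, src.xy, src.frame_interval))
        table = compute_feature_table(twins)
        np.testing.assert_array_equal(
            table.values().loc["a"].to_numpy(), table.values().loc["b"].to_numpy()
        )


class TestGeometricInvariants:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_descriptor_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        xy = np.cumsum(rng.normal(0, 2, size=(n, 2)), axis=0)
        t = Track("p", np.arange(n), xy)
        net = net_displacement(t)
        dmax = diameter_stats(t)[0]
        assert confinement_ratio(t) <= 1 + 1e-12
        assert dmax >= net - 1e-12
        assert gyration_tensor_features(t)[0] <= dmax + 1e-12
        # triangle inequality for gapless tracks
        assert mean_straight_line_speed(t) <= speed_stats(t)[0] + 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_and_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        xy = np.cumsum(rng.normal(0, 2, size=(n, 2)), axis=0)
        t = Track("p", np.arange(n), xy)
        shift = rng.normal(0, 100, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t2 = Track("p2", np.arange(n), (xy + shift) @ rot.T)
        for fn in (path_length, net_displacement, confinement_ratio):
            assert fn(t) == pytest.approx(fn(t2), rel=1e-9, abs=1e-9)
        assert diameter_stats(t) == pytest.approx(diameter_stats(t2), rel=1e-9)
        assert gyration_tensor_features(t)[:4] == pytest.approx(
            gyration_tensor_features(t2)[:4], rel=1e-7, abs=1e-9
        )
        assert directional_change_stats(t) == pytest.approx(
            directional_change_stats(t2), rel=1e-7, abs=1e-9
        )
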