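"""Point clouds, Rips degree-1 persistence, Betti-curve features."""

import numpy as np
import pytest

import knotph as kp
from knotph.ph import BettiCurve, local_maxima, to_radius_scale


def circle_cloud(n, radius=1.0):
    th = 2 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(th), np.sin(th), np.zeros(n)])


def wedge_cloud(theta, spacing=0.1):
    """Two unit edges meeting at internal angle theta, sampled along both."""
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([np.cos(theta), np.sin(theta), 0.0])
    a = np.arange(0, 1.0001, spacing)
    return np.vstack([np.outer(a, u1), np.outer(a[1:], u2)])


class TestInterpolate:
    def test_point_count_and_spacing(self):
        P = kp.sample_random_polygon(50, rng=0)
        cloud = kp.interpolate(P, 10)
        assert len(cloud) == 500
        gaps = np.linalg.norm(np.diff(cloud.points[:10], axis=0), axis=1)
        assert np.allclose(gaps, 0.1, atol=1e-12)

    def test_s_one_is_vertex_set(self):
        P = kp.regular_polygon(7)
        assert np.array_equal(kp.interpolate(P, 1).points, P.vertices)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            kp.interpolate(kp.regular_polygon(5), 0)


class TestRipsEngine:
    def test_circle_has_one_dominant_class(self):
        bc = kp.rips_h1_barcode(circle_cloud(200))
        dominant = bc.intervals[bc.persistences > 1.0]
        assert len(dominant) == 1
        # the Rips class of the circle dies at diameter-scale sqrt(3)
        assert dominant[0, 1] == pytest.approx(np.sqrt(3), abs=0.05)

    def test_collinear_points_have_no_cycle(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert len(kp.rips_h1_barcode(pts)) == 0

    def test_wedge_spike_interval_closed_form(self):
        # internal angle 35 deg, spacing d=0.1: the trapezoid class is born
        # at 4 d sin(theta/2) and dies at d sqrt(5 - 4 cos theta)
        theta = np.radians(35.0)
        bc = kp.rips_h1_barcode(wedge_cloud(theta))
        assert len(bc) == 1
        birth, death = bc.intervals[0]
        assert birth == pytest.approx(0.4 * np.sin(theta / 2), abs=1e-9)
        assert death == pytest.approx(0.1 * np.sqrt(5 - 4 * np.cos(theta)),
                                      abs=1e-9)

    def test_wide_angle_has_no_spike(self):
        assert len(kp.rips_h1_barcode(wedge_cloud(np.radians(50.0)))) == 0

    def test_engine_matches_reference_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            pts = rng.normal(size=(int(rng.integers(5, 41)), 3))
            got = kp.rips_h1_barcode(pts).intervals
            ref = kp.reference_persistence_h1(pts).intervals
            assert got.shape == ref.shape
            assert np.allclose(got, ref, atol=1e-9)

    def test_engine_matches_oracle_on_curve_sample(self):
        P = kp.sample_random_polygon(20, rng=5)
        cloud = kp.interpolate(P, 2)  # 40 points along the knot
        got = kp.rips_h1_barcode(cloud).intervals
        ref = kp.reference_persistence_h1(cloud).intervals
        assert np.allclose(got, ref, atol=1e-9)

    def test_square_corners(self):
        sq = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1, 0], [0.0, 1, 0]])
        for compute in (kp.rips_h1_barcode, kp.reference_persistence_h1):
            bc = compute(sq)
            assert len(bc) == 1
            assert bc.intervals[0] == pytest.approx([1.0, np.sqrt(2)],
                                                    abs=1e-12)

    def test_oracle_refuses_large_clouds(self):
        with pytest.raises(ValueError):
            kp.reference_persistence_h1(np.zeros((61, 3)))

    def test_rigid_motion_invariance_and_scaling(self):
        rng = np.random.default_rng(30)
        pts = rng.normal(size=(60, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        b = rng.normal(size=3)
        base = kp.rips_h1_barcode(pts)
        moved = kp.rips_h1_barcode(pts @ Q.T + b)
        assert np.allclose(base.intervals, moved.intervals, atol=1e-9)
        scaled = kp.rips_h1_barcode(2.5 * pts)
        assert np.allclose(scaled.intervals, 2.5 * base.intervals, atol=1e-9)
        assert kp.integral_I(scaled) == pytest.approx(
            2.5 * kp.integral_I(base), abs=1e-9)
        assert kp.max_bar_M(scaled) == pytest.approx(
            2.5 * kp.max_bar_M(base), abs=1e-9)


class TestBettiCurve:
    def test_counting_function(self):
        curve = kp.betti_curve(kp.Barcode([(1.0, 3.0), (2.0, 4.0)]))
        assert curve(2.5) == 2
        assert curve(3.5) == 1
        assert curve(4.0) == 0
        assert curve(1.0) == 1  # closed at birth

    def test_empty_barcode(self):
        curve = kp.betti_curve(kp.Barcode(np.empty((0, 2))))
        assert curve.is_zero()
        assert curve.integral() == 0.0

    def test_integral_identity(self):
        # two routes to the same number: sum of bar lengths vs curve integral
        P = kp.sample_random_polygon(30, rng=7)
        bc = kp.rips_h1_barcode(kp.interpolate(P, 10))
        assert kp.betti_curve(bc).integral() == pytest.approx(
            kp.integral_I(bc), abs=1e-12)

    def test_bar_feature_arithmetic(self):
        bc = kp.Barcode([(1.0, 3.0), (2.0, 4.0)])
        assert kp.integral_I(bc) == 4.0
        assert kp.max_bar_M(bc) == 2.0
        assert kp.num_bars_B(bc) == 2
        shifted = kp.Barcode(bc.intervals + 5.0)
        assert kp.integral_I(shifted) == 4.0
        assert kp.max_bar_M(shifted) == 2.0
        assert kp.num_bars_B(shifted) == 2

    def test_radius_scale_helper(self):
        assert to_radius_scale(1.0) == 0.5


class TestSpikeFilter:
    def test_removes_shallow_angle_artefact(self):
        bc = kp.rips_h1_barcode(wedge_cloud(np.radians(35.0)))
        assert len(kp.spike_filter(bc)) == 0

    def test_keeps_persistent_bar_born_in_window(self):
        bc = kp.Barcode([(0.105, 0.505)])
        assert len(kp.spike_filter(bc)) == 1

    def test_idempotent(self):
        P = kp.sample_random_polygon(40, rng=3)
        bc = kp.rips_h1_barcode(kp.interpolate(P, 10))
        once = kp.spike_filter(bc)
        twice = kp.spike_filter(once)
        assert np.array_equal(once.intervals, twice.intervals)


class TestAverageCurve:
    def test_average_of_identical_curves(self):
        c = kp.betti_curve(kp.Barcode([(0.0, 2.0)]))
        avg = kp.average_betti_curve([c, c])
        assert avg(1.0) == 1.0
        assert avg.integral() == pytest.approx(c.integral(), abs=1e-12)

    def test_pointwise_mean_on_merged_grid(self):
        c1 = BettiCurve(np.array([0.0, 2.0]), np.array([1]))
        c2 = BettiCurve(np.array([0.0, 1.0]), np.array([3]))
        avg = kp.average_betti_curve([c1, c2])
        assert avg(0.5) == 2.0
        assert avg(1.5) == 0.5

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            kp.average_betti_curve([])

    def test_curve_max_tie_break(self):
        c = BettiCurve(np.array([0.0, 1.0, 2.0, 3.0]), np.array([2, 1, 2]))
        t_star, value = kp.curve_max(c)
        assert (t_star, value) == (0.0, 2.0)

    def test_local_maxima_of_step_function(self):
        c = BettiCurve(np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
                       np.array([2, 1, 3, 3]))
        peaks = local_maxima(c)
        assert peaks == [(0.0, 2.0), (2.0, 3.0)]
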