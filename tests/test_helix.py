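"""Helix morphometrics: closed-form oracles, invariances, edge cases."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import slimemetrics as sm
from slimemetrics.helix import DegenerateGeometryError


class TestPairMidpoints:
    def test_midpoint_of_a_pair(self):
        series = sm.LandmarkSeries("t", np.array([[[0, 0, 0], [0, 1, 0]]], dtype=float))
        np.testing.assert_allclose(sm.pair_midpoints(series), [[0, 0.5, 0]])

    def test_degenerate_pair_returns_the_point(self):
        q = np.array([1.0, 2.0, 3.0])
        series = sm.LandmarkSeries("t", np.array([[q, q]]))
        np.testing.assert_allclose(sm.pair_midpoints(series), [q])

    def test_matches_generator_centerline(self, clean_series, clean_helix_spec):
        mids = sm.pair_midpoints(clean_series)
        k = np.arange(clean_helix_spec.n_half_loops + 1)
        expected = np.stack(
            [
                clean_helix_spec.pitch_P * k / 2.0,
                (clean_helix_spec.helical_diameter_D / 2.0) * (-1.0) ** k,
                np.zeros_like(k, dtype=float),
            ],
            axis=1,
        )
        np.testing.assert_allclose(mids, expected, atol=1e-9)


class TestDirectionOfIncrease:
    def test_simple_axis(self):
        v = sm.direction_of_increase(np.array([[0, 0, 0], [2, 0, 0]], dtype=float))
        np.testing.assert_allclose(v, [1, 0, 0])

    def test_antisymmetry_under_reversal(self, clean_series):
        mids = sm.pair_midpoints(clean_series)
        np.testing.assert_allclose(
            sm.direction_of_increase(mids), -sm.direction_of_increase(mids[::-1]), atol=1e-12
        )

    def test_noise_free_even_helix_gives_axis(self, clean_series):
        v = sm.direction_of_increase(sm.pair_midpoints(clean_series))
        np.testing.assert_allclose(v, [1, 0, 0], atol=1e-9)

    def test_coincident_endpoints_error(self):
        pts = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            sm.direction_of_increase(pts)


class TestThreadDiameter:
    def test_mean_of_two_pairs(self):
        pairs = np.array(
            [[[0, 0, 0], [0.2, 0, 0]], [[0, 0, 0], [1.0, 0, 0]]], dtype=float
        )
        phi, mean = sm.thread_diameter(sm.LandmarkSeries("t", pairs))
        np.testing.assert_allclose(phi, [0.2, 1.0])
        assert mean == pytest.approx(0.6)

    def test_recovers_generator_diameter(self):
        spec = sm.HelixSpec(thread_diameter_phi=0.52)
        _, mean = sm.thread_diameter(sm.make_helix_landmarks(spec))
        assert mean == pytest.approx(0.52, abs=1e-9)


class TestHalfLoops:
    @pytest.mark.parametrize(
        "P,D",
        [(2.0, 0.5), (1.4, 0.35)],
        ids=["round-numbers", "thread-scale"],
    )
    def test_closed_form_on_ideal_helix(self, P, D):
        """Every half loop: axial P/2, lateral D, theta=atan(P/(2D)), D recovered."""
        spec = sm.HelixSpec(helical_diameter_D=D, pitch_P=P, n_half_loops=10)
        geom = sm.analyze_thread(sm.make_helix_landmarks(spec))
        theta_true = np.degrees(np.arctan2(P / 2, D))
        for h in geom.half_loops:
            assert h.axial_length == pytest.approx(P / 2, abs=1e-9)
            assert h.lateral_length == pytest.approx(D, abs=1e-9)
            assert h.theta == pytest.approx(theta_true, abs=1e-9)
            assert h.D == pytest.approx(D, abs=1e-9)

    def test_pure_lateral_displacement_flagged_degenerate(self):
        pts = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 0]], dtype=float)
        with pytest.warns(UserWarning, match="degenerate"):
            loops = sm.analyze_half_loops(pts, np.array([1.0, 0, 0]))
        assert all(h.degenerate for h in loops)
        assert loops[0].theta == pytest.approx(0.0)

    def test_axis_aligned_segment_gives_theta_90_and_zero_D(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        loops = sm.analyze_half_loops(pts, np.array([1.0, 0, 0]))
        for h in loops:
            assert h.theta == pytest.approx(90.0)
            assert h.D == pytest.approx(0.0, abs=1e-12)


class TestScalarOps:
    @pytest.mark.parametrize(
        "theta,expected",
        [(90.0, 0.0), (30.0, 0.5), (63.5, 1 - np.sin(np.radians(63.5)))],
    )
    def test_extension_ratio(self, theta, expected):
        assert sm.extension_ratio(theta) == pytest.approx(expected, abs=1e-9)

    def test_extension_ratio_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sm.extension_ratio(-1.0)
        with pytest.raises(ValueError):
            sm.extension_ratio(90.5)

    def test_extension_ratio_monotone_decreasing(self):
        thetas = np.linspace(0, 90, 91)
        vals = [sm.extension_ratio(t) for t in thetas]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "L,theta,expected",
        [(2.2, 63.5, 2.2 * np.sin(np.radians(63.5))), (5.0, 90.0, 5.0), (1.0, 30.0, 0.5)],
    )
    def test_centerline_length(self, L, theta, expected):
        assert sm.centerline_length(L, theta) == pytest.approx(expected, abs=1e-9)


class TestHandedness:
    def test_right_handed_dense_helix(self, clean_series):
        v = sm.direction_of_increase(sm.pair_midpoints(clean_series))
        assert sm.detect_handedness(clean_series.dense_centerline, v) == "right"

    def test_mirroring_flips_chirality(self, clean_series):
        v = sm.direction_of_increase(sm.pair_midpoints(clean_series))
        mirrored = clean_series.dense_centerline * np.array([1.0, 1.0, -1.0])
        assert sm.detect_handedness(mirrored, v) == "left"

    def test_left_handed_spec_detected(self):
        spec = sm.HelixSpec(handedness="left")
        s = sm.make_helix_landmarks(spec, dense=True)
        geom = sm.analyze_thread(s)
        assert geom.handedness == "left"

    def test_extremum_only_input_is_undetermined(self, clean_series):
        mids = sm.pair_midpoints(clean_series)
        v = sm.direction_of_increase(mids)
        assert sm.detect_handedness(mids, v) == "undetermined"

    def test_all_seeds_recovered_at_zero_noise(self):
        for seed in range(20):
            for hand in ("right", "left"):
                spec = sm.HelixSpec(handedness=hand, seed=seed)
                s = sm.make_helix_landmarks(spec, dense=True)
                assert sm.analyze_thread(s).handedness == hand


class TestOlsTrend:
    def test_exact_line(self):
        x = np.arange(5.0)
        slope, intercept, p = sm.ols_trend(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert p < 1e-10

    def test_constant_response(self):
        slope, _, _ = sm.ols_trend([1, 2, 3, 4], [5, 5, 5, 5])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        slope, _, _ = sm.ols_trend([1, 2, 3], [1, 3, 2])
        assert slope == pytest.approx(0.5)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sm.ols_trend([1, 1, 1], [1, 2, 3])


class TestInvariances:
    @given(seed=st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        """phi, theta, D, R_ext unchanged under any rotation + translation."""
        base = sm.HelixSpec(helical_diameter_D=0.35, pitch_P=1.4, n_half_loops=6)
        plain = sm.analyze_thread(sm.make_helix_landmarks(base))
        motion = sm.RigidMotion.random(np.random.default_rng(seed))
        moved = sm.analyze_thread(
            sm.make_helix_landmarks(dataclasses.replace(base, rigid_motion=motion))
        )
        assert moved.phi_mean == pytest.approx(plain.phi_mean, abs=1e-9)
        assert moved.theta_mean == pytest.approx(plain.theta_mean, abs=1e-9)
        assert moved.D_mean == pytest.approx(plain.D_mean, abs=1e-9)
        assert moved.R_ext_mean == pytest.approx(plain.R_ext_mean, abs=1e-9)

    @given(scale=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, scale):
        """Scaling coordinates by s scales phi and D by s; theta, R_ext unchanged."""
        base = sm.make_helix_landmarks(
            sm.HelixSpec(helical_diameter_D=0.35, pitch_P=1.4, n_half_loops=6)
        )
        plain = sm.analyze_thread(base)
        scaled = sm.analyze_thread(
            sm.LandmarkSeries(base.thread_id, base.pairs * scale)
        )
        assert scaled.phi_mean == pytest.approx(scale * plain.phi_mean, rel=1e-9)
        assert scaled.D_mean == pytest.approx(scale * plain.D_mean, rel=1e-9)
        assert scaled.theta_mean == pytest.approx(plain.theta_mean, abs=1e-9)
        assert scaled.R_ext_mean == pytest.approx(plain.R_ext_mean, abs=1e-9)
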