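import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

import valveflow as vf
from valveflow.synthetic import generate_volume_trace
from valveflow.wss import (
    ParticleTracks, ShearTrace, VolumeTrace, WallGeometry, compare_traces,
    flow_rate_from_volume, max_inscribed_circle, near_wall_shear,
    parabolic_wall_shear, poiseuille_wall_shear_rate, postprocess_trace,
    volume_from_slices)

import pandas as pd


def straight_wall(n_frames, y=0.0, dt=0.01):
    times = np.arange(n_frames) * dt
    poly = np.array([[-100.0, y], [300.0, y]])
    return WallGeometry(times=times, contours=[[poly]] * n_frames)


class TestNearWallShear:
    def test_parallel_particle_hand_value(self):
        # v = 100 μm/s at d = 5 μm from a straight wall, mu = 1.5 mPa·s
        # -> gamma = 20 1/s, tau = 0.03 Pa
        dt = 0.01
        df = pd.DataFrame({
            "frame": [0, 1], "particle_id": [0, 0],
            "x_um": [0.0, 100.0 * dt], "y_um": [5.0, 5.0]})
        trace = near_wall_shear(ParticleTracks(df, dt), straight_wall(2),
                                viscosity=1.5, near_wall_cutoff=10.0)
        assert trace.shear_rate[0] == pytest.approx(20.0, rel=1e-9)
        assert trace.shear_stress[0] == pytest.approx(0.03, rel=1e-9)

    def test_normal_velocity_contributes_zero(self):
        dt = 0.01
        df = pd.DataFrame({
            "frame": [0, 1], "particle_id": [0, 0],
            "x_um": [0.0, 0.0], "y_um": [5.0, 6.0]})
        trace = near_wall_shear(ParticleTracks(df, dt), straight_wall(2),
                                viscosity=1.5, near_wall_cutoff=10.0)
        assert trace.shear_rate[0] == pytest.approx(0.0, abs=1e-9)

    def test_magnitude_projection_counts_normal_motion(self):
        dt = 0.01
        df = pd.DataFrame({
            "frame": [0, 1], "particle_id": [0, 0],
            "x_um": [0.0, 0.0], "y_um": [5.0, 6.0]})
        trace = near_wall_shear(ParticleTracks(df, dt), straight_wall(2),
                                viscosity=1.5, near_wall_cutoff=10.0,
                                projection="magnitude")
        assert trace.shear_rate[0] == pytest.approx(20.0, rel=1e-9)

    def test_no_qualifying_particle_raises(self):
        dt = 0.01
        df = pd.DataFrame({
            "frame": [0, 1], "particle_id": [0, 0],
            "x_um": [0.0, 1.0], "y_um": [50.0, 50.0]})
        with pytest.raises(ValueError, match="cutoff"):
            near_wall_shear(ParticleTracks(df, dt), straight_wall(2),
                            viscosity=1.5, near_wall_cutoff=10.0)

    def test_moving_wall_correction(self):
        # wall and particle both advect at 100 μm/s: relative velocity zero
        dt = 0.01
        times = np.arange(2) * dt
        walls = [[np.array([[-100.0 + 100.0 * dt * f, 0.0],
                            [300.0 + 100.0 * dt * f, 0.0]])]
                 for f in range(2)]
        wall = WallGeometry(times=times, contours=walls)
        df = pd.DataFrame({
            "frame": [0, 1], "particle_id": [0, 0],
            "x_um": [0.0, 100.0 * dt], "y_um": [5.0, 5.0]})
        rel = near_wall_shear(ParticleTracks(df, dt), wall, 1.5, 10.0)
        lab = near_wall_shear(ParticleTracks(df, dt), wall, 1.5, 10.0,
                              wall_relative=False)
        assert rel.shear_rate[0] == pytest.approx(0.0, abs=1e-6)
        assert lab.shear_rate[0] == pytest.approx(20.0, rel=1e-9)

    def test_matches_poiseuille_ground_truth(self, poiseuille_movie):
        # near-wall linear profile is the Taylor limit of the parabola:
        # particles at d < 0.15 R give estimates within 15% of 4Q/(pi R^3)
        sc, movie = poiseuille_movie
        gt = movie.ground_truth
        trace = near_wall_shear(movie.tracks, movie.wall, sc.viscosity,
                                near_wall_cutoff=0.15 * 25.0)
        true = gt["wall_shear_rate_s"]
        assert trace.max_rate == pytest.approx(true.max(), rel=0.15)
        assert trace.p95_rate == pytest.approx(
            np.percentile(true, 95), rel=0.15)
        # pointwise during high flow (away from flow reversals)
        high = np.abs(gt["flow_nl_s"]) > 0.5 * sc.peak_flow
        est, ref = trace.shear_rate[high], true[high]
        ok = ~np.isnan(est)
        assert np.median(np.abs(est[ok] - ref[ok]) / ref[ok]) < 0.15


class TestFlowRateFromVolume:
    def test_constant_volume_zero_flow(self):
        tr = VolumeTrace(np.linspace(0, 1, 11), np.full(11, 2.0))
        _, q = flow_rate_from_volume(tr)
        assert np.allclose(q, 0.0)

    def test_exact_on_affine(self):
        t = np.linspace(0, 1, 11)
        tr = VolumeTrace(t, 5.0 - 0.7 * t)
        _, q = flow_rate_from_volume(tr)
        assert np.allclose(q, 0.7, rtol=1e-12)

    def test_sinusoid_matches_closed_form(self):
        period = 0.5
        trace, q_true = generate_volume_trace(
            v0=2.0, amplitude=0.5, period=period, dt=period / 100, n=200)
        _, q = flow_rate_from_volume(trace)
        amp = 0.5 * 2 * math.pi / period
        # second-order bound holds for the interior central differences;
        # the one-sided end stencils are second order with a larger constant
        assert np.max(np.abs(q - q_true)[1:-1]) < 1e-3 * amp
        assert np.max(np.abs(q - q_true)) < 2e-3 * amp

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            flow_rate_from_volume(VolumeTrace([0.0, 1.0], [1.0, 2.0]))


class TestMaxInscribedCircle:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        (cx, cy), r = max_inscribed_circle(sq, resolution=0.05)
        assert (cx, cy) == pytest.approx((0.5, 0.5), abs=1e-4)
        assert r == pytest.approx(0.5, abs=1e-4)

    def test_regular_64gon_inradius(self):
        theta = np.linspace(0, 2 * math.pi, 65)[:-1]
        r_circ = 7.0
        poly = r_circ * np.column_stack([np.cos(theta), np.sin(theta)])
        _, r = max_inscribed_circle(poly, resolution=0.2)
        assert r == pytest.approx(r_circ * math.cos(math.pi / 64), abs=1e-3)

    def test_l_shape_matches_brute_force(self):
        poly = np.array([[0, 0], [4, 0], [4, 2], [2, 2], [2, 5], [0, 5]],
                        float)
        res = 0.1
        _, r = max_inscribed_circle(poly, resolution=res)
        # exhaustive fine-grid oracle
        sp = Polygon(poly)
        xs = np.arange(0, 4, 0.01)
        ys = np.arange(0, 5, 0.01)
        gx, gy = np.meshgrid(xs, ys)
        pts = shapely.points(gx.ravel(), gy.ravel())
        d = shapely.distance(pts, sp.boundary)
        inside = shapely.contains_xy(sp, gx.ravel(), gy.ravel())
        r_brute = d[inside].max()
        assert abs(r - r_brute) < res

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError):
            max_inscribed_circle(
                np.array([[0, 0], [1, 0], [2, 0]], float), 0.1)


class TestParabolicWallShear:
    def test_coherent_identity(self):
        assert poiseuille_wall_shear_rate(math.pi / 4, 1.0) == \
            pytest.approx(1.0, rel=1e-14)

    def test_cubic_scaling(self):
        t = np.arange(3.0)
        q = np.ones(3)
        a = parabolic_wall_shear(t, q, 10.0, 1.5)
        b = parabolic_wall_shear(t, q, 20.0, 1.5)
        assert a.shear_rate[0] == pytest.approx(8.0 * b.shear_rate[0],
                                                rel=1e-12)

    def test_physical_units(self):
        # Q = 1 nl/s = 1e-12 m^3/s, r = 10 μm = 1e-5 m:
        # gamma = 4e-12 / (pi 1e-15) = 1273.24 1/s; tau = 1.5e-3 * gamma
        tr = parabolic_wall_shear(np.array([0.0]), np.array([1.0]), 10.0, 1.5)
        assert tr.shear_rate[0] == pytest.approx(4e-12 / (math.pi * 1e-15),
                                                 rel=1e-12)
        assert tr.shear_stress[0] == pytest.approx(1.909859, rel=1e-6)

    def test_unit_rescaling_invariance(self):
        # μm -> mm (x1e-3) with matching volume rescale nl -> μl (x1e-3...)
        # 4Q/(pi r^3): scaling r by k and Q by k^3 leaves gamma unchanged
        t = np.arange(3.0)
        a = parabolic_wall_shear(t, np.full(3, 2.0), 25.0, 1.5)
        b = parabolic_wall_shear(t, np.full(3, 2.0 * 8.0), 50.0, 1.5)
        assert np.allclose(a.shear_rate, b.shear_rate, rtol=1e-12)

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            parabolic_wall_shear(np.arange(2.0), np.ones(2), -1.0, 1.5)


class TestShearTrace:
    def test_stress_rate_consistency(self):
        tr = ShearTrace(np.arange(4.0), np.array([1.0, 2.0, np.nan, 4.0]),
                        viscosity=1.5, method="one_phase")
        ok = ~np.isnan(tr.shear_rate)
        assert np.allclose(tr.shear_stress[ok],
                           1.5e-3 * tr.shear_rate[ok], rtol=1e-15)

    def test_aggregates_recomputable(self):
        rate = np.abs(np.sin(np.linspace(0, 2 * np.pi, 50)))
        tr = ShearTrace(np.arange(50.0), rate, 1.5, "one_phase")
        assert tr.max_rate == pytest.approx(np.nanmax(rate))
        assert tr.p95_rate == pytest.approx(np.nanpercentile(rate, 95))


class TestPostprocess:
    def test_zero_halfwidth_identity(self):
        rate = np.arange(10.0)
        tr = ShearTrace(np.arange(10.0) * 0.1, rate, 1.5, "one_phase")
        out = postprocess_trace(tr, envelope_halfwidth=0)
        assert np.array_equal(out.smoothed_rate, rate)

    def test_constant_trace_aggregates(self):
        tr = ShearTrace(np.arange(10.0), np.full(10, 3.0), 1.5, "x")
        out = postprocess_trace(tr, envelope_halfwidth=2)
        assert out.max_rate == pytest.approx(3.0)
        assert out.p95_rate == pytest.approx(3.0)

    def test_impulse_response(self):
        rate = np.zeros(12)
        rate[5] = 5.0
        tr = ShearTrace(np.arange(12.0), rate, 1.5, "x")
        out = postprocess_trace(tr, envelope_halfwidth=2)
        expected = np.zeros(12)
        expected[3:8] = 1.0
        assert np.allclose(out.smoothed_rate, expected, atol=1e-15)
        assert out.smoothed_rate.sum() == pytest.approx(5.0, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e3), min_size=5, max_size=60),
           st.integers(0, 5))
    def test_periodic_smoothing_conserves_mean(self, values, halfwidth):
        rate = np.asarray(values)
        tr = ShearTrace(np.arange(rate.size, dtype=float), rate, 1.5, "x")
        out = postprocess_trace(tr, envelope_halfwidth=halfwidth)
        assert out.smoothed_rate.mean() == pytest.approx(
            rate.mean(), rel=1e-9, abs=1e-9)

    def test_alignment_shifts_event(self):
        rate = np.zeros(10)
        rate[2] = 1.0
        tr = ShearTrace(np.arange(10.0) * 0.01, rate, 1.5, "x")
        out = postprocess_trace(tr, align_at=0.05, event_time=0.02,
                                envelope_halfwidth=0)
        assert out.shear_rate[5] == 1.0


class TestCompareTraces:
    def _trace(self, mu, scale=1.0):
        rate = scale * np.abs(np.sin(np.linspace(0, 2 * np.pi, 40)))
        return ShearTrace(np.arange(40.0), rate, mu, "x")

    def test_self_comparison_unity(self):
        a = self._trace(1.5)
        c = compare_traces(a, a)
        assert c.max_stress_ratio == 1.0
        assert c.p95_stress_ratio == 1.0

    def test_halved_trace(self):
        c = compare_traces(self._trace(1.5), self._trace(1.5, scale=0.5))
        assert c.max_stress_ratio == pytest.approx(2.0, rel=1e-12)

    def test_viscosity_fold_change(self):
        # identical kinematics, viscosities mu and mu/3 -> stress ratio 3,
        # shear-rate ratio 1
        c = compare_traces(self._trace(1.5), self._trace(0.5))
        assert c.max_stress_ratio == pytest.approx(3.0, rel=1e-12)
        assert c.max_rate_ratio == pytest.approx(1.0, rel=1e-12)

    def test_zero_denominator_guarded(self):
        a = self._trace(1.5)
        zero = ShearTrace(np.arange(40.0), np.zeros(40), 1.5, "x")
        c = compare_traces(a, zero)
        assert math.isnan(c.max_stress_ratio)
        assert np.all(np.isnan(c.pointwise_stress_ratio))


class TestVolumeFromSlices:
    def test_disk_summation(self):
        # two 100x100 μm squares, 2 μm apart: 2e4 μm2 * 2 μm = 4e4 μm3
        sq = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float)
        v = volume_from_slices([sq, sq], slice_spacing_um=2.0)
        assert v == pytest.approx(4e4 * 1e-6, rel=1e-12)


def test_wall_geometry_validation():
    with pytest.raises(ValueError, match="increasing"):
        WallGeometry(times=[0.0, 0.0],
                     contours=[[np.zeros((3, 2))], [np.zeros((3, 2))]])
    with pytest.raises(ValueError, match="vertices"):
        WallGeometry(times=[0.0], contours=[[np.zeros((1, 2))]])


def test_volume_trace_validation():
    with pytest.raises(ValueError, match="positive"):
        VolumeTrace([0.0, 1.0, 2.0], [1.0, -1.0, 1.0])
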