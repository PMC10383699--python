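"""Signal-processing building blocks: filtering, calculus, IMU handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from vbtval import (
    FilterSpec,
    IMUStream,
    LoadVelocityParams,
    UniformSeries,
    barbell_point_at_offset,
    differentiate,
    generate_rep_profile,
    integrate_with_zvu,
    interpolate_gaps,
    lowpass,
    resultant_speed,
    world_vertical_accel,
)


def series(values, dt=0.005, t0=0.0):
    return UniformSeries(t0, dt, np.asarray(values, dtype=float))


class TestInterpolateGaps:
    def test_no_gaps_identity(self):
        s = series(np.sin(np.linspace(0, 1, 100)))
        out, spans = interpolate_gaps(s)
        assert spans == []
        assert np.array_equal(out.values, s.values)

    def test_single_missing_sample_on_ramp_is_linear_midpoint(self):
        vals = np.linspace(0.0, 1.0, 101)
        vals[50] = np.nan
        out, spans = interpolate_gaps(series(vals))
        assert spans == []
        assert out.values[50] == pytest.approx(0.5, abs=1e-12)

    def test_long_gap_is_flagged_not_trusted(self):
        vals = np.sin(np.linspace(0, 5, 400))
        vals[100:200] = np.nan  # 0.5 s at 200 Hz
        out, spans = interpolate_gaps(series(vals), max_gap=0.1)
        assert len(spans) == 1
        (a, b), = spans
        assert a == pytest.approx(100 * 0.005)
        assert b == pytest.approx(199 * 0.005)
        assert not np.isnan(out.values).any()

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            interpolate_gaps(series([np.nan] * 10))


class TestLowpass:
    def test_dc_gain_unity(self):
        s = series(np.full(400, 3.7))
        out = lowpass(s, FilterSpec(cutoff_hz=10.0))
        assert np.max(np.abs(out.values - 3.7)) < 1e-9

    def test_passband_tone_preserved(self):
        t = np.arange(0, 5, 0.005)
        s = series(np.sin(2 * np.pi * 1.0 * t))
        out = lowpass(s, FilterSpec(cutoff_hz=10.0, order=4))
        mid = slice(200, -200)
        assert np.max(np.abs(out.values[mid])) == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated(self):
        t = np.arange(0, 5, 0.005)
        s = series(np.sin(2 * np.pi * 45.0 * t))
        out = lowpass(s, FilterSpec(cutoff_hz=10.0, order=4))
        assert np.max(np.abs(out.values[200:-200])) < 0.01

    def test_idempotent_below_cutoff(self):
        t = np.arange(0, 5, 0.005)
        s = series(np.sin(2 * np.pi * 2.0 * t))
        once = lowpass(s, FilterSpec(cutoff_hz=10.0))
        twice = lowpass(once, FilterSpec(cutoff_hz=10.0))
        a1 = np.max(np.abs(once.values[200:-200]))
        a2 = np.max(np.abs(twice.values[200:-200]))
        assert abs(a2 - a1) / a1 < 0.001

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(series(np.zeros(100)), FilterSpec(cutoff_hz=150.0))


class TestBarbellPoint:
    def test_collinear_interpolation(self):
        left = series(np.tile([0.0, 0.0, 1.0], (10, 1)))
        right = series(np.tile([2.2, 0.0, 1.0], (10, 1)))
        p = barbell_point_at_offset(left, right, 0.6)
        assert np.allclose(p.values, [0.6, 0.0, 1.0])

    def test_tilted_bar_height(self):
        left = series(np.tile([0.0, 0.0, 1.0], (5, 1)))
        right = series(np.tile([2.2, 0.0, 1.1], (5, 1)))
        p = barbell_point_at_offset(left, right, 0.6)
        sep = np.sqrt(2.2**2 + 0.1**2)
        assert p.values[0, 2] == pytest.approx(1.0 + 0.6 / sep * 0.1, abs=1e-9)

    def test_zero_offset_returns_left_marker(self):
        left = series(np.random.default_rng(0).normal(size=(20, 3)))
        right = left.with_values(left.values + [1.0, 0.0, 0.0])
        p = barbell_point_at_offset(left, right, 0.0)
        assert np.allclose(p.values, left.values, atol=1e-12)

    def test_coincident_markers_rejected(self):
        left = series(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            barbell_point_at_offset(left, left, 0.6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(offset=st.floats(0.0, 2.2), z=st.floats(-0.5, 0.5))
    def test_marker_swap_symmetry(self, offset, z):
        """Swapping markers with the complementary offset gives the same point."""
        left = series(np.tile([0.0, 0.0, 1.0], (5, 1)))
        right = series(np.tile([2.2, 0.3, 1.0 + z], (5, 1)))
        sep = float(np.linalg.norm(right.values[0] - left.values[0]))
        p1 = barbell_point_at_offset(left, right, offset)
        p2 = barbell_point_at_offset(right, left, sep - offset)
        assert np.allclose(p1.values, p2.values, atol=1e-9)


class TestCalculus:
    def test_linear_position_gives_constant_velocity(self):
        t = np.arange(0, 1, 0.005)
        out = differentiate(series(t))
        assert np.allclose(out.values, 1.0, atol=1e-9)

    def test_sinusoid_derivative_within_truncation_bound(self):
        t = np.arange(0, 2, 0.005)
        out = differentiate(series(np.sin(2 * np.pi * t)))
        exact = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.max(np.abs(out.values[1:-1] - exact[1:-1])) < 1e-2

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            differentiate(series([1.0, 2.0]))

    def test_resultant_speed_345(self):
        v = series(np.tile([3.0, 4.0, 0.0], (4, 1)))
        assert np.allclose(resultant_speed(v).values, 5.0)
        assert np.allclose(resultant_speed(series(np.zeros((4, 3)))).values, 0.0)

    def test_resultant_speed_pure_vertical(self):
        vz = np.linspace(-2, 2, 50)
        v = series(np.column_stack([np.zeros(50), np.zeros(50), vz]))
        assert np.allclose(resultant_speed(v).values, np.abs(vz), atol=1e-12)


class TestWorldVerticalAccel:
    def test_rest_with_gravity_vector_is_zero(self):
        n = 50
        stream = IMUStream(0.0, 0.01, np.zeros((n, 3)),
                           gravity=np.tile([0.0, 0.0, -1.0], (n, 1)))
        out = world_vertical_accel(stream)
        assert np.allclose(out.values, 0.0)

    def test_rotated_device_with_attitude(self):
        """Device rotated 90 deg about x: device-frame (0, a, 0) is vertical."""
        n, a = 20, 2.5
        rot = Rotation.from_euler("x", 90, degrees=True)
        q = rot.as_quat()  # xyzw
        quat = np.tile([q[3], q[0], q[1], q[2]], (n, 1))
        stream = IMUStream(0.0, 0.01, np.tile([0.0, a, 0.0], (n, 1)), quat=quat)
        out = world_vertical_accel(stream)
        assert np.allclose(out.values, a, atol=1e-9)

    def test_missing_orientation_rejected(self):
        with pytest.raises(ValueError):
            world_vertical_accel(IMUStream(0.0, 0.01, np.zeros((5, 3))))


class TestZeroVelocityUpdates:
    def test_zero_acceleration_gives_zero_velocity(self):
        acc = series(np.zeros(1000))
        out = integrate_with_zvu(acc, [(0.0, 0.5), (4.0, 4.5)])
        assert np.allclose(out.values, 0.0)

    def test_constant_bias_removed_exactly(self):
        """A constant accelerometer bias integrates to a linear ramp, which the
        anchor-to-anchor detrend removes identically."""
        acc = series(np.full(2000, 0.1))
        out = integrate_with_zvu(acc, [(0.0, 0.5), (9.0, 9.5)])
        anchors = [out.index_at(0.25), out.index_at(9.25)]
        assert all(out.values[i] == 0.0 for i in anchors)
        assert np.max(np.abs(out.values)) < 1e-9

    def test_synthetic_rep_velocity_reconstruction(self, rng):
        """ZVU integration of the ground-truth acceleration recovers the
        ground-truth velocity."""
        rep = generate_rep_profile(65.0, LoadVelocityParams(sd=0.0), rng)
        dt = rep.time[1] - rep.time[0]
        acc = UniformSeries(0.0, dt, rep.acceleration)
        windows = [(0.05, 0.45), (rep.time[-1] - 0.6, rep.time[-1] - 0.1)]
        out = integrate_with_zvu(acc, windows)
        assert np.max(np.abs(out.values - rep.velocity)) < 1e-3

    def test_requires_stationary_windows(self):
        with pytest.raises(ValueError):
            integrate_with_zvu(series(np.zeros(100)), [])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_velocity_exactly_zero_at_anchors(self, seed):
        r = np.random.default_rng(seed)
        acc = series(r.normal(size=800))
        windows = [(0.2, 0.6), (1.5, 1.9), (3.0, 3.4)]
        out = integrate_with_zvu(acc, windows)
        for a, b in windows:
            assert out.values[out.index_at((a + b) / 2)] == 0.0
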