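"""From raw measurement streams to clean vertical barbell kinematics.

Two measurement pathways feed the pipeline:

* optical markers on both barbell ends -> interpolate dropouts, low-pass,
  locate the point of interest along the bar axis, differentiate to velocity
  (the 3-D speed magnitude is the validation criterion; the vertical
  component drives phase segmentation);
* a body- or bar-mounted IMU -> project the device-frame linear acceleration
  onto the world vertical, integrate to velocity with zero-velocity updates
  anchored on the inter-repetition pauses the lifting protocol enforces.

All series are in SI units, world z up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .series import FilterSpec, UniformSeries

GRAVITY = 9.81  # m/s^2


@dataclass
class IMUStream:
    """Inertial stream: device-frame linear acceleration plus orientation.

    Orientation is carried either as a per-sample gravity unit vector in the
    device frame (consumer devices expose this directly) or as a per-sample
    device->world attitude quaternion ``(w, x, y, z)``. At least one of the
    two must be present.
    """

    t0: float
    dt: float
    accel: np.ndarray = field(repr=False)  # (n, 3), m/s^2, gravity removed
    gravity: np.ndarray | None = field(default=None, repr=False)  # (n, 3) unit
    quat: np.ndarray | None = field(default=None, repr=False)  # (n, 4) wxyz

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be (n, 3)")
        for name in ("gravity", "quat"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.accel):
                    raise ValueError(f"{name} length mismatch with accel")
                setattr(self, name, v)

    @property
    def n(self) -> int:
        return len(self.accel)

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)


# ---------------------------------------------------------------------------
# gap handling
# ---------------------------------------------------------------------------

def interpolate_gaps(
    series: UniformSeries, max_gap: float = 0.1
) -> tuple[UniformSeries, list[tuple[float, float]]]:
    """Fill NaN gaps by cubic interpolation; flag gaps longer than ``max_gap``.

    Short gaps (``<= max_gap`` seconds) are filled with a natural cubic
    spline through the valid samples (which reproduces linear trends
    exactly).  Longer gaps are still filled so the series stays finite, but
    their time spans are returned so the enclosing repetitions can be marked
    unusable downstream.

    Returns
    -------
    (filled, flagged_spans)
        ``flagged_spans`` is a list of ``(t_start, t_end)`` intervals that
        must not be trusted.
    """
    vals = series.values
    missing = np.isnan(vals if vals.ndim == 1 else vals).reshape(series.n, -1).any(axis=1)
    if not missing.any():
        return series, []
    if missing.all():
        raise ValueError("series is entirely missing")

    t = series.times()
    valid = ~missing
    flat = vals.reshape(series.n, -1)
    filled = flat.copy()
    for k in range(flat.shape[1]):
        spline = CubicSpline(t[valid], flat[valid, k])
        filled[missing, k] = spline(t[missing])

    # locate contiguous missing runs; long runs are filled linearly instead
    # (a spline extrapolated across seconds swings wildly) and flagged
    flagged: list[tuple[float, float]] = []
    idx = np.flatnonzero(missing)
    run_start = idx[0]
    prev = idx[0]
    runs = []
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    for a, b in runs:
        length = (b - a + 1) * series.dt
        touches_edge = a == 0 or b == series.n - 1
        if length > max_gap or touches_edge:
            flagged.append((t[a], t[b]))
            for k in range(flat.shape[1]):
                filled[a : b + 1, k] = np.interp(
                    t[a : b + 1], t[valid], flat[valid, k]
                )
    filled = filled.reshape(vals.shape)
    return series.with_values(filled), flagged


# ---------------------------------------------------------------------------
# filtering and calculus
# ---------------------------------------------------------------------------

def lowpass(series: UniformSeries, spec: FilterSpec) -> UniformSeries:
    """Zero-phase (or causal) Butterworth low-pass."""
    spec.validate_for_rate(series.rate)
    sos = sp_signal.butter(spec.order, spec.cutoff_hz, btype="low",
                           fs=series.rate, output="sos")
    if spec.zero_phase:
        out = sp_signal.sosfiltfilt(sos, series.values, axis=0)
    else:
        out = sp_signal.sosfilt(sos, series.values, axis=0)
    return series.with_values(out)


def filter_smear(spec: FilterSpec, rate_hz: float) -> float:
    """RMS temporal width of the filter's impulse response, in seconds.

    Quantifies how far the (zero-phase) low-pass smears signal features
    outward; the segmentation uses it to compensate boundary estimates.
    """
    spec.validate_for_rate(rate_hz)
    n = max(int(4.0 * rate_hz / spec.cutoff_hz), 64)
    impulse = np.zeros(2 * n + 1)
    impulse[n] = 1.0
    sos = sp_signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate_hz,
                           output="sos")
    h = sp_signal.sosfiltfilt(sos, impulse) if spec.zero_phase else sp_signal.sosfilt(sos, impulse)
    t = (np.arange(len(h)) - n) / rate_hz
    h = h / h.sum()
    var = float(np.sum(h * (t - np.sum(h * t)) ** 2))
    return float(np.sqrt(max(var, 0.0)))


def differentiate(series: UniformSeries) -> UniformSeries:
    """Time derivative: central differences inside, one-sided at the edges."""
    if series.n < 3:
        raise ValueError("differentiation needs at least 3 samples")
    return series.with_values(np.gradient(series.values, series.dt, axis=0))


def integrate(series: UniformSeries, initial: float = 0.0) -> UniformSeries:
    """Cumulative trapezoidal integral (matches the O(h^2) differentiation)."""
    from scipy.integrate import cumulative_trapezoid

    out = cumulative_trapezoid(series.values, dx=series.dt, axis=0, initial=0.0)
    return series.with_values(out + initial)


def barbell_point_at_offset(
    left: UniformSeries, right: UniformSeries, offset: float = 0.60
) -> UniformSeries:
    """Point at ``offset`` metres from the left marker along the bar axis.

    ``P = L + (offset / |R - L|) * (R - L)``; the default 0.60 m matches a
    sensor mounted next to the lifter's left hand.
    """
    if left.n != right.n or abs(left.t0 - right.t0) > 1e-12 or abs(left.dt - right.dt) > 1e-15:
        raise ValueError("marker trajectories must share the same time base")
    axis = right.values - left.values
    sep = np.linalg.norm(axis, axis=1)
    if np.any(sep <= 1e-9):
        raise ValueError("coincident markers: bar axis undefined at some sample")
    point = left.values + (offset / sep)[:, None] * axis
    return left.with_values(point)


def resultant_speed(vel3d: UniformSeries) -> UniformSeries:
    """Euclidean norm per sample — the criterion velocity magnitude."""
    return vel3d.with_values(np.linalg.norm(vel3d.values, axis=1))


# ---------------------------------------------------------------------------
# IMU pathway
# ---------------------------------------------------------------------------

def world_vertical_accel(imu: IMUStream) -> UniformSeries:
    """Project device-frame linear acceleration onto the world vertical (up +).

    Uses the attitude quaternion when present, otherwise the gravity unit
    vector: with ``g_hat`` pointing along gravity (down), the upward linear
    acceleration is ``-a . g_hat``.
    """
    if imu.quat is not None:
        rot = Rotation.from_quat(imu.quat[:, [1, 2, 3, 0]])  # wxyz -> xyzw
        world = rot.apply(imu.accel)
        vertical = world[:, 2]
    elif imu.gravity is not None:
        g = imu.gravity
        norm = np.linalg.norm(g, axis=1)
        if np.any(norm <= 0):
            raise ValueError("gravity vector has zero norm at some sample")
        vertical = -np.einsum("ij,ij->i", imu.accel, g / norm[:, None])
    else:
        raise ValueError("IMU stream carries neither gravity vector nor attitude quaternion")
    return UniformSeries(imu.t0, imu.dt, vertical)


def detect_stationary_windows(
    accel: UniformSeries,
    window: float = 0.3,
    threshold: float = 0.2,
) -> list[tuple[float, float]]:
    """Intervals where the smoothed |acceleration| stays below ``threshold``.

    A sliding boxcar of ``window`` seconds smooths the magnitude first; runs
    shorter than ``window`` are discarded.  The lifting protocol's deliberate
    inter-repetition pauses guarantee such windows exist between movements.
    """
    mag = np.abs(accel.values)
    w = max(int(round(window / accel.dt)), 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(mag, kernel, mode="same")
    quiet = smooth < threshold
    spans: list[tuple[float, float]] = []
    t = accel.times()
    i = 0
    n = accel.n
    while i < n:
        if quiet[i]:
            j = i
            while j + 1 < n and quiet[j + 1]:
                j += 1
            if (j - i + 1) >= w:
                spans.append((t[i], t[j]))
            i = j + 1
        else:
            i += 1
    return spans


def integrate_with_zvu(
    accel: UniformSeries,
    stationary_windows: list[tuple[float, float]] | None = None,
) -> UniformSeries:
    """Acceleration -> velocity with zero-velocity updates.

    Trapezoidal integration, then the velocity is clamped to zero throughout
    every stationary window (the lifter is standing still there) and the
    drift implied by the window-edge residuals is removed by piecewise-linear
    detrending between windows.  A constant accelerometer bias integrates to
    a linear ramp, so it is removed exactly; the velocity is exactly zero at
    the midpoint sample of every stationary window for every input.
    """
    if stationary_windows is None:
        stationary_windows = detect_stationary_windows(accel)
    if not stationary_windows:
        raise ValueError("no stationary windows available for zero-velocity updates")

    vel = integrate(accel)
    t = vel.times()
    knots_i: list[int] = []
    window_spans: list[tuple[int, int]] = []
    for ta, tb in sorted(stationary_windows):
        mid = 0.5 * (ta + tb)
        if mid < t[0] - 1e-9 or mid > t[-1] + 1e-9:
            raise ValueError(f"stationary anchor {mid:.3f}s outside series range")
        ia, ib = vel.index_at(ta), vel.index_at(tb)
        window_spans.append((ia, ib))
        knots_i.extend((ia, vel.index_at(mid), ib))
    knots_i = sorted(set(knots_i))
    knot_t = t[knots_i]
    residual = vel.values[knots_i]
    drift = np.interp(t, knot_t, residual)
    # extend the first/last drift slope beyond the end windows, so e.g. a
    # constant bias is removed identically over the whole record
    if len(knots_i) >= 2:
        s0 = (residual[1] - residual[0]) / max(knot_t[1] - knot_t[0], vel.dt)
        s1 = (residual[-1] - residual[-2]) / max(knot_t[-1] - knot_t[-2], vel.dt)
        before = t < knot_t[0]
        after = t > knot_t[-1]
        drift[before] = residual[0] + s0 * (t[before] - knot_t[0])
        drift[after] = residual[-1] + s1 * (t[after] - knot_t[-1])
    corrected = vel.values - drift
    for ia, ib in window_spans:
        corrected[ia : ib + 1] = 0.0  # stationary by definition
    return vel.with_values(corrected)
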