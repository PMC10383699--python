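"""Concentric-phase detection and per-repetition velocity parameters.

A repetition's concentric (upward) phase starts when the vertical velocity
leaves the zero band after the bottom position and ends when it returns to
zero at lockout.  Three velocity parameters are derived per repetition:

* ``vmean`` — time-average velocity over the whole concentric phase;
* ``vpeak`` — maximum instantaneous velocity in the phase;
* ``vprop`` — time-average over the propulsive portion only, which ends the
  first time the acceleration drops below −1 g (the braking portion, where
  the bar decelerates faster than free fall, is excluded).  At heavy loads
  the braking criterion never binds and ``vprop`` equals ``vmean``.

Candidates with a range of motion below a minimum threshold (default 0.3 m)
are discarded: this suppresses "ghost repetitions" caused by re-racking the
barbell.  Repetitions are classed into a fast/slow velocity spectrum by
concentric duration at 1.25 s (durations at or above the threshold count as
slow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import GRAVITY
from .series import UniformSeries

FAST = "fast"
SLOW = "slow"


@dataclass(frozen=True)
class SegmentationConfig:
    min_rom: float = 0.30            # m, ghost-suppression threshold
    eps: float = 0.02                # m/s, velocity zero band
    prop_accel_threshold: float = -GRAVITY  # m/s^2, propulsive-phase end
    duration_threshold: float = 1.25  # s, fast/slow boundary
    onset_floor: float = 0.0         # m/s, velocity treated as zero in refinement
    boundary_smear: float = 0.0      # s, RMS width of the smoothing kernel
    min_samples: int = 5

    def __post_init__(self) -> None:
        if self.min_rom <= 0:
            raise ValueError("min_rom must be positive")
        if self.eps <= 0:
            raise ValueError("zero band must be positive")
        if self.duration_threshold <= 0:
            raise ValueError("duration threshold must be positive")


@dataclass
class RepSegment:
    """One detected concentric ascent."""

    t_start: float
    t_end_con: float
    rom: float
    i_start: int = 0
    i_end: int = 0
    t_end_prop: float | None = None  # filled by compute_metrics

    @property
    def duration(self) -> float:
        return self.t_end_con - self.t_start


@dataclass
class RepMetrics:
    vmean: float
    vpeak: float
    vprop: float
    duration: float
    spectrum: str
    valid: bool
    prop_criterion_bound: bool = False
    segment: RepSegment | None = field(default=None, repr=False)


def _noise_floor(v: np.ndarray, dt: float, base_floor: float) -> float:
    """Velocity noise level from the initial rest period, as a refinement floor.

    Recordings start with the lifter standing still, so the velocity over
    the first second (skipping filter start-up) is pure measurement noise;
    a median-absolute-deviation estimate of it sets the refinement floor at
    three noise standard deviations, keeping the boundary walk out of
    pauses where the velocity is indistinguishable from zero.  In clean
    data the floor collapses to ``base_floor``.
    """
    a = int(round(0.2 / dt))
    b = int(round(1.2 / dt))
    seg = v[a:b] if b <= len(v) and (b - a) >= 8 else v
    sigma = 1.4826 * float(np.median(np.abs(seg - np.median(seg))))
    return max(base_floor, 3.0 * sigma)


def _refine_onset(v: np.ndarray, i: int, floor: float, max_steps: int) -> int:
    """Walk back from an eps-crossing toward the underlying zero crossing.

    Moves left while the velocity stays above ``floor`` (still part of the
    ascent); ``max_steps`` bounds the walk so a drifting baseline cannot
    drag the boundary away.
    """
    stop = max(i - max_steps, 0)
    while i > stop and v[i - 1] > floor:
        i -= 1
    return i


def _refine_end(v: np.ndarray, i: int, floor: float, max_steps: int) -> int:
    stop = min(i + max_steps, len(v) - 1)
    while i < stop and v[i + 1] > floor:
        i += 1
    return i


def _extrapolate_zero(t_arr: np.ndarray, v_arr: np.ndarray,
                      fallback: float, limit: float, smear: float = 0.0) -> float:
    """Zero-crossing time of a rise that is locally ~ c (t - t0)^2.

    sqrt(v) is then linear in t, so a weighted least-squares line through
    ``sqrt(v_arr)`` vs ``t_arr`` crosses zero at t0; using every sample
    between the noise floor and the lever level averages the measurement
    noise down.  A symmetric smoothing kernel of RMS width ``smear`` turns
    the foot into c[(t - t0)^2 + smear^2], pulling the fitted crossing
    outward by ~ smear^2 * mean(1/(t - t0)) / 2; that known shift is
    compensated.  Falls back to ``fallback`` when the geometry is
    degenerate and never moves further than ``limit`` from it.
    """
    m = v_arr > 0
    if m.sum() < 2:
        return fallback
    t_arr, s = t_arr[m], np.sqrt(v_arr[m])
    beta, alpha = np.polyfit(t_arr, s, 1, w=s)
    if beta <= 0:
        return fallback
    t0 = -alpha / beta
    if smear > 0:
        u = t_arr - t0
        u = u[u > smear]
        if u.size:
            t0 += 0.5 * smear * smear * float(np.mean(1.0 / u))
    return float(np.clip(t0, fallback - limit, fallback))


def _local_baseline(v: np.ndarray, idx: int, direction: int, dt: float,
                    eps: float) -> float:
    """Quiet-level velocity just outside a candidate ascent.

    Median over ~0.35 s of the adjacent pause (bottom pause before the
    onset, standing pause after lockout); it absorbs baseline plateaus such
    as residual inter-anchor drift of the inertial pathway.  Clamped to
    +/- 2 eps so a pathological window cannot derail the boundary walk.
    """
    w = max(int(round(0.4 / dt)), 6)
    g = max(int(round(0.05 / dt)), 1)
    n = len(v)
    if direction < 0:
        a, b = max(idx - w, 0), max(idx - g, 1)
    else:
        a, b = min(idx + g, n - 2), min(idx + w, n - 1)
    baseline = float(np.median(v[a:b])) if b > a else 0.0
    return float(np.clip(baseline, -2 * eps, 2 * eps))


def segment_reps(
    vertical_pos: UniformSeries,
    vertical_vel: UniformSeries,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> list[RepSegment]:
    """Detect concentric ascents on a shared position/velocity time base.

    Candidate phases are contiguous runs where the velocity exceeds the zero
    band ``eps``; boundaries are then refined toward the true zero crossings,
    and candidates whose range of motion falls short of ``min_rom`` are
    dropped.  Segments come out disjoint and time-ordered.
    """
    if vertical_pos.n != vertical_vel.n or abs(vertical_pos.t0 - vertical_vel.t0) > 1e-9:
        raise ValueError("position and velocity must share a time base")
    if vertical_vel.n < cfg.min_samples:
        raise ValueError("series shorter than one detection window")

    v = vertical_vel.values
    p = vertical_pos.values
    t = vertical_vel.times()
    floor = _noise_floor(v, vertical_vel.dt, cfg.onset_floor)
    above = v > max(cfg.eps, 1.5 * floor)

    segments: list[RepSegment] = []
    n = len(v)
    i = 0
    last_end = -1
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        dt = vertical_vel.dt
        max_steps = int(round(0.5 / dt))
        # each boundary walks down to the local quiet baseline plus the
        # noise floor, so neither a baseline plateau (inertial drift between
        # anchors) nor pause noise can drag the boundary away
        b0 = _local_baseline(v, i, -1, dt, cfg.eps)
        b1 = _local_baseline(v, j, +1, dt, cfg.eps)
        thr0 = b0 + max(floor, 1e-4)
        thr1 = b1 + max(floor, 1e-4)
        i0 = max(_refine_onset(v, i, thr0, max_steps), last_end + 1)
        i1 = _refine_end(v, j, thr1, max_steps)
        if (i1 - i0 + 1) >= cfg.min_samples:
            rom = float(p[i1] - p[i0])
            if rom >= cfg.min_rom:
                if floor <= 0.005:
                    # clean data: the walk reaches the baseline crossing
                    # itself; interpolate it between the last two samples
                    t_start = float(t[i0])
                    if i0 > 0 and v[i0] > v[i0 - 1] and v[i0 - 1] <= thr0:
                        frac = (thr0 - v[i0 - 1]) / (v[i0] - v[i0 - 1])
                        t_start = float(t[i0 - 1] + frac * dt)
                    t_end = float(t[i1])
                    if i1 < n - 1 and v[i1] > v[i1 + 1] and v[i1 + 1] <= thr1:
                        frac = (v[i1] - thr1) / (v[i1] - v[i1 + 1])
                        t_end = float(t[i1] + frac * dt)
                else:
                    # noisy data: the walk stops at the floor level; project
                    # the locally quadratic, baseline-subtracted velocity
                    # foot back to its zero
                    lever0 = b0 + max(2 * cfg.eps, 4 * (thr0 - b0))
                    k2 = i0
                    while k2 < j and v[k2] < lever0:
                        k2 += 1
                    t_start = _extrapolate_zero(
                        t[i0 : k2 + 1], v[i0 : k2 + 1] - b0,
                        fallback=float(t[i0]), limit=0.15,
                        smear=cfg.boundary_smear,
                    )
                    lever1 = b1 + max(2 * cfg.eps, 4 * (thr1 - b1))
                    k3 = i1
                    while k3 > i and v[k3] < lever1:
                        k3 -= 1
                    t_end = -_extrapolate_zero(
                        -t[k3 : i1 + 1][::-1], v[k3 : i1 + 1][::-1] - b1,
                        fallback=-float(t[i1]), limit=0.15,
                        smear=cfg.boundary_smear,
                    )
                segments.append(
                    RepSegment(
                        t_start=t_start,
                        t_end_con=t_end,
                        rom=rom,
                        i_start=i0,
                        i_end=i1,
                    )
                )
                last_end = i1
        i = j + 1
    return segments


def compute_metrics(
    seg: RepSegment,
    vel: UniformSeries,
    accel: UniformSeries,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> RepMetrics:
    """Derive (vmean, vpeak, vprop, duration, spectrum, validity) for a segment.

    ``vmean`` averages velocity over [t_start, t_end_con]; ``vprop`` averages
    over [t_start, t_end_prop], where ``t_end_prop`` is the first time the
    acceleration drops below the −1 g braking threshold — or the concentric
    end if it never does, in which case ``vprop`` falls back to ``vmean``.
    """
    i0, i1 = seg.i_start, seg.i_end
    if i1 - i0 < 2:
        raise ValueError("degenerate segment window (< 3 samples)")
    if i1 >= vel.n or i1 >= accel.n:
        raise ValueError("segment outside series bounds")
    v = vel.values[i0 : i1 + 1]
    a = accel.values[i0 : i1 + 1]
    dt = vel.dt
    t_grid0 = vel.t0 + i0 * dt
    t_grid1 = vel.t0 + i1 * dt

    # integral over the grid window plus the sub-sample boundary tails
    tail0 = 0.5 * v[0] * (t_grid0 - seg.t_start)
    tail1 = 0.5 * v[-1] * (seg.t_end_con - t_grid1)
    duration = seg.duration
    vmean = float((np.trapezoid(v, dx=dt) + tail0 + tail1) / duration)
    vpeak = float(np.max(v))

    below = np.flatnonzero(a < cfg.prop_accel_threshold)
    if below.size and below[0] >= 2:
        ip = int(below[0])
        # sub-sample crossing of the braking threshold
        frac = float((a[ip - 1] - cfg.prop_accel_threshold) / (a[ip - 1] - a[ip]))
        frac = min(max(frac, 0.0), 1.0)
        t_end_prop = t_grid0 + (ip - 1 + frac) * dt
        v_at = v[ip - 1] + frac * (v[ip] - v[ip - 1])
        area = (
            np.trapezoid(v[:ip], dx=dt)
            + 0.5 * (v[ip - 1] + v_at) * frac * dt
            + tail0
        )
        vprop = float(area / (t_end_prop - seg.t_start))
        bound = True
    else:
        t_end_prop = seg.t_end_con
        vprop = vmean
        bound = False
    seg.t_end_prop = t_end_prop

    return RepMetrics(
        vmean=vmean,
        vpeak=vpeak,
        vprop=vprop,
        duration=duration,
        spectrum=classify_spectrum(duration, cfg),
        valid=vpeak > vmean,
        prop_criterion_bound=bound,
        segment=seg,
    )


def classify_spectrum(duration: float, cfg: SegmentationConfig = SegmentationConfig()) -> str:
    """Fast/slow spectrum label: durations >= the threshold are slow."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return FAST if duration < cfg.duration_threshold else SLOW


def validity_check(m: RepMetrics) -> bool:
    """Plausibility gate: the peak velocity must strictly exceed the mean."""
    return m.vpeak > m.vmean
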