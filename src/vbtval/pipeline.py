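"""End-to-end orchestration: raw streams -> metrics -> pairs -> validity report.

The criterion pathway processes the optical markers (gap interpolation,
zero-phase low-pass, point of interest at 0.60 m along the bar, numerical
differentiation); device pathways either integrate an inertial stream with
zero-velocity updates or read a black-box per-rep export.  Repetitions are
segmented per modality, grouped into sets by the long inter-set pauses,
paired by within-set order, filtered, and fed to the three-tier agreement
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import (
    IMUStream,
    barbell_point_at_offset,
    differentiate,
    filter_smear,
    integrate,
    integrate_with_zvu,
    interpolate_gaps,
    lowpass,
    resultant_speed,
    world_vertical_accel,
)
from .pairing import (
    ExclusionRecord,
    RepPair,
    accounting_table,
    apply_validity_filter,
    expand_pairs,
    pair_by_order,
)
from .segmentation import (
    RepMetrics,
    RepSegment,
    SegmentationConfig,
    compute_metrics,
    segment_reps,
)
from .series import FilterSpec, UniformSeries
from .stats import three_tier_report
from .synthetic import SyntheticSession

MARKER_FILTER = FilterSpec(cutoff_hz=10.0)
ACCEL_FILTER = FilterSpec(cutoff_hz=15.0)
SET_GAP = 4.0  # s between concentric ends that separates sets
POINT_OFFSET = 0.60  # m from the left bar end


@dataclass
class Signals:
    """Clean vertical kinematics of one modality on a single time base."""

    pos: UniformSeries
    vel: UniformSeries      # vertical velocity (segmentation)
    speed: UniformSeries    # velocity magnitude (criterion parameter source)
    accel: UniformSeries
    flagged_spans: list[tuple[float, float]] = field(default_factory=list)
    smear: float = 0.0      # s, RMS width of the low-pass impulse response


def process_markers(
    left: UniformSeries,
    right: UniformSeries,
    offset: float = POINT_OFFSET,
    filter_spec: FilterSpec = MARKER_FILTER,
    max_gap: float = 0.1,
) -> Signals:
    """Optical pathway: markers -> point of interest -> velocity/acceleration."""
    left, spans_l = interpolate_gaps(left, max_gap)
    right, spans_r = interpolate_gaps(right, max_gap)
    point = barbell_point_at_offset(left, right, offset)
    point = lowpass(point, filter_spec)
    vel3d = differentiate(point)
    accel = differentiate(vel3d.component(2))
    return Signals(
        pos=point.component(2),
        vel=vel3d.component(2),
        speed=resultant_speed(vel3d),
        accel=accel,
        flagged_spans=sorted(spans_l + spans_r),
        smear=filter_smear(filter_spec, point.rate),
    )


def process_imu(
    stream: IMUStream,
    filter_spec: FilterSpec = ACCEL_FILTER,
    max_gap: float = 0.1,
    stationary_windows: list[tuple[float, float]] | None = None,
) -> Signals:
    """Inertial pathway: vertical projection -> ZVU integration -> position."""
    raw = world_vertical_accel(stream)
    raw, spans = interpolate_gaps(raw, max_gap) if np.isnan(raw.values).any() else (raw, [])
    accel = lowpass(raw, filter_spec)
    vel = integrate_with_zvu(accel, stationary_windows)
    pos = integrate(vel)
    return Signals(pos=pos, vel=vel, speed=vel.with_values(np.abs(vel.values)),
                   accel=accel, flagged_spans=spans,
                   smear=filter_smear(filter_spec, raw.rate))


def metrics_from_signals(
    signals: Signals,
    cfg: SegmentationConfig = SegmentationConfig(),
    drop_flagged: bool = True,
) -> list[RepMetrics]:
    """Segment one modality and compute per-repetition metrics.

    Segments overlapping a flagged (untrusted) gap span are discarded; the
    pairing stage re-inserts them as connection-issue placeholders.
    """
    if cfg.boundary_smear == 0.0 and signals.smear > 0.0:
        cfg = replace(cfg, boundary_smear=signals.smear)
    segments = segment_reps(signals.pos, signals.vel, cfg)
    out = []
    for seg in segments:
        if drop_flagged and _overlaps(seg, signals.flagged_spans):
            continue
        out.append(compute_metrics(seg, signals.vel, signals.accel, cfg))
    return out


def _overlaps(seg: RepSegment, spans: list[tuple[float, float]]) -> bool:
    return any(seg.t_start <= b and seg.t_end_con >= a for a, b in spans)


# ---------------------------------------------------------------------------
# set grouping and device assignment
# ---------------------------------------------------------------------------

def group_into_sets(metrics: list[RepMetrics], set_gap: float = SET_GAP) -> list[list[RepMetrics]]:
    """Split a time-ordered repetition list into sets at long quiet gaps."""
    sets: list[list[RepMetrics]] = []
    current: list[RepMetrics] = []
    last_end = None
    for m in metrics:
        start = m.segment.t_start
        if last_end is not None and start - last_end > set_gap:
            sets.append(current)
            current = []
        current.append(m)
        last_end = m.segment.t_end_con
    if current:
        sets.append(current)
    return sets


def _set_windows(criterion_sets: list[list[RepMetrics]]) -> list[tuple[float, float]]:
    windows = []
    for s in criterion_sets:
        t0 = s[0].segment.t_start - SET_GAP / 2
        t1 = s[-1].segment.t_end_con + SET_GAP / 2
        windows.append((t0, t1))
    return windows


def assign_stream_device_sets(
    device_metrics: list[RepMetrics],
    device_spans: list[tuple[float, float]],
    criterion_sets: list[list[RepMetrics]],
    set_ids: list[str],
) -> dict[str, list[RepMetrics | None]]:
    """Arrange stream-device repetitions into the criterion's set structure.

    Device repetitions are binned into the criterion set time windows (sets
    are separated by long pauses, so coarse clock agreement suffices);
    criterion repetitions falling inside a flagged device gap produce a
    ``None`` placeholder, which pairing turns into a connection-issue
    exclusion.
    """
    windows = _set_windows(criterion_sets)
    binned: list[list[RepMetrics]] = [[] for _ in windows]
    for m in device_metrics:
        for k, (t0, t1) in enumerate(windows):
            if t0 <= m.segment.t_start <= t1:
                binned[k].append(m)
                break
    out: dict[str, list[RepMetrics | None]] = {}
    for k, (crit_set, dev_list) in enumerate(zip(criterion_sets, binned)):
        slots: list[RepMetrics | None] = []
        dev_iter = iter(dev_list)
        pending = list(dev_list)
        for cm in crit_set:
            gap_hit = any(
                cm.segment.t_start <= b and cm.segment.t_end_con >= a
                for a, b in device_spans
            )
            if gap_hit:
                slots.append(None)
            elif pending:
                slots.append(pending.pop(0))
            else:
                slots.append(None)
        # surplus device segments make the count mismatch visible downstream
        slots.extend(pending)
        out[set_ids[k]] = slots
    return out


def blackbox_metrics(df: pd.DataFrame) -> dict[str, list[RepMetrics]]:
    """Turn export rows into per-set metric lists (duration unknown)."""
    out: dict[str, list[RepMetrics]] = {}
    for set_id, sub in df.groupby("set_id", sort=False):
        reps = []
        for _, row in sub.sort_values("rep_index").iterrows():
            reps.append(
                RepMetrics(
                    vmean=float(row["vmean"]),
                    vpeak=float(row["vpeak"]),
                    vprop=float(row["vprop"]),
                    duration=float("nan"),
                    spectrum="",
                    valid=float(row["vpeak"]) > float(row["vmean"]),
                )
            )
        out[str(set_id)] = reps
    return out


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    pairs: list[RepPair]
    exclusions: list[ExclusionRecord]
    accounting: pd.DataFrame
    report: pd.DataFrame
    metrics: pd.DataFrame  # per-rep metrics of every modality


def metrics_table(per_device: dict[str, dict[str, list[RepMetrics | None]]]) -> pd.DataFrame:
    rows = []
    for device, sets in per_device.items():
        for set_id, reps in sets.items():
            for i, m in enumerate(reps):
                if m is None:
                    continue
                rows.append(
                    {
                        "set_id": set_id,
                        "rep_index": i,
                        "device": device,
                        "vmean": m.vmean,
                        "vpeak": m.vpeak,
                        "vprop": m.vprop,
                        "duration": m.duration,
                        "spectrum": m.spectrum,
                        "valid": m.valid,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["set_id", "rep_index", "device", "vmean", "vpeak", "vprop",
                 "duration", "spectrum", "valid"],
    )


def analyze_session(
    session: SyntheticSession,
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    alpha: float = 0.05,
    residuals: str = "vertical",
    devices: tuple[str, ...] = ("barbell_imu", "wrist_imu", "blackbox"),
) -> ValidationResult:
    """Run the whole validation analysis on a synthetic session in memory."""
    left = UniformSeries(0.0, session.dt, session.marker_left)
    right = UniformSeries(0.0, session.dt, session.marker_right)
    criterion = process_markers(left, right)
    crit_metrics = metrics_from_signals(criterion, seg_cfg)
    crit_sets = group_into_sets(crit_metrics)
    set_ids = session.set_ids
    if len(crit_sets) != len(set_ids):
        # fall back to ordinal ids if the criterion found a different set count
        set_ids = [f"S{k:02d}" for k in range(len(crit_sets))]
    crit_by_set = {sid: s for sid, s in zip(set_ids, crit_sets)}

    all_pairs: list[RepPair] = []
    all_excl: list[ExclusionRecord] = []
    per_device: dict[str, dict[str, list[RepMetrics | None]]] = {
        "criterion": crit_by_set
    }

    for device in devices:
        if device in ("barbell_imu", "wrist_imu"):
            stream = session.imu_barbell if device == "barbell_imu" else session.imu_wrist
            signals = process_imu(stream)
            dev_metrics = metrics_from_signals(signals, seg_cfg)
            dev_sets = assign_stream_device_sets(
                dev_metrics, signals.flagged_spans, crit_sets, set_ids
            )
            pairs, excl = pair_by_order(dev_sets, crit_by_set, "stream", device)
        elif device == "blackbox":
            dev_sets_raw = blackbox_metrics(session.blackbox)
            # align export set ids with criterion sets by order of appearance
            export_ids = list(dev_sets_raw.keys())
            dev_sets = {
                sid: dev_sets_raw.get(exp_id, [])
                for sid, exp_id in zip(set_ids, export_ids)
            }
            dropout_log = [
                (sid, idx)
                for sid, exp_id in zip(set_ids, export_ids)
                for s, idx in session.dropout_log
                if s == exp_id
            ]
            pairs, excl = pair_by_order(
                dev_sets, crit_by_set, "blackbox", device, dropout_log=dropout_log
            )
        else:
            raise ValueError(f"unknown device {device!r}")
        per_device[device] = dev_sets if device != "blackbox" else dev_sets
        pairs, vexcl = apply_validity_filter(pairs)
        all_pairs.extend(pairs)
        all_excl.extend(excl + vexcl)

    observations = expand_pairs(all_pairs)
    report = three_tier_report(observations, alpha=alpha, residuals=residuals)
    accounting = accounting_table(all_pairs, all_excl, devices=list(devices))
    return ValidationResult(
        pairs=all_pairs,
        exclusions=all_excl,
        accounting=accounting,
        report=report,
        metrics=metrics_table(per_device),
    )
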