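"""Synthetic squat-session generator: ground truth plus every measurement modality.

The generator emulates a velocity-based-training testing session: a
load–velocity profile block (several loads, a few maximal-intent repetitions
each), a single-repetition maximum attempt, and a set to exhaustion, with
deliberate stationary pauses between repetitions.  Each repetition is a
smooth eccentric–pause–concentric vertical trajectory built from raised
half-cosine velocity lobes:

* eccentric descent: one full raised-cosine lobe (downward);
* concentric ascent: a rising half-lobe (75 % of the phase) followed by a
  steeper braking half-lobe (25 %).  Mean concentric velocity is exactly
  ``ROM / duration`` and peak velocity exactly twice the mean.  For light
  (fast) loads the braking deceleration exceeds 1 g, so the propulsive
  phase ends strictly before the concentric phase; at heavy loads the
  criterion never binds and propulsive velocity equals mean velocity.
  All phase integrals are closed-form, so per-repetition ground truth
  (Vmean, Vpeak, Vprop, duration, ROM) is analytic.

From the ground-truth motion the generator derives every observation mode:
optical markers on both barbell ends (position noise, optional dropouts),
barbell- and wrist-mounted inertial streams (device frame, constant bias,
white noise; the wrist adds low-frequency arm-swing interference), and a
"black-box" commercial device that exports only per-repetition velocities
with its own error model (multiplicative error, occasional duplicated or
missed repetitions, plausibility failures).  Re-rack "ghost" movements with
a small range of motion can be injected between sets; every injected
artifact is recorded in a manifest so downstream accounting can be checked
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.spatial.transform import Rotation

from .kinematics import GRAVITY, IMUStream

RISE_FRACTION = 0.75  # concentric rise fraction; the rest is braking


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class LoadVelocityParams(BaseModel):
    """Linear athlete load–velocity profile in %1RM.

    Mean concentric velocity interpolates linearly between ``v_at_45`` (at
    45 %1RM) and ``v_at_100`` (at 100 %1RM); ``sd`` is the between-repetition
    variability added on top.
    """

    v_at_45: float = 1.0
    v_at_100: float = 0.3
    sd: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "LoadVelocityParams":
        if not (self.v_at_45 > self.v_at_100 > 0):
            raise ValueError("load-velocity profile requires v_at_45 > v_at_100 > 0")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        return self

    def velocity_at(self, load_pct: float) -> float:
        slope = (self.v_at_100 - self.v_at_45) / 55.0
        return max(self.v_at_45 + slope * (load_pct - 45.0), 0.12)


class NoiseModel(BaseModel):
    marker_sd: float = 0.0005          # m
    accel_sd: float = 0.02             # m/s^2 white noise
    accel_bias_range: float = 0.05     # m/s^2, constant bias ~ U(-range, range)
    wrist_interference_amp: float = 0.3  # m/s^2, 1-3 Hz arm-swing artifact
    orientation_sd: float = 0.002      # gravity-vector jitter


class DropoutModel(BaseModel):
    """Per-repetition connectivity-loss probability per modality."""

    markers: float = 0.0
    barbell_imu: float = Field(default=0.03, ge=0, le=1)
    wrist_imu: float = Field(default=0.08, ge=0, le=1)
    blackbox: float = Field(default=0.06, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "DropoutModel":
        for name in ("markers", "barbell_imu", "wrist_imu", "blackbox"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"dropout probability {name} must be in [0, 1]")
        return self


class BlackboxErrorModel(BaseModel):
    """Error model of the per-rep-export commercial device."""

    mult_sd: float = 0.03              # multiplicative error N(1, sd)
    additive_sd: float = 0.0           # m/s
    miscount_probability: float = Field(default=0.05, ge=0, le=1)  # per set
    validity_fail_probability: float = Field(default=0.03, ge=0, le=1)  # per rep
    slow_underestimate: float = 0.0    # fractional shrink of slow reps


class SessionConfig(BaseModel):
    """Full parameterization of one synthetic testing session."""

    loads: list[float] = [45.0, 55.0, 65.0, 75.0, 85.0]
    reps_per_load: int = 3
    include_1rm_attempt: bool = True
    exhaustion_set_load: float = 80.0
    exhaustion_reps: int = 6
    exhaustion_decline: float = 0.08   # fractional velocity loss per rep
    lv_params: LoadVelocityParams = LoadVelocityParams()
    mocap_rate: float = 200.0
    imu_rate: float = 100.0
    noise: NoiseModel = NoiseModel()
    dropout: DropoutModel = DropoutModel()
    blackbox: BlackboxErrorModel = BlackboxErrorModel()
    ghost_count: int = 25
    rom_range: tuple[float, float] = (0.45, 0.70)
    bar_height: float = 1.45           # standing bar height, m
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SessionConfig":
        if self.mocap_rate <= 0 or self.imu_rate <= 0:
            raise ValueError("sampling rates must be positive")
        for load in self.loads + [self.exhaustion_set_load]:
            if not 0 < load <= 100:
                raise ValueError("loads must lie in (0, 100] %1RM")
        if self.reps_per_load < 1 or self.exhaustion_reps < 0 or self.ghost_count < 0:
            raise ValueError("counts must be non-negative")
        if not 0 < self.rom_range[0] <= self.rom_range[1]:
            raise ValueError("invalid ROM range")
        return self


# ---------------------------------------------------------------------------
# analytic piecewise motion
# ---------------------------------------------------------------------------

@dataclass
class _Seg:
    t0: float
    d: float
    kind: str           # pause | rise | fall | lobe
    amp: float          # peak velocity of the piece (signed for lobe)
    p0: float           # absolute position at piece start


class PiecewiseMotion:
    """Vertical motion assembled from closed-form velocity pieces.

    ``rise``/``fall`` are half raised-cosine lobes (0 -> amp, amp -> 0);
    ``lobe`` is a full raised cosine (0 -> amp -> 0), used for the eccentric
    descent with negative amplitude.  Position, velocity and acceleration
    are exact at any time, so sampling never accumulates error.
    """

    def __init__(self, start_height: float = 0.0) -> None:
        self.segments: list[_Seg] = []
        self.t = 0.0
        self.p = start_height

    def add_pause(self, d: float) -> None:
        self.segments.append(_Seg(self.t, d, "pause", 0.0, self.p))
        self.t += d

    def add_rise(self, amp: float, d: float) -> None:
        self.segments.append(_Seg(self.t, d, "rise", amp, self.p))
        self.t += d
        self.p += amp * d / 2.0

    def add_fall(self, amp: float, d: float) -> None:
        self.segments.append(_Seg(self.t, d, "fall", amp, self.p))
        self.t += d
        self.p += amp * d / 2.0

    def add_lobe(self, amp: float, d: float) -> None:
        self.segments.append(_Seg(self.t, d, "lobe", amp, self.p))
        self.t += d
        self.p += amp * d / 2.0

    def sample(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact (position, velocity, acceleration) at the given times."""
        times = np.asarray(times, dtype=float)
        pos = np.full_like(times, self.p)
        vel = np.zeros_like(times)
        acc = np.zeros_like(times)
        starts = np.array([s.t0 for s in self.segments])
        idx = np.searchsorted(starts, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        for k, seg in enumerate(self.segments):
            m = idx == k
            if not m.any():
                continue
            tau = times[m] - seg.t0
            tau = np.clip(tau, 0.0, seg.d)
            A, d = seg.amp, seg.d
            if seg.kind == "pause":
                v = np.zeros_like(tau)
                a = np.zeros_like(tau)
                dp = np.zeros_like(tau)
            elif seg.kind == "rise":
                v = A * 0.5 * (1.0 - np.cos(np.pi * tau / d))
                a = A * np.pi / (2 * d) * np.sin(np.pi * tau / d)
                dp = A * 0.5 * (tau - (d / np.pi) * np.sin(np.pi * tau / d))
            elif seg.kind == "fall":
                v = A * 0.5 * (1.0 + np.cos(np.pi * tau / d))
                a = -A * np.pi / (2 * d) * np.sin(np.pi * tau / d)
                dp = A * 0.5 * (tau + (d / np.pi) * np.sin(np.pi * tau / d))
            else:  # lobe
                v = A * 0.5 * (1.0 - np.cos(2 * np.pi * tau / d))
                a = A * np.pi / d * np.sin(2 * np.pi * tau / d)
                dp = A * 0.5 * (tau - (d / (2 * np.pi)) * np.sin(2 * np.pi * tau / d))
            vel[m] = v
            acc[m] = a
            pos[m] = seg.p0 + dp
        beyond = times >= self.t
        pos[beyond] = self.p
        vel[beyond] = 0.0
        acc[beyond] = 0.0
        return pos, vel, acc


def _trapezoid_consistent_accel(vel: np.ndarray, dt: float, a0: float = 0.0) -> np.ndarray:
    """Grid acceleration whose cumulative trapezoid reproduces ``vel`` exactly.

    Solves a_{k+1} = 2 (v_{k+1} - v_k) / dt - a_k, which makes the discrete
    ground truth self-consistent: integrating the returned acceleration with
    the trapezoid rule recovers the velocity to machine precision.  The
    construction deviates from the analytic acceleration only by an
    alternating O(dt^2) term.
    """
    d = 2.0 * np.diff(vel) / dt
    signs = np.where(np.arange(len(d)) % 2 == 0, -1.0, 1.0)  # (-1)^(j+1)
    cs = np.concatenate([[0.0], np.cumsum(signs * d)])
    parity = np.where(np.arange(len(vel)) % 2 == 0, 1.0, -1.0)
    return parity * (a0 + cs)


# ---------------------------------------------------------------------------
# ground truth records
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthRep:
    """One repetition's exact kinematics and derived velocity parameters."""

    set_id: str
    rep_index: int
    load_pct: float
    t_ecc_start: float
    t_con_start: float
    t_con_end: float
    true_t_end_prop: float
    rom: float
    true_vmean: float
    true_vpeak: float
    true_vprop: float
    true_duration: float
    prop_criterion_bound: bool
    # grid arrays covering the repetition plus surrounding pauses
    time: np.ndarray = field(default=None, repr=False)
    position: np.ndarray = field(default=None, repr=False)
    velocity: np.ndarray = field(default=None, repr=False)
    acceleration: np.ndarray = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "set_id": self.set_id,
            "rep_index": self.rep_index,
            "load_pct": self.load_pct,
            "t_ecc_start": self.t_ecc_start,
            "t_con_start": self.t_con_start,
            "t_con_end": self.t_con_end,
            "true_t_end_prop": self.true_t_end_prop,
            "rom": self.rom,
            "true_vmean": self.true_vmean,
            "true_vpeak": self.true_vpeak,
            "true_vprop": self.true_vprop,
            "true_duration": self.true_duration,
            "prop_criterion_bound": self.prop_criterion_bound,
        }


@dataclass
class ArtifactRecord:
    """Manifest entry for one injected artifact."""

    kind: str  # ghost_rep | connection_issue | miscount | validity_fail
    modality: str  # markers | barbell_imu | wrist_imu | blackbox | motion
    set_id: str
    rep_index: int | None = None
    t_start: float | None = None
    t_end: float | None = None
    rom: float | None = None
    detail: str = ""

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class SyntheticSession:
    """Ground truth plus all emulated measurement streams for one session."""

    config: SessionConfig
    dt: float
    time: np.ndarray = field(repr=False)
    position: np.ndarray = field(repr=False)
    velocity: np.ndarray = field(repr=False)
    acceleration: np.ndarray = field(repr=False)
    reps: list[GroundTruthRep] = field(default_factory=list)
    set_ids: list[str] = field(default_factory=list)
    marker_left: np.ndarray = field(default=None, repr=False)
    marker_right: np.ndarray = field(default=None, repr=False)
    imu_barbell: IMUStream | None = None
    imu_wrist: IMUStream | None = None
    blackbox: pd.DataFrame | None = None
    dropout_log: list[tuple[str, int]] = field(default_factory=list)
    manifest: list[ArtifactRecord] = field(default_factory=list)

    def reps_by_set(self) -> dict[str, list[GroundTruthRep]]:
        out: dict[str, list[GroundTruthRep]] = {s: [] for s in self.set_ids}
        for r in self.reps:
            out[r.set_id].append(r)
        return out

    def manifest_count(self, kind: str, modality: str | None = None) -> int:
        return sum(
            1
            for m in self.manifest
            if m.kind == kind and (modality is None or m.modality == modality)
        )


# ---------------------------------------------------------------------------
# repetition construction
# ---------------------------------------------------------------------------

def _concentric_truths(
    vmean: float, rom: float, t_con_start: float
) -> tuple[float, float, float, float, bool]:
    """Closed-form (duration, vpeak, vprop, t_end_prop, bound) of one ascent."""
    T = rom / vmean
    vpeak = 2.0 * vmean
    t_r = RISE_FRACTION * T
    t_f = T - t_r
    a_max = vpeak * np.pi / (2.0 * t_f)
    if a_max > GRAVITY:
        tau = (t_f / np.pi) * math.asin(2.0 * GRAVITY * t_f / (np.pi * vpeak))
        area = vpeak * t_r / 2.0 + vpeak * 0.5 * (
            tau + (t_f / np.pi) * math.sin(np.pi * tau / t_f)
        )
        vprop = area / (t_r + tau)
        return T, vpeak, vprop, t_con_start + t_r + tau, True
    return T, vpeak, vmean, t_con_start + T, False


def _add_rep(
    motion: PiecewiseMotion,
    set_id: str,
    rep_index: int,
    load_pct: float,
    vmean: float,
    rom: float,
    rng: np.random.Generator,
    pause_after: float,
) -> GroundTruthRep:
    """Append eccentric–pause–concentric–pause to the motion; return its truth."""
    t_ecc_start = motion.t
    t_ecc = float(rng.uniform(1.0, 1.4))
    motion.add_lobe(-2.0 * rom / t_ecc, t_ecc)          # descent
    motion.add_pause(float(rng.uniform(0.25, 0.45)))    # bottom pause
    t_con_start = motion.t
    T, vpeak, vprop, t_end_prop, bound = _concentric_truths(vmean, rom, t_con_start)
    motion.add_rise(vpeak, RISE_FRACTION * T)
    motion.add_fall(vpeak, T - RISE_FRACTION * T)
    t_con_end = motion.t
    motion.add_pause(pause_after)
    return GroundTruthRep(
        set_id=set_id,
        rep_index=rep_index,
        load_pct=load_pct,
        t_ecc_start=t_ecc_start,
        t_con_start=t_con_start,
        t_con_end=t_con_end,
        true_t_end_prop=t_end_prop,
        rom=rom,
        true_vmean=vmean,
        true_vpeak=vpeak,
        true_vprop=vprop,
        true_duration=T,
        prop_criterion_bound=bound,
    )


def generate_rep_profile(
    load_pct: float,
    lv: LoadVelocityParams,
    rng: np.random.Generator,
    rate: float = 200.0,
    rom: float | None = None,
) -> GroundTruthRep:
    """One standalone repetition at ``load_pct`` %1RM with grid arrays attached.

    The trajectory is lead-in pause, eccentric descent, bottom pause,
    concentric ascent, tail pause; velocity is exactly zero at both
    concentric endpoints and the mean concentric velocity follows the
    load–velocity profile plus its configured noise.
    """
    if not 0 < load_pct <= 110:
        raise ValueError(f"load must lie in (0, 110] %1RM, got {load_pct}")
    if rom is None:
        rom = float(rng.uniform(0.45, 0.70))
    vmean = lv.velocity_at(load_pct) + float(rng.normal(0.0, lv.sd)) if lv.sd else lv.velocity_at(load_pct)
    vmean = max(vmean, 0.12)
    motion = PiecewiseMotion(start_height=1.45)
    motion.add_pause(0.5)
    rep = _add_rep(motion, "single", 0, load_pct, vmean, rom, rng, pause_after=0.8)
    dt = 1.0 / rate
    t = np.arange(0.0, motion.t + dt / 2, dt)
    pos, vel, _ = motion.sample(t)
    acc = _trapezoid_consistent_accel(vel, dt)
    rep.time, rep.position, rep.velocity, rep.acceleration = t, pos, vel, acc
    return rep


# ---------------------------------------------------------------------------
# session construction
# ---------------------------------------------------------------------------

def _set_plan(config: SessionConfig, rng: np.random.Generator) -> list[tuple[str, list[tuple[float, float]]]]:
    """(set_id, [(load_pct, target_vmean), ...]) per set, in session order."""
    lv = config.lv_params
    plan: list[tuple[str, list[tuple[float, float]]]] = []

    def target(load: float) -> float:
        v = lv.velocity_at(load)
        if lv.sd:
            v += float(rng.normal(0.0, lv.sd))
        return max(v, 0.12)

    for load in config.loads:
        plan.append((f"L{load:g}", [(load, target(load)) for _ in range(config.reps_per_load)]))
    if config.include_1rm_attempt:
        plan.append(("RM", [(100.0, target(100.0))]))
    if config.exhaustion_reps:
        base = lv.velocity_at(config.exhaustion_set_load)
        reps = []
        for k in range(config.exhaustion_reps):
            v = base * (1.0 - config.exhaustion_decline * k)
            if lv.sd:
                v += float(rng.normal(0.0, lv.sd))
            reps.append((config.exhaustion_set_load, max(v, 0.12)))
        plan.append(("EXH", reps))
    return plan


@dataclass
class _Ghost:
    set_id: str
    t_start: float
    t_end: float
    rom: float
    vmean: float


def _add_ghost(motion: PiecewiseMotion, set_id: str, rng: np.random.Generator) -> _Ghost:
    """A re-rack movement: small, slow up–down excursion (ROM < 0.3 m)."""
    rom = float(rng.uniform(0.08, 0.25))
    T = float(rng.uniform(1.4, 1.8))
    vpeak = 2.0 * rom / T
    t_start = motion.t
    motion.add_rise(vpeak, T / 2)
    motion.add_fall(vpeak, T / 2)
    t_end = motion.t
    motion.add_pause(float(rng.uniform(0.5, 0.8)))
    motion.add_lobe(-vpeak, T)  # lower it back
    motion.add_pause(float(rng.uniform(0.4, 0.7)))
    return _Ghost(set_id, t_start, t_end, rom, rom / T)


def _make_imu_stream(
    motion: PiecewiseMotion,
    duration: float,
    rate: float,
    noise: NoiseModel,
    rng: np.random.Generator,
    interference_amp: float = 0.0,
) -> IMUStream:
    dt = 1.0 / rate
    t = np.arange(0.0, duration + dt / 2, dt)
    _, v_true, a_vert = motion.sample(t)
    world = np.zeros((len(t), 3))
    world[:, 2] = a_vert
    if interference_amp > 0:
        # arm-swing artifact: present only while the lifter is moving, so the
        # inter-rep pauses stay usable as zero-velocity anchors
        f = float(rng.uniform(1.0, 3.0))
        phase = float(rng.uniform(0.0, 2 * np.pi))
        envelope = np.clip(np.abs(v_true) / 0.2, 0.0, 1.0)
        world[:, 2] += envelope * interference_amp * np.sin(2 * np.pi * f * t + phase)
        world[:, 0] += envelope * 0.5 * interference_amp * np.sin(2 * np.pi * f * t + phase + 1.0)
    rot = Rotation.from_quat(rng.normal(size=4))  # uniform-ish fixed attitude
    device = rot.inv().apply(world)
    device += rng.uniform(-noise.accel_bias_range, noise.accel_bias_range, size=3)
    device += rng.normal(0.0, noise.accel_sd, size=device.shape)
    g_dev = rot.inv().apply(np.array([0.0, 0.0, -1.0]))
    gravity = np.tile(g_dev, (len(t), 1))
    gravity += rng.normal(0.0, noise.orientation_sd, size=gravity.shape)
    gravity /= np.linalg.norm(gravity, axis=1, keepdims=True)
    return IMUStream(t0=0.0, dt=dt, accel=device, gravity=gravity)


def _blackbox_export(
    reps_by_set: dict[str, list[GroundTruthRep]],
    ghosts: list[_Ghost],
    err: BlackboxErrorModel,
    rng: np.random.Generator,
    duration_threshold: float = 1.25,
) -> tuple[pd.DataFrame, list[ArtifactRecord]]:
    manifest: list[ArtifactRecord] = []
    rows: list[dict] = []
    ghosts_by_set: dict[str, list[_Ghost]] = {}
    for g in ghosts:
        ghosts_by_set.setdefault(g.set_id, []).append(g)

    def noisy(value: float) -> float:
        v = value * float(rng.normal(1.0, err.mult_sd))
        if err.additive_sd:
            v += float(rng.normal(0.0, err.additive_sd))
        return max(v, 0.01)

    for set_id, reps in reps_by_set.items():
        set_rows: list[dict] = []
        for rep in reps:
            shrink = 1.0
            if err.slow_underestimate and rep.true_duration >= duration_threshold:
                shrink = 1.0 - err.slow_underestimate
            row = {
                "set_id": set_id,
                "vmean": noisy(rep.true_vmean * shrink),
                "vpeak": noisy(rep.true_vpeak * shrink),
                "vprop": noisy(rep.true_vprop * shrink),
            }
            if rng.uniform() < err.validity_fail_probability:
                row["vpeak"] = row["vmean"] * float(rng.uniform(0.7, 0.95))
                manifest.append(
                    ArtifactRecord(
                        kind="validity_fail", modality="blackbox",
                        set_id=set_id, rep_index=rep.rep_index,
                    )
                )
            set_rows.append(row)
        if set_rows and rng.uniform() < err.miscount_probability:
            k = int(rng.integers(len(set_rows)))
            if rng.uniform() < 0.5:
                set_rows.insert(k + 1, dict(set_rows[k]))
                detail = "duplicate"
            else:
                set_rows.pop(k)
                detail = "missed"
            manifest.append(
                ArtifactRecord(
                    kind="miscount", modality="blackbox",
                    set_id=set_id, rep_index=k, detail=detail,
                )
            )
        for g in ghosts_by_set.get(set_id, []):
            set_rows.append(
                {
                    "set_id": set_id,
                    "vmean": noisy(g.vmean),
                    "vpeak": noisy(2.0 * g.vmean),
                    "vprop": noisy(g.vmean),
                }
            )
        for i, row in enumerate(set_rows):
            row["rep_index"] = i
        rows.extend(set_rows)
    df = pd.DataFrame(rows, columns=["set_id", "rep_index", "vmean", "vpeak", "vprop"])
    return df, manifest


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Build a full synthetic session: ground truth and all modalities.

    Identical configurations (including the seed) produce bit-identical
    sessions after serialization.
    """
    rng = np.random.default_rng(config.seed)
    plan = _set_plan(config, rng)

    motion = PiecewiseMotion(start_height=config.bar_height)
    motion.add_pause(2.0)
    reps: list[GroundTruthRep] = []
    ghosts: list[_Ghost] = []
    set_ids = [sid for sid, _ in plan]

    # pre-draw ghost placement: each ghost lands in the re-rack window
    # after a uniformly chosen set
    ghost_sets = [set_ids[int(rng.integers(len(set_ids)))] for _ in range(config.ghost_count)]

    for sid, rep_specs in plan:
        for k, (load, vmean) in enumerate(rep_specs):
            rom = float(rng.uniform(*config.rom_range))
            pause = float(rng.uniform(1.0, 1.5))
            reps.append(_add_rep(motion, sid, k, load, vmean, rom, rng, pause))
        motion.add_pause(float(rng.uniform(1.5, 2.5)))
        for g_sid in [s for s in ghost_sets if s == sid]:
            ghosts.append(_add_ghost(motion, g_sid, rng))
        motion.add_pause(float(rng.uniform(1.5, 2.5)))
    motion.add_pause(1.5)

    dt = 1.0 / config.mocap_rate
    t = np.arange(0.0, motion.t + dt / 2, dt)
    pos, vel, _ = motion.sample(t)
    acc = _trapezoid_consistent_accel(vel, dt)

    # attach per-rep grid windows (views into the session arrays)
    for rep in reps:
        i0 = max(int((rep.t_ecc_start - 0.5) / dt), 0)
        i1 = min(int((rep.t_con_end + 0.5) / dt) + 1, len(t))
        rep.time = t[i0:i1]
        rep.position = pos[i0:i1]
        rep.velocity = vel[i0:i1]
        rep.acceleration = acc[i0:i1]

    # optical markers: bar ends at x = 0 and 2.2 m, sharing the bar height
    n = len(t)
    left = np.column_stack([np.zeros(n), np.zeros(n), pos])
    right = np.column_stack([np.full(n, 2.2), np.zeros(n), pos])
    left = left + rng.normal(0.0, config.noise.marker_sd, size=left.shape)
    right = right + rng.normal(0.0, config.noise.marker_sd, size=right.shape)

    imu_barbell = _make_imu_stream(motion, t[-1], config.imu_rate, config.noise, rng)
    imu_wrist = _make_imu_stream(
        motion, t[-1], config.imu_rate, config.noise, rng,
        interference_amp=config.noise.wrist_interference_amp,
    )

    reps_by_set: dict[str, list[GroundTruthRep]] = {sid: [] for sid in set_ids}
    for rep in reps:
        reps_by_set[rep.set_id].append(rep)
    blackbox, bb_manifest = _blackbox_export(reps_by_set, ghosts, config.blackbox, rng)

    manifest = [
        ArtifactRecord(
            kind="ghost_rep", modality="motion", set_id=g.set_id,
            t_start=g.t_start, t_end=g.t_end, rom=g.rom,
        )
        for g in ghosts
    ] + bb_manifest

    session = SyntheticSession(
        config=config,
        dt=dt,
        time=t,
        position=pos,
        velocity=vel,
        acceleration=acc,
        reps=reps,
        set_ids=set_ids,
        marker_left=left,
        marker_right=right,
        imu_barbell=imu_barbell,
        imu_wrist=imu_wrist,
        blackbox=blackbox,
        manifest=manifest,
    )
    if any(
        p > 0
        for p in (
            config.dropout.markers,
            config.dropout.barbell_imu,
            config.dropout.wrist_imu,
            config.dropout.blackbox,
        )
    ):
        session = inject_connectivity_gaps(session, config.dropout, rng)
    return session


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_connectivity_gaps(
    session: SyntheticSession,
    probabilities: DropoutModel | dict[str, float],
    rng: np.random.Generator,
) -> SyntheticSession:
    """Wipe whole repetitions from chosen modalities to emulate lost packets.

    For stream modalities the samples spanning the repetition (eccentric
    start to concentric end, with a small margin) are blanked to NaN; for
    the black-box export the repetition's row is deleted and logged in the
    device's dropout log.  Every wipe is recorded in the manifest with
    reason ``connection_issue``.
    """
    if isinstance(probabilities, dict):
        probabilities = DropoutModel(**probabilities)

    margin = 0.1
    t = session.time

    def wipe_span(arr: np.ndarray, t0: float, t1: float, times: np.ndarray) -> None:
        m = (times >= t0) & (times <= t1)
        arr[m] = np.nan

    for rep in session.reps:
        t0, t1 = rep.t_ecc_start - margin, rep.t_con_end + margin
        if rng.uniform() < probabilities.markers:
            wipe_span(session.marker_left, t0, t1, t)
            wipe_span(session.marker_right, t0, t1, t)
            session.manifest.append(
                ArtifactRecord("connection_issue", "markers", rep.set_id,
                               rep.rep_index, t0, t1)
            )
        if session.imu_barbell is not None and rng.uniform() < probabilities.barbell_imu:
            wipe_span(session.imu_barbell.accel, t0, t1, session.imu_barbell.times())
            session.manifest.append(
                ArtifactRecord("connection_issue", "barbell_imu", rep.set_id,
                               rep.rep_index, t0, t1)
            )
        if session.imu_wrist is not None and rng.uniform() < probabilities.wrist_imu:
            wipe_span(session.imu_wrist.accel, t0, t1, session.imu_wrist.times())
            session.manifest.append(
                ArtifactRecord("connection_issue", "wrist_imu", rep.set_id,
                               rep.rep_index, t0, t1)
            )
        if session.blackbox is not None and rng.uniform() < probabilities.blackbox:
            df = session.blackbox
            mask = (df["set_id"] == rep.set_id) & (df["rep_index"] == rep.rep_index)
            if mask.any():
                session.blackbox = df[~mask].reset_index(drop=True)
                session.dropout_log.append((rep.set_id, rep.rep_index))
                session.manifest.append(
                    ArtifactRecord("connection_issue", "blackbox", rep.set_id,
                                   rep.rep_index)
                )
    return session


def inject_validity_failures(
    blackbox: pd.DataFrame, count: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[ArtifactRecord]]:
    """Force ``count`` export rows to fail the Vpeak > Vmean plausibility check."""
    df = blackbox.copy()
    idx = rng.choice(len(df), size=count, replace=False)
    records = []
    for i in sorted(int(j) for j in idx):
        df.loc[df.index[i], "vpeak"] = df.iloc[i]["vmean"] * float(rng.uniform(0.7, 0.95))
        records.append(
            ArtifactRecord(
                kind="validity_fail", modality="blackbox",
                set_id=str(df.iloc[i]["set_id"]),
                rep_index=int(df.iloc[i]["rep_index"]),
            )
        )
    return df, records
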