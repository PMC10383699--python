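"""Readers and writers for the plain-text measurement formats.

* marker file: CSV with columns ``time_s, lx, ly, lz, rx, ry, rz`` (metres);
  dropouts are empty fields;
* IMU file: CSV with ``time_s, ax, ay, az`` (m/s^2, device frame) plus either
  ``gx, gy, gz`` (gravity unit vector in the device frame) or
  ``qw, qx, qy, qz`` (device->world attitude quaternion);
* black-box export: CSV with ``set_id, rep_index, vmean, vpeak, vprop`` (m/s);
* ground truth and artifact manifest: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import IMUStream
from .series import UniformSeries
from .synthetic import SyntheticSession

_FLOAT_FMT = "%.9g"


def _uniform_dt(times: np.ndarray, path: Path) -> float:
    diffs = np.diff(times)
    dt = float(np.median(diffs))
    if dt <= 0 or np.any(np.abs(diffs - dt) > 1e-6):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return dt


# -- markers ----------------------------------------------------------------

def write_markers(session: SyntheticSession, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": session.time,
            "lx": session.marker_left[:, 0],
            "ly": session.marker_left[:, 1],
            "lz": session.marker_left[:, 2],
            "rx": session.marker_right[:, 0],
            "ry": session.marker_right[:, 1],
            "rz": session.marker_right[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_markers(path: str | Path) -> tuple[UniformSeries, UniformSeries]:
    path = Path(path)
    df = pd.read_csv(path)
    required = ["time_s", "lx", "ly", "lz", "rx", "ry", "rz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing marker columns {missing}")
    t = df["time_s"].to_numpy(float)
    dt = _uniform_dt(t, path)
    left = UniformSeries(float(t[0]), dt, df[["lx", "ly", "lz"]].to_numpy(float))
    right = UniformSeries(float(t[0]), dt, df[["rx", "ry", "rz"]].to_numpy(float))
    return left, right


# -- IMU --------------------------------------------------------------------

def write_imu(stream: IMUStream, path: str | Path) -> None:
    data = {
        "time_s": stream.times(),
        "ax": stream.accel[:, 0],
        "ay": stream.accel[:, 1],
        "az": stream.accel[:, 2],
    }
    if stream.gravity is not None:
        data.update(gx=stream.gravity[:, 0], gy=stream.gravity[:, 1], gz=stream.gravity[:, 2])
    if stream.quat is not None:
        data.update(
            qw=stream.quat[:, 0], qx=stream.quat[:, 1],
            qy=stream.quat[:, 2], qz=stream.quat[:, 3],
        )
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_imu(path: str | Path) -> IMUStream:
    path = Path(path)
    df = pd.read_csv(path)
    for c in ("time_s", "ax", "ay", "az"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing IMU column {c!r}")
    t = df["time_s"].to_numpy(float)
    dt = _uniform_dt(t, path)
    accel = df[["ax", "ay", "az"]].to_numpy(float)
    gravity = quat = None
    if {"gx", "gy", "gz"}.issubset(df.columns):
        gravity = df[["gx", "gy", "gz"]].to_numpy(float)
    if {"qw", "qx", "qy", "qz"}.issubset(df.columns):
        quat = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
    if gravity is None and quat is None:
        raise ValueError(
            f"{path}: needs gravity columns (gx, gy, gz) or attitude "
            "quaternion columns (qw, qx, qy, qz)"
        )
    return IMUStream(t0=float(t[0]), dt=dt, accel=accel, gravity=gravity, quat=quat)


# -- black-box export -------------------------------------------------------

def write_blackbox(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_blackbox(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = ["set_id", "rep_index", "vmean", "vpeak", "vprop"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing export columns {missing}")
    return df


# -- ground truth and manifest ---------------------------------------------

def write_ground_truth(session: SyntheticSession, path: str | Path) -> None:
    payload = {
        "set_ids": session.set_ids,
        "dt": session.dt,
        "reps": [rep.summary() for rep in session.reps],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_manifest(session: SyntheticSession, path: str | Path) -> None:
    payload = {
        "artifacts": [m.as_dict() for m in session.manifest],
        "dropout_log": [list(x) for x in session.dropout_log],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_session(session: SyntheticSession, out_dir: str | Path) -> dict[str, Path]:
    """Write the six session files; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": out / "markers.csv",
        "imu_barbell": out / "imu_barbell.csv",
        "imu_wrist": out / "imu_wrist.csv",
        "blackbox": out / "blackbox.csv",
        "ground_truth": out / "ground_truth.json",
        "manifest": out / "manifest.json",
    }
    write_markers(session, paths["markers"])
    write_imu(session.imu_barbell, paths["imu_barbell"])
    write_imu(session.imu_wrist, paths["imu_wrist"])
    write_blackbox(session.blackbox, paths["blackbox"])
    write_ground_truth(session, paths["ground_truth"])
    write_manifest(session, paths["manifest"])
    return paths
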