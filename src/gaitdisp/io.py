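"""CSV interchange for recordings, traces, quaternions and events.

Schemas
-------
IMU:        time_s, gyro_x, gyro_y, gyro_z, acc_x, acc_y, acc_z
            (rad/s and m/s²; a ``# gyro_units: deg/s`` comment line converts)
Trace3D:    ``# quantity: <name>`` comment, then time_s, ml, vt, ap
Quaternion: time_s, qw, qx, qy, qz
Events:     index, time_s, source
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImuRecording, QuaternionSeries, Trace3D
from .segmentation import StrideSegmentation

_IMU_COLUMNS = ["time_s", "gyro_x", "gyro_y", "gyro_z", "acc_x", "acc_y", "acc_z"]
_GRID_REL_TOL = 1e-6


def _read_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, value = line[1:].split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def _infer_sampling_rate(time: np.ndarray) -> float:
    dt = np.diff(time)
    step = np.median(dt)
    if np.any(np.abs(dt - step) > _GRID_REL_TOL * max(step, 1e-9)):
        raise ValueError("time grid is not uniform")
    return 1.0 / step


def load_imu_csv(path: str | Path, site: str = "lower_trunk") -> ImuRecording:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path.name}: {missing}")
    time = df["time_s"].to_numpy()
    gyro = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy()
    if meta.get("gyro_units", "rad/s") == "deg/s":
        gyro = np.deg2rad(gyro)
    fs = _infer_sampling_rate(time)
    # rebuild the grid so float round-trips stay exact
    time = time[0] + np.arange(len(time)) / fs
    return ImuRecording(
        time=time, gyro=gyro,
        specific_force=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
        sampling_rate=fs, site=meta.get("site", site),
    )


def save_imu_csv(path: str | Path, imu: ImuRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([imu.time, imu.gyro, imu.specific_force]),
        columns=_IMU_COLUMNS,
    )
    with open(path, "w") as fh:
        fh.write(f"# site: {imu.site}\n# gyro_units: rad/s\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def load_trace_csv(path: str | Path) -> Trace3D:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "ml", "vt", "ap"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path.name}")
    return Trace3D(
        time=df["time_s"].to_numpy(), ml=df["ml"].to_numpy(),
        vt=df["vt"].to_numpy(), ap=df["ap"].to_numpy(),
        quantity=meta.get("quantity", "displacement"),
    )


def save_trace_csv(path: str | Path, trace: Trace3D) -> None:
    df = pd.DataFrame(
        {"time_s": trace.time, "ml": trace.ml, "vt": trace.vt, "ap": trace.ap}
    )
    with open(path, "w") as fh:
        fh.write(f"# quantity: {trace.quantity}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def load_quaternion_csv(path: str | Path) -> QuaternionSeries:
    df = pd.read_csv(path, comment="#")
    return QuaternionSeries(
        time=df["time_s"].to_numpy(),
        q=df[["qw", "qx", "qy", "qz"]].to_numpy(),
    )


def save_quaternion_csv(path: str | Path, quats: QuaternionSeries) -> None:
    pd.DataFrame(
        np.column_stack([quats.time, quats.q]),
        columns=["time_s", "qw", "qx", "qy", "qz"],
    ).to_csv(path, index=False, float_format="%.12g")


def save_events_csv(path: str | Path, seg: StrideSegmentation) -> None:
    pd.DataFrame(
        {"index": seg.heel_strike_indices, "time_s": seg.heel_strike_times,
         "source": seg.source}
    ).to_csv(path, index=False)


def load_events_csv(path: str | Path, time: np.ndarray) -> StrideSegmentation:
    df = pd.read_csv(path)
    source = str(df["source"].iloc[0]) if len(df) else "ground_truth"
    return StrideSegmentation(df["index"].to_numpy(dtype=int), time, source)
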