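"""Plain-text serialisation of sensor logs, surveys and trajectories.

Sensor logs are one CSV per sensor location with header
``t,ax,ay,az,gx,gy,gz[,mx,my,mz]`` in SI units; gate surveys are CSV
``gate_id,x,y,z`` in the Earth frame; trajectories are CSV
``t,x,y,z[,vx,vy,vz]``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anchors import AnchorSet
from .core import FRAME_EARTH, FRAME_SENSOR, InvalidInputError, TimeSeries3D
from .synthetic import SensorSet


def write_sensor_csv(path, accel: TimeSeries3D, gyro: TimeSeries3D,
                     mag: TimeSeries3D | None = None) -> None:
    df = pd.DataFrame({
        "t": accel.t,
        "ax": accel.values[:, 0], "ay": accel.values[:, 1], "az": accel.values[:, 2],
        "gx": gyro.values[:, 0], "gy": gyro.values[:, 1], "gz": gyro.values[:, 2],
    })
    if mag is not None:
        # magnetometer runs at a lower rate; pad with NaN on the IMU grid
        m = np.full((len(accel), 3), np.nan)
        idx = np.searchsorted(accel.t, mag.t)
        m[idx] = mag.values
        df[["mx", "my", "mz"]] = m
    df.to_csv(path, index=False, float_format="%.9g")


def read_sensor_csv(path) -> tuple[TimeSeries3D, TimeSeries3D, TimeSeries3D | None]:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    accel = TimeSeries3D(t, df[["ax", "ay", "az"]].to_numpy(), FRAME_SENSOR)
    gyro = TimeSeries3D(t, df[["gx", "gy", "gz"]].to_numpy(), FRAME_SENSOR)
    mag = None
    if "mx" in df.columns:
        mask = df["mx"].notna().to_numpy()
        mag = TimeSeries3D(t[mask], df.loc[mask, ["mx", "my", "mz"]].to_numpy(),
                           FRAME_SENSOR)
    return accel, gyro, mag


def write_sensor_set(directory, sensors: SensorSet) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in sensors.accel:
        mag = sensors.mag if name == "sacrum" else None
        write_sensor_csv(directory / f"{name}.csv", sensors.accel[name],
                         sensors.gyro[name], mag)


def read_sensor_set(directory) -> SensorSet:
    directory = Path(directory)
    accel, gyro, mag = {}, {}, None
    for path in sorted(directory.glob("*.csv")):
        a, g, m = read_sensor_csv(path)
        accel[path.stem] = a
        gyro[path.stem] = g
        if m is not None:
            mag = m
    if not accel:
        raise InvalidInputError(f"no sensor CSV files in {directory}")
    if mag is None:
        raise InvalidInputError("no magnetometer columns found (expected on sacrum)")
    return SensorSet(accel=accel, gyro=gyro, mag=mag, rate=accel["sacrum"].rate)


def write_gate_survey(path, anchors: AnchorSet) -> None:
    pd.DataFrame({
        "gate_id": anchors.gate_ids,
        "x": anchors.positions[:, 0],
        "y": anchors.positions[:, 1],
        "z": anchors.positions[:, 2],
    }).to_csv(path, index=False, float_format="%.6f")


def read_gate_survey(path) -> AnchorSet:
    df = pd.read_csv(path)
    return AnchorSet(df[["x", "y", "z"]].to_numpy(), df["gate_id"].to_numpy())


def write_trajectory(path, position: TimeSeries3D,
                     velocity: TimeSeries3D | None = None) -> None:
    df = pd.DataFrame({"t": position.t, "x": position.values[:, 0],
                       "y": position.values[:, 1], "z": position.values[:, 2]})
    if velocity is not None:
        df[["vx", "vy", "vz"]] = velocity.values
    df.to_csv(path, index=False, float_format="%.9g")


def read_trajectory(path) -> tuple[TimeSeries3D, TimeSeries3D | None]:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    pos = TimeSeries3D(t, df[["x", "y", "z"]].to_numpy(), FRAME_EARTH)
    vel = None
    if "vx" in df.columns:
        vel = TimeSeries3D(t, df[["vx", "vy", "vz"]].to_numpy(), FRAME_EARTH)
    return pos, vel


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
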