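"""Readers and writers for the pipeline's on-disk formats.

Frame stacks live in HDF5 (dataset ``rf``, transducer x frame x sample,
float32, with acquisition constants as attributes); 1-D traces, ground
truth, and gait events in CSV; models and configuration in JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .kinematics import AngleTrace, GaitEvents
from .simulate import GroundTruth, UltrasoundFrameSeries
from .torque import QuadraticTorqueModel, TorqueTrace
from .tracking import BoundaryTrace, ThicknessTrace

__all__ = [
    "write_frames",
    "read_frames",
    "write_ground_truth",
    "read_ground_truth",
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "save_model",
    "load_model",
]


def write_frames(path, series: UltrasoundFrameSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=series.data.astype(np.float32))
        f.attrs["sampling_frequency_hz"] = series.sampling_frequency
        f.attrs["frame_rate_hz"] = series.frame_rate
        f.attrs["speed_of_sound_m_s"] = series.speed_of_sound


def read_frames(path) -> UltrasoundFrameSeries:
    with h5py.File(path, "r") as f:
        data = f["rf"][...]
        fs = float(f.attrs["sampling_frequency_hz"])
        fr = float(f.attrs["frame_rate_hz"])
        c = float(f.attrs["speed_of_sound_m_s"])
    timestamps = np.arange(data.shape[1]) / fr
    return UltrasoundFrameSeries(data, fs, fr, c, timestamps)


def write_ground_truth(path, truth: GroundTruth, frame_rate: float) -> None:
    n = truth.n_frames
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(n),
        "time_s": np.arange(n) / frame_rate,
    }
    for b in range(truth.boundary_depths_mm.shape[0]):
        cols[f"depth_mm_boundary{b}"] = truth.boundary_depths_mm[b]
    if truth.thickness_mm.size:
        cols["thickness_mm"] = truth.thickness_mm
    if truth.angle_deg is not None:
        cols["angle_deg"] = truth.angle_deg
    if truth.torque_nm is not None:
        cols["torque_nm"] = truth.torque_nm
    pd.DataFrame(cols).to_csv(path, index=False)


def read_ground_truth(path) -> tuple[GroundTruth, float]:
    df = pd.read_csv(path)
    depth_cols = sorted(
        (c for c in df.columns if c.startswith("depth_mm_boundary")),
        key=lambda c: int(c.rsplit("boundary", 1)[1]),
    )
    depths = np.vstack([df[c].to_numpy() for c in depth_cols]) if depth_cols else np.empty((0, len(df)))
    truth = GroundTruth(
        boundary_depths_mm=depths,
        thickness_mm=df["thickness_mm"].to_numpy() if "thickness_mm" in df else np.empty(0),
        angle_deg=df["angle_deg"].to_numpy() if "angle_deg" in df else None,
        torque_nm=df["torque_nm"].to_numpy() if "torque_nm" in df else None,
    )
    dt = np.diff(df["time_s"].to_numpy())
    frame_rate = 1.0 / float(np.mean(dt)) if dt.size else 0.0
    return truth, frame_rate


_TRACE_COLUMNS = {
    BoundaryTrace: "depth_mm",
    ThicknessTrace: "thickness_mm",
    AngleTrace: "angle_deg",
    TorqueTrace: "torque_nm",
}


def write_trace(path, trace) -> None:
    """Write any 1-D trace as CSV ``frame,time_s,<value column>``."""
    for cls, col in _TRACE_COLUMNS.items():
        if isinstance(trace, cls):
            break
    else:
        raise TypeError(f"unsupported trace type {type(trace).__name__}")
    values = getattr(trace, col)
    fr = trace.frame_rate or 1.0
    n = len(values)
    pd.DataFrame(
        {"frame": np.arange(n), "time_s": np.arange(n) / fr, col: values}
    ).to_csv(path, index=False)


def read_trace(path):
    """Read a trace CSV back into the matching trace type."""
    df = pd.read_csv(path)
    dt = np.diff(df["time_s"].to_numpy())
    fr = 1.0 / float(np.mean(dt)) if dt.size else 1.0
    for cls, col in _TRACE_COLUMNS.items():
        if col in df.columns:
            values = df[col].to_numpy()
            if cls is BoundaryTrace:
                return BoundaryTrace(values, fr)
            if cls is ThicknessTrace:
                return ThicknessTrace(values, fr, superficial_depth_mm=0.0)
            if cls is AngleTrace:
                return AngleTrace(values, fr)
            return TorqueTrace(values, fr)
    raise ValueError(f"no recognised value column in {path}: {list(df.columns)}")


def write_events(path, events: GaitEvents, frame_rate: float) -> None:
    rows = [("heel_strike", int(i), i / frame_rate) for i in events.heel_strikes]
    rows += [("toe_off", int(i), i / frame_rate) for i in events.toe_offs]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["event", "frame", "time_s"]).to_csv(path, index=False)


def read_events(path) -> GaitEvents:
    df = pd.read_csv(path)
    hs = df.loc[df["event"] == "heel_strike", "frame"].to_numpy(int)
    to = df.loc[df["event"] == "toe_off", "frame"].to_numpy(int)
    return GaitEvents(np.sort(hs), np.sort(to))


def save_model(path, model: QuadraticTorqueModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path) -> QuadraticTorqueModel:
    return QuadraticTorqueModel.from_dict(json.loads(Path(path).read_text()))
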