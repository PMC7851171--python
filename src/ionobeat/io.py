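"""HDF5 / CSV persistence for traces, dose maps and pulse trains."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .acoustics import PressureTrace
from .timing import PulseTrain

__all__ = [
    "save_trace",
    "load_trace",
    "trace_to_csv",
    "save_dose_map",
    "train_to_csv",
    "train_from_csv",
]


def save_trace(path, trace: PressureTrace, name: str = "pressure") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        ds = fh.create_dataset(name, data=trace.p)
        ds.attrs["sampling_rate_hz"] = trace.fs
        ds.attrs["t0_s"] = trace.t0
        ds.attrs["component"] = trace.component
        ds.attrs["meta_json"] = json.dumps(trace.meta, default=str)


def load_trace(path, name: str = "pressure") -> PressureTrace:
    with h5py.File(path, "r") as fh:
        ds = fh[name]
        return PressureTrace(
            ds[()],
            fs=float(ds.attrs["sampling_rate_hz"]),
            t0=float(ds.attrs["t0_s"]),
            component=str(ds.attrs.get("component", "iono")),
            meta=json.loads(ds.attrs.get("meta_json", "{}")),
        )


def trace_to_csv(path, trace: PressureTrace) -> None:
    pd.DataFrame({"time_s": trace.t, "pressure_pa": trace.p}).to_csv(path, index=False)


def save_dose_map(path, dose, name: str = "dose") -> None:
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.create_dataset("values_gy", data=dose.values)
        g.create_dataset("x_m", data=dose.x)
        if dose.y is not None:
            g.create_dataset("y_m", data=dose.y)


def train_to_csv(path, train: PulseTrain) -> None:
    pd.DataFrame({"time_s": train.t, "intensity_protons_per_s": train.intensity}).to_csv(path, index=False)


def train_from_csv(path, kind: str = "imported") -> PulseTrain:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    return PulseTrain(df["intensity_protons_per_s"].to_numpy(), float(t[1] - t[0]), kind)
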