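"""HDF5 session container and tabular exports.

Schema::

    /bat0/trajectory  (t, x, y)      raw tag samples
    /bat1/trajectory  (t, x, y)
    /cells/<id>/spike_times
    /clicks/bat{0,1}/times
    attrs: config (JSON echo), duration

Flight tables are exported as CSV (one row per segment).
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd


def write_session(path: str, raw: list[pd.DataFrame],
                  cells: dict[str, np.ndarray] | None = None,
                  clicks: dict[int, np.ndarray] | None = None,
                  config=None, duration: float | None = None) -> None:
    with h5py.File(path, "w") as f:
        for b, df in enumerate(raw):
            g = f.create_group(f"bat{b}/trajectory")
            for col in ("t", "x", "y"):
                g.create_dataset(col, data=df[col].to_numpy())
        for cid, times in (cells or {}).items():
            f.create_dataset(f"cells/{cid}/spike_times", data=np.asarray(times))
        for b, times in (clicks or {}).items():
            f.create_dataset(f"clicks/bat{b}/times", data=np.asarray(times))
        if config is not None:
            if dataclasses.is_dataclass(config):
                config = dataclasses.asdict(config)
            f.attrs["config"] = json.dumps(config)
        if duration is not None:
            f.attrs["duration"] = duration


def read_session(path: str) -> dict:
    out: dict = {"raw": [], "cells": {}, "clicks": {}}
    with h5py.File(path, "r") as f:
        b = 0
        while f"bat{b}" in f:
            g = f[f"bat{b}/trajectory"]
            out["raw"].append(pd.DataFrame({c: g[c][:] for c in ("t", "x", "y")}))
            b += 1
        if "cells" in f:
            for cid in f["cells"]:
                out["cells"][cid] = f[f"cells/{cid}/spike_times"][:]
        if "clicks" in f:
            for key in f["clicks"]:
                out["clicks"][int(key.removeprefix("bat"))] = f[f"clicks/{key}/times"][:]
        if "config" in f.attrs:
            out["config"] = json.loads(f.attrs["config"])
        if "duration" in f.attrs:
            out["duration"] = float(f.attrs["duration"])
    return out


def flight_table_to_csv(segments: pd.DataFrame, crossovers, path: str) -> None:
    seg = segments.copy()
    seg.to_csv(path, index=False)
    cross_path = path.replace(".csv", "_crossovers.csv")
    rows = [{"t_cross": c.t_cross, "x_cross": c.x_cross,
             "direction": c.direction, "valid": c.valid,
             "invalid_reason": c.invalid_reason} for c in crossovers]
    pd.DataFrame(rows).to_csv(cross_path, index=False)
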