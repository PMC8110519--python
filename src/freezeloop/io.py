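"""Reading and writing the artifact's on-disk formats.

Continuous signals go to an HDF5 container (one dataset per channel with
``rate_hz``/``units``/``t0`` attributes), spikes and behavioural
timelines to plain CSV, ground-truth parameters and run summaries to
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import SpikeTrain, TimeSeriesSignal
from .markov import ACTIVE, FREEZE, BehaviouralTimeline


def save_signals(path, signals: dict) -> None:
    """Write ``{name: TimeSeriesSignal}`` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for name, sig in signals.items():
            d = f.create_dataset(name, data=sig.data)
            d.attrs["rate_hz"] = sig.rate_hz
            d.attrs["t0"] = sig.t0
            d.attrs["units"] = sig.units
            d.attrs["channel"] = sig.channel or name


def load_signals(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            d = f[name]
            out[name] = TimeSeriesSignal(
                d[...], float(d.attrs["rate_hz"]),
                t0=float(d.attrs.get("t0", 0.0)),
                channel=str(d.attrs.get("channel", name)),
                units=str(d.attrs.get("units", "a.u.")),
            )
    return out


def save_spikes_csv(path, spikes: list) -> None:
    rows = [(s.unit_id, t) for s in spikes for t in s.times]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def load_spikes_csv(path) -> list:
    df = pd.read_csv(path)
    return [SpikeTrain(g["time_s"].to_numpy(), unit_id=str(uid))
            for uid, g in df.groupby("unit_id", sort=True)]


def save_timeline_csv(path, timeline: BehaviouralTimeline) -> None:
    rows = [(timeline.t0 + b0 * timeline.bin_width,
             timeline.t0 + b1 * timeline.bin_width,
             "Fz" if s == FREEZE else "Act")
            for b0, b1, s in timeline.bouts]
    pd.DataFrame(rows, columns=["start_s", "end_s", "state"]).to_csv(
        path, index=False)


def load_timeline_csv(path, bin_width: float = 2.0) -> BehaviouralTimeline:
    df = pd.read_csv(path).sort_values("start_s")
    t0 = float(df["start_s"].iloc[0])
    n_bins = int(round((df["end_s"].iloc[-1] - t0) / bin_width))
    states = np.full(n_bins, ACTIVE)
    for _, row in df.iterrows():
        b0 = int(round((row["start_s"] - t0) / bin_width))
        b1 = int(round((row["end_s"] - t0) / bin_width))
        states[b0:b1] = FREEZE if str(row["state"]).strip() == "Fz" else ACTIVE
    return BehaviouralTimeline(states, bin_width=bin_width, t0=t0)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def load_json(path):
    return json.loads(Path(path).read_text())
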