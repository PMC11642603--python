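"""File formats: design CSV, long-format trajectory CSV, epochs HDF5, JSON.

All writers round-trip: reading a written file reproduces the in-memory
structure (to float precision for arrays).  Schema violations raise
descriptive errors naming the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from dyaddraw.design import TrialRecord
from dyaddraw.eeggen import EpochSet
from dyaddraw.trajectory import Trajectory

DESIGN_COLUMNS = [
    "trial_id", "context", "combination", "cue_pair", "is_catch", "block",
    "start_time", "drawing_duration", "partner_duration", "delta_time",
    "catch_response",
]


def write_design_csv(trials: Sequence[TrialRecord], path) -> None:
    df = pd.DataFrame([{c: getattr(t, c) for c in DESIGN_COLUMNS} for t in trials])
    df.to_csv(path, index=False)


def read_design_csv(path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design CSV missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                TrialRecord(
                    trial_id=int(row["trial_id"]), context=str(row["context"]),
                    combination=str(row["combination"]), cue_pair=int(row["cue_pair"]),
                    is_catch=bool(row["is_catch"]), block=int(row["block"]),
                    start_time=float(row["start_time"]),
                    drawing_duration=float(row["drawing_duration"]),
                    partner_duration=float(row["partner_duration"]),
                    delta_time=float(row["delta_time"]),
                    catch_response=bool(row["catch_response"]),
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"design CSV row {i}: {e}") from e
    return out


def write_trajectories_csv(trajs: Sequence[Trajectory], path) -> None:
    """Long format: one row per sample (trial_id, sample_idx, x, y, t)."""
    frames = []
    for traj in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": traj.trial_id,
                    "sample_idx": np.arange(len(traj.points)),
                    "x": traj.points[:, 0],
                    "y": traj.points[:, 1],
                    "t": traj.t,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    needed = {"trial_id", "sample_idx", "x", "y", "t"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("sample_idx")
        out.append(
            Trajectory(
                points=grp[["x", "y"]].to_numpy(float),
                t=grp["t"].to_numpy(float),
                trial_id=int(tid),
            )
        )
    return out


def write_epochs_h5(epochs: EpochSet, path) -> None:
    """HDF5 layout: dataset ``data``; attrs sfreq/channels/positions;
    ``events`` group of per-trial label columns."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=epochs.data)
        d.attrs["sfreq"] = epochs.sfreq
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"))
        f.create_dataset("channel_pos", data=epochs.channel_pos)
        ev = f.create_group("events")
        ev.attrs["columns"] = json.dumps(list(epochs.labels.columns))
        for col in epochs.labels.columns:
            vals = epochs.labels[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind == "U":
                vals = np.array([str(v) for v in vals], dtype="S")
            ev.create_dataset(col, data=vals)


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "channel_names", "channel_pos"):
            if name not in f:
                raise ValueError(f"epochs HDF5 missing dataset {name!r}")
        if "events" not in f:
            raise ValueError("epochs HDF5 missing 'events' group")
        data = f["data"][()]
        sfreq = float(f["data"].attrs["sfreq"])
        names = [n.decode() for n in f["channel_names"][()]]
        pos = f["channel_pos"][()]
        ev = f["events"]
        order = json.loads(ev.attrs["columns"]) if "columns" in ev.attrs else list(ev)
        cols = {}
        for col in order:
            vals = ev[col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            cols[col] = vals
        labels = pd.DataFrame(cols)
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"label count ({len(labels)}) does not match trial count ({data.shape[0]})"
        )
    for col in ("is_catch", "catch_response"):
        if col in labels:
            labels[col] = labels[col].astype(bool)
    return EpochSet(data=data, sfreq=sfreq, labels=labels,
                    channel_names=names, channel_pos=pos)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
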