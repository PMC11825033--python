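"""On-disk session format: CSV event tables plus per-trial trajectories.

Layout of a session directory::

    trials.csv       trial_id,mouse_id,entry_id,t_start,stage,required_hold_time,hold_time,success
    entries.csv      entry_id,mouse_id,t_enter,t_exit
    metadata.yaml    cage_id, day0, genotypes {mouse_id: label}
    trajectories/<trial_id>.csv   columns t_s,angle_deg          (default)
    trajectories.h5               one dataset per trial_id       (alternative)

Floats are written with ``repr`` round-trip precision so that
``load_session(save_session(x)) == x`` exactly and repeated saves are
byte-identical.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DEFAULT_FS,
    EntryRecord,
    SessionLog,
    Trajectory,
    TrialRecord,
    ValidationError,
)

__all__ = ["load_session", "save_session", "LoadError"]

TRIAL_COLS = [
    "trial_id",
    "mouse_id",
    "entry_id",
    "t_start",
    "stage",
    "required_hold_time",
    "hold_time",
    "success",
]
ENTRY_COLS = ["entry_id", "mouse_id", "t_enter", "t_exit"]


class LoadError(IOError):
    """A session directory is missing a required file."""


def _fmt(x: float) -> str:
    return repr(float(x))


def save_session(log: SessionLog, path: str, trajectory_format: str = "csv") -> None:
    """Write a validated SessionLog to ``path`` (created if needed).

    ``trajectory_format`` is ``"csv"`` (one file per trial, human
    inspectable) or ``"hdf5"`` (single container, compact at study scale).
    """
    log.validate()
    os.makedirs(path, exist_ok=True)

    lines = [",".join(TRIAL_COLS)]
    for t in sorted(log.trials, key=lambda t: (t.t_start, t.trial_id)):
        lines.append(
            ",".join(
                [
                    t.trial_id,
                    t.mouse_id,
                    t.entry_id,
                    _fmt(t.t_start),
                    str(t.stage),
                    _fmt(t.required_hold_time),
                    _fmt(t.hold_time),
                    "1" if t.success else "0",
                ]
            )
        )
    with open(os.path.join(path, "trials.csv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    lines = [",".join(ENTRY_COLS)]
    for e in sorted(log.entries, key=lambda e: (e.t_enter, e.entry_id)):
        lines.append(",".join([e.entry_id, e.mouse_id, _fmt(e.t_enter), _fmt(e.t_exit)]))
    with open(os.path.join(path, "entries.csv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    meta = {
        "cage_id": log.cage_id,
        "day0": log.day0,
        "genotypes": {k: log.genotypes[k] for k in sorted(log.genotypes)},
    }
    with open(os.path.join(path, "metadata.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    if trajectory_format == "csv":
        tdir = os.path.join(path, "trajectories")
        os.makedirs(tdir, exist_ok=True)
        for tid in sorted(log.trajectories):
            tj = log.trajectories[tid]
            ts = np.arange(len(tj.angle)) / tj.fs
            rows = ["t_s,angle_deg"]
            rows += [f"{_fmt(a)},{_fmt(b)}" for a, b in zip(ts, tj.angle)]
            with open(os.path.join(tdir, f"{tid}.csv"), "w") as fh:
                fh.write("\n".join(rows) + "\n")
    elif trajectory_format == "hdf5":
        with h5py.File(os.path.join(path, "trajectories.h5"), "w") as h5:
            for tid in sorted(log.trajectories):
                h5.create_dataset(tid, data=log.trajectories[tid].angle)
    else:
        raise ValueError(f"unknown trajectory_format: {trajectory_format!r}")


def load_session(path: str) -> SessionLog:
    """Read a session directory back into a validated SessionLog."""
    for fname in ("trials.csv", "entries.csv", "metadata.yaml"):
        if not os.path.exists(os.path.join(path, fname)):
            raise LoadError(f"session directory {path!r} is missing {fname}")

    tdf = pd.read_csv(
        os.path.join(path, "trials.csv"),
        dtype={"trial_id": str, "mouse_id": str, "entry_id": str},
        float_precision="round_trip",
    )
    edf = pd.read_csv(
        os.path.join(path, "entries.csv"),
        dtype={"entry_id": str, "mouse_id": str},
        float_precision="round_trip",
    )
    with open(os.path.join(path, "metadata.yaml")) as fh:
        meta = yaml.safe_load(fh) or {}

    trials = [
        TrialRecord(
            trial_id=r.trial_id,
            mouse_id=r.mouse_id,
            entry_id=r.entry_id,
            t_start=float(r.t_start),
            stage=int(r.stage),
            required_hold_time=float(r.required_hold_time),
            hold_time=float(r.hold_time),
            success=bool(int(r.success)),
        )
        for r in tdf.itertuples(index=False)
    ]
    entries = [
        EntryRecord(
            entry_id=r.entry_id,
            mouse_id=r.mouse_id,
            t_enter=float(r.t_enter),
            t_exit=float(r.t_exit),
        )
        for r in edf.itertuples(index=False)
    ]

    trajectories: dict[str, Trajectory] = {}
    tdir = os.path.join(path, "trajectories")
    h5path = os.path.join(path, "trajectories.h5")
    if os.path.isdir(tdir):
        for fname in sorted(os.listdir(tdir)):
            if not fname.endswith(".csv"):
                continue
            tid = fname[:-4]
            arr = pd.read_csv(os.path.join(tdir, fname), float_precision="round_trip")
            trajectories[tid] = Trajectory(tid, arr["angle_deg"].to_numpy(float), DEFAULT_FS)
    elif os.path.exists(h5path):
        with h5py.File(h5path, "r") as h5:
            for tid in h5:
                trajectories[tid] = Trajectory(tid, np.asarray(h5[tid], dtype=float), DEFAULT_FS)

    # trajectory refs are positional: a trial owns the trajectory named by its id
    for t in trials:
        t.trajectory_ref = t.trial_id if t.trial_id in trajectories else None

    log = SessionLog(
        trials=sorted(trials, key=lambda t: (t.t_start, t.trial_id)),
        entries=sorted(entries, key=lambda e: (e.t_enter, e.entry_id)),
        trajectories=trajectories,
        cage_id=str(meta.get("cage_id", "cage0")),
        genotypes={str(k): str(v) for k, v in (meta.get("genotypes") or {}).items()},
        day0=str(meta.get("day0", "1970-01-01")),
    )
    log.validate()
    return log
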