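"""Plain-text / HDF5 serialization of schedules, traces, and manifests.

Schedules travel as CSV with columns
``trial_index,type,cue_onset_s,cue_offset_s,laser_onset_s,laser_offset_s``
(laser fields empty when absent) preceded by ``# key: value`` metadata lines.
Raw traces are HDF5 (datasets ``t``, ``f405``, ``f470``; attribute ``fs``)
or 3-column CSV; dF/F traces use dataset ``dff``.  Manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import IOFormatError
from .preprocess import DffTrace
from .simulate import RawTrace
from .task import EventSchedule, Trial

SCHEDULE_COLUMNS = ["trial_index", "type", "cue_onset_s", "cue_offset_s",
                    "laser_onset_s", "laser_offset_s"]

PathLike = Union[str, Path]


def write_schedule(schedule: EventSchedule, path: PathLike) -> None:
    path = Path(path)
    lines = [f"# session_index: {schedule.session_index}",
             f"# seed: {schedule.seed if schedule.seed is not None else ''}",
             ",".join(SCHEDULE_COLUMNS)]
    for tr in schedule.trials:
        laser_on = "" if tr.laser_onset_s is None else repr(float(tr.laser_onset_s))
        laser_off = "" if tr.laser_offset_s is None else repr(float(tr.laser_offset_s))
        lines.append(f"{tr.index},{tr.type},{float(tr.cue_onset_s)!r},"
                     f"{float(tr.cue_offset_s)!r},{laser_on},{laser_off}")
    path.write_text("\n".join(lines) + "\n")


def read_schedule(path: PathLike) -> EventSchedule:
    """Read and validate a schedule CSV (errors name the offending line)."""
    path = Path(path)
    meta = {"session_index": 1, "seed": None}
    trials = []
    header_seen = False
    for lineno, raw_line in enumerate(path.read_text().splitlines(), start=1):
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            key, val = key.strip(), val.strip()
            if key in meta and val:
                meta[key] = int(val)
            continue
        fields = line.split(",")
        if not header_seen:
            if [f.strip() for f in fields] != SCHEDULE_COLUMNS:
                raise IOFormatError(
                    f"{path}:{lineno}: expected header {','.join(SCHEDULE_COLUMNS)}")
            header_seen = True
            continue
        if len(fields) != len(SCHEDULE_COLUMNS):
            raise IOFormatError(f"{path}:{lineno}: expected "
                                f"{len(SCHEDULE_COLUMNS)} fields, got {len(fields)}")
        try:
            laser_on = float(fields[4]) if fields[4] != "" else None
            laser_off = float(fields[5]) if fields[5] != "" else None
            trial = Trial(index=int(fields[0]), type=fields[1],
                          cue_onset_s=float(fields[2]), cue_offset_s=float(fields[3]),
                          laser_onset_s=laser_on, laser_offset_s=laser_off)
        except Exception as exc:  # ValueError or Trial's own validation
            raise IOFormatError(f"{path}:{lineno}: {exc}") from exc
        trials.append(trial)
    if not header_seen:
        raise IOFormatError(f"{path}: no header line found")
    try:
        return EventSchedule(trials=tuple(trials),
                             session_index=meta["session_index"], seed=meta["seed"])
    except Exception as exc:
        raise IOFormatError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# Traces


def write_raw_trace(trace: RawTrace, path: PathLike) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=trace.t)
            f.create_dataset("f405", data=trace.f_control)
            f.create_dataset("f470", data=trace.f_signal)
            f.attrs["fs"] = trace.fs
    else:
        pd.DataFrame({"t": trace.t, "f405": trace.f_control,
                      "f470": trace.f_signal}).to_csv(path, index=False)


def read_raw_trace(path: PathLike) -> RawTrace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for name in ("t", "f405", "f470"):
                if name not in f:
                    raise IOFormatError(f"{path}: missing dataset {name!r}")
            t = f["t"][:]
            ctrl = f["f405"][:]
            sig = f["f470"][:]
            fs = float(f.attrs.get("fs", 0.0))
    else:
        df = pd.read_csv(path)
        missing = {"t", "f405", "f470"} - set(df.columns)
        if missing:
            raise IOFormatError(f"{path}: missing columns {sorted(missing)}")
        t, ctrl, sig = (df[c].to_numpy(float) for c in ("t", "f405", "f470"))
        fs = 0.0
    if fs <= 0.0:
        if len(t) < 2:
            raise IOFormatError(f"{path}: cannot infer fs from < 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return RawTrace(t=np.asarray(t, float), f_control=np.asarray(ctrl, float),
                    f_signal=np.asarray(sig, float), fs=fs)


def write_dff_trace(trace: DffTrace, path: PathLike) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=trace.t)
            f.create_dataset("dff", data=trace.dff)
            f.attrs["fs"] = trace.fs
            if trace.fit is not None:
                f.attrs["fit_slope"] = trace.fit.slope
                f.attrs["fit_intercept"] = trace.fit.intercept
    else:
        pd.DataFrame({"t": trace.t, "dff": trace.dff}).to_csv(path, index=False)


def read_dff_trace(path: PathLike) -> DffTrace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "dff" not in f:
                raise IOFormatError(f"{path}: missing dataset 'dff'")
            t = f["t"][:]
            dff = f["dff"][:]
            fs = float(f.attrs.get("fs", 0.0))
    else:
        df = pd.read_csv(path)
        if not {"t", "dff"}.issubset(df.columns):
            raise IOFormatError(f"{path}: need columns t,dff")
        t, dff = df["t"].to_numpy(float), df["dff"].to_numpy(float)
        fs = 0.0
    if fs <= 0.0:
        if len(t) < 2:
            raise IOFormatError(f"{path}: cannot infer fs from < 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return DffTrace(t=np.asarray(t, float), dff=np.asarray(dff, float), fs=fs)


# --------------------------------------------------------------------------
# Manifests and configs


def write_manifest(manifest: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=float) + "\n")


def read_manifest(path: PathLike) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise IOFormatError(f"{path}: invalid JSON: {exc}") from exc


def read_yaml(path: PathLike) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise IOFormatError(f"{path}: invalid YAML: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise IOFormatError(f"{path}: top-level YAML must be a mapping")
    return data


def write_yaml(data: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
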