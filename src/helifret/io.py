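"""Reading and writing the on-disk formats.

Trace tables are CSV (columns ``molecule_id, frame, time_s, I_D, I_A``)
or HDF5 (one dataset per column), auto-detected by extension.  Ground
truth goes to CSV (``molecule_id, label, t_start, t_end``), dwell tables
to TSV, manifests and reports to JSON.  All text is UTF-8, comma/tab
separated, '.' decimal; round trips are lossless at float64 precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .substep_segmentation import DwellTable
from .synthetic_data import IntensityTrace, StatePath, Segment

TRACE_COLUMNS = ["molecule_id", "frame", "time_s", "I_D", "I_A"]
_HDF5_EXT = {".h5", ".hdf5", ".hdf"}


def _traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)


def _frame_to_traces(df: pd.DataFrame, source: str) -> list[IntensityTrace]:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    for col in ("I_D", "I_A", "time_s"):
        bad = df.index[df[col].isna()]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValueError(
                f"{source}: NaN {col} for molecule {row['molecule_id']} "
                f"(line {bad[0] + 2})"
            )
    out = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) != 1) or (len(frames) and frames[0] != 0):
            raise ValueError(f"{source}: non-monotone frames for molecule {mol}")
        tvals = grp["time_s"].to_numpy()
        frame_s = float(tvals[1] - tvals[0]) if len(tvals) > 1 else 0.1
        out.append(
            IntensityTrace(int(mol), frame_s,
                           grp["I_D"].to_numpy(float), grp["I_A"].to_numpy(float))
        )
    return out


def write_traces(traces: list[IntensityTrace], path) -> Path:
    path = Path(path)
    df = _traces_to_frame(traces)
    if path.suffix.lower() in _HDF5_EXT:
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("traces")
            for col in TRACE_COLUMNS:
                grp.create_dataset(col, data=df[col].to_numpy())
    else:
        df.to_csv(path, index=False)
    return path


def read_traces(path) -> list[IntensityTrace]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _HDF5_EXT:
        with h5py.File(path, "r") as fh:
            grp = fh["traces"]
            missing = [c for c in TRACE_COLUMNS if c not in grp]
            if missing:
                raise ValueError(f"{path}: missing column(s) {missing}")
            df = pd.DataFrame({c: grp[c][()] for c in TRACE_COLUMNS})
    else:
        df = pd.read_csv(path)
    return _frame_to_traces(df, str(path))


def write_truth(paths: list[StatePath], path) -> Path:
    path = Path(path)
    pd.concat([p.to_frame() for p in paths], ignore_index=True).to_csv(path, index=False)
    return path


def read_truth(path) -> list[StatePath]:
    df = pd.read_csv(path)
    out = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        segs = [
            Segment(r.label, float(r.t_start), float(r.t_end))
            for r in grp.itertuples()
        ]
        terminal = segs[-1].label if segs and segs[-1].label in (
            "separated", "bleached") else "trace_end"
        out.append(StatePath(int(mol), segs, terminal))
    return out


def write_dwell_table(table: DwellTable, dwell_path, event_path=None) -> Path:
    dwell_path = Path(dwell_path)
    table.dwells.to_csv(dwell_path, sep="\t", index=False)
    if event_path is not None:
        table.events.to_csv(Path(event_path), sep="\t", index=False)
    return dwell_path


def read_dwell_table(dwell_path, event_path=None) -> DwellTable:
    dwells = pd.read_csv(dwell_path, sep="\t")
    events = (
        pd.read_csv(event_path, sep="\t")
        if event_path is not None
        else pd.DataFrame()
    )
    # an empty condition key round-trips as NaN; restore the empty string
    for df in (dwells, events):
        if "condition" in df.columns:
            df["condition"] = df["condition"].fillna("")
    return DwellTable(dwells, events)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
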