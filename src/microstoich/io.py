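"""Run outputs: tidy time-series tables, grid snapshots, metadata sidecars.

Everything is plain, versioned, tool-agnostic text: the per-step record
table as CSV at full float precision, run metadata as JSON, grid snapshots
as whitespace-delimited matrices (occupancy encodes the resident group index
per site, -1 for empty).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import SimState
from .scheduler import SimulationResult

__all__ = [
    "write_outputs",
    "read_records",
    "snapshot_occupancy",
    "write_snapshot",
    "read_snapshot",
]

TABLE_VERSION = "microstoich-records-v1"

#: pool fields a snapshot can contain
SNAPSHOT_FIELDS = (
    "occupancy", "plant_c", "mrc_c", "mrn_c", "dom_c", "dom_n", "din",
)


def write_outputs(
    result: SimulationResult,
    outdir: str | Path,
    snapshots: dict[str, SimState] | None = None,
) -> Path:
    """Write a run's records, metadata and optional snapshots to ``outdir``.

    Produces ``records.csv`` (one row per recorded step, full precision,
    ``# version`` header line), ``metadata.json`` (seed, parameter echo,
    termination reason) and one ``snapshot_<label>_<field>.txt`` per
    requested snapshot field.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_path = outdir / "records.csv"
    with open(records_path, "w") as fh:
        fh.write(f"# {TABLE_VERSION}\n")
        # default float formatting is the shortest round-trip representation
        result.records.to_csv(fh, index=False)
    (outdir / "metadata.json").write_text(
        json.dumps(_jsonable(result.metadata), indent=2, sort_keys=True)
    )
    for label, state in (snapshots or {}).items():
        write_snapshot(state, outdir, label)
    return outdir


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a records table written by :func:`write_outputs`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def snapshot_occupancy(state: SimState) -> np.ndarray:
    """Group index per site (-1 for empty), the Fig-3-style occupancy map."""
    return state.group.copy()


def write_snapshot(
    state: SimState,
    outdir: str | Path,
    label: str,
    fields: tuple[str, ...] = SNAPSHOT_FIELDS,
) -> list[Path]:
    """Write grid fields as text matrices, one file per field."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in fields:
        arr = snapshot_occupancy(state) if name == "occupancy" else getattr(state, name)
        path = outdir / f"snapshot_{label}_{name}.txt"
        fmt = "%d" if name == "occupancy" else "%.17g"
        np.savetxt(path, arr, fmt=fmt, header=f"{name} t={state.t}")
        paths.append(path)
    return paths


def read_snapshot(path: str | Path) -> np.ndarray:
    """Read one snapshot matrix back (occupancy comes back as integers)."""
    arr = np.loadtxt(path)
    if "occupancy" in Path(path).name:
        return arr.astype(np.int64)
    return arr


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj
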