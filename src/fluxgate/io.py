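"""File formats: trace CSV + JSON sidecars, trajectory CSV, results JSON.

Plain CSV and JSON only - desk-scale, dependency-light, diffable.  Numeric
round trips are lossless at double precision (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import CurrentTrace
from .occupancy import IonTrajectory

__all__ = [
    "ParseError",
    "read_trace",
    "write_trace",
    "read_trajectory",
    "write_trajectory",
    "read_results",
    "write_results",
]

_TRACE_COLUMNS = ["time_ms", "voltage_mV", "current_pA"]
_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas reports the offending line number
        raise ParseError(f"{path}: {exc}") from exc


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write a trace as CSV with a JSON metadata sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_ms": trace.time,
            "voltage_mV": trace.voltage,
            "current_pA": trace.current,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(_jsonable(trace.metadata), indent=1))
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace CSV (and its sidecar, if present).

    Extra columns beyond time/voltage/current are preserved under
    ``metadata["extra_columns"]``.
    """
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    metadata: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        metadata.update(json.loads(sidecar.read_text()))
    extra = [c for c in df.columns if c not in _TRACE_COLUMNS]
    if extra:
        metadata["extra_columns"] = {c: df[c].tolist() for c in extra}
    return CurrentTrace(
        time=df["time_ms"].to_numpy(),
        voltage=df["voltage_mV"].to_numpy(),
        current=df["current_pA"].to_numpy(),
        metadata=metadata,
    )


def write_trajectory(traj: IonTrajectory, path: str | Path) -> Path:
    """Trajectory CSV: one ``frame`` column plus one column per ion (nm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"frame": np.arange(traj.n_frames)}
    for i in range(traj.n_ions):
        cols[f"ion_{i}"] = traj.positions[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = dict(traj.metadata)
    meta["frame_interval_ns"] = traj.frame_interval_ns
    _sidecar(path).write_text(json.dumps(_jsonable(meta), indent=1))
    return path


def read_trajectory(path: str | Path) -> IonTrajectory:
    path = Path(path)
    df = _read_csv(path)
    ion_cols = [c for c in df.columns if c.startswith("ion_")]
    if not ion_cols:
        raise ParseError(f"{path}: no ion_* coordinate columns")
    metadata: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        metadata.update(json.loads(sidecar.read_text()))
    interval = float(metadata.pop("frame_interval_ns", 1.0))
    positions = np.vstack([df[c].to_numpy() for c in ion_cols])
    return IonTrajectory(
        frame_interval_ns=interval, positions=positions, metadata=metadata
    )


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for json.dump."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.ndarray, pd.Series)):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_results(results: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(results), indent=1) + "\n")
    return path


def read_results(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: file is empty")
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
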