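"""Readers and writers for session trial tables and analysis results.

A session on disk is a UTF-8 delimited trial table (tab by default, one
row per trial, named-column header) plus a JSON sidecar header carrying
the session metadata (``<stem>.json`` next to ``<stem>.tsv``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import (
    SchemaError,
    Session,
    TrialRecord,
    ValidationError,
)

REQUIRED_COLUMNS = [
    "trial_id", "task", "slant_deg", "tilt_deg", "depth_cm", "choice", "spike_count",
]
OPTIONAL_COLUMNS = ["spike_times_ms", "eye_vpos_deg", "eye_vvel_deg_s", "vergence_deg"]


def _sidecar_path(table_path: Path) -> Path:
    return table_path.with_suffix(".json")


def _parse_spike_times(cell: Any) -> tuple[float, ...] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    if isinstance(cell, (tuple, list)):
        return tuple(float(x) for x in cell)
    return tuple(float(x) for x in str(cell).split(";") if x != "")


def read_session(path: str | Path, sep: str = "\t", validate: bool = True) -> Session:
    """Read a trial table + JSON sidecar into a validated :class:`Session`.

    Malformed rows are reported with their 1-based data-row number.
    """
    path = Path(path)
    header_path = _sidecar_path(path)
    if not header_path.exists():
        raise FileNotFoundError(f"missing session header {header_path}")
    header = json.loads(header_path.read_text())

    table = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in table.columns:
            table[col] = None

    records = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        d = row._asdict()
        try:
            rec = TrialRecord(
                trial_id=int(d["trial_id"]),
                task=str(d["task"]),
                slant_deg=float(d["slant_deg"]),
                tilt_deg=float(d["tilt_deg"]) if not pd.isna(d["tilt_deg"]) else np.nan,
                depth_cm=float(d["depth_cm"]),
                choice=str(d["choice"]),
                spike_count=int(d["spike_count"]),
                spike_times_ms=_parse_spike_times(d["spike_times_ms"]),
                eye_vpos_deg=None if pd.isna(d["eye_vpos_deg"]) else float(d["eye_vpos_deg"]),
                eye_vvel_deg_s=None if pd.isna(d["eye_vvel_deg_s"]) else float(d["eye_vvel_deg_s"]),
                vergence_deg=None if pd.isna(d["vergence_deg"]) else float(d["vergence_deg"]),
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from None
        records.append(rec)

    session = Session(
        neuron_id=str(header["neuron_id"]),
        area=str(header["area"]),
        monkey_id=str(header["monkey_id"]),
        trials=records,
        stim_dur_ms=float(header.get("stim_dur_ms", 1000.0)),
        preferred_sign_fixation=str(header.get("preferred_sign_fixation", "unknown")),
        extra=header.get("extra", {}),
    )
    if validate:
        session.validate()
    return session


def write_session(session: Session, path: str | Path, sep: str = "\t") -> Path:
    """Write a session as trial table + JSON sidecar; returns the table path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = session.trials.copy()
    table["spike_times_ms"] = [
        ";".join(repr(float(t)) for t in ts) if ts is not None else ""
        for ts in table["spike_times_ms"]
    ]
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")
    header = {
        "neuron_id": session.neuron_id,
        "area": session.area,
        "monkey_id": session.monkey_id,
        "stim_dur_ms": session.stim_dur_ms,
        "preferred_sign_fixation": session.preferred_sign_fixation,
        "extra": _jsonable(session.extra),
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=1))
    return path


def _jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, numpy, pandas) to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_results(
    result: Any,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write an analysis result to disk, machine-readable.

    Scalars/fit objects go to JSON; a DataFrame (per-trial or per-bin
    series) goes to a TSV with a ``#``-prefixed JSON provenance line.
    The seed and config are always embedded.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"seed": seed, "config": _jsonable(config or {})}
    if isinstance(result, pd.DataFrame):
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            result.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    else:
        payload = {"meta": meta, "result": _jsonable(result)}
        path.write_text(json.dumps(payload, indent=1, default=str))
    return path


def read_results(path: str | Path) -> Any:
    """Inverse of :func:`write_results` (JSON → dict, TSV → DataFrame)."""
    path = Path(path)
    head = path.read_text().lstrip()[:1]
    if head == "#":
        return pd.read_csv(path, sep="\t", comment="#")
    return json.loads(path.read_text())
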