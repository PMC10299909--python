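"""Delimited-text table I/O with schema validation.

Dialect is fixed: comma separator, "." decimal, UTF-8, header row required.
Lines starting with "#" before the header carry provenance and are ignored
on read. Malformed numeric cells raise :class:`DataError` naming the row and
column; missing schema columns are fatal, extra columns are tolerated.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_dose_response",
    "write_dose_response",
    "read_binding_curve",
    "write_binding_curve",
    "read_feature_series",
    "write_feature_series",
]


@dataclass(frozen=True)
class TableSchema:
    name: str
    numeric: tuple  # required numeric columns
    string: tuple = ()  # required string columns
    optional_numeric: tuple = ()
    optional_string: tuple = ()


SCHEMAS = {
    "dose_response": TableSchema(
        name="dose_response",
        numeric=("log_conc_m", "response", "replicate"),
        string=("ligand", "receptor"),
    ),
    "binding_curve": TableSchema(
        name="binding_curve",
        numeric=("log_conc_m", "signal"),
        optional_numeric=("replicate",),
        optional_string=("series",),
    ),
    "feature_series": TableSchema(name="feature_series", numeric=("time_ns",)),
    "coordinates": TableSchema(
        name="coordinates", numeric=("frame", "x", "y", "z"), string=("atom",)
    ),
    "frequency": TableSchema(
        name="frequency", numeric=("fraction", "n_frames_used"),
        string=("simulation_id", "state"), optional_string=("group",),
    ),
}


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> None:
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise DataError(
            f"{path}: malformed numeric cell in column {col!r}, row {row + 2} "
            f"(value {raw[bad].iloc[0]!r}); dialect requires '.' decimal"
        )
    df[col] = coerced.astype(float)


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read a comma-separated table, skipping '#' provenance lines, and
    validate/coerce it against the schema."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in (*schema.numeric, *schema.string) if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing} for schema {schema.name}")
    for col in schema.numeric:
        _coerce_numeric(df, col, path)
    for col in schema.optional_numeric:
        if col in df.columns:
            _coerce_numeric(df, col, path)
    if schema.name == "feature_series":
        for col in df.columns:
            if col not in schema.numeric:
                _coerce_numeric(df, col, path)
        t = df["time_ns"].to_numpy(float)
        if t.size and not np.all(np.diff(t) > 0):
            raise DataError(f"{path}: time_ns must be strictly increasing")
    return df


def write_table(df: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    """Write a table with optional '# key: value' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    for key, val in (provenance or {}).items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# typed round-trips with ground-truth sidecars
# ---------------------------------------------------------------------------


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def _write_with_meta(df, path, meta, provenance):
    write_table(df, path, provenance)
    if meta:
        _sidecar(path).write_text(json.dumps(meta, indent=2, default=float))


def _read_meta(path) -> dict:
    sc = _sidecar(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


def write_dose_response(ds, path, provenance=None) -> None:
    _write_with_meta(ds.data, path, ds.meta, provenance)


def read_dose_response(path):
    from .synthetic import DoseResponseSet

    return DoseResponseSet(read_table(path, "dose_response"), _read_meta(path))


def write_binding_curve(bs, path, provenance=None) -> None:
    _write_with_meta(bs.data, path, bs.meta, provenance)


def read_binding_curve(path):
    from .synthetic import BindingCurveSet

    return BindingCurveSet(read_table(path, "binding_curve"), _read_meta(path))


def write_feature_series(fs, path, provenance=None) -> None:
    _write_with_meta(fs.data, path, {**fs.meta, "simulation_id": fs.simulation_id}, provenance)


def read_feature_series(path, simulation_id: str | None = None):
    from .trajstate import FeatureSeries

    meta = _read_meta(path)
    sim = simulation_id or meta.get("simulation_id", Path(path).stem)
    return FeatureSeries(simulation_id=sim, data=read_table(path, "feature_series"), meta=meta)
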