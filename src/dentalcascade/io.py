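"""Readers/writers for the package's CSV and JSON schemas.

All tabular I/O is plain CSV with documented headers and units embedded in
column names (``length_mm``, ``canine_to_P4_um``).  Readers validate schema
and value domains and report offending rows by their 1-based data-row number
(header excluded).  Repeated measurements of the same crown (the triplicate
measurement protocol) are averaged on read, with the replicate count
retained in ``replicate_n``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .rd_simulator import InsertionEvent

TOOTH_LABELS = ("P2", "P3", "P4", "M1", "M2", "M3", "dP3", "dP4")
SIDES = ("L", "R")

MEASUREMENT_COLUMNS = ["species_id", "individual_id", "side", "tooth",
                       "length_mm", "width_mm"]
METADATA_COLUMNS = ["species_id", "jaw_length_mm", "body_mass_g", "diet",
                    "premolar_count", "molar_count"]
EMBRYO_COLUMNS = ["species_id", "stage", "canine_to_P4_um"]
EVENT_COLUMNS = ["t_event", "x_event", "cascade", "ordinal", "locus_label",
                 "size_proxy"]


def _load_csv(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{what} file is empty: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{what} file {path} contains no data rows")
    return df


def _require_numeric(df: pd.DataFrame, column: str, what: str,
                     positive: bool = True):
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna()
    if positive:
        bad |= vals <= 0
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise SchemaError(
            f"{what}: non-{'positive ' if positive else ''}numeric value "
            f"{df[column].iloc[row - 1]!r} in column '{column}' at data row {row}")
    return vals.astype(float)


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format crown measurement CSV.

    Repeated rows with identical (species_id, individual_id, side, tooth)
    keys are treated as replicate measurements and averaged; the replicate
    count is kept in ``replicate_n``.  Files that already carry a
    ``replicate_n`` column are taken as pre-aggregated and must have unique
    keys.
    """
    df = _load_csv(path, MEASUREMENT_COLUMNS, "measurement")
    bad_tooth = ~df["tooth"].isin(TOOTH_LABELS)
    if bad_tooth.any():
        row = int(np.nonzero(bad_tooth.to_numpy())[0][0]) + 1
        raise SchemaError(
            f"measurement file: unknown tooth label {df['tooth'].iloc[row - 1]!r} "
            f"at data row {row} (allowed: {', '.join(TOOTH_LABELS)})")
    bad_side = ~df["side"].isin(SIDES)
    if bad_side.any():
        row = int(np.nonzero(bad_side.to_numpy())[0][0]) + 1
        raise SchemaError(
            f"measurement file: side must be L or R, got "
            f"{df['side'].iloc[row - 1]!r} at data row {row}")
    df["length_mm"] = _require_numeric(df, "length_mm", "measurement file")
    df["width_mm"] = _require_numeric(df, "width_mm", "measurement file")

    keys = ["species_id", "individual_id", "side", "tooth"]
    if "replicate_n" in df.columns:
        if df.duplicated(keys).any():
            raise SchemaError(
                "measurement file carries replicate_n but has duplicate "
                "(species, individual, side, tooth) keys")
        out = df[MEASUREMENT_COLUMNS + ["replicate_n"]].copy()
        out["replicate_n"] = out["replicate_n"].astype(int)
    else:
        grouped = df.groupby(keys, sort=True)
        out = grouped[["length_mm", "width_mm"]].mean().reset_index()
        out["replicate_n"] = grouped.size().to_numpy()
    return out.sort_values(keys, ignore_index=True)


def write_measurements(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = MEASUREMENT_COLUMNS + (["replicate_n"] if "replicate_n" in df.columns else [])
    df[cols].to_csv(path, index=False)
    return path


def read_species_metadata(path) -> pd.DataFrame:
    """Read and validate the species metadata CSV (extra columns pass through)."""
    df = _load_csv(path, METADATA_COLUMNS, "species metadata")
    df["jaw_length_mm"] = _require_numeric(df, "jaw_length_mm", "species metadata")
    df["body_mass_g"] = _require_numeric(df, "body_mass_g", "species metadata")
    for col in ("premolar_count", "molar_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 3) | (vals != vals.round())
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
            raise SchemaError(
                f"species metadata: '{col}' must be an integer in 0..3, got "
                f"{df[col].iloc[row - 1]!r} at data row {row}")
        df[col] = vals.astype(int)
    if df["species_id"].duplicated().any():
        dup = df["species_id"][df["species_id"].duplicated()].iloc[0]
        raise SchemaError(f"species metadata: duplicate species_id {dup!r}")
    return df


def write_species_metadata(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_embryo_series(path) -> pd.DataFrame:
    """Read and validate the embryonic (stage, canine-to-P4 length) series CSV."""
    from .morphometrics import _stage_value  # shared stage-label parser

    df = _load_csv(path, EMBRYO_COLUMNS, "embryo series")
    df["canine_to_P4_um"] = _require_numeric(df, "canine_to_P4_um", "embryo series")
    for i, stage in enumerate(df["stage"]):
        try:
            _stage_value(stage)
        except SchemaError:
            raise SchemaError(
                f"embryo series: unrecognized stage label {stage!r} at data "
                f"row {i + 1}") from None
    return df


def write_embryo_series(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df[EMBRYO_COLUMNS].to_csv(path, index=False)
    return path


def events_to_frame(events: list[InsertionEvent]) -> pd.DataFrame:
    rows = [(e.t_event, e.x_event, e.cascade, e.ordinal, e.locus_label,
             e.size_proxy) for e in sorted(events, key=lambda e: (e.t_event, e.ordinal))]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: list[InsertionEvent], path) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, index=False)
    return path


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline output directory."""

    tool_version: str
    timestamp: str
    seed: int | None
    configuration: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_timings_s: dict = field(default_factory=dict)

    @classmethod
    def create(cls, tool_version: str, seed: int | None,
               configuration: dict) -> "RunManifest":
        return cls(tool_version=tool_version,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                   seed=seed, configuration=configuration)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True,
                                   default=str) + "\n")
        return path
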