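"""Delimited-text readers and writers for logs and matrices.

Formats: UTF-8 CSV with header for the two logs, TSV with roster ids as
row/column labels for matrices, JSON for analysis reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CENSUS_COLUMNS,
    EVENT_COLUMNS,
    CensusLog,
    EventLog,
    ValidationError,
)

__all__ = [
    "read_event_log",
    "write_event_log",
    "read_census_log",
    "write_census_log",
    "read_matrix",
    "write_matrix",
    "write_report",
]


def read_event_log(path: str | Path, roster: Sequence[str] | None = None) -> EventLog:
    """Parse an events CSV (``day,winner,loser,behavior,vivarium,zone``).

    The roster is inferred from the union of ids when not supplied. Malformed
    rows raise :class:`ValidationError` naming the offending line (1-based,
    counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in ("day", "vivarium"):
        bad = ~df[col].str.fullmatch(r"\d+")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValidationError(f"{path}: line {line}: non-integer {col!r}")
    self_fight = df["winner"] == df["loser"]
    if self_fight.any():
        line = int(np.flatnonzero(self_fight.to_numpy())[0]) + 2
        raise ValidationError(f"{path}: line {line}: winner equals loser")
    return EventLog(df, roster=roster)


def write_event_log(log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    log.events[EVENT_COLUMNS].to_csv(path, index=False)
    return path


def read_census_log(
    path: str | Path, roster: Sequence[str] | None = None
) -> CensusLog:
    """Parse a census CSV (``day,timepoint,vivarium,id``).

    Duplicate (day, timepoint, id) rows are collapsed with a warning; ids not
    in a supplied roster raise :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in ("day", "vivarium"):
        bad = ~df[col].str.fullmatch(r"\d+")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValidationError(f"{path}: line {line}: non-integer {col!r}")
    if roster is None:
        roster = sorted(df["id"].astype(str).unique())
    return CensusLog(df, roster=roster)


def write_census_log(census: CensusLog, path: str | Path) -> Path:
    path = Path(path)
    census.sightings[CENSUS_COLUMNS].to_csv(path, index=False)
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an id-labelled square TSV matrix."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: matrix row and column labels differ")
    return df


def write_matrix(m: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    m.to_csv(path, sep="\t")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize a (possibly numpy-laden) result dict to pretty JSON."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return path
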