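"""Reading and writing clinic transfer tables and fitted artifacts.

The on-disk schema is a plain UTF-8 comma-separated file with a header
row (names case-insensitive): ``age_at_retrieval``, ``embryo_stage``
(cleavage|blastocyst), ``cycle_type`` (fresh|frozen), ``n_transferred``,
``n_live_born``, and optionally ``n_fetal_heartbeats``.  Unknown columns
are preserved on disk but ignored on load.  Input files are expected to
be pre-filtered to analyzable transfers (no gestational carriers, PGT
cycles, etc.); only schema-level validity is enforced here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .estimation import TransferRecord
from .model import Cycle, EmbryoCategory, Stage

__all__ = [
    "REQUIRED_COLUMNS",
    "RejectionReport",
    "load_transfers",
    "frame_to_records",
    "records_to_frame",
    "write_transfers",
    "save_json",
]

REQUIRED_COLUMNS = (
    "age_at_retrieval",
    "embryo_stage",
    "cycle_type",
    "n_transferred",
    "n_live_born",
)
OPTIONAL_COLUMNS = ("n_fetal_heartbeats",)


@dataclass
class RejectionReport:
    """Row-level load diagnostics: what was dropped and why."""

    n_rows: int = 0
    n_loaded: int = 0
    rejected: List[Tuple[int, str]] = field(default_factory=list)  # (row, reason)
    ignored_columns: List[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _row_to_record(row: pd.Series) -> TransferRecord:
    try:
        stage = Stage(str(row["embryo_stage"]).strip().lower())
        cycle = Cycle(str(row["cycle_type"]).strip().lower())
    except ValueError as exc:
        raise ValueError(f"unknown stage/cycle value: {exc}") from None
    heartbeats = row.get("n_fetal_heartbeats")
    if heartbeats is None or (isinstance(heartbeats, float) and np.isnan(heartbeats)):
        heartbeats = None
    else:
        heartbeats = _as_int(heartbeats, "n_fetal_heartbeats")
    return TransferRecord(
        age_at_retrieval=_as_int(row["age_at_retrieval"], "age_at_retrieval"),
        category=EmbryoCategory(stage, cycle),
        n_embryos=_as_int(row["n_transferred"], "n_transferred"),
        n_live_births=_as_int(row["n_live_born"], "n_live_born"),
        n_fetal_heartbeats=heartbeats,
    )


def _as_int(value, name: str) -> int:
    f = float(value)
    if not f.is_integer():
        raise ValueError(f"{name} must be an integer, got {value!r}")
    return int(f)


def frame_to_records(
    df: pd.DataFrame, strict: bool = False
) -> Tuple[List[TransferRecord], RejectionReport]:
    """Validate a dataframe against the transfer schema row by row."""
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    report = RejectionReport(
        n_rows=len(df),
        ignored_columns=sorted(c for c in df.columns if c not in known),
    )
    records: List[TransferRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(_row_to_record(row))
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {i + 2}: {exc}") from None  # 1-based + header
            report.rejected.append((i + 2, str(exc)))
    report.n_loaded = len(records)
    return records, report


def load_transfers(
    path: Union[str, Path], strict: bool = False
) -> Tuple[List[TransferRecord], RejectionReport]:
    """Load transfer records from CSV.

    In strict mode the first invalid row aborts the load with its row
    number and reason; otherwise invalid rows are dropped and itemized in
    the returned report.
    """
    df = pd.read_csv(path)
    return frame_to_records(df, strict=strict)


def records_to_frame(records: Sequence[TransferRecord]) -> pd.DataFrame:
    rows = [
        {
            "age_at_retrieval": r.age_at_retrieval,
            "embryo_stage": r.category.stage.value,
            "cycle_type": r.category.cycle.value,
            "n_transferred": r.n_embryos,
            "n_live_born": r.n_live_births,
            "n_fetal_heartbeats": r.n_fetal_heartbeats,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))


def write_transfers(records: Sequence[TransferRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(obj, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
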