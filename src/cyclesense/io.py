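"""CSV reading/writing for cohort tables.

Formats: daily_records.csv (participant_id,date,bbt,hr,sdnn,lf_hf,menses,synced)
and cycles.csv (participant_id,cycle_index,start_date,length,menses_duration,
ovulation_day,qualified[,group]). Dates are ISO-8601, missing values empty
cells, booleans 0/1. An optional participants.csv sidecar carries group and
age per participant.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .data import BBT_RANGE, HR_RANGE, CohortTable, RowError, SchemaError

RECORD_COLUMNS = ["participant_id", "date", "bbt", "hr", "sdnn", "lf_hf", "menses", "synced"]
CYCLE_COLUMNS = [
    "participant_id",
    "cycle_index",
    "start_date",
    "length",
    "menses_duration",
    "ovulation_day",
    "qualified",
]

PathLike = Union[str, os.PathLike]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing mandatory column '{col}'")


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RowError(f"unparsable {what} '{series[bad.idxmax()]}'", line=line)
    return parsed


def read_daily_records(
    records_path: PathLike,
    cycles_path: Optional[PathLike] = None,
    participants_path: Optional[PathLike] = None,
) -> CohortTable:
    """Parse a cohort from daily_records.csv and its companion cycles.csv.

    When ``cycles_path`` is omitted, a ``cycles.csv`` next to the records
    file is used if present. Empty signal cells become missing (NaN); range
    violations raise a row-level error naming the CSV line.
    """
    records_path = Path(records_path)
    recs = pd.read_csv(records_path)
    _require_columns(recs, RECORD_COLUMNS, "daily records CSV")
    recs["date"] = _parse_dates(recs["date"], "date")
    for col in ("bbt", "hr", "sdnn", "lf_hf"):
        recs[col] = pd.to_numeric(recs[col], errors="coerce")
    for col in ("menses", "synced"):
        recs[col] = recs[col].astype(float).astype(bool)

    for idx, rec in recs.iterrows():
        line = idx + 2
        if not pd.isna(rec["bbt"]) and not (BBT_RANGE[0] <= rec["bbt"] <= BBT_RANGE[1]):
            raise RowError(f"bbt={rec['bbt']} outside {BBT_RANGE}", line=line)
        if not pd.isna(rec["hr"]) and not (HR_RANGE[0] <= rec["hr"] <= HR_RANGE[1]):
            raise RowError(f"hr={rec['hr']} outside {HR_RANGE}", line=line)
        for col in ("sdnn", "lf_hf"):
            if not pd.isna(rec[col]) and rec[col] <= 0:
                raise RowError(f"{col}={rec[col]} must be positive", line=line)

    if cycles_path is None:
        candidate = records_path.parent / "cycles.csv"
        cycles_path = candidate if candidate.exists() else None
    if cycles_path is not None:
        cycles = pd.read_csv(cycles_path)
        _require_columns(cycles, CYCLE_COLUMNS, "cycles CSV")
        cycles["start_date"] = _parse_dates(cycles["start_date"], "start_date")
        cycles["ovulation_day"] = pd.to_numeric(cycles["ovulation_day"], errors="coerce")
        cycles["qualified"] = cycles["qualified"].astype(float).astype(bool)
    else:
        cycles = pd.DataFrame(columns=CYCLE_COLUMNS)

    participants = None
    if participants_path is None:
        candidate = records_path.parent / "participants.csv"
        participants_path = candidate if candidate.exists() else None
    if participants_path is not None:
        participants = pd.read_csv(participants_path)

    return CohortTable(records=recs, cycles=cycles, participants=participants)


def write_daily_records(
    cohort: CohortTable,
    records_path: PathLike,
    cycles_path: Optional[PathLike] = None,
    participants_path: Optional[PathLike] = None,
) -> None:
    """Write a cohort back to CSV; inverse of :func:`read_daily_records`.

    Missing values serialize as empty cells, booleans as 0/1, dates ISO-8601.
    """
    records_path = Path(records_path)
    recs = cohort.records.copy()
    recs["date"] = pd.to_datetime(recs["date"]).dt.strftime("%Y-%m-%d")
    recs["menses"] = recs["menses"].astype(int)
    recs["synced"] = recs["synced"].astype(int)
    cols = RECORD_COLUMNS + [c for c in recs.columns if c not in RECORD_COLUMNS]
    recs[cols].to_csv(records_path, index=False)

    if cycles_path is None:
        cycles_path = records_path.parent / "cycles.csv"
    cyc = cohort.cycles.copy()
    if len(cyc):
        cyc["start_date"] = pd.to_datetime(cyc["start_date"]).dt.strftime("%Y-%m-%d")
        cyc["qualified"] = cyc["qualified"].astype(int)
        ov = cyc["ovulation_day"]
        cyc["ovulation_day"] = ov.map(lambda v: "" if pd.isna(v) else str(int(v)))
    cols = CYCLE_COLUMNS + [c for c in cyc.columns if c not in CYCLE_COLUMNS]
    cyc.reindex(columns=cols).to_csv(cycles_path, index=False)

    if cohort.participants is not None:
        if participants_path is None:
            participants_path = records_path.parent / "participants.csv"
        cohort.participants.to_csv(participants_path, index=False)


def read_cohort_dir(directory: PathLike) -> CohortTable:
    """Read daily_records.csv + cycles.csv (+ participants.csv) from a directory."""
    d = Path(directory)
    return read_daily_records(d / "daily_records.csv")


def write_cohort_dir(cohort: CohortTable, directory: PathLike) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_daily_records(cohort, d / "daily_records.csv")
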