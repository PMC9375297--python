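"""Core domain types, phase labeling, and cohort validation.

The pipeline's atomic observation is one participant-night of wearable and
thermometer signals; cycles are annotated with menses onset, length, menses
duration, and the ground-truth ovulation day. Phase labels derive entirely
from the cycle annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PhaseLabel",
    "NightRecord",
    "CycleAnnotation",
    "CohortTable",
    "Group",
    "label_phases",
    "validate_cohort",
    "SchemaError",
    "RowError",
    "LabelingError",
    "ConfigError",
    "BBT_RANGE",
    "HR_RANGE",
]

BBT_RANGE = (34.0, 39.0)
HR_RANGE = (30.0, 120.0)


class SchemaError(ValueError):
    """A mandatory CSV column is absent or malformed."""


class RowError(ValueError):
    """A single row violates a parsing or range rule."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class LabelingError(ValueError):
    """A cycle cannot be phase-labeled (e.g. unknown ovulation day)."""


class ConfigError(ValueError):
    """An invalid configuration value."""


class PhaseLabel(str, enum.Enum):
    MENSTRUAL = "MENSTRUAL"
    FOLLICULAR = "FOLLICULAR"
    FERTILE = "FERTILE"
    LUTEAL = "LUTEAL"


class Group(str, enum.Enum):
    REGULAR = "REGULAR"
    IRREGULAR = "IRREGULAR"


@dataclass
class NightRecord:
    """One participant-night: signals, menses flag, and sync status.

    ``synced`` means the wearable uploaded data that night; when False the
    wearable signals (hr, sdnn, lf_hf) must be missing. BBT comes from an
    independent thermometer and can be present on unsynced nights.
    """

    participant_id: str
    date: pd.Timestamp
    bbt: Optional[float] = None
    hr: Optional[float] = None
    sdnn: Optional[float] = None
    lf_hf: Optional[float] = None
    menses: bool = False
    synced: bool = True


@dataclass
class CycleAnnotation:
    """One menstrual cycle: onset date, length, menses duration, ovulation day.

    Cycle length is days from the first day of one menses to the first day
    of the next; day-of-cycle is 1-based, so the cycle spans
    ``[start_date, start_date + length - 1]``. ``ovulation_day`` is a 1-based
    day-of-cycle, or None when ovulation could not be determined.
    """

    participant_id: str
    cycle_index: int
    start_date: pd.Timestamp
    length: int
    menses_duration: int
    ovulation_day: Optional[int] = None
    qualified: bool = True

    @property
    def cycle_uid(self) -> str:
        return f"{self.participant_id}/c{self.cycle_index}"


@dataclass
class CohortTable:
    """The cohort: nightly records, cycle annotations, and participant metadata.

    ``records`` columns: participant_id, date, bbt, hr, sdnn, lf_hf, menses,
    synced. ``cycles`` columns: participant_id, cycle_index, start_date,
    length, menses_duration, ovulation_day, qualified (+ optional group).
    ``participants`` (optional): participant_id, group, age.
    """

    records: pd.DataFrame
    cycles: pd.DataFrame
    participants: Optional[pd.DataFrame] = None

    def group_of(self, participant_id: str) -> Group:
        if self.participants is not None:
            row = self.participants.loc[
                self.participants["participant_id"] == participant_id
            ]
            if len(row):
                return Group(row["group"].iloc[0])
        if "group" in self.cycles.columns:
            row = self.cycles.loc[self.cycles["participant_id"] == participant_id]
            if len(row):
                return Group(row["group"].iloc[0])
        return Group.REGULAR

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.records["participant_id"].unique())

    def annotations(self) -> list[CycleAnnotation]:
        out = []
        for _, r in self.cycles.iterrows():
            ov = r["ovulation_day"]
            out.append(
                CycleAnnotation(
                    participant_id=r["participant_id"],
                    cycle_index=int(r["cycle_index"]),
                    start_date=pd.Timestamp(r["start_date"]),
                    length=int(r["length"]),
                    menses_duration=int(r["menses_duration"]),
                    ovulation_day=None if pd.isna(ov) else int(ov),
                    qualified=bool(r["qualified"]),
                )
            )
        return out


def label_phases(annotation: CycleAnnotation) -> list[PhaseLabel]:
    """Assign one phase label to every day of a cycle.

    Days 1..menses_duration are MENSTRUAL; the fertile window is the five
    days before ovulation plus the ovulation day; the follicular phase is
    whatever lies between menses and the fertile window; post-ovulation days
    are LUTEAL. When a short cycle makes menses and the fertile window
    overlap, precedence is MENSTRUAL > FERTILE > FOLLICULAR (menses is
    directly observed; the follicular phase is defined as the remainder
    outside both menses and the window).

    Raises
    ------
    LabelingError
        If the ovulation day is unknown; such cycles must be excluded.
    """
    if annotation.ovulation_day is None:
        raise LabelingError(
            f"cycle {annotation.cycle_uid} has no determined ovulation day; "
            "exclude it from phase-labeled analyses"
        )
    n = annotation.length
    ov = annotation.ovulation_day
    md = annotation.menses_duration
    if not (1 <= md < n):
        raise LabelingError(f"menses_duration {md} out of bounds for length {n}")
    if not (1 <= ov <= n):
        raise LabelingError(f"ovulation_day {ov} out of bounds for length {n}")

    labels: list[PhaseLabel] = []
    for day in range(1, n + 1):
        if day <= md:
            labels.append(PhaseLabel.MENSTRUAL)
        elif ov - 5 <= day <= ov:
            labels.append(PhaseLabel.FERTILE)
        elif day <= ov - 6:
            labels.append(PhaseLabel.FOLLICULAR)
        else:  # day > ov
            labels.append(PhaseLabel.LUTEAL)
    return labels


def _check_signal_ranges(rec: pd.Series) -> list[str]:
    problems = []
    bbt = rec.get("bbt")
    if bbt is not None and not pd.isna(bbt) and not (BBT_RANGE[0] <= bbt <= BBT_RANGE[1]):
        problems.append("bbt-range")
    hr = rec.get("hr")
    if hr is not None and not pd.isna(hr) and not (HR_RANGE[0] <= hr <= HR_RANGE[1]):
        problems.append("hr-range")
    for col in ("sdnn", "lf_hf"):
        v = rec.get(col)
        if v is not None and not pd.isna(v) and v <= 0:
            problems.append(f"{col}-positive")
    return problems


def validate_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Check every type invariant; violations are data, not exceptions.

    Returns a DataFrame with columns participant_id, date, rule; empty iff
    the cohort is valid. Rules: signal ranges, synced-consistency (an
    unsynced night must carry no wearable signals), cycle bounds, and
    cycle-overlap/contiguity per participant.
    """
    rows = []
    for _, rec in cohort.records.iterrows():
        for rule in _check_signal_ranges(rec):
            rows.append((rec["participant_id"], rec["date"], rule))
        if not rec["synced"]:
            if any(not pd.isna(rec[c]) for c in ("hr", "sdnn", "lf_hf")):
                rows.append((rec["participant_id"], rec["date"], "synced-consistency"))

    for ann in cohort.annotations():
        if not (1 <= ann.menses_duration < ann.length):
            rows.append((ann.participant_id, ann.start_date, "menses-duration-bounds"))
        if ann.ovulation_day is not None and not (1 <= ann.ovulation_day <= ann.length):
            rows.append((ann.participant_id, ann.start_date, "ovulation-day-bounds"))

    for pid, grp in cohort.cycles.groupby("participant_id"):
        grp = grp.sort_values("cycle_index")
        prev_end = None
        for _, r in grp.iterrows():
            start = pd.Timestamp(r["start_date"])
            end = start + pd.Timedelta(days=int(r["length"]) - 1)
            if prev_end is not None and start <= prev_end:
                rows.append((pid, start, "cycle-overlap"))
            prev_end = end

    # every record date maps to at most one cycle (implied by non-overlap,
    # but check directly so the rule fires even with unsorted indices)
    return pd.DataFrame(rows, columns=["participant_id", "date", "rule"])


def truth_from_annotations(cohort: CohortTable) -> pd.DataFrame:
    """Per-day phase labels derived from the cycle annotations.

    One row per day of every cycle with a determined ovulation day, with
    columns participant_id, date, cycle_index, day_of_cycle, phase. This is
    the fallback when generator truth labels are not available: for
    annotated real data the two coincide by construction.
    """
    rows = []
    for ann in cohort.annotations():
        try:
            labels = label_phases(ann)
        except LabelingError:
            continue
        for d, lab in enumerate(labels, start=1):
            rows.append(
                {
                    "participant_id": ann.participant_id,
                    "date": ann.start_date + pd.Timedelta(days=d - 1),
                    "cycle_index": ann.cycle_index,
                    "day_of_cycle": d,
                    "phase": lab.value,
                }
            )
    return pd.DataFrame(rows)


def day_of_cycle(cohort: CohortTable) -> pd.DataFrame:
    """Map each record to (cycle_index, day_of_cycle, phase) where possible.

    Records outside any annotated cycle, or in cycles without a determined
    ovulation day, get NaN phase. Returns records joined with the mapping.
    """
    recs = cohort.records.copy()
    recs["date"] = pd.to_datetime(recs["date"])
    recs["cycle_index"] = np.nan
    recs["day_of_cycle"] = np.nan
    recs["phase"] = None
    for ann in cohort.annotations():
        try:
            labels = label_phases(ann)
        except LabelingError:
            labels = None
        mask = (recs["participant_id"] == ann.participant_id) & (
            recs["date"] >= ann.start_date
        ) & (recs["date"] <= ann.start_date + pd.Timedelta(days=ann.length - 1))
        days = (recs.loc[mask, "date"] - ann.start_date).dt.days + 1
        recs.loc[mask, "cycle_index"] = ann.cycle_index
        recs.loc[mask, "day_of_cycle"] = days
        if labels is not None:
            recs.loc[mask, "phase"] = [labels[d - 1].value for d in days]
    return recs
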