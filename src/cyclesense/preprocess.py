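"""Data-cleaning rules: night summarization, imputation, transforms, filtering.

Nightly intranight traces are edge-trimmed (first/last 30 min) and a night
counts only when continuous sleep exceeds 4 h. Daily gaps are filled by the
mean of available values up to two days on either side, in a single pass so
imputed values never feed other imputations. SDNN and LF/HF are natural-log
transformed. A cycle qualifies when the band synced on at least 80% of its
nights and the ovulation day is determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CohortTable, ConfigError, RowError


@dataclass
class QualifyConfig:
    completeness_threshold: float = 0.80
    min_sleep_minutes: int = 240
    trim_minutes: int = 30
    impute_radius: int = 2
    smooth_window: int = 5

    def __post_init__(self):
        if not 0.0 < self.completeness_threshold <= 1.0:
            raise ConfigError("completeness_threshold must be in (0, 1]")
        if self.trim_minutes < 0:
            raise ConfigError("trim_minutes must be >= 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd and >= 1")


def summarize_night(series: pd.Series, config: QualifyConfig | None = None) -> float | None:
    """Nightly HR summary: mean of the trace with sleep edges trimmed.

    Returns None (night invalid, treated as unsynced) unless the trace is
    strictly longer than ``min_sleep_minutes``; otherwise the mean of minutes
    trim+1 .. n-trim.
    """
    config = config or QualifyConfig()
    values = np.asarray(series, dtype=float)
    n = len(values)
    if n <= config.min_sleep_minutes:
        return None
    t = config.trim_minutes
    kept = values[t : n - t] if n > 2 * t else values
    return float(kept.mean())


def impute_missing(
    values: pd.Series,
    config: QualifyConfig | None = None,
    imputed_mask: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Fill each gap with the mean of neighbors at +-1 and +-2 days.

    Single pass over the original values: only originally observed days
    contribute (never previously imputed ones, which are identified via
    ``imputed_mask`` on reapplication), so imputation never chains and is
    idempotent given its own mask. Days with no observed neighbor in the
    window stay missing. Returns (completed series, boolean mask covering
    all imputed days, prior and new).
    """
    config = config or QualifyConfig()
    r = config.impute_radius
    orig = np.asarray(values, dtype=float)
    out = orig.copy()
    mask = np.zeros(len(orig), dtype=bool)
    if imputed_mask is not None:
        mask |= np.asarray(imputed_mask, dtype=bool)
        orig = orig.copy()
        orig[mask] = np.nan  # prior imputations are not donors
        out[mask] = np.asarray(values, dtype=float)[mask]  # but keep their values
    targets = np.flatnonzero(np.isnan(orig) & ~mask)
    for i in targets:
        lo, hi = max(0, i - r), min(len(orig), i + r + 1)
        neighbors = np.concatenate([orig[lo:i], orig[i + 1 : hi]])
        neighbors = neighbors[~np.isnan(neighbors)]
        if len(neighbors):
            out[i] = neighbors.mean()
            mask[i] = True
    idx = values.index if isinstance(values, pd.Series) else None
    return pd.Series(out, index=idx), pd.Series(mask, index=idx)


def ln_transform(cohort: CohortTable) -> CohortTable:
    """Add ln_sdnn and ln_lfhf columns; missing values propagate.

    Raises a row-level error on nonpositive SDNN or LF/HF.
    """
    recs = cohort.records.copy()
    for src, dst in (("sdnn", "ln_sdnn"), ("lf_hf", "ln_lfhf")):
        vals = recs[src].astype(float)
        bad = (vals <= 0) & vals.notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise RowError(f"{src}={vals.iloc[i]} must be positive for ln transform", line=i + 2)
        recs[dst] = np.log(vals)
    return CohortTable(records=recs, cycles=cohort.cycles, participants=cohort.participants)


def qualify_cycles(cohort: CohortTable, config: QualifyConfig | None = None) -> pd.DataFrame:
    """Set the qualified flag: synced-night completeness >= threshold (inclusive)
    AND a determined ovulation day. Returns the cycles table with flags set."""
    config = config or QualifyConfig()
    recs = cohort.records.copy()
    recs["date"] = pd.to_datetime(recs["date"])
    cycles = cohort.cycles.copy()
    flags = []
    for _, c in cycles.iterrows():
        start = pd.Timestamp(c["start_date"])
        end = start + pd.Timedelta(days=int(c["length"]) - 1)
        mask = (
            (recs["participant_id"] == c["participant_id"])
            & (recs["date"] >= start)
            & (recs["date"] <= end)
        )
        synced = int(recs.loc[mask, "synced"].sum())
        completeness = synced / int(c["length"])
        ok = completeness >= config.completeness_threshold and not pd.isna(c["ovulation_day"])
        flags.append(ok)
    cycles["qualified"] = flags
    return cycles


def smooth_cycle_waveform(values, window: int) -> np.ndarray:
    """Centered moving average over one cycle, truncated at the boundaries.

    Never borrows data across cycles; output length equals input length.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigError("smoothing window must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    n = len(v)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = v[lo:hi].mean()
    return out


def preprocess_cohort(
    cohort: CohortTable, config: QualifyConfig | None = None
) -> CohortTable:
    """Run the full cleaning chain on a cohort.

    Imputes bbt and hr per participant (date-ordered), adds ln_sdnn/ln_lfhf
    (imputed on the ln scale), adds *_imputed mask columns, and sets the
    qualified flag on every cycle. Returns a new CohortTable.
    """
    config = config or QualifyConfig()
    cohort = ln_transform(cohort)
    recs = cohort.records.copy()
    recs["date"] = pd.to_datetime(recs["date"])
    recs = recs.sort_values(["participant_id", "date"]).reset_index(drop=True)

    for col in ("bbt", "hr", "ln_sdnn", "ln_lfhf"):
        filled_parts, mask_parts = [], []
        for _, grp in recs.groupby("participant_id", sort=False):
            filled, mask = impute_missing(grp[col], config)
            filled_parts.append(filled)
            mask_parts.append(mask)
        recs[col] = pd.concat(filled_parts)
        recs[f"{col}_imputed"] = pd.concat(mask_parts)

    out = CohortTable(records=recs, cycles=cohort.cycles, participants=cohort.participants)
    out.cycles = qualify_cycles(out, config)
    return out
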