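"""Trailing-window biphasic features for day-level prediction.

To decide whether day t is in the fertile window (or menses), only data
strictly before t is used: the participant's recent daily BBT/HR (optionally
ln-SDNN / ln-LF/HF) series is smoothed, and features describing the biphasic
structure of that trailing window are extracted — the detected switch point
(the split maximizing the pre/post segment-mean difference), its signed step
size and recency, short-horizon level shifts, a z-scored last value, and a
trailing slope. Within-window features cancel participant and cycle
intercepts, so the model keys on waveform shape rather than absolute level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocess import smooth_cycle_waveform

FEATURE_VERSION = "1"

BASE_SIGNALS = ("bbt", "hr")
HRV_SIGNALS = ("ln_sdnn", "ln_lfhf")

MENSES_ONSET_CAP = 60  # days; used when no onset is visible in the history


@dataclass
class FeatureConfig:
    window: int = 14  # trailing window length W, days
    smooth_window: int = 5  # odd; 1 disables smoothing
    min_history: int = 7
    min_segment: int = 2  # switch-point guard segments
    use_calendar: bool = False  # days_since_menses_onset feature
    use_hrv: bool = False

    @property
    def signals(self) -> Tuple[str, ...]:
        return BASE_SIGNALS + (HRV_SIGNALS if self.use_hrv else ())

    def feature_names(self) -> list[str]:
        names = []
        for s in self.signals:
            names += [
                f"recent3_mean_delta_{s}",
                f"last_z_{s}",
                f"switch_delta_{s}",
                f"days_since_switch_{s}",
                f"trailing_slope_{s}",
            ]
        if self.use_calendar:
            names.append("days_since_menses_onset")
        names.append("completeness")
        return names


def detect_switch_point(
    smoothed_values, min_segment: int = 3
) -> Optional[Tuple[int, float]]:
    """Find the biphasic switch point of a series.

    Returns (k, delta) where k is the size of the pre-segment (days 1..k vs
    k+1..n) maximizing |mean(post) - mean(pre)| over k in
    [min_segment, n - min_segment], and delta the signed difference
    (post minus pre). Ties break toward the latest k. Returns None when the
    series is shorter than 2 * min_segment.
    """
    v = np.asarray(smoothed_values, dtype=float)
    n = len(v)
    if n < 2 * min_segment:
        return None
    cum = np.cumsum(v)
    total = cum[-1]
    best_k, best_delta = None, 0.0
    for k in range(min_segment, n - min_segment + 1):
        pre = cum[k - 1] / k
        post = (total - cum[k - 1]) / (n - k)
        delta = post - pre
        if best_k is None or abs(delta) >= abs(best_delta):
            best_k, best_delta = k, delta
    return best_k, float(best_delta)


def _signal_features(window_values: np.ndarray, raw_values: np.ndarray,
                     min_segment: int) -> list[float]:
    v = window_values
    n = len(v)
    recent3 = v[-3:].mean() if n >= 3 else v.mean()
    baseline = v[:-3].mean() if n > 3 else v.mean()
    recent3_delta = recent3 - baseline
    # z of the raw last observation: smoothing would dilute one-day events
    # (the pre-ovulatory nadir) that the last night carries
    sd = raw_values.std()
    last_z = (raw_values[-1] - raw_values.mean()) / sd if sd > 1e-12 else 0.0
    sw = detect_switch_point(v, min_segment)
    if sw is None:
        switch_delta, days_since = 0.0, 0.0
    else:
        k, switch_delta = sw
        days_since = float(n - k)
    tail = v[-5:] if n >= 5 else v
    if len(tail) >= 2:
        slope = np.polyfit(np.arange(len(tail)), tail, 1)[0]
    else:
        slope = 0.0
    return [recent3_delta, last_z, switch_delta, days_since, float(slope)]


@dataclass
class _ParticipantArrays:
    """Column-extracted per-participant daily series for fast windowing."""

    signals: Dict[str, np.ndarray]
    menses: np.ndarray
    imputed_any: np.ndarray

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: "FeatureConfig") -> "_ParticipantArrays":
        signals = {s: np.asarray(frame[s], dtype=float) for s in config.signals}
        menses = np.asarray(frame["menses"], dtype=bool)
        mask_cols = [f"{s}_imputed" for s in config.signals if f"{s}_imputed" in frame.columns]
        if mask_cols:
            imputed_any = np.asarray(frame[mask_cols]).any(axis=1)
        else:
            imputed_any = np.zeros(len(frame), dtype=bool)
        return cls(signals=signals, menses=menses, imputed_any=imputed_any)


def _features_at(arrays: _ParticipantArrays, t_pos: int, config: FeatureConfig) -> Optional[np.ndarray]:
    """Feature vector for the day at position ``t_pos`` (history = rows < t_pos)."""
    if t_pos < config.min_history:
        return None
    lo = max(0, t_pos - config.window)

    feats: list[float] = []
    for s in config.signals:
        vals = arrays.signals[s][lo:t_pos]
        if np.isnan(vals).any():
            return None
        smoothed = smooth_cycle_waveform(vals, config.smooth_window)
        feats += _signal_features(smoothed, vals, config.min_segment)

    if config.use_calendar:
        menses = arrays.menses[:t_pos]
        starts = menses.copy()
        starts[1:] = menses[1:] & ~menses[:-1]
        onsets = np.flatnonzero(starts)
        feats.append(float(t_pos - onsets[-1]) if len(onsets) else float(MENSES_ONSET_CAP))

    completeness = 1.0 - float(arrays.imputed_any[lo:t_pos].mean())
    feats.append(completeness)
    return np.asarray(feats, dtype=float)


def extract_day_features(
    history: pd.DataFrame, config: FeatureConfig | None = None
) -> Optional[np.ndarray]:
    """Feature vector for the day immediately after ``history``.

    ``history`` holds the participant's completed daily records strictly
    before the target day, date-ordered, with signal columns (post
    imputation), a ``menses`` flag, and optional ``*_imputed`` masks. The
    trailing window is the last ``window`` days (truncated to what exists),
    smoothed with a centered moving average before feature computation.
    Returns None when fewer than ``min_history`` days are available or the
    window still contains missing values for a used signal.
    """
    config = config or FeatureConfig()
    arrays = _ParticipantArrays.from_frame(history, config)
    return _features_at(arrays, len(history), config)


def build_training_matrix(
    daily: pd.DataFrame,
    cycles: pd.DataFrame,
    target: str,
    config: FeatureConfig | None = None,
    truth: Optional[pd.DataFrame] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """One row per eligible participant-day of every qualified cycle.

    ``target`` is "fertile" (positive = FERTILE-labeled day) or "menses"
    (positive = MENSTRUAL-labeled day); labels come from ``truth`` when
    given, else from the annotations via the labeling rule. Days in the
    first ``min_history`` days of a participant's record, or whose trailing
    window has residual missingness, are excluded. Returns (X, y, groups,
    meta) where groups carries participant ids for grouped CV and meta has
    participant, date, cycle_index, cycle_length per row.
    """
    from .data import CohortTable
    from .mixed_model import build_long_table

    config = config or FeatureConfig()
    target = target.lower()
    if target not in ("fertile", "menses"):
        raise ValueError("target must be 'fertile' or 'menses'")
    positive_phase = "FERTILE" if target == "fertile" else "MENSTRUAL"

    cohort = CohortTable(records=daily, cycles=cycles)
    labeled = build_long_table(cohort, truth=truth)
    if labeled.empty:
        raise ValueError("no eligible days: no qualified labeled cycles")
    labeled = labeled.sort_values(["participant_id", "date"])

    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    daily = daily.sort_values(["participant_id", "date"])
    by_pid = {pid: grp.reset_index(drop=True) for pid, grp in daily.groupby("participant_id")}
    length_by_cycle = {
        (r["participant_id"], int(r["cycle_index"])): int(r["length"])
        for _, r in cycles.iterrows()
    }

    X_rows, y_rows, group_rows, meta_rows = [], [], [], []
    for pid, days in labeled.groupby("participant_id", sort=True):
        series = by_pid[pid]
        arrays = _ParticipantArrays.from_frame(series, config)
        pos_by_date = {d: i for i, d in enumerate(series["date"])}
        for _, row in days.iterrows():
            t_pos = pos_by_date.get(row["date"])
            if t_pos is None:
                continue
            feats = _features_at(arrays, t_pos, config)
            if feats is None:
                continue
            X_rows.append(feats)
            y_rows.append(1 if row["phase"] == positive_phase else 0)
            group_rows.append(pid)
            ci = int(row["cycle_index"])
            meta_rows.append(
                {
                    "participant_id": pid,
                    "date": row["date"],
                    "cycle_index": ci,
                    "cycle_length": length_by_cycle.get((pid, ci), np.nan),
                }
            )
    if not X_rows:
        raise ValueError("no eligible days after history/missingness filters")
    return (
        np.vstack(X_rows),
        np.asarray(y_rows, dtype=int),
        np.asarray(group_rows),
        pd.DataFrame(meta_rows),
    )
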