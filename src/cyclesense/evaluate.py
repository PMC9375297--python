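"""Train/test splitting, day-level confusion metrics, ROC/AUC, stratification."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass
class SplitSpec:
    """Participant-level train/test partition of the regular group.

    Irregular participants are never in training; they form their own test
    set evaluated with the regular-trained model.
    """

    n_train_participants: int = 68
    n_test_participants: int = 21
    seed: int = 0


def split_participants(
    participant_ids: Sequence[str], spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Uniformly random, seed-deterministic partition into train/test ids."""
    ids = list(participant_ids)
    if len(ids) != spec.n_train_participants + spec.n_test_participants:
        raise ValueError(
            f"{len(ids)} ids cannot be split into {spec.n_train_participants} "
            f"train + {spec.n_test_participants} test"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(sorted(ids))
    train = sorted(perm[: spec.n_train_participants].tolist())
    test = sorted(perm[spec.n_train_participants :].tolist())
    return train, test


def confusion_metrics(predictions, truth) -> dict:
    """Day-level confusion counts and accuracy/sensitivity/specificity.

    With one-class truth the undefined entry is NaN and flagged, never
    silently zero.
    """
    pred = np.asarray(predictions, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if len(pred) != len(t):
        raise ValueError("predictions and truth must have equal length")
    tp = int(np.sum(pred & t))
    fp = int(np.sum(pred & ~t))
    tn = int(np.sum(~pred & ~t))
    fn = int(np.sum(~pred & t))
    n = tp + fp + tn + fn
    out = {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "undefined": [],
    }
    if tp + fn == 0:
        out["undefined"].append("sensitivity")
    if tn + fp == 0:
        out["undefined"].append("specificity")
    return out


def roc_auc(probabilities, truth) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoidal AUC.

    Equals the Mann-Whitney concordance probability with ties counted 1/2.
    Raises on one-class truth.
    """
    p = np.asarray(probabilities, dtype=float)
    t = np.asarray(truth, dtype=int)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC requires at least one positive and one negative day")
    fpr, tpr, _ = _roc_curve(t, p)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


def stratified_evaluation(
    predictions: pd.DataFrame,
    strata: pd.Series,
    prob_col: str = "probability",
    pred_col: str = "predicted",
    truth_col: str = "truth",
) -> Dict[str, dict]:
    """Per-stratum confusion metrics (and AUC where both classes occur).

    ``strata`` aligns with ``predictions`` rows; empty strata are omitted.
    Strata without positive days report sensitivity as NaN with a flag.
    """
    out: Dict[str, dict] = {}
    for key, idx in predictions.groupby(strata.values).groups.items():
        sub = predictions.loc[idx]
        if sub.empty:
            continue
        m = confusion_metrics(sub[pred_col], sub[truth_col])
        if sub[truth_col].nunique() == 2:
            _, m["auc"] = roc_auc(sub[prob_col], sub[truth_col])
        else:
            m["auc"] = float("nan")
        m["n_days"] = int(len(sub))
        out[str(key)] = m
    return out


def cycle_length_stratum(length: float) -> str:
    if pd.isna(length):
        return "unknown"
    if length < 25:
        return "<25"
    if length > 35:
        return ">35"
    return "25-35"


@dataclass
class EvalReport:
    """Day-level evaluation of one model on one group."""

    target: str
    group: str
    metrics: dict
    auc: float
    roc_points: np.ndarray
    n_days: int
    subgroups: Dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        m = {k: v for k, v in self.metrics.items()}
        return {
            "target": self.target,
            "group": self.group,
            "n_days": self.n_days,
            "auc": self.auc,
            **{k: m[k] for k in ("TP", "FP", "TN", "FN", "accuracy", "sensitivity", "specificity")},
            "undefined": m.get("undefined", []),
            "subgroups": {
                k: {kk: vv for kk, vv in v.items() if kk != "undefined"}
                for k, v in self.subgroups.items()
            },
        }


def evaluate_predictions(
    predictions: pd.DataFrame,
    truth_labels: pd.DataFrame,
    target: str,
    group: str,
    cycles: Optional[pd.DataFrame] = None,
) -> EvalReport:
    """Join day predictions with truth phases and compute the report.

    Only days that fall inside a labeled (qualified, ovulation-known) cycle
    are scored. Subgroup breakdowns use cycle-length strata <25 / 25-35 / >35
    when the cycles table is supplied.
    """
    positive_phase = "FERTILE" if target.lower() == "fertile" else "MENSTRUAL"
    t = truth_labels.copy()
    t["date"] = pd.to_datetime(t["date"])
    merged = predictions.merge(
        t[["participant_id", "date", "cycle_index", "phase"]],
        on=["participant_id", "date"],
        how="inner",
    )
    merged["truth"] = (merged["phase"] == positive_phase).astype(int)
    metrics = confusion_metrics(merged["predicted"], merged["truth"])
    if merged["truth"].nunique() == 2:
        points, auc_val = roc_auc(merged["probability"], merged["truth"])
    else:
        points, auc_val = np.empty((0, 2)), float("nan")

    subgroups: Dict[str, dict] = {}
    if cycles is not None and not merged.empty:
        lengths = {
            (r["participant_id"], int(r["cycle_index"])): int(r["length"])
            for _, r in cycles.iterrows()
        }
        strat = merged.apply(
            lambda r: cycle_length_stratum(
                lengths.get((r["participant_id"], int(r["cycle_index"])), np.nan)
            ),
            axis=1,
        )
        subgroups = stratified_evaluation(merged, strat)

    return EvalReport(
        target=target,
        group=group,
        metrics=metrics,
        auc=auc_val,
        roc_points=points,
        n_days=len(merged),
        subgroups=subgroups,
    )
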