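"""Day-level probability model: L2 logistic regression over biphasic features.

`DayProbabilityClassifier` is a scikit-learn estimator (fit/predict_proba/
predict) that standardizes features, selects the L2 strength by
participant-grouped fivefold cross-validated AUC, and refits on all data.
`train_day_model` runs the outer search over the feature hyperparameters
(trailing-window length and smoothing window), rebuilding the feature matrix
per candidate, and returns a serializable trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_VERSION, FeatureConfig, build_training_matrix

DEFAULT_CS = (0.01, 0.1, 1.0, 10.0)
DEFAULT_WINDOWS = (7, 10, 14)
DEFAULT_SMOOTH_WINDOWS = (3, 5)


class DayProbabilityClassifier(BaseEstimator, ClassifierMixin):
    """L2-regularized logistic day classifier with grouped-CV strength selection.

    Parameters
    ----------
    Cs : sequence of float
        Inverse-regularization grid searched by grouped fivefold CV
        (maximizing mean validation AUC). A single value skips the search.
    n_folds : int
        Number of participant-grouped folds.
    threshold : float
        Decision threshold on the predicted probability; ``predict`` is
        positive when probability >= threshold (inclusive).
    random_state : int
        Seed for the solver; folds themselves are deterministic.

    Attributes
    ----------
    best_C_ : float
        Selected inverse-regularization strength.
    cv_results_ : dict
        Mean validation AUC per candidate C.
    coef_, intercept_ : ndarray
        Weights on the standardized feature scale.
    scaler_mean_, scaler_scale_ : ndarray
        Standardization constants, from training data only.
    """

    def __init__(self, Cs=DEFAULT_CS, n_folds: int = 5, threshold: float = 0.5,
                 random_state: int = 0):
        self.Cs = Cs
        self.n_folds = n_folds
        self.threshold = threshold
        self.random_state = random_state

    def _make_estimator(self, C: float) -> LogisticRegression:
        return LogisticRegression(
            C=C, solver="lbfgs", max_iter=2000, class_weight="balanced",
            random_state=self.random_state,
        )

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("degenerate labels: only one class present")
        self.classes_ = classes

        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        self.scaler_mean_ = scaler.mean_
        self.scaler_scale_ = scaler.scale_

        Cs = list(self.Cs)
        if len(Cs) > 1 and groups is not None and len(np.unique(groups)) >= self.n_folds:
            cv = GroupKFold(n_splits=self.n_folds)
            scores: Dict[float, float] = {}
            for C in Cs:
                fold_aucs = []
                for tr, va in cv.split(Xs, y, groups):
                    if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                        continue
                    sc = StandardScaler().fit(X[tr])
                    est = self._make_estimator(C).fit(sc.transform(X[tr]), y[tr])
                    prob = est.predict_proba(sc.transform(X[va]))[:, 1]
                    fold_aucs.append(roc_auc_score(y[va], prob))
                scores[C] = float(np.mean(fold_aucs)) if fold_aucs else -np.inf
            self.cv_results_ = scores
            self.best_C_ = max(Cs, key=lambda c: scores[c])
        else:
            self.cv_results_ = {}
            self.best_C_ = Cs[0]

        est = self._make_estimator(self.best_C_).fit(Xs, y)
        self.coef_ = est.coef_
        self.intercept_ = est.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length mismatch: got {X.shape[1]}, expected {self.n_features_in_}"
            )
        Xs = (X - self.scaler_mean_) / self.scaler_scale_
        score = Xs @ self.coef_.ravel() + self.intercept_[0]
        p = 1.0 / (1.0 + np.exp(-score))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


def predict_day_probability(model: "DayProbabilityClassifier", features) -> float:
    """Probability for a single feature vector (standardized linear-logistic)."""
    feats = np.asarray(features, dtype=float).reshape(1, -1)
    return float(model.predict_proba(feats)[0, 1])


def classify_day(probability: float, threshold: float = 0.5) -> bool:
    """Inclusive decision rule: positive when probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return probability >= threshold


@dataclass
class TrainedDayModel:
    """A fitted day classifier plus the feature configuration that built it."""

    target: str
    feature_config: FeatureConfig
    classifier: DayProbabilityClassifier
    feature_names: list[str]
    cv_auc: float
    search_results: list[dict] = field(default_factory=list)
    feature_version: str = FEATURE_VERSION

    def predict_days(self, daily: pd.DataFrame, participant_ids: Sequence[str]) -> pd.DataFrame:
        """Day-level probabilities for each eligible day of given participants.

        Features use only data strictly before each day; days with
        insufficient or incomplete history are skipped.
        """
        from .features import _features_at, _ParticipantArrays

        daily = daily.copy()
        daily["date"] = pd.to_datetime(daily["date"])
        daily = daily.sort_values(["participant_id", "date"])
        rows = []
        for pid in participant_ids:
            series = daily[daily["participant_id"] == pid].reset_index(drop=True)
            arrays = _ParticipantArrays.from_frame(series, self.feature_config)
            feats_list, dates = [], []
            for t_pos in range(self.feature_config.min_history, len(series)):
                feats = _features_at(arrays, t_pos, self.feature_config)
                if feats is None:
                    continue
                feats_list.append(feats)
                dates.append(series["date"].iloc[t_pos])
            if not feats_list:
                continue
            probs = self.classifier.predict_proba(np.vstack(feats_list))[:, 1]
            for d, p in zip(dates, probs):
                rows.append(
                    {
                        "participant_id": pid,
                        "date": d,
                        "probability": float(p),
                        "predicted": classify_day(float(p), self.classifier.threshold),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        clf = self.classifier
        payload = {
            "target": self.target,
            "feature_version": self.feature_version,
            "feature_names": self.feature_names,
            "feature_config": {
                "window": self.feature_config.window,
                "smooth_window": self.feature_config.smooth_window,
                "min_history": self.feature_config.min_history,
                "min_segment": self.feature_config.min_segment,
                "use_calendar": self.feature_config.use_calendar,
                "use_hrv": self.feature_config.use_hrv,
            },
            "classifier": {
                "best_C": clf.best_C_,
                "threshold": clf.threshold,
                "coef": clf.coef_.ravel().tolist(),
                "intercept": float(clf.intercept_[0]),
                "scaler_mean": clf.scaler_mean_.tolist(),
                "scaler_scale": clf.scaler_scale_.tolist(),
            },
            "cv_auc": self.cv_auc,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedDayModel":
        payload = json.loads(text)
        fc = FeatureConfig(**payload["feature_config"])
        c = payload["classifier"]
        clf = DayProbabilityClassifier(Cs=(c["best_C"],), threshold=c["threshold"])
        clf.best_C_ = c["best_C"]
        clf.coef_ = np.asarray([c["coef"]])
        clf.intercept_ = np.asarray([c["intercept"]])
        clf.scaler_mean_ = np.asarray(c["scaler_mean"])
        clf.scaler_scale_ = np.asarray(c["scaler_scale"])
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = len(c["coef"])
        clf.cv_results_ = {}
        return cls(
            target=payload["target"],
            feature_config=fc,
            classifier=clf,
            feature_names=payload["feature_names"],
            cv_auc=payload.get("cv_auc", float("nan")),
            feature_version=payload.get("feature_version", FEATURE_VERSION),
        )


def train_day_model(
    daily: pd.DataFrame,
    cycles: pd.DataFrame,
    target: str,
    truth: Optional[pd.DataFrame] = None,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    smooth_windows: Sequence[int] = DEFAULT_SMOOTH_WINDOWS,
    Cs: Sequence[float] = DEFAULT_CS,
    use_calendar: Optional[bool] = None,
    use_hrv: Optional[bool] = None,
    threshold: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
) -> TrainedDayModel:
    """Full hyperparameter search and fit for one prediction target.

    For every (window, smoothing) candidate the feature matrix is rebuilt
    and every L2 strength is scored by participant-grouped fivefold CV AUC;
    the best triple refits on all training data. ``use_calendar`` defaults
    to ON for the menses target and OFF for the fertile target, so fertile
    prediction stays physiology-driven; ``use_hrv`` defaults to the opposite
    pattern (HRV channels for fertile only). Deterministic given ``seed``.
    """
    target = target.lower()
    if use_calendar is None:
        use_calendar = target == "menses"
    if use_hrv is None:
        # HRV channels add a small but CV-consistent gain for the
        # physiology-only fertile model; the calendar-driven menses model
        # gains nothing from them
        use_hrv = target == "fertile"

    search_results = []
    best = None
    for w in windows:
        for sw in smooth_windows:
            fc = FeatureConfig(
                window=w, smooth_window=sw, use_calendar=use_calendar, use_hrv=use_hrv
            )
            X, y, groups, _ = build_training_matrix(daily, cycles, target, fc, truth=truth)
            if len(np.unique(y)) < 2:
                continue
            cv = GroupKFold(n_splits=min(n_folds, len(np.unique(groups))))
            for C in Cs:
                fold_aucs = []
                for tr, va in cv.split(X, y, groups):
                    if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                        continue
                    sc = StandardScaler().fit(X[tr])
                    est = LogisticRegression(
                        C=C, solver="lbfgs", max_iter=2000,
                        class_weight="balanced", random_state=seed,
                    ).fit(sc.transform(X[tr]), y[tr])
                    prob = est.predict_proba(sc.transform(X[va]))[:, 1]
                    fold_aucs.append(roc_auc_score(y[va], prob))
                mean_auc = float(np.mean(fold_aucs)) if fold_aucs else -np.inf
                entry = {"window": w, "smooth_window": sw, "C": C, "cv_auc": mean_auc}
                search_results.append(entry)
                if best is None or mean_auc > best["cv_auc"]:
                    best = entry
    if best is None:
        raise ValueError("hyperparameter search found no valid configuration")

    fc = FeatureConfig(
        window=best["window"], smooth_window=best["smooth_window"],
        use_calendar=use_calendar, use_hrv=use_hrv,
    )
    X, y, groups, _ = build_training_matrix(daily, cycles, target, fc, truth=truth)
    clf = DayProbabilityClassifier(
        Cs=(best["C"],), threshold=threshold, random_state=seed
    ).fit(X, y, groups)
    return TrainedDayModel(
        target=target,
        feature_config=fc,
        classifier=clf,
        feature_names=fc.feature_names(),
        cv_auc=best["cv_auc"],
        search_results=search_results,
    )
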