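"""Switch-point detection, day features, leakage guards, and the day classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclesense import (
    DayProbabilityClassifier,
    FeatureConfig,
    build_training_matrix,
    classify_day,
    detect_switch_point,
    extract_day_features,
    predict_day_probability,
)
from cyclesense.model import TrainedDayModel, train_day_model
from cyclesense.preprocess import preprocess_cohort


def brute_force_switch(values, min_segment):
    """Independent exhaustive-split oracle (naive double loop)."""
    n = len(values)
    if n < 2 * min_segment:
        return None
    best = None
    for k in range(min_segment, n - min_segment + 1):
        pre = sum(values[:k]) / k
        post = sum(values[k:]) / (n - k)
        delta = post - pre
        if best is None or abs(delta) >= abs(best[1]):
            best = (k, delta)
    return best


class TestSwitchPoint:
    def test_clean_step_found_with_full_delta(self):
        k, delta = detect_switch_point([0, 0, 0, 1, 1, 1], min_segment=2)
        assert (k, delta) == (3, 1.0)

    def test_constant_series_ties_break_late(self):
        k, delta = detect_switch_point([5.0] * 8, min_segment=2)
        assert delta == 0.0
        assert k == 6  # latest admissible split

    def test_too_short_returns_none(self):
        assert detect_switch_point([1.0, 2.0, 3.0], min_segment=2) is None

    def test_matches_oracle_on_all_binary_series_up_to_length_10(self):
        for n in range(4, 11):
            for bits in itertools.product((0.0, 1.0), repeat=n):
                assert detect_switch_point(bits, 2) == brute_force_switch(bits, 2)

    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=20), st.integers(2, 3))
    @settings(max_examples=300, deadline=None)
    def test_matches_oracle_on_real_series(self, values, min_segment):
        got = detect_switch_point(values, min_segment)
        want = brute_force_switch(values, min_segment)
        if want is None:
            assert got is None
        else:
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1], abs=1e-9)


def _history_frame(bbt, hr=None, menses=None):
    n = len(bbt)
    return pd.DataFrame(
        {
            "bbt": bbt,
            "hr": hr if hr is not None else [62.0] * n,
            "menses": menses if menses is not None else [False] * n,
        }
    )


class TestDayFeatures:
    def test_constant_history_gives_zero_shape_features(self):
        cfg = FeatureConfig(window=14, smooth_window=1)
        feats = extract_day_features(_history_frame([36.5] * 10), cfg)
        names = cfg.feature_names()
        vec = dict(zip(names, feats))
        for s in ("bbt", "hr"):
            assert vec[f"recent3_mean_delta_{s}"] == 0.0
            assert vec[f"last_z_{s}"] == 0.0
            assert vec[f"switch_delta_{s}"] == 0.0
            assert vec[f"trailing_slope_{s}"] == pytest.approx(0.0)
        assert vec["completeness"] == 1.0

    def test_step_three_days_ago_detected(self):
        cfg = FeatureConfig(window=14, smooth_window=1)
        feats = extract_day_features(_history_frame([36.5] * 7 + [36.7] * 3), cfg)
        vec = dict(zip(cfg.feature_names(), feats))
        assert vec["recent3_mean_delta_bbt"] == pytest.approx(0.2)
        assert vec["days_since_switch_bbt"] == 3.0
        assert vec["switch_delta_bbt"] == pytest.approx(0.2)

    def test_insufficient_history_unavailable(self):
        cfg = FeatureConfig(min_history=7)
        assert extract_day_features(_history_frame([36.5] * 5), cfg) is None

    def test_missing_value_in_window_unavailable(self):
        cfg = FeatureConfig(window=10, min_history=7)
        bbt = [36.5] * 9 + [np.nan]
        assert extract_day_features(_history_frame(bbt), cfg) is None

    def test_calendar_feature_counts_days_since_onset(self):
        cfg = FeatureConfig(window=14, smooth_window=1, use_calendar=True)
        menses = [True, True, False, False, False, False, False, False]
        feats = extract_day_features(_history_frame([36.5] * 8, menses=menses), cfg)
        vec = dict(zip(cfg.feature_names(), feats))
        assert vec["days_since_menses_onset"] == 8.0

    def test_no_leakage_future_deletion_is_noop(self, small_cohort):
        cohort, _ = small_cohort
        clean = preprocess_cohort(cohort)
        daily = clean.records[clean.records["participant_id"] == "R001"].reset_index(drop=True)
        cfg = FeatureConfig()
        t_pos = 20
        full = extract_day_features(daily.iloc[:t_pos], cfg)
        truncated_world = daily.iloc[:t_pos]  # all records on/after day t deleted
        again = extract_day_features(truncated_world, cfg)
        np.testing.assert_array_equal(full, again)


class TestTrainingMatrix:
    def test_row_and_positive_counts_for_known_cycle(self, noise_free_cohort):
        cohort, truth = noise_free_cohort
        clean = preprocess_cohort(cohort)
        pid = "R001"
        daily = clean.records[clean.records["participant_id"] == pid]
        cycles = clean.cycles[clean.cycles["participant_id"] == pid]
        cfg = FeatureConfig(min_history=7)
        X, y, groups, meta = build_training_matrix(daily, cycles, "fertile", cfg, truth=truth)
        n_days = cycles["length"].sum()
        assert len(y) == n_days - cfg.min_history
        per_cycle = meta.groupby("cycle_index").size()
        assert len(per_cycle) == len(cycles)
        # every cycle carries a 6-day fertile window; only the first can lose
        # window days to the history guard
        fertile_per_cycle = pd.Series(y).groupby(meta["cycle_index"]).sum()
        assert (fertile_per_cycle.iloc[1:] == 6).all()
        assert 0 <= fertile_per_cycle.iloc[0] <= 6

    def test_menses_target_positive_count(self, noise_free_cohort):
        cohort, truth = noise_free_cohort
        clean = preprocess_cohort(cohort)
        pid = "R001"
        daily = clean.records[clean.records["participant_id"] == pid]
        cycles = clean.cycles[clean.cycles["participant_id"] == pid]
        X, y, groups, meta = build_training_matrix(
            daily, cycles, "menses", FeatureConfig(), truth=truth
        )
        counts = pd.Series(y).groupby(meta["cycle_index"]).sum()
        durations = cycles.set_index("cycle_index")["menses_duration"]
        # cycle 1 loses its first min_history days (all menstrual or early)
        for ci in counts.index[1:]:
            assert counts[ci] == durations[ci]

    def test_unqualified_cycles_excluded(self, noise_free_cohort):
        cohort, truth = noise_free_cohort
        clean = preprocess_cohort(cohort)
        cycles = clean.cycles.copy()
        cycles["qualified"] = False
        with pytest.raises(ValueError):
            build_training_matrix(clean.records, cycles, "fertile", truth=truth)


class TestDayClassifier:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += y * 3.0
        groups = np.repeat(np.arange(10), n // 10)
        return X, y, groups

    def test_separable_training_auc_is_one(self):
        from cyclesense.evaluate import roc_auc

        X, y, groups = self._separable()
        clf = DayProbabilityClassifier(Cs=(10.0,)).fit(X, y, groups)
        _, auc = roc_auc(clf.predict_proba(X)[:, 1], y)
        assert auc == 1.0

    def test_permuted_labels_give_chance_cv_auc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 5))
        y = rng.integers(0, 2, size=2000)
        groups = np.repeat(np.arange(20), 100)
        clf = DayProbabilityClassifier(Cs=(0.1, 1.0)).fit(X, y, groups)
        mean_auc = np.mean(list(clf.cv_results_.values()))
        assert 0.45 <= mean_auc <= 0.55

    def test_same_seed_identical_weights(self):
        X, y, groups = self._separable(seed=5)
        c1 = DayProbabilityClassifier(random_state=3).fit(X, y, groups)
        c2 = DayProbabilityClassifier(random_state=3).fit(X, y, groups)
        np.testing.assert_array_equal(c1.coef_, c2.coef_)
        assert c1.best_C_ == c2.best_C_

    def test_single_class_labels_raise(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="one class"):
            DayProbabilityClassifier().fit(X, np.zeros(10))

    def test_feature_length_mismatch_raises(self):
        X, y, groups = self._separable()
        clf = DayProbabilityClassifier(Cs=(1.0,)).fit(X, y, groups)
        with pytest.raises(ValueError, match="mismatch"):
            clf.predict_proba(np.zeros((1, 7)))


class TestProbabilityAndThreshold:
    def _manual_model(self, coef, intercept):
        clf = DayProbabilityClassifier()
        clf.coef_ = np.asarray([coef])
        clf.intercept_ = np.asarray([intercept])
        clf.scaler_mean_ = np.zeros(len(coef))
        clf.scaler_scale_ = np.ones(len(coef))
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = len(coef)
        return clf

    def test_zero_weights_give_half(self):
        clf = self._manual_model([0.0, 0.0], 0.0)
        assert predict_day_probability(clf, [5.0, -3.0]) == pytest.approx(0.5)

    def test_intercept_ln3_gives_three_quarters(self):
        clf = self._manual_model([0.0], float(np.log(3.0)))
        assert predict_day_probability(clf, [0.0]) == pytest.approx(0.75)

    def test_probability_monotone_in_score(self):
        clf = self._manual_model([1.0], 0.0)
        probs = [predict_day_probability(clf, [x]) for x in np.linspace(-20, 20, 9)]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 1 - 1e-8

    @pytest.mark.parametrize(
        "prob,threshold,expected",
        [(0.6, 0.5, True), (0.5, 0.5, True), (0.49, 0.5, False)],
    )
    def test_threshold_rule_inclusive(self, prob, threshold, expected):
        assert classify_day(prob, threshold) is expected


class TestTrainDayModel:
    def test_serialization_round_trip_preserves_predictions(self, small_cohort):
        cohort, truth = small_cohort
        clean = preprocess_cohort(cohort)
        reg = clean.participants.loc[
            clean.participants["group"] == "REGULAR", "participant_id"
        ].tolist()
        daily = clean.records[clean.records["participant_id"].isin(reg)]
        cycles = clean.cycles[clean.cycles["participant_id"].isin(reg)]
        model = train_day_model(
            daily, cycles, "menses", truth=truth,
            windows=(10,), smooth_windows=(3,), Cs=(1.0,), seed=2,
        )
        back = TrainedDayModel.from_json(model.to_json())
        p1 = model.predict_days(daily, reg[:2])
        p2 = back.predict_days(daily, reg[:2])
        pd.testing.assert_frame_equal(p1, p2)

    def test_deterministic_given_seed(self, small_cohort):
        cohort, truth = small_cohort
        clean = preprocess_cohort(cohort)
        daily, cycles = clean.records, clean.cycles
        kw = dict(windows=(7,), smooth_windows=(3,), Cs=(0.1, 1.0), seed=4, truth=truth)
        m1 = train_day_model(daily, cycles, "fertile", **kw)
        m2 = train_day_model(daily, cycles, "fertile", **kw)
        np.testing.assert_array_equal(m1.classifier.coef_, m2.classifier.coef_)
        assert m1.cv_auc == m2.cv_auc
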