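"""Generator: pmf calibration, cycle structure, phase-mean fidelity, missingness."""

import numpy as np
import pandas as pd
import pytest

from cyclesense import (
    GeneratorConfig,
    Group,
    calibrate_length_pmf,
    generate_cohort,
    generate_intranight,
    inject_missingness,
    sample_cycle_structure,
    simulate_night_signals,
)
from cyclesense.data import ConfigError, PhaseLabel, label_phases
from cyclesense.simulate import (
    SIGNALS,
    empirical_quantile_lower_nearest,
    quantile_lower_nearest,
    verify_pmf_quantiles,
)


class TestLengthPmf:
    def test_default_regular_pmf_hits_quartile_targets(self):
        pmf = GeneratorConfig().regular_length_pmf
        # exhaustive cumulative-sum check (the brute-force oracle)
        cum, cdf = 0.0, {}
        for day in sorted(pmf):
            cum += pmf[day]
            cdf[day] = cum
        q = lambda p: min(d for d, c in cdf.items() if c >= p - 1e-12)
        assert (q(0.25), q(0.5), q(0.75)) == (28, 29, 32)

    def test_calibrated_irregular_pmf_passes_cdf_check(self):
        pmf = calibrate_length_pmf(33, 27, 40, (20, 60))
        assert verify_pmf_quantiles(pmf, 33, 27, 40)
        assert min(pmf) < 25 and max(pmf) > 35

    @pytest.mark.parametrize(
        "median,q1,q3,support",
        [(29, 28, 32, (25, 35)), (33, 27, 40, (20, 50)), (30, 30, 30, (25, 35))],
    )
    def test_calibration_verified_for_varied_targets(self, median, q1, q3, support):
        pmf = calibrate_length_pmf(median, q1, q3, support)
        assert verify_pmf_quantiles(pmf, median, q1, q3)
        assert abs(sum(pmf.values()) - 1.0) < 1e-9

    def test_infeasible_targets_raise(self):
        with pytest.raises(ConfigError):
            calibrate_length_pmf(30, 31, 32, (25, 35))


class TestCycleStructure:
    def test_regular_lengths_stay_in_band(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        for _ in range(200):
            ann = sample_cycle_structure(cfg, Group.REGULAR, rng)
            assert 25 <= ann.length <= 35
            assert 1 <= ann.menses_duration < ann.length
            assert 1 <= ann.ovulation_day <= ann.length

    def test_large_sample_quantiles_match_study(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(1)
        reg = np.array(
            [sample_cycle_structure(cfg, Group.REGULAR, rng).length for _ in range(10000)]
        )
        assert empirical_quantile_lower_nearest(reg, 0.5) == 29
        assert empirical_quantile_lower_nearest(reg, 0.25) == 28
        assert empirical_quantile_lower_nearest(reg, 0.75) == 32

    def test_luteal_anchored_ovulation_arithmetic(self):
        # length 29 and a forced luteal length of 14 puts ovulation on day 15
        cfg = GeneratorConfig(luteal_mean=14.0, luteal_sd=1e-9, luteal_bounds=(13.9, 14.1))
        rng = np.random.default_rng(0)
        ann = sample_cycle_structure(cfg, Group.REGULAR, rng)
        assert ann.ovulation_day == ann.length - 14


class TestNightSignals:
    def _noise_free_config(self, **kw):
        zero = {s: 0.0 for s in SIGNALS}
        return GeneratorConfig(
            sigma_participant=dict(zero), sigma_cycle=dict(zero), sigma_night=dict(zero),
            nadir_depth=0.0, ramp_days=0, p_missing_wearable=0.0, p_missing_bbt=0.0, **kw
        )

    def test_noise_free_phase_means_are_exact(self, annotation_29):
        cfg = self._noise_free_config()
        rng = np.random.default_rng(0)
        recs = simulate_night_signals(annotation_29, {s: 0.0 for s in SIGNALS}, cfg, rng)
        labels = [lab.value for lab in label_phases(annotation_29)]
        recs["phase"] = labels
        mens_bbt = recs.loc[recs["phase"] == "MENSTRUAL", "bbt"]
        lut_bbt = recs.loc[recs["phase"] == "LUTEAL", "bbt"]
        diffs = lut_bbt.values[:, None] - mens_bbt.values[None, :]
        assert np.allclose(diffs, 0.19)
        lut_hr = recs.loc[recs["phase"] == "LUTEAL", "hr"]
        mens_hr = recs.loc[recs["phase"] == "MENSTRUAL", "hr"]
        assert np.allclose(lut_hr.values[:, None] - mens_hr.values[None, :], 2.69)

    def test_hrv_generated_on_log_scale(self, annotation_29):
        cfg = self._noise_free_config()
        rng = np.random.default_rng(0)
        recs = simulate_night_signals(annotation_29, {s: 0.0 for s in SIGNALS}, cfg, rng)
        labels = label_phases(annotation_29)
        ln_sdnn = np.log(recs["sdnn"])
        for i, lab in enumerate(labels):
            b = 0.0 if lab is PhaseLabel.MENSTRUAL else cfg.beta["ln_sdnn"][lab.value]
            assert ln_sdnn.iloc[i] == pytest.approx(4.80 + b)

    def test_nadir_dips_bbt_day_before_ovulation(self, annotation_29):
        cfg = self._noise_free_config()
        cfg.nadir_depth = 0.05
        rng = np.random.default_rng(0)
        recs = simulate_night_signals(annotation_29, {s: 0.0 for s in SIGNALS}, cfg, rng)
        ov = annotation_29.ovulation_day
        fertile_bbt = 36.63 + 0.01
        assert recs["bbt"].iloc[ov - 2] == pytest.approx(fertile_bbt - 0.05)
        assert recs["bbt"].iloc[ov - 3] == pytest.approx(fertile_bbt)

    def test_menses_flag_matches_menstrual_days(self, annotation_29):
        cfg = self._noise_free_config()
        rng = np.random.default_rng(0)
        recs = simulate_night_signals(annotation_29, {s: 0.0 for s in SIGNALS}, cfg, rng)
        assert recs["menses"].tolist() == [
            lab is PhaseLabel.MENSTRUAL for lab in label_phases(annotation_29)
        ]


class TestMissingness:
    def _records(self, n=10000):
        dates = pd.date_range("2021-01-01", periods=n)
        return pd.DataFrame(
            {
                "participant_id": "P1", "date": dates, "bbt": 36.6, "hr": 62.0,
                "sdnn": 120.0, "lf_hf": 0.6, "menses": False, "synced": True,
            }
        )

    def test_zero_rates_are_identity(self):
        recs = self._records(100)
        cfg = GeneratorConfig(p_missing_wearable=0.0, p_missing_bbt=0.0)
        out = inject_missingness(recs, cfg, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, recs)

    def test_rate_one_clears_all_wearable_nights(self):
        recs = self._records(50)
        cfg = GeneratorConfig(p_missing_wearable=1.0)
        out = inject_missingness(recs, cfg, np.random.default_rng(0))
        assert (~out["synced"]).all()
        assert out["hr"].isna().all()

    def test_missing_fraction_within_binomial_bounds(self):
        recs = self._records(10000)
        cfg = GeneratorConfig(p_missing_wearable=0.05)
        out = inject_missingness(recs, cfg, np.random.default_rng(3))
        frac = 1.0 - out["synced"].mean()
        sd = np.sqrt(0.05 * 0.95 / 10000)
        assert abs(frac - 0.05) < 3 * sd


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        cfg = GeneratorConfig(n_regular=4, n_irregular=2, seed=11)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(GeneratorConfig(n_regular=4, n_irregular=2, seed=11))
        pd.testing.assert_frame_equal(c1.records, c2.records)
        pd.testing.assert_frame_equal(c1.cycles, c2.cycles)
        pd.testing.assert_frame_equal(t1, t2)

    def test_default_cohort_sizes(self, small_cohort):
        cohort, _ = small_cohort
        groups = cohort.participants.groupby("group")["participant_id"].nunique()
        assert groups["REGULAR"] == 10 and groups["IRREGULAR"] == 3

    def test_cycles_per_participant_in_range_and_contiguous(self, small_cohort):
        cohort, _ = small_cohort
        for pid, grp in cohort.cycles.groupby("participant_id"):
            assert len(grp) in (3, 4)
            grp = grp.sort_values("cycle_index")
            starts = pd.to_datetime(grp["start_date"]).tolist()
            lengths = grp["length"].tolist()
            for i in range(1, len(starts)):
                assert starts[i] == starts[i - 1] + pd.Timedelta(days=lengths[i - 1])

    def test_truth_labels_cover_every_cycle_day(self, small_cohort):
        cohort, truth = small_cohort
        assert len(truth) == cohort.cycles["length"].sum()


class TestIntranight:
    def test_edges_elevated_interior_centered(self):
        rng = np.random.default_rng(5)
        interior_means, edge_means = [], []
        for _ in range(30):
            s = generate_intranight(62.0, GeneratorConfig(), rng)
            n = len(s)
            assert 200 <= n <= 540
            edge_means.append(np.mean(np.r_[s[:30], s[n - 30:]]))
            interior_means.append(s[30 : n - 30].mean())
        assert np.mean(interior_means) == pytest.approx(62.0, abs=0.5)
        assert np.mean(edge_means) == pytest.approx(70.0, abs=1.0)
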