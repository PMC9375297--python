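"""Synthetic cohort generator for nightly cycle physiology.

Emulates a wearable study cohort: regular and irregular menstruators, 3-4
cycles each, nightly BBT/HR/SDNN/LF-HF with additive phase effects, nested
participant and cycle random intercepts, a pre-ovulatory BBT nadir, a
sigmoidal post-ovulatory rise, and realistic missingness. Cycle-length
distributions are discrete pmfs calibrated to target median/IQR under the
lower-nearest inverse-CDF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortTable, ConfigError, CycleAnnotation, Group, PhaseLabel, label_phases

SIGNALS = ("bbt", "hr", "ln_sdnn", "ln_lfhf")

MENSES_DURATION_PMF: Dict[int, float] = {4: 0.10, 5: 0.22, 6: 0.33, 7: 0.22, 8: 0.13}


def quantile_lower_nearest(pmf: Dict[int, float], q: float) -> int:
    """Smallest support point whose cumulative probability reaches q."""
    cum = 0.0
    for x in sorted(pmf):
        cum += pmf[x]
        if cum >= q - 1e-12:
            return x
    return max(pmf)


def empirical_quantile_lower_nearest(samples: np.ndarray, q: float) -> int:
    """Lower-nearest inverse-CDF quantile of an integer sample."""
    values, counts = np.unique(np.asarray(samples), return_counts=True)
    cum = np.cumsum(counts) / counts.sum()
    return int(values[np.searchsorted(cum, q - 1e-12)])


def verify_pmf_quantiles(
    pmf: Dict[int, float], median: int, q1: int, q3: int
) -> bool:
    """Exhaustive cumulative-sum check of the three quartile targets."""
    total = sum(pmf.values())
    if abs(total - 1.0) > 1e-9 or any(p < 0 for p in pmf.values()):
        return False
    return (
        quantile_lower_nearest(pmf, 0.25) == q1
        and quantile_lower_nearest(pmf, 0.50) == median
        and quantile_lower_nearest(pmf, 0.75) == q3
    )


def calibrate_length_pmf(
    target_median: int, target_q1: int, target_q3: int, support: Tuple[int, int]
) -> Dict[int, float]:
    """Build a pmf on integer ``support`` hitting the quartile targets.

    Mass is spread uniformly within the four segments ending at q1, median,
    q3 and the support maximum, with segment-end cumulative probabilities
    placed just past each quartile (0.27/0.52/0.77) so the lower-nearest
    inverse CDF lands exactly on the targets. The result is verified by the
    exhaustive cumulative-sum check before being returned.
    """
    lo, hi = support
    if not (lo <= target_q1 <= target_median <= target_q3 <= hi):
        raise ConfigError(
            f"infeasible quartile targets ({target_q1}, {target_median}, "
            f"{target_q3}) for support [{lo}, {hi}]"
        )
    knots = [
        (target_q1, 0.27, 0.25),
        (target_median, 0.52, 0.50),
        (target_q3, 0.77, 0.75),
        (hi, 1.0, None),
    ]
    # merge coincident knots: largest cumulative target, smallest quartile level
    merged: list[list] = []
    for x, c, q in knots:
        if merged and merged[-1][0] == x:
            merged[-1][1] = max(merged[-1][1], c)
            qs = [v for v in (merged[-1][2], q) if v is not None]
            merged[-1][2] = min(qs) if qs else None
        else:
            merged.append([x, c, q])
    pmf: Dict[int, float] = {}
    prev_x, prev_c = lo - 1, 0.0
    for x, c, q in merged:
        interior = range(prev_x + 1, x)
        if q is None:
            # terminal knot: spread the remaining mass evenly up to hi
            p = (c - prev_c) / (x - prev_x)
            for day in range(prev_x + 1, x + 1):
                pmf[day] = pmf.get(day, 0.0) + p
        else:
            # keep the CDF strictly below the quartile level until x itself
            t = max(prev_c, q - 0.02) if len(interior) else prev_c
            if len(interior):
                p = (t - prev_c) / len(interior)
                for day in interior:
                    pmf[day] = pmf.get(day, 0.0) + p
            pmf[x] = pmf.get(x, 0.0) + (c - t)
        prev_x, prev_c = x, c
    if not verify_pmf_quantiles(pmf, target_median, target_q1, target_q3):
        raise ConfigError(
            "calibration failed the exhaustive CDF check for targets "
            f"({target_q1}, {target_median}, {target_q3}) on [{lo}, {hi}]"
        )
    return pmf


def default_regular_pmf() -> Dict[int, float]:
    """Regular-group pmf: median 29, IQR 28-32 on the 25-35 day band.

    Produced by the calibration routine, which leaves a 0.02 cumulative-mass
    margin past each quartile so finite-sample quantile estimates are stable.
    """
    return calibrate_length_pmf(29, 28, 32, (25, 35))


def default_irregular_pmf() -> Dict[int, float]:
    """Irregular-group pmf: median 33, IQR 27-40, support beyond 25-35."""
    return calibrate_length_pmf(33, 27, 40, (20, 50))


@dataclass
class GeneratorConfig:
    """Everything that seeds the simulator.

    Population means and phase effects default to the regular-group fitted
    values (menstrual phase as reference); variance components are split
    across participant, cycle-within-participant, and night levels.
    """

    n_regular: int = 89
    n_irregular: int = 25
    cycles_min: int = 3
    cycles_max: int = 4
    regular_length_pmf: Dict[int, float] = field(default_factory=default_regular_pmf)
    irregular_length_pmf: Dict[int, float] = field(default_factory=default_irregular_pmf)
    menses_duration_pmf: Dict[int, float] = field(
        default_factory=lambda: dict(MENSES_DURATION_PMF)
    )
    luteal_mean: float = 13.6
    luteal_sd: float = 1.2
    luteal_bounds: Tuple[float, float] = (11.0, 16.0)
    mu: Dict[str, float] = field(
        default_factory=lambda: {"bbt": 36.63, "hr": 62.50, "ln_sdnn": 4.80, "ln_lfhf": -0.55}
    )
    beta: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "bbt": {"FOLLICULAR": -0.03, "FERTILE": 0.01, "LUTEAL": 0.19},
            "hr": {"FOLLICULAR": 0.23, "FERTILE": 0.84, "LUTEAL": 2.69},
            "ln_sdnn": {"FOLLICULAR": 0.00, "FERTILE": -0.04, "LUTEAL": -0.10},
            "ln_lfhf": {"FOLLICULAR": 0.02, "FERTILE": 0.05, "LUTEAL": 0.05},
        }
    )
    sigma_participant: Dict[str, float] = field(
        default_factory=lambda: {"bbt": 0.15, "hr": 4.0, "ln_sdnn": 0.15, "ln_lfhf": 0.15}
    )
    sigma_cycle: Dict[str, float] = field(
        default_factory=lambda: {"bbt": 0.05, "hr": 1.0, "ln_sdnn": 0.05, "ln_lfhf": 0.05}
    )
    sigma_night: Dict[str, float] = field(
        default_factory=lambda: {"bbt": 0.12, "hr": 1.5, "ln_sdnn": 0.20, "ln_lfhf": 0.20}
    )
    nadir_depth: float = 0.05  # deg C dip at ovulation_day - 1 (BBT only)
    ramp_days: int = 2  # sigmoidal BBT/HR rise after ovulation instead of a step
    p_missing_wearable: float = 0.05
    p_missing_bbt: float = 0.07
    seed: int = 0

    def validate(self) -> None:
        for name, pmf in (
            ("regular_length_pmf", self.regular_length_pmf),
            ("irregular_length_pmf", self.irregular_length_pmf),
            ("menses_duration_pmf", self.menses_duration_pmf),
        ):
            if abs(sum(pmf.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} does not sum to 1")
            if any(p < 0 for p in pmf.values()):
                raise ConfigError(f"{name} has negative mass")
        for d in (self.sigma_participant, self.sigma_cycle, self.sigma_night):
            if any(v < 0 for v in d.values()):
                raise ConfigError("negative standard deviation")
        for p in (self.p_missing_wearable, self.p_missing_bbt):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("missingness probability outside [0, 1]")


def _draw_pmf(pmf: Dict[int, float], rng: np.random.Generator, size=None):
    xs = np.array(sorted(pmf))
    ps = np.array([pmf[x] for x in xs], dtype=float)
    ps = ps / ps.sum()
    return rng.choice(xs, size=size, p=ps)


def sample_cycle_structure(
    config: GeneratorConfig,
    group: Group,
    rng: np.random.Generator,
    participant_id: str = "P",
    cycle_index: int = 1,
    start_date: Optional[pd.Timestamp] = None,
) -> CycleAnnotation:
    """Draw one cycle: length, menses duration, and luteal-anchored ovulation.

    The ovulation day is length minus a truncated-normal luteal length
    (mean 13.6 d, sd 1.2, bounds 11-16), clamped to day 1; long irregular
    cycles therefore get long follicular phases, matching physiology.
    """
    pmf = (
        config.regular_length_pmf if group is Group.REGULAR else config.irregular_length_pmf
    )
    length = int(_draw_pmf(pmf, rng))
    menses = int(_draw_pmf(config.menses_duration_pmf, rng))
    menses = min(menses, length - 1)
    lo, hi = config.luteal_bounds
    a, b = (lo - config.luteal_mean) / config.luteal_sd, (hi - config.luteal_mean) / config.luteal_sd
    luteal = stats.truncnorm.rvs(a, b, loc=config.luteal_mean, scale=config.luteal_sd,
                                 random_state=rng)
    ovulation = max(1, length - int(round(luteal)))
    return CycleAnnotation(
        participant_id=participant_id,
        cycle_index=cycle_index,
        start_date=start_date if start_date is not None else pd.Timestamp("2021-01-01"),
        length=length,
        menses_duration=menses,
        ovulation_day=ovulation,
        qualified=True,
    )


def _ramp_weights(ramp_days: int) -> np.ndarray:
    """Logistic weights for the post-ovulation rise; 0 < w < 1, increasing."""
    if ramp_days <= 0:
        return np.empty(0)
    j = np.arange(1, ramp_days + 1, dtype=float)
    x = 6.0 * (j - (ramp_days + 1) / 2.0) / (ramp_days + 1)
    return 1.0 / (1.0 + np.exp(-x))


def simulate_night_signals(
    annotation: CycleAnnotation,
    participant_effects: Dict[str, float],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate one cycle of nightly records (before missingness injection).

    Each signal on each day is mean + phase effect + participant intercept +
    cycle intercept + waveform shape + nightly Gaussian noise. SDNN and the
    LF/HF ratio are generated on the natural-log scale and exponentiated.
    The BBT waveform dips by ``nadir_depth`` the day before ovulation, and
    the BBT/HR fertile-to-luteal step is replaced by a sigmoidal ramp over
    ``ramp_days`` days so the biphasic transition is not an exact step.
    """
    labels = label_phases(annotation)
    n = annotation.length
    ov = annotation.ovulation_day
    cycle_effects = {s: rng.normal(0.0, config.sigma_cycle[s]) for s in SIGNALS}
    ramp_w = _ramp_weights(config.ramp_days)

    values: Dict[str, np.ndarray] = {}
    for s in SIGNALS:
        beta = config.beta[s]
        base = np.empty(n)
        for i, lab in enumerate(labels):
            b = 0.0 if lab is PhaseLabel.MENSTRUAL else beta[lab.value]
            base[i] = config.mu[s] + b
        shape = np.zeros(n)
        if s == "bbt" and ov is not None and 2 <= ov <= n:
            shape[ov - 2] -= config.nadir_depth  # day ov-1, 0-based index ov-2
        if s in ("bbt", "hr") and ov is not None:
            step = beta["LUTEAL"] - beta["FERTILE"]
            for j, w in enumerate(ramp_w, start=1):
                day = ov + j  # 1-based luteal day
                if day <= n and labels[day - 1] is PhaseLabel.LUTEAL:
                    shape[day - 1] -= (1.0 - w) * step
        noise = rng.normal(0.0, config.sigma_night[s], size=n)
        values[s] = base + participant_effects[s] + cycle_effects[s] + shape + noise

    dates = pd.date_range(annotation.start_date, periods=n, freq="D")
    return pd.DataFrame(
        {
            "participant_id": annotation.participant_id,
            "date": dates,
            "bbt": values["bbt"],
            "hr": values["hr"],
            "sdnn": np.exp(values["ln_sdnn"]),
            "lf_hf": np.exp(values["ln_lfhf"]),
            "menses": [lab is PhaseLabel.MENSTRUAL for lab in labels],
            "synced": True,
        }
    )


def inject_missingness(
    records: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Independently drop wearable nights and BBT readings.

    Each night: with ``p_missing_wearable`` the band did not sync (hr, sdnn,
    lf_hf cleared, synced=False); with ``p_missing_bbt`` the thermometer
    reading is absent. The menses flag is never missing (self-report).
    """
    out = records.copy()
    n = len(out)
    drop_wear = rng.random(n) < config.p_missing_wearable
    drop_bbt = rng.random(n) < config.p_missing_bbt
    out.loc[drop_wear, ["hr", "sdnn", "lf_hf"]] = np.nan
    out.loc[drop_wear, "synced"] = False
    out.loc[drop_bbt, "bbt"] = np.nan
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Generate the full cohort plus noiseless truth phase labels.

    Returns (cohort, truth) where ``truth`` has one row per participant-day
    with the generating phase label and day-of-cycle. Deterministic given
    ``config.seed``; consecutive cycles of a participant are contiguous.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    all_records, all_cycles, truth_rows, participants = [], [], [], []

    def make_participant(pid: str, group: Group, age: float) -> None:
        participants.append({"participant_id": pid, "group": group.value, "age": age})
        effects = {s: rng.normal(0.0, config.sigma_participant[s]) for s in SIGNALS}
        n_cycles = int(rng.integers(config.cycles_min, config.cycles_max + 1))
        start = pd.Timestamp("2021-01-01")
        for ci in range(1, n_cycles + 1):
            ann = sample_cycle_structure(config, group, rng, pid, ci, start)
            recs = simulate_night_signals(ann, effects, config, rng)
            recs = inject_missingness(recs, config, rng)
            all_records.append(recs)
            all_cycles.append(
                {
                    "participant_id": pid,
                    "cycle_index": ci,
                    "start_date": ann.start_date,
                    "length": ann.length,
                    "menses_duration": ann.menses_duration,
                    "ovulation_day": ann.ovulation_day,
                    "qualified": True,
                    "group": group.value,
                }
            )
            labels = label_phases(ann)
            for d, lab in enumerate(labels, start=1):
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "date": ann.start_date + pd.Timedelta(days=d - 1),
                        "cycle_index": ci,
                        "day_of_cycle": d,
                        "phase": lab.value,
                    }
                )
            start = ann.start_date + pd.Timedelta(days=ann.length)

    for i in range(config.n_regular):
        age = float(np.clip(rng.normal(30.5, 4.0), 20, 45))
        make_participant(f"R{i + 1:03d}", Group.REGULAR, round(age, 1))
    for i in range(config.n_irregular):
        age = float(np.clip(rng.normal(28.5, 4.0), 20, 45))
        make_participant(f"I{i + 1:03d}", Group.IRREGULAR, round(age, 1))

    records = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    cohort = CohortTable(
        records=records,
        cycles=pd.DataFrame(all_cycles),
        participants=pd.DataFrame(participants),
    )
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def generate_intranight(
    night_hr: float, config: GeneratorConfig, rng: np.random.Generator
) -> pd.Series:
    """Simulate a 1-minute-resolution sleep HR trace for one night.

    Sleep duration is uniform on [200, 540] minutes; interior minutes follow
    an AR(1) process (rho 0.8, innovation scaled so the marginal sd is 2 bpm)
    around ``night_hr``; the first and last 30 minutes carry a +8 bpm wake
    artifact, which is why edge trimming matters downstream.
    """
    minutes = int(rng.integers(200, 541))
    rho, sd = 0.8, 2.0
    innov_sd = sd * np.sqrt(1 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=minutes)
    x = np.empty(minutes)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, minutes):
        x[i] = rho * x[i - 1] + eps[i]
    trace = night_hr + x
    edge = min(30, minutes // 2)
    trace[:edge] += 8.0
    trace[-edge:] += 8.0
    return pd.Series(np.clip(trace, 30, 150), name="minute_hr")
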