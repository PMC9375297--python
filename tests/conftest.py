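import warnings

import pandas as pd
import pytest

from cyclesense import CohortTable, CycleAnnotation, GeneratorConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*singular fit.*")


@pytest.fixture
def annotation_29():
    """Length-29 cycle, 5 menses days, ovulation on day 15."""
    return CycleAnnotation(
        participant_id="P1",
        cycle_index=1,
        start_date=pd.Timestamp("2021-01-01"),
        length=29,
        menses_duration=5,
        ovulation_day=15,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """10 regular + 3 irregular participants, default signal structure."""
    cfg = GeneratorConfig(n_regular=10, n_irregular=3, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """All variance components, missingness, and waveform shapes zeroed."""
    cfg = GeneratorConfig(
        n_regular=4,
        n_irregular=0,
        sigma_participant={s: 0.0 for s in ("bbt", "hr", "ln_sdnn", "ln_lfhf")},
        sigma_cycle={s: 0.0 for s in ("bbt", "hr", "ln_sdnn", "ln_lfhf")},
        sigma_night={s: 0.0 for s in ("bbt", "hr", "ln_sdnn", "ln_lfhf")},
        nadir_depth=0.0,
        ramp_days=0,
        p_missing_wearable=0.0,
        p_missing_bbt=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


def make_cohort_frame(records_rows, cycles_rows, participants=None) -> CohortTable:
    records = pd.DataFrame(
        records_rows,
        columns=["participant_id", "date", "bbt", "hr", "sdnn", "lf_hf", "menses", "synced"],
    )
    records["date"] = pd.to_datetime(records["date"])
    cycles = pd.DataFrame(
        cycles_rows,
        columns=[
            "participant_id", "cycle_index", "start_date", "length",
            "menses_duration", "ovulation_day", "qualified",
        ],
    )
    if len(cycles):
        cycles["start_date"] = pd.to_datetime(cycles["start_date"])
    return CohortTable(records=records, cycles=cycles, participants=participants)
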