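"""End-to-end orchestration: simulate -> preprocess -> analyze -> train -> evaluate.

One master seed drives every stochastic stage (generation, the participant
split, solver seeds); reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .data import CohortTable, Group
from .evaluate import SplitSpec, evaluate_predictions, split_participants
from .io import write_cohort_dir
from .mixed_model import (
    DEFAULT_CONTRASTS,
    build_long_table,
    fit_phase_lmm,
    pairwise_contrasts,
)
from .model import DEFAULT_CS, DEFAULT_SMOOTH_WINDOWS, DEFAULT_WINDOWS, train_day_model
from .preprocess import QualifyConfig, preprocess_cohort
from .simulate import GeneratorConfig, generate_cohort

OUTCOMES = ("bbt", "hr", "ln_sdnn", "ln_lfhf")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qualify: QualifyConfig = field(default_factory=QualifyConfig)
    n_train_participants: int = 68
    targets: Sequence[str] = ("fertile", "menses")
    windows: Sequence[int] = DEFAULT_WINDOWS
    smooth_windows: Sequence[int] = DEFAULT_SMOOTH_WINDOWS
    Cs: Sequence[float] = DEFAULT_CS
    use_hrv: Optional[bool] = None  # None: per-target default
    threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        qual = QualifyConfig(**raw.pop("qualify", {}))
        return cls(generator=gen, qualify=qual, **raw)


def phase_analysis_report(cohort: CohortTable, truth: Optional[pd.DataFrame] = None) -> dict:
    """Fit the phase LMM for every signal and tabulate the five contrasts."""
    long = build_long_table(cohort, truth=truth)
    report = {}
    for outcome in OUTCOMES:
        res = fit_phase_lmm(long, outcome, reference="MENSTRUAL")
        table = pairwise_contrasts(res, DEFAULT_CONTRASTS)
        report[outcome] = {
            "intercept": res.intercept,
            "intercept_se": res.intercept_se,
            "variance_components": {
                "participant": res.variance_components[0],
                "cycle": res.variance_components[1],
                "residual": res.variance_components[2],
            },
            "n_obs": res.n_obs,
            "n_participants": res.n_participants,
            "n_cycles": res.n_cycles,
            "converged": res.converged,
            "contrasts": table.to_dict(orient="records"),
        }
    return report


def run_pipeline(
    config: PipelineConfig | None = None, out_dir=None
) -> dict:
    """Execute every stage with one master seed; returns all artifacts.

    Stages: cohort generation, preprocessing (imputation, ln transforms,
    qualification), phase LMM analysis, regular-group 68/21 participant
    split, model training on the regular training partition (both targets),
    and day-level evaluation on the regular test partition and on the
    irregular group (regular-trained model). When ``out_dir`` is given,
    cohort CSVs, models, and JSON reports are written there.
    """
    config = config or PipelineConfig()
    master = np.random.SeedSequence(config.seed)
    gen_seed, split_seed, model_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3)
    )

    config.generator.seed = gen_seed
    cohort, truth = generate_cohort(config.generator)
    clean = preprocess_cohort(cohort, config.qualify)

    phase_report = phase_analysis_report(clean, truth=truth)

    regular_ids = sorted(
        clean.participants.loc[
            clean.participants["group"] == Group.REGULAR.value, "participant_id"
        ]
    )
    irregular_ids = sorted(
        clean.participants.loc[
            clean.participants["group"] == Group.IRREGULAR.value, "participant_id"
        ]
    )
    spec = SplitSpec(
        n_train_participants=min(config.n_train_participants, max(len(regular_ids) - 1, 1)),
        n_test_participants=len(regular_ids)
        - min(config.n_train_participants, max(len(regular_ids) - 1, 1)),
        seed=split_seed,
    )
    train_ids, test_ids = split_participants(regular_ids, spec)

    daily = clean.records
    train_daily = daily[daily["participant_id"].isin(train_ids)]
    train_cycles = clean.cycles[clean.cycles["participant_id"].isin(train_ids)]

    models, reports = {}, {}
    for target in config.targets:
        model = train_day_model(
            train_daily,
            train_cycles,
            target,
            truth=truth[truth["participant_id"].isin(train_ids)],
            windows=config.windows,
            smooth_windows=config.smooth_windows,
            Cs=config.Cs,
            use_hrv=config.use_hrv,
            threshold=config.threshold,
            seed=model_seed,
        )
        models[target] = model

        for group_name, ids in (("regular_test", test_ids), ("irregular", irregular_ids)):
            if not ids:
                continue
            preds = model.predict_days(daily, ids)
            if preds.empty:
                continue
            scored_cycles = clean.cycles[
                clean.cycles["participant_id"].isin(ids) & clean.cycles["qualified"]
            ]
            scored_truth = truth.merge(
                scored_cycles[["participant_id", "cycle_index"]],
                on=["participant_id", "cycle_index"],
            )
            reports[(target, group_name)] = evaluate_predictions(
                preds, scored_truth, target, group_name, cycles=scored_cycles
            )

    result = {
        "cohort": clean,
        "truth": truth,
        "phase_report": phase_report,
        "split": {"train": train_ids, "test": test_ids, "irregular": irregular_ids},
        "models": models,
        "reports": reports,
        "seed": config.seed,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_dir(clean, out)
        truth_out = truth.copy()
        truth_out["date"] = pd.to_datetime(truth_out["date"]).dt.strftime("%Y-%m-%d")
        truth_out.to_csv(out / "truth_labels.csv", index=False)
        with open(out / "phase_analysis.json", "w") as fh:
            json.dump(phase_report, fh, indent=2)
        for target, model in models.items():
            (out / f"model_{target}.json").write_text(model.to_json())
        serializable = {
            f"{t}/{g}": r.to_dict() for (t, g), r in reports.items()
        }
        with open(out / "evaluation.json", "w") as fh:
            json.dump(serializable, fh, indent=2)
    return result


def recover_phase_effects(
    seeds: Sequence[int],
    generator: Optional[GeneratorConfig] = None,
) -> Dict[str, float]:
    """Regenerate regular-only default cohorts and refit the phase model.

    For each seed: generate an 89-participant regular cohort with the
    default generator, preprocess it, fit the nested random-intercept LMM
    per signal (menstrual reference), and read the contrasts of interest
    from the fixed-effect covariance. Returns seed-averaged estimates:
    luteal-vs-fertile BBT and HR, fertile-vs-follicular BBT/HR/ln-SDNN/
    ln-LF-HF, and the BBT intercept.
    """
    sums: Dict[str, float] = {}
    keys = [
        "bbt_luteal_vs_fertile",
        "hr_luteal_vs_fertile",
        "bbt_fertile_vs_follicular",
        "hr_fertile_vs_follicular",
        "ln_sdnn_fertile_vs_follicular",
        "ln_lfhf_fertile_vs_follicular",
        "bbt_intercept",
    ]
    for k in keys:
        sums[k] = 0.0
    n_obs_total = 0
    wanted = [("LUTEAL", "FERTILE"), ("FERTILE", "FOLLICULAR")]
    for seed in seeds:
        cfg = generator or GeneratorConfig()
        cfg = GeneratorConfig(**{**cfg.__dict__, "n_irregular": 0, "seed": int(seed)})
        cohort, truth = generate_cohort(cfg)
        clean = preprocess_cohort(cohort)
        long = build_long_table(clean, truth=truth)
        for outcome in OUTCOMES:
            res = fit_phase_lmm(long, outcome, reference="MENSTRUAL")
            table = pairwise_contrasts(res, wanted)
            lut_fert = float(table.loc[table["contrast"] == "LUTEAL_vs_FERTILE", "estimate"].iloc[0])
            fert_foll = float(
                table.loc[table["contrast"] == "FERTILE_vs_FOLLICULAR", "estimate"].iloc[0]
            )
            if outcome == "bbt":
                sums["bbt_luteal_vs_fertile"] += lut_fert
                sums["bbt_fertile_vs_follicular"] += fert_foll
                sums["bbt_intercept"] += res.intercept
            elif outcome == "hr":
                sums["hr_luteal_vs_fertile"] += lut_fert
                sums["hr_fertile_vs_follicular"] += fert_foll
            elif outcome == "ln_sdnn":
                sums["ln_sdnn_fertile_vs_follicular"] += fert_foll
            elif outcome == "ln_lfhf":
                sums["ln_lfhf_fertile_vs_follicular"] += fert_foll
            if outcome == "bbt":
                n_obs_total += res.n_obs
    n = len(seeds)
    out = {k: v / n for k, v in sums.items()}
    out["n_obs_total"] = n_obs_total
    return out
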