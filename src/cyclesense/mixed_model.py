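"""Phase analysis: linear mixed models with nested random intercepts.

Each signal is modeled as value ~ cycle phase (fixed) with random intercepts
for participant and for cycle nested within participant, fitted by REML.
Pairwise phase contrasts (five by default: follicular/fertile/luteal vs
menstrual, fertile vs follicular, luteal vs fertile) are Wald tests from the
fixed-effect covariance with Bonferroni adjustment. Group comparisons refit
the same random structure with group as the fixed effect within one phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .data import PhaseLabel

PHASES = [p.value for p in PhaseLabel]

DEFAULT_CONTRASTS: list[Tuple[str, str]] = [
    ("FOLLICULAR", "MENSTRUAL"),
    ("FERTILE", "MENSTRUAL"),
    ("LUTEAL", "MENSTRUAL"),
    ("FERTILE", "FOLLICULAR"),
    ("LUTEAL", "FERTILE"),
]


@dataclass
class ContrastResult:
    estimate: float
    se: float
    p: float
    p_adjusted: float


@dataclass
class LMMResult:
    outcome: str
    reference_phase: str
    fixed_effects: Dict[str, ContrastResult]
    variance_components: Tuple[float, float, float]  # participant, cycle, residual
    n_obs: int
    n_participants: int
    n_cycles: int
    converged: bool
    intercept: float = np.nan
    intercept_se: float = np.nan
    # internals needed for arbitrary contrasts / diagnostics
    params: Optional[pd.Series] = None
    cov_params: Optional[pd.DataFrame] = None
    phase_param_names: Dict[str, Optional[str]] = field(default_factory=dict)
    residuals: Optional[np.ndarray] = None
    fitted: Optional[np.ndarray] = None


def _phase_term(reference: str, present: Sequence[str]) -> str:
    levels = [reference] + [p for p in PHASES if p != reference and p in set(present)]
    return f"C(phase, levels={levels!r})"


def fit_phase_lmm(
    long_table: pd.DataFrame,
    outcome: str,
    reference: str | PhaseLabel = PhaseLabel.MENSTRUAL,
    family_size: int = 5,
) -> LMMResult:
    """Fit the nested random-intercept phase model by REML.

    ``long_table`` needs columns participant_id, cycle_uid, phase, and the
    outcome. Rows with a missing outcome are dropped. Fixed effects are
    phase effects relative to ``reference``; random intercepts for
    participant and cycle-within-participant. A singular variance component
    is reported as 0 with a warning; non-convergence is flagged, not raised.
    """
    reference = reference.value if isinstance(reference, PhaseLabel) else reference
    df = long_table.dropna(subset=[outcome]).copy()
    if df["participant_id"].nunique() < 2 or df["phase"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 phases")

    if reference not in set(df["phase"]):
        raise ValueError(f"reference phase '{reference}' absent from the data")
    term = _phase_term(reference, df["phase"].unique())
    formula = f"{outcome} ~ {term}"
    vc = {"cycle": "0 + C(cycle_uid)"}
    model = smf.mixedlm(formula, df, groups=df["participant_id"], re_formula="1", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs")
            converged = bool(getattr(res, "converged", True))
        except np.linalg.LinAlgError:
            res = model.fit(reml=True, method="powell")
            converged = bool(getattr(res, "converged", False))
        if not converged:
            try:
                res2 = model.fit(reml=True, method="powell")
                if getattr(res2, "converged", False):
                    res, converged = res2, True
            except (np.linalg.LinAlgError, ValueError):
                pass

    var_participant = float(res.cov_re.iloc[0, 0])
    var_cycle = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)
    if var_participant <= 1e-10 or var_cycle <= 1e-10:
        warnings.warn(
            f"singular fit for {outcome}: a variance component is 0", stacklevel=2
        )

    params = res.fe_params
    try:
        # conditional residuals (random effects subtracted); falls back to
        # marginal residuals when a singular covariance blocks RE prediction
        fitted = np.asarray(res.fittedvalues)
        resid = np.asarray(res.resid)
    except (np.linalg.LinAlgError, ValueError):
        fitted = np.asarray(model.exog @ params)
        resid = np.asarray(model.endog) - fitted
    cov = res.cov_params().loc[params.index, params.index]
    phase_names: Dict[str, Optional[str]] = {reference: None}
    for ph in PHASES:
        if ph == reference:
            continue
        match = [n for n in params.index if n.endswith(f"[T.{ph}]")]
        if match:
            phase_names[ph] = match[0]

    fixed: Dict[str, ContrastResult] = {}
    for ph, name in phase_names.items():
        if name is None:
            continue
        est, se = float(params[name]), float(res.bse_fe[name])
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        fixed[f"{ph}_vs_{reference}"] = ContrastResult(
            est, se, p, min(1.0, p * family_size)
        )

    return LMMResult(
        outcome=outcome,
        reference_phase=reference,
        fixed_effects=fixed,
        variance_components=(var_participant, var_cycle, var_resid),
        n_obs=len(df),
        n_participants=df["participant_id"].nunique(),
        n_cycles=df["cycle_uid"].nunique(),
        converged=converged,
        intercept=float(params["Intercept"]),
        intercept_se=float(res.bse_fe["Intercept"]),
        params=params,
        cov_params=cov,
        phase_param_names=phase_names,
        residuals=resid,
        fitted=fitted,
    )


def pairwise_contrasts(
    result: LMMResult,
    contrasts: Sequence[Tuple[str, str]] = tuple(DEFAULT_CONTRASTS),
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Phase-pair contrasts from one fit, with Bonferroni adjustment.

    Each contrast (a, b) estimates the mean difference phase a minus phase b
    using the fixed-effect covariance; p_adjusted = min(1, p * m) with m the
    family size (default: the number of contrasts requested).
    """
    m = family_size if family_size is not None else len(contrasts)
    names = result.phase_param_names
    rows = []
    for a, b in contrasts:
        for ph in (a, b):
            if ph not in names:
                raise ValueError(f"phase '{ph}' absent from the fitted model")
        vec = pd.Series(0.0, index=result.params.index)
        if names[a] is not None:
            vec[names[a]] += 1.0
        if names[b] is not None:
            vec[names[b]] -= 1.0
        est = float(vec @ result.params)
        var = float(vec @ result.cov_params @ vec)
        se = float(np.sqrt(max(var, 0.0)))
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        rows.append(
            {
                "contrast": f"{a}_vs_{b}",
                "estimate": est,
                "se": se,
                "p": p,
                "p_adjusted": min(1.0, p * m) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_groups_lmm(
    long_table: pd.DataFrame, outcome: str, reference_group: str = "REGULAR"
) -> pd.DataFrame:
    """Group effect (IRREGULAR vs REGULAR) within one phase subset.

    Same nested random-intercept structure, with group as the fixed effect.
    ``long_table`` must already be restricted to a single phase and carry a
    ``group`` column with both levels present.
    """
    df = long_table.dropna(subset=[outcome]).copy()
    groups_present = df["group"].unique()
    if len(groups_present) < 2:
        raise ValueError("both groups must be present in the phase subset")
    levels = [reference_group] + [g for g in sorted(groups_present) if g != reference_group]
    formula = f"{outcome} ~ C(group, levels={levels!r})"
    vc = {"cycle": "0 + C(cycle_uid)"}
    model = smf.mixedlm(formula, df, groups=df["participant_id"], re_formula="1", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="lbfgs")
    rows = []
    for name in res.fe_params.index:
        if name == "Intercept":
            continue
        est, se = float(res.fe_params[name]), float(res.bse_fe[name])
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        label = name.split("[T.")[-1].rstrip("]")
        rows.append(
            {
                "effect": f"{label}_vs_{reference_group}",
                "estimate": est,
                "se": se,
                "p": p,
                "intercept": float(res.fe_params["Intercept"]),
            }
        )
    return pd.DataFrame(rows)


def residual_diagnostics(result: LMMResult) -> dict:
    """Descriptive residual bundle: summaries plus a normality statistic.

    Uses the D'Agostino-Pearson omnibus test on conditional residuals. The
    normality report never gates the pipeline; the transforms applied to
    SDNN/LF-HF are fixed policy.
    """
    resid = result.residuals
    if resid is None:
        raise ValueError("fit carried no residuals")
    finite = resid[np.isfinite(resid)]
    if len(finite) >= 20 and np.std(finite) > 1e-12:
        stat, p = stats.normaltest(finite)
    else:
        stat, p = np.nan, np.nan
    return {
        "n": int(len(finite)),
        "mean": float(np.mean(finite)) if len(finite) else np.nan,
        "sd": float(np.std(finite)) if len(finite) else np.nan,
        "skew": float(stats.skew(finite)) if len(finite) > 2 else np.nan,
        "kurtosis": float(stats.kurtosis(finite)) if len(finite) > 3 else np.nan,
        "normality_stat": float(stat),
        "normality_p": float(p),
        "residuals": finite,
        "fitted": result.fitted,
    }


def build_long_table(cohort, truth: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Long-format (participant, cycle, phase, signals) table for the LMM.

    Restricted to qualified cycles. Phase labels come from ``truth`` when
    given, otherwise from the cycle annotations via the labeling rule.
    """
    from .data import day_of_cycle

    if truth is not None:
        recs = cohort.records.copy()
        recs["date"] = pd.to_datetime(recs["date"])
        t = truth.copy()
        t["date"] = pd.to_datetime(t["date"])
        merged = recs.merge(
            t[["participant_id", "date", "cycle_index", "phase"]],
            on=["participant_id", "date"],
            how="inner",
        )
    else:
        merged = day_of_cycle(cohort)
        merged = merged.dropna(subset=["phase"])

    qualified = cohort.cycles.loc[cohort.cycles["qualified"], ["participant_id", "cycle_index"]]
    merged = merged.merge(qualified, on=["participant_id", "cycle_index"], how="inner")
    merged["cycle_uid"] = (
        merged["participant_id"] + "/c" + merged["cycle_index"].astype(int).astype(str)
    )
    if cohort.participants is not None:
        merged = merged.merge(
            cohort.participants[["participant_id", "group"]], on="participant_id", how="left"
        )
    elif "group" not in merged.columns:
        merged["group"] = "REGULAR"
    return merged
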