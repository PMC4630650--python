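"""Time-matched univariate analysis of the metabolite time course.

Each treated slot is compared against the pooled untreated slots sharing
its time of day (morning vs mornings, midday vs middays, evening vs
evenings), because roughly half of the plasma metabolome is circadian
and an unmatched comparison would confound dose with time of day.
Pooling the untreated replicates of one daytime is justified by a
pre-check: between two same-daytime untreated slots the number of
nominally significant metabolites stays at the chance level
(0.05 x n_metabolites, about 11 of 214).

Per metabolite the model is a mixed-effects ANOVA on log10 values with
the categorical fixed factor treatment, numeric fixed covariates age and
BMI, and a random intercept per subject (REML).  Read-outs per
metabolite and comparison: the linear-scale ratio of group means, the
treatment Wald t, its two-sided p, and the Benjamini-Hochberg q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign
from .preprocess import ProcessedMatrix


@dataclass(frozen=True)
class Comparison:
    """A group-vs-reference contrast over disjoint slot sets."""

    name: str
    group_slots: frozenset[str]
    reference_slots: frozenset[str]

    def __post_init__(self) -> None:
        if self.group_slots & self.reference_slots:
            raise ValueError(f"{self.name}: group and reference slots overlap")
        if not self.group_slots or not self.reference_slots:
            raise ValueError(f"{self.name}: empty slot set")


def treatment_comparisons(design: StudyDesign) -> list[Comparison]:
    """One time-matched comparison per treated slot.

    The reference pools every untreated slot with the same daytime
    (e.g., the +18 h morning draw against day-2 and day-3 mornings).
    """
    comps = []
    for slot in design.treated_slots:
        matched = design.matched_untreated(slot.daytime)
        comps.append(
            Comparison(
                name=f"treated_{int(slot.hours_post_dose)}h_vs_untreated_{slot.daytime}",
                group_slots=frozenset([slot.label]),
                reference_slots=frozenset(s.label for s in matched),
            )
        )
    return comps


def circadian_comparisons(design: StudyDesign) -> list[Comparison]:
    """Untreated midday-vs-morning and evening-vs-morning contrasts."""
    by_daytime = {
        dt: frozenset(s.label for s in design.untreated_slots if s.daytime == dt)
        for dt in ("morning", "midday", "evening")
    }
    return [
        Comparison("untreated_midday_vs_morning", by_daytime["midday"], by_daytime["morning"]),
        Comparison("untreated_evening_vs_morning", by_daytime["evening"], by_daytime["morning"]),
    ]


def ratio(
    linear_values: pd.DataFrame, sample_slots: pd.Series, comparison: Comparison
) -> pd.Series:
    """Group arithmetic mean / reference arithmetic mean, linear scale."""
    g = sample_slots.isin(comparison.group_slots).to_numpy()
    r = sample_slots.isin(comparison.reference_slots).to_numpy()
    if not g.any() or not r.any():
        raise ValueError(f"{comparison.name}: empty group or reference")
    return linear_values.loc[g].mean(axis=0) / linear_values.loc[r].mean(axis=0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_i = min over j with p_(j) >= p_(i) of min(1, m p_(j) / j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _mixed_fit_single(
    y: np.ndarray,
    exog: np.ndarray,
    groups: np.ndarray,
    n_subjects: int,
    n_between: int,
) -> tuple[float, float, float, np.ndarray, str]:
    """Fit one metabolite; return (t, p, group coef, covariate p's, flag).

    Wald t for the treatment indicator with inner-level residual df
    (n_obs - n_subjects - 1); between-subject covariates are tested at
    the subject level (df = n_subjects - n_between - 1).  Singular or
    non-converged fits fall back to OLS with subject-clustered errors.
    """
    import statsmodels.api as sm

    n_obs = y.size
    df_within = max(n_obs - n_subjects - 1, 1)
    df_between = max(n_subjects - n_between - 1, 1)
    flag = "mixed"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=True, method="lbfgs")
            if not np.isfinite(res.bse_fe[1]) or res.bse_fe[1] == 0:
                raise ValueError("degenerate SE")
        except Exception:
            flag = "ols_fallback"
            res = sm.OLS(y, exog).fit(cov_type="cluster", cov_kwds={"groups": groups})
    coef = np.asarray(res.params)[: exog.shape[1]]
    se = np.asarray(res.bse)[: exog.shape[1]]
    t = coef[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), df_within)
    cov_p = np.array(
        [
            2.0 * stats.t.sf(abs(coef[k] / se[k]), df_between)
            for k in range(2, exog.shape[1])
        ]
    )
    return t, p, coef[1], cov_p, flag


def fit_mixed_anova(
    data: ProcessedMatrix,
    comparison: Comparison,
    covariates: bool = True,
) -> pd.DataFrame:
    """Per-metabolite mixed ANOVA for one comparison.

    Returns a tidy frame (one row per metabolite) with the linear-scale
    ratio, treatment t and p, BH q across metabolites, covariate p's
    (when fitted) and a fit flag.
    """
    meta = data.sample_meta
    slots = meta["slot"]
    mask = slots.isin(comparison.group_slots | comparison.reference_slots).to_numpy()
    sub = meta.loc[mask]
    log_vals = data.log_values.loc[mask]

    subjects_in_group = sub.loc[sub["slot"].isin(comparison.group_slots), "subject_id"]
    subjects_in_ref = sub.loc[sub["slot"].isin(comparison.reference_slots), "subject_id"]
    if subjects_in_group.nunique() < 2 or subjects_in_ref.nunique() < 2:
        raise ValueError(f"{comparison.name}: need >=2 subjects per side")

    group_ind = sub["slot"].isin(comparison.group_slots).to_numpy(dtype=float)
    cols = [np.ones(len(sub)), group_ind]
    use_cov = covariates
    if use_cov:
        age, bmi = sub["age"].to_numpy(), sub["bmi"].to_numpy()
        if np.std(age) == 0 or np.std(bmi) == 0 or np.isnan(age).any():
            use_cov = False  # degenerate covariates cannot be fit
        else:
            cols += [age - age.mean(), bmi - bmi.mean()]
    exog = np.column_stack(cols)
    groups = sub["subject_id"].to_numpy()
    n_subjects = sub["subject_id"].nunique()

    ratios = ratio(10.0**log_vals, sub["slot"], comparison)
    records = []
    for met in log_vals.columns:
        t, p, coef, cov_p, flag = _mixed_fit_single(
            log_vals[met].to_numpy(), exog, groups, n_subjects, exog.shape[1] - 2
        )
        rec = {
            "metabolite": met,
            "comparison": comparison.name,
            "ratio": ratios[met],
            "t_value": t,
            "p_value": p,
            "log10_effect": coef,
            "n_group": int(group_ind.sum()),
            "n_reference": int(len(sub) - group_ind.sum()),
            "fit_flag": flag,
        }
        if use_cov:
            rec["age_p"], rec["bmi_p"] = cov_p
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    if use_cov:
        out["age_q"] = bh_adjust(out["age_p"].to_numpy())
        out["bmi_q"] = bh_adjust(out["bmi_p"].to_numpy())
    return out


def precheck_combination(
    data: ProcessedMatrix, slot_a: str, slot_b: str, alpha: float = 0.05
) -> tuple[int, float]:
    """Count metabolites nominally different between two untreated slots.

    Paired per-subject comparison (t-test on log10 differences).  Returns
    the count of p < alpha and the chance expectation alpha x M; pooling
    same-daytime untreated slots is sound when the count stays near the
    expectation.
    """
    meta = data.sample_meta
    for label in (slot_a, slot_b):
        row = meta.loc[meta["slot"] == label]
        if row.empty:
            raise ValueError(f"slot {label} not present")
        if row["treated"].any():
            raise ValueError(f"slot {label} is treated; pre-check is untreated-only")
    dt_a = meta.loc[meta["slot"] == slot_a, "daytime"].iloc[0]
    dt_b = meta.loc[meta["slot"] == slot_b, "daytime"].iloc[0]
    if dt_a != dt_b:
        raise ValueError(f"slots {slot_a}/{slot_b} have different daytimes")

    a = data.log_values.loc[meta["slot"].to_numpy() == slot_a]
    b = data.log_values.loc[meta["slot"].to_numpy() == slot_b]
    a = a.set_index(meta.loc[meta["slot"] == slot_a, "subject_id"]).sort_index()
    b = b.set_index(meta.loc[meta["slot"] == slot_b, "subject_id"]).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("subject sets differ between the two slots")
    res = stats.ttest_rel(a.to_numpy(), b.to_numpy(), axis=0)
    count = int(np.sum(res.pvalue < alpha))
    expected = alpha * data.log_values.shape[1]
    return count, expected


def circadian_contrasts(
    data: ProcessedMatrix, design: StudyDesign, covariates: bool = True
) -> pd.DataFrame:
    """Untreated midday/evening vs morning, same mixed-model machinery."""
    untreated_mask = (~data.sample_meta["treated"]).to_numpy()
    sub = ProcessedMatrix(
        log_values=data.log_values.loc[untreated_mask],
        sample_meta=data.sample_meta.loc[untreated_mask],
        metabolite_meta=data.metabolite_meta,
        provenance=data.provenance,
    )
    frames = [
        fit_mixed_anova(sub, comp, covariates=covariates)
        for comp in circadian_comparisons(design)
    ]
    return pd.concat(frames, ignore_index=True)


def run_treatment_anova(
    data: ProcessedMatrix, design: StudyDesign, covariates: bool = True
) -> pd.DataFrame:
    """All four time-matched post-dose comparisons, concatenated."""
    frames = [
        fit_mixed_anova(data, comp, covariates=covariates)
        for comp in treatment_comparisons(design)
    ]
    return pd.concat(frames, ignore_index=True)


def count_deregulated(results: pd.DataFrame, q_threshold: float = 0.05) -> dict:
    """Tally significant metabolites across the four post-dose comparisons.

    Returns per-comparison counts plus the number significant on at
    least one and on all four post-dose slots.
    """
    comps = sorted(results["comparison"].unique())
    if len(comps) != 4:
        raise ValueError(f"expected 4 treated comparisons, got {comps}")
    sig = results.assign(sig=results["q_value"] < q_threshold).pivot_table(
        index="metabolite", columns="comparison", values="sig", aggfunc="first"
    )
    per_comparison = {c: int(sig[c].sum()) for c in comps}
    return {
        "per_comparison": per_comparison,
        "any_slot": int(sig.any(axis=1).sum()),
        "all_four_slots": int(sig.all(axis=1).sum()),
        "q_threshold": q_threshold,
        "n_metabolites": int(sig.shape[0]),
    }
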