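import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from dexmet.cohort import generate_cohort
from dexmet.design import default_design
from dexmet.preprocess import log10_transform, normalize_to_pool, preprocess
from dexmet.univariate import (
    Comparison,
    bh_adjust,
    circadian_contrasts,
    count_deregulated,
    fit_mixed_anova,
    precheck_combination,
    ratio,
    run_treatment_anova,
    treatment_comparisons,
)
from conftest import small_spec

DESIGN = default_design()


# --- BH correction ---------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01], [0.01]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.005, 0.04, 0.5], [0.015, 0.06, 0.5]),  # hand step-up
    ],
)
def test_bh_hand_examples(p, expected):
    assert np.allclose(bh_adjust(p), expected)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
@settings(max_examples=60, deadline=None)
def test_bh_matches_statsmodels_and_dominates_p(p):
    q = bh_adjust(p)
    oracle = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, oracle, atol=1e-12)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all((q >= 0) & (q <= 1))


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


# --- ratio -----------------------------------------------------------------

def _frame(values, slots):
    idx = pd.Index([f"s{i}" for i in range(len(values))], name="sample_id")
    return (
        pd.DataFrame({"m": values}, index=idx),
        pd.Series(slots, index=idx, name="slot"),
    )


def test_ratio_identical_groups_is_one():
    vals, slots = _frame([2.0, 3.0, 2.0, 3.0], ["a", "a", "b", "b"])
    comp = Comparison("c", frozenset({"a"}), frozenset({"b"}))
    assert ratio(vals, slots, comp)["m"] == pytest.approx(1.0)


def test_ratio_direct_arithmetic():
    vals, slots = _frame([2.0, 2.0, 4.0, 4.0], ["a", "a", "b", "b"])
    comp = Comparison("c", frozenset({"a"}), frozenset({"b"}))
    assert ratio(vals, slots, comp)["m"] == pytest.approx(0.5)


def test_comparison_validation():
    with pytest.raises(ValueError, match="overlap"):
        Comparison("c", frozenset({"a"}), frozenset({"a", "b"}))
    with pytest.raises(ValueError, match="empty"):
        Comparison("c", frozenset(), frozenset({"b"}))


# --- mixed ANOVA -----------------------------------------------------------

def test_mixed_estimate_equals_paired_means_when_balanced():
    """Balanced design, no covariates: the mixed-model treatment estimate
    equals the difference of group means of log10 values (closed form)."""
    spec = small_spec(seed=21, n_subjects=8, n_metabolites=3)
    proc = preprocess(generate_cohort(spec))
    comp = treatment_comparisons(DESIGN)[1]  # +18 h morning, 1 vs 2 slots/subject
    res = fit_mixed_anova(proc, comp, covariates=False)
    meta = proc.sample_meta
    for _, row in res.iterrows():
        y = proc.log_values[row["metabolite"]]
        g = y[meta["slot"].isin(comp.group_slots)].mean()
        r = y[meta["slot"].isin(comp.reference_slots)].mean()
        assert row["log10_effect"] == pytest.approx(g - r, abs=1e-6)


def test_ratio_recovery_large_cohort():
    """A 1.2x multiplicative effect at +6 h is recovered by the univariate
    stage at n_subjects = 200 (generative plug-in expectation)."""
    m = 5
    treat = np.zeros((m, 4))
    treat[0, 0] = np.log10(1.2)
    spec = small_spec(
        seed=13, n_subjects=200, n_metabolites=m,
        treatment_profile=treat, noise_sd=np.full(m, 0.02),
        subject_sd=np.full(m, 0.1),
    )
    proc = preprocess(generate_cohort(spec))
    comp = next(c for c in treatment_comparisons(DESIGN) if "6h" in c.name)
    res = fit_mixed_anova(proc, comp).set_index("metabolite")
    assert res.loc["metabolite_001", "ratio"] == pytest.approx(1.20, abs=0.02)
    assert res.loc["metabolite_001", "p_value"] < 1e-6
    # null metabolites stay near ratio 1
    assert np.allclose(res.drop("metabolite_001")["ratio"], 1.0, atol=0.02)


def test_anova_two_subject_precondition():
    spec = small_spec(seed=1, n_subjects=1, n_metabolites=2)
    proc = preprocess(generate_cohort(spec))
    with pytest.raises(ValueError, match="subjects"):
        fit_mixed_anova(proc, treatment_comparisons(DESIGN)[0])


# --- pre-check -------------------------------------------------------------

def test_precheck_duplicated_slot_finds_nothing():
    spec = small_spec(seed=5)
    mpm = generate_cohort(spec)
    proc = log10_transform(normalize_to_pool(mpm))
    # overwrite d2_midday with d1_midday per subject: identical data
    meta = proc.sample_meta
    a_rows = meta.index[meta["slot"] == "d1_midday"]
    b_rows = meta.index[meta["slot"] == "d2_midday"]
    proc.log_values.loc[b_rows] = proc.log_values.loc[a_rows].to_numpy()
    count, expected = precheck_combination(proc, "d1_midday", "d2_midday")
    assert count == 0
    assert expected == pytest.approx(0.05 * 12)


def test_precheck_rejects_mismatched_or_treated_slots():
    proc = log10_transform(normalize_to_pool(generate_cohort(small_spec(seed=5))))
    with pytest.raises(ValueError, match="daytime"):
        precheck_combination(proc, "d1_midday", "d1_evening")
    with pytest.raises(ValueError, match="treated"):
        precheck_combination(proc, "d1_evening", "d3_evening")


# --- circadian contrasts ---------------------------------------------------

def test_circadian_monotone_trend_recovered():
    """Positive monotone increments give evening/morning > midday/morning > 1."""
    m = 3
    circ = np.tile([[0.15, 0.15]], (m, 1))
    spec = small_spec(
        seed=17, n_subjects=20, n_metabolites=m,
        circadian_profile=circ, noise_sd=np.full(m, 0.03),
    )
    proc = preprocess(generate_cohort(spec))
    res = circadian_contrasts(proc, DESIGN)
    mid = res[res["comparison"] == "untreated_midday_vs_morning"].set_index("metabolite")
    eve = res[res["comparison"] == "untreated_evening_vs_morning"].set_index("metabolite")
    assert (eve["ratio"] > mid["ratio"]).all()
    assert (mid["ratio"] > 1).all()
    assert (eve["q_value"] < 0.05).all()


# --- deregulation counts ---------------------------------------------------

def test_count_deregulated_manual_tally():
    comps = [c.name for c in treatment_comparisons(DESIGN)]
    q = {
        "m1": [0.01, 0.01, 0.01, 0.01],  # all four
        "m2": [0.01, 0.50, 0.50, 0.50],  # one slot
        "m3": [0.50, 0.50, 0.50, 0.50],  # none
        "m4": [0.04, 0.04, 0.50, 0.04],  # three slots
        "m5": [0.06, 0.06, 0.06, 0.06],  # never below threshold
    }
    rows = [
        {"metabolite": met, "comparison": comp, "q_value": qv}
        for met, qvals in q.items()
        for comp, qv in zip(comps, qvals)
    ]
    counts = count_deregulated(pd.DataFrame(rows), q_threshold=0.05)
    assert counts["any_slot"] == 3
    assert counts["all_four_slots"] == 1
    assert counts["per_comparison"][comps[0]] == 3
    assert counts["per_comparison"][comps[2]] == 1


def test_all_q_one_counts_zero():
    comps = [c.name for c in treatment_comparisons(DESIGN)]
    rows = [
        {"metabolite": f"m{i}", "comparison": c, "q_value": 1.0}
        for i in range(4) for c in comps
    ]
    counts = count_deregulated(pd.DataFrame(rows))
    assert counts["any_slot"] == 0
    assert counts["all_four_slots"] == 0


def test_strong_all_slot_effects_recovered():
    """30 metabolites affected on all four slots at low noise -> the
    'all four' tally recovers exactly those 30."""
    m = 60
    treat = np.zeros((m, 4))
    treat[:30, :] = 0.4
    spec = small_spec(
        seed=23, n_subjects=20, n_metabolites=m,
        treatment_profile=treat, noise_sd=np.full(m, 0.03),
        subject_sd=np.full(m, 0.1),
    )
    proc = preprocess(generate_cohort(spec))
    res = run_treatment_anova(proc, DESIGN)
    counts = count_deregulated(res)
    assert counts["all_four_slots"] == 30
    # every true effect is caught; BH permits a few single-slot false
    # discoveries among the nulls (FDR, not FWER), so >= not ==
    sig = res[res["q_value"] < 0.05]["metabolite"].unique()
    assert set(f"metabolite_{i + 1:03d}" for i in range(30)) <= set(sig)
    assert counts["any_slot"] >= 30
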