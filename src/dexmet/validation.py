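"""Statistical validation studies for the pipeline.

Each function runs a self-contained simulation study against the
synthetic-cohort generator — type-I error calibration of the mixed
ANOVA, the chance-level behaviour of the combination pre-check,
permutation-null and strong-signal behaviour of the subject-wise
cross-validated Q², and sensitivity/specificity of the Kendall
rank-stability selection — and returns plain numbers.  They are used
by the test suite and by ``scripts/acceptance.py``.

All randomness flows from an integer seed; problem sizes are the
study's own (20 subjects, 11 slots) with metabolite counts chosen per
study (documented per function).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cohort import CohortSpec, default_cohort_spec, generate_cohort
from .design import default_design
from .phenotype import stability_scores, untreated_slots
from .plsda import q2_loso, treated_labels
from .preprocess import log10_transform, normalize_to_pool, preprocess
from .univariate import (
    fit_mixed_anova,
    precheck_combination,
    treatment_comparisons,
)


def _null_spec(seed: int, n_metabolites: int, n_subjects: int = 20) -> CohortSpec:
    """A no-effect cohort: subject offsets and noise only."""
    m = n_metabolites
    return CohortSpec(
        n_subjects=n_subjects,
        n_metabolites=m,
        baseline_log_mean=np.full(m, 1.5),
        subject_sd=np.full(m, 0.15),
        noise_sd=np.full(m, 0.1),
        n_pool_replicates=10,
        seed=seed,
    )


def expected_false_positive_reference(
    n_metabolites: int = 214, alpha: float = 0.05
) -> float:
    """Chance expectation of nominal positives among independent nulls."""
    return alpha * n_metabolites


def null_pvalue_ks(seed: int, n_metabolites: int = 1000) -> float:
    """KS distance to Uniform(0,1) of mixed-ANOVA p-values under the null.

    One no-effect cohort of 20 subjects; the +18 h morning comparison
    (1 treated vs 2 pooled untreated mornings per subject) is fitted for
    every metabolite and the p-value distribution compared with uniform.
    """
    proc = preprocess(generate_cohort(_null_spec(seed, n_metabolites)))
    comp = next(c for c in treatment_comparisons(default_design()) if "18h" in c.name)
    res = fit_mixed_anova(proc, comp)
    return float(stats.kstest(res["p_value"].to_numpy(), "uniform").statistic)


def ratio_recovery(seed: int, true_ratio: float = 1.5) -> tuple[float, float]:
    """Recover a known multiplicative +6 h effect at low noise.

    20 subjects, 20 metabolites of which the first carries the effect;
    returns (estimated ratio, p-value) for the effect metabolite.
    """
    m = 20
    spec = _null_spec(seed, m)
    spec.noise_sd = np.full(m, 0.02)
    treat = np.zeros((m, 4))
    treat[0, 0] = np.log10(true_ratio)
    spec.treatment_profile = treat
    proc = preprocess(generate_cohort(spec))
    comp = next(c for c in treatment_comparisons(default_design()) if "6h" in c.name)
    res = fit_mixed_anova(proc, comp).set_index("metabolite")
    row = res.iloc[0]
    return float(row["ratio"]), float(row["p_value"])


def precheck_null_counts(seed: int, n_sims: int = 200) -> tuple[float, float]:
    """Mean count of nominal positives between two same-daytime untreated
    slots over replicate null cohorts (214 metabolites each).

    Returns (mean count, chance expectation 0.05 x 214 = 10.7).
    """
    rng = np.random.default_rng([seed, 7])
    counts = []
    for _ in range(n_sims):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        mpm = generate_cohort(_null_spec(sim_seed, 214))
        proc = log10_transform(normalize_to_pool(mpm))
        count, expected = precheck_combination(proc, "d1_midday", "d2_midday")
        counts.append(count)
    return float(np.mean(counts)), float(expected)


def q2_null_permutation(seed: int, n_reps: int = 100) -> tuple[float, float]:
    """Permuted-label null of the leave-one-subject-out Q².

    One no-effect cohort (214 metabolites); treated/untreated labels are
    randomly permuted across samples ``n_reps`` times.  Returns the
    fraction of replicates with Q²cum(2) <= 0.1 and the median Q²cum(2).
    """
    proc = preprocess(generate_cohort(_null_spec(seed, 214)))
    X = proc.scaled_values.to_numpy()
    y = treated_labels(proc.sample_meta)
    subj = proc.sample_meta["subject_id"].to_numpy()
    rng = np.random.default_rng([seed, 11])
    q2cum2 = []
    for _ in range(n_reps):
        y_perm = rng.permutation(y)
        try:
            _, q2c, _ = q2_loso(X, y_perm, subj, 2)
            q2cum2.append(q2c[1])
        except ValueError:  # degenerate permutation (single-class folds)
            continue
    q2cum2 = np.asarray(q2cum2)
    return float(np.mean(q2cum2 <= 0.1)), float(np.median(q2cum2))


def q2_strong_cohort(seed: int) -> float:
    """Q²cum(2) on the default strongly-affected synthetic study."""
    proc = preprocess(generate_cohort(default_cohort_spec(seed=seed)))
    X = proc.scaled_values.to_numpy()
    _, q2c, _ = q2_loso(
        X, treated_labels(proc.sample_meta),
        proc.sample_meta["subject_id"].to_numpy(), 2,
    )
    return float(q2c[1])


def phenotype_recovery(
    seed: int, n_truth: int = 1000, n_null: int = 1000
) -> tuple[float, float]:
    """Sensitivity and false-selection rate of the rank-stability rule.

    One cohort of 20 subjects carrying ``n_truth`` phenotype metabolites
    (subject_sd/noise_sd = 4, the generator default) and ``n_null`` iid
    noise metabolites (no subject offset); scores over the 7 untreated
    slots at threshold mean - SD >= 0.6.  Returns (sensitivity on truth,
    selection rate on nulls).
    """
    m = n_truth + n_null
    spec = CohortSpec(
        n_subjects=20,
        n_metabolites=m,
        baseline_log_mean=np.full(m, 1.5),
        subject_sd=np.concatenate([np.full(n_truth, 0.4), np.zeros(n_null)]),
        noise_sd=np.full(m, 0.1),
        phenotype_set=frozenset(range(n_truth)),
        n_pool_replicates=4,
        seed=seed,
    )
    mpm = generate_cohort(spec)
    scores = stability_scores(mpm, untreated_slots(default_design()))
    selected = scores["selected"].to_numpy()
    sensitivity = float(selected[:n_truth].mean())
    false_rate = float(selected[n_truth:].mean())
    return sensitivity, false_rate
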