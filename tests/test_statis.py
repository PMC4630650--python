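import numpy as np
import pytest

from dexmet.cohort import generate_cohort
from dexmet.preprocess import preprocess
from dexmet.statis import (
    SubjectTable,
    build_subject_tables,
    compromise_eigen,
    crossproduct_matrix,
    fit_statis,
    metabolite_loadings,
    project_tables,
    rv_matrix,
    statis_weights,
)
from conftest import small_spec


def _table(X, subj="s1"):
    X = np.asarray(X, dtype=float)
    return SubjectTable(subj, X, [f"t{i}" for i in range(X.shape[0])])


# --- cross-products --------------------------------------------------------

def test_crossproduct_hand_example():
    W = crossproduct_matrix(_table([[1, 0], [1, 0]]))
    assert np.allclose(W, [[0.5, 0.5], [0.5, 0.5]])


def test_crossproduct_orthonormal_rows_give_identity():
    # rows orthogonal with squared norm M=2 -> identity
    W = crossproduct_matrix(_table([[1, 1], [1, -1]]))
    assert np.allclose(W, np.eye(2))


def test_crossproduct_duplicate_row_symmetry():
    W = crossproduct_matrix(_table([[1, 2, 3], [4, 5, 6], [1, 2, 3]]))
    assert np.allclose(W[0], W[2])
    assert np.allclose(W[:, 0], W[:, 2])
    assert np.allclose(W, W.T)


# --- RV interstructure -----------------------------------------------------

def test_rv_diagonal_and_orthogonal():
    A = np.array([[1.0, 0.0], [0.0, 0.0]])
    B = np.array([[0.0, 0.0], [0.0, 1.0]])  # <A, B>_F = 0
    C = rv_matrix([A, B])
    assert np.allclose(np.diag(C), 1.0)
    assert C[0, 1] == pytest.approx(0.0)


def test_rv_hand_example():
    C = rv_matrix([np.eye(2), np.array([[1.0, 0.0], [0.0, 0.0]])])
    assert C[0, 1] == pytest.approx(1 / np.sqrt(2))


def test_rv_rejects_zero_norm():
    with pytest.raises(ValueError, match="zero-norm"):
        rv_matrix([np.eye(2), np.zeros((2, 2))])


# --- weights ---------------------------------------------------------------

@pytest.mark.parametrize("K", [4, 20])
def test_identical_tables_weigh_equally(K):
    """K identical tables give alpha_k = 1/sqrt(K)."""
    C = np.ones((K, K))
    alpha = statis_weights(C)
    assert np.allclose(alpha, 1 / np.sqrt(K))


@pytest.mark.parametrize("r", [0.1, 0.5, 0.9])
def test_two_table_weights_independent_of_rv(r):
    alpha = statis_weights(np.array([[1.0, r], [r, 1.0]]))
    assert np.allclose(alpha, 1 / np.sqrt(2))


def test_weights_require_symmetry():
    with pytest.raises(ValueError, match="symmetric"):
        statis_weights(np.array([[1.0, 0.2], [0.4, 1.0]]))


def test_weights_permutation_equivariance():
    rng = np.random.default_rng(0)
    Ws = [w @ w.T for w in rng.normal(size=(5, 4, 3))]
    alpha = statis_weights(rv_matrix(Ws))
    perm = [3, 0, 4, 1, 2]
    alpha_p = statis_weights(rv_matrix([Ws[i] for i in perm]))
    assert np.allclose(alpha_p, alpha[perm])


def test_noise_subject_gets_lowest_weight():
    """Replacing one subject's table by noise strictly lowers its weight."""
    rng = np.random.default_rng(1)
    base = rng.normal(size=(6, 40))
    tables = [base + 0.05 * rng.normal(size=base.shape) for _ in range(8)]
    Ws = [X @ X.T / X.shape[1] for X in tables]
    alpha_before = statis_weights(rv_matrix(Ws))
    noisy = list(Ws)
    X_noise = rng.normal(size=base.shape)
    noisy[3] = X_noise @ X_noise.T / X_noise.shape[1]
    alpha_after = statis_weights(rv_matrix(noisy))
    assert alpha_after[3] < alpha_before[3]
    assert np.argmin(alpha_after) == 3


# --- compromise ------------------------------------------------------------

def test_compromise_eigen_small_oracle():
    """3x3 hand-built compromise: eigenvalues match the roots of the
    characteristic polynomial (independent brute-force oracle)."""
    W0 = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 1.0], [0.0, 1.0, 2.0]])
    Wc, evals, evecs, scores, explained = compromise_eigen([W0], np.array([1.0]))
    # characteristic polynomial det(W - x I) via explicit 3x3 cofactors
    a, b, c, d, e, f = W0[0, 0], W0[0, 1], W0[0, 2], W0[1, 1], W0[1, 2], W0[2, 2]
    coeffs = [
        -1.0,
        a + d + f,
        -(a * d + a * f + d * f - b**2 - c**2 - e**2),
        a * d * f + 2 * b * e * c - a * e**2 - d * c**2 - f * b**2,
    ]
    roots = np.sort(np.roots(coeffs))[::-1]
    assert np.allclose(evals, roots.real, atol=1e-10)
    for lam, u in zip(evals, evecs.T):
        assert np.allclose(W0 @ u, lam * u, atol=1e-10)
    assert evals.sum() == pytest.approx(np.trace(Wc), rel=1e-12)
    assert np.allclose(scores, evecs * np.sqrt(evals))
    assert explained.sum() == pytest.approx(1.0)


def test_identical_tables_compromise_matches_single_table():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 20))
    W = X @ X.T / 20
    _, ev1, U1, _, _ = compromise_eigen([W], np.array([1.0]))
    _, ev4, U4, _, _ = compromise_eigen([W] * 4, np.full(4, 0.5))
    # compromise = 2W: same eigenvectors, scaled eigenvalues
    assert np.allclose(ev4, 2 * ev1)
    assert np.allclose(np.abs(U4), np.abs(U1))


def test_non_psd_compromise_rejected():
    with pytest.raises(ValueError, match="PSD|positive"):
        compromise_eigen([np.diag([1.0, -0.5])], np.array([1.0]))


# --- full fit on cohorts ---------------------------------------------------

def test_shapes_on_default_cohort(default_processed):
    model = fit_statis(default_processed)
    assert len(model.W_list) == 20
    assert model.compromise.shape == (11, 11)
    assert model.C.shape == (20, 20)
    assert np.all(model.weights >= 0)
    assert np.linalg.norm(model.weights) == pytest.approx(1.0)
    assert model.eigenvalues.sum() == pytest.approx(
        np.trace(model.compromise), rel=1e-8
    )
    assert np.all(np.diff(model.eigenvalues) <= 1e-12)


def test_single_subject_reduces_to_pca():
    """K = 1: STATIS time-point scores equal the PCA scores of that
    subject's table (SVD oracle), up to sign."""
    spec = small_spec(seed=31, n_subjects=1, n_metabolites=30,
                      subject_sd=np.zeros(30))
    proc = preprocess(generate_cohort(spec))
    tables = build_subject_tables(proc)
    assert len(tables) == 1
    model = fit_statis(proc)
    U, s, _ = np.linalg.svd(tables[0].X / np.sqrt(tables[0].X.shape[1]))
    pca_scores = U * s  # left singular vectors scaled by singular values
    k = min(3, len(s))
    assert np.allclose(
        np.abs(model.timepoint_scores[:, :k]), np.abs(pca_scores[:, :k]), atol=1e-8
    )


def test_missing_slot_raises(default_processed):
    proc = default_processed
    keep = proc.sample_meta.index != "subj01_d2_morning"
    import dataclasses
    broken = dataclasses.replace(
        proc,
        log_values=proc.log_values.loc[keep],
        scaled_values=proc.scaled_values.loc[keep],
        sample_meta=proc.sample_meta.loc[keep],
    )
    with pytest.raises(ValueError, match="subj01.*d2_morning"):
        build_subject_tables(broken)


def test_trajectory_weighted_mean_is_compromise(default_processed):
    model = fit_statis(default_processed)
    traj = project_tables(model, n_axes=2)
    agg = traj.groupby("slot", sort=False)
    for a in (1, 2):
        col = f"axis{a}"
        weighted = np.array([
            np.dot(model.weights, grp[col].to_numpy())
            for _, grp in agg
        ])
        assert np.allclose(weighted, model.timepoint_scores[:, a - 1], atol=1e-8)


def test_identical_tables_trajectories_equal_compromise():
    spec = small_spec(seed=33, n_subjects=4, n_metabolites=10,
                      subject_sd=np.zeros(10), noise_sd=np.zeros(10),
                      circadian_profile=np.tile([[0.2, -0.1]], (10, 1)))
    proc = preprocess(generate_cohort(spec))
    model = fit_statis(proc)
    traj = project_tables(model, n_axes=1)
    # with unit-norm weights alpha_k = 1/sqrt(K), K identical tables give
    # identical trajectories equal to the compromise scores / sqrt(K)
    expected = model.timepoint_scores[:, 0] / 2.0  # K = 4
    for _, grp in traj.groupby("subject_id"):
        assert np.allclose(grp["axis1"].to_numpy(), expected, atol=1e-10)


def test_treated_slots_separate_on_compromise_axes():
    """A strong uniform post-dose shift separates treated from untreated
    slots in compromise score space (positive silhouette)."""
    m = 40
    treat = np.full((m, 4), 0.5)
    spec = small_spec(seed=35, n_subjects=10, n_metabolites=m,
                      treatment_profile=treat, noise_sd=np.full(m, 0.05))
    proc = preprocess(generate_cohort(spec))
    model = fit_statis(proc)
    pts = model.timepoint_scores[:, :2]
    treated = np.array([lbl in ("d3_evening", "d4_morning", "d4_midday", "d4_evening")
                        for lbl in model.slot_labels])
    sil = _silhouette(pts, treated)
    assert sil > 0


def _silhouette(points, labels):
    from scipy.spatial.distance import cdist
    D = cdist(points, points)
    vals = []
    for i in range(len(points)):
        same = labels == labels[i]
        same[i] = False
        a = D[i, same].mean()
        b = D[i, ~same & (np.arange(len(points)) != i)].mean()
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def test_loadings_rank_effect_metabolites_highest():
    """Post-dose effect metabolites carry larger loadings on the
    treated-vs-untreated axis than null metabolites."""
    m = 30
    treat = np.zeros((m, 4))
    treat[:10] = 0.5
    spec = small_spec(seed=37, n_subjects=10, n_metabolites=m,
                      treatment_profile=treat, noise_sd=np.full(m, 0.05))
    proc = preprocess(generate_cohort(spec))
    model = fit_statis(proc)
    treated = np.array([model.slot_labels.index(s)
                        for s in ("d3_evening", "d4_morning", "d4_midday", "d4_evening")])
    # pick the axis (of the first three) contrasting treated vs untreated most
    contrast = [
        abs(model.timepoint_scores[treated, a].mean()
            - np.delete(model.timepoint_scores[:, a], treated).mean())
        for a in range(3)
    ]
    axis = int(np.argmax(contrast)) + 1
    load = metabolite_loadings(proc, model, n_axes=3)[f"axis{axis}"].abs()
    effect = load.iloc[:10]
    null = load.iloc[10:]
    assert effect.median() > null.median()
    assert effect.min() > null.quantile(0.75)


def test_single_metabolite_loading_is_unit():
    spec = small_spec(seed=39, n_subjects=1, n_metabolites=1,
                      circadian_profile=np.array([[0.3, 0.2]]))
    proc = preprocess(generate_cohort(spec))
    model = fit_statis(proc)
    load = metabolite_loadings(proc, model, n_axes=1)
    assert abs(load.iloc[0, 0]) == pytest.approx(1.0, abs=1e-8)


def test_projection_rejects_zero_eigenvalue_axis():
    spec = small_spec(seed=41, n_subjects=2, n_metabolites=1)
    proc = preprocess(generate_cohort(spec))
    model = fit_statis(proc)  # rank-1 tables -> trailing eigenvalues 0
    with pytest.raises(ValueError, match="zero eigenvalue"):
        project_tables(model, n_axes=11)
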