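"""STATIS multi-table ordination of the per-subject time courses.

STATIS ("Structuration des Tableaux A Trois Indices de la Statistique")
summarizes K data tables sharing their observations — here one
time points x metabolites table per subject, on globally autoscaled
data — by an optimally weighted average of their cross-product
matrices, the *compromise*:

1. per subject k, the cross-product W_k = X_k X_k' / M over the M
   metabolites, an 11 x 11 similarity of the time points;
2. the interstructure C of RV coefficients between subjects,
   C_ij = <W_i, W_j>_F / (||W_i||_F ||W_j||_F);
3. weights alpha = the leading eigenvector of C, sign-fixed
   non-negative with unit Euclidean norm, so subjects similar to the
   consensus weigh more (equal similarity at K subjects gives
   alpha_k = 1/sqrt(K), e.g. 0.224 at K = 20);
4. the compromise W = sum_k alpha_k W_k, whose eigendecomposition
   yields consensus time-point coordinates U diag(sqrt(lambda));
5. projections: each subject's trajectory W_k u_a / sqrt(lambda_a)
   (their alpha-weighted mean is the compromise scores) and metabolite
   loadings from the alpha-weighted average table.

With K = 1 the procedure reduces exactly to a PCA of that table's
cross-product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ProcessedMatrix


@dataclass
class SubjectTable:
    """One subject's time points x metabolites slice of the scaled data."""

    subject_id: str
    X: np.ndarray  # (T, M), rows in chronological slot order
    slot_labels: list[str]


@dataclass
class StatisModel:
    subject_ids: list[str]
    slot_labels: list[str]
    W_list: list[np.ndarray]
    C: np.ndarray
    weights: np.ndarray
    compromise: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns u_a
    timepoint_scores: np.ndarray  # U diag(sqrt(lambda))
    explained_variance: np.ndarray

    def scores_frame(self, n_axes: int = 2) -> pd.DataFrame:
        return pd.DataFrame(
            self.timepoint_scores[:, :n_axes],
            index=pd.Index(self.slot_labels, name="slot"),
            columns=[f"axis{a + 1}" for a in range(n_axes)],
        )

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "weight": self.weights}
        ).set_index("subject_id")


def build_subject_tables(scaled: ProcessedMatrix) -> list[SubjectTable]:
    """Split globally autoscaled data into one table per subject.

    Every subject must contribute every design slot; rows are ordered by
    the slot order of the first subject encountered (the design order
    when the cohort came from the generator).
    """
    if scaled.scaled_values is None:
        raise ValueError("autoscaled data required (run autoscale first)")
    meta = scaled.sample_meta
    if meta["is_pool_reference"].any():
        raise ValueError("pool samples must be removed before STATIS")
    subjects = list(dict.fromkeys(meta["subject_id"]))
    slot_order = list(dict.fromkeys(meta["slot"]))
    tables = []
    for subj in subjects:
        rows = meta.index[meta["subject_id"] == subj]
        got = set(meta.loc[rows, "slot"])
        missing = [s for s in slot_order if s not in got]
        if missing:
            raise ValueError(f"subject {subj} missing slots {missing}")
        by_slot = pd.Series(rows.to_numpy(), index=meta.loc[rows, "slot"])
        ordered = by_slot.loc[slot_order].to_numpy()
        tables.append(
            SubjectTable(
                subject_id=subj,
                X=scaled.scaled_values.loc[ordered].to_numpy(),
                slot_labels=slot_order,
            )
        )
    return tables


def crossproduct_matrix(table: SubjectTable) -> np.ndarray:
    """W_k = X_k X_k' / M: time-point scalar products averaged over metabolites."""
    X = np.asarray(table.X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    return X @ X.T / X.shape[1]


def rv_matrix(W_list: list[np.ndarray]) -> np.ndarray:
    """RV-coefficient interstructure: normalized Frobenius inner products."""
    shapes = {W.shape for W in W_list}
    if len(shapes) != 1:
        raise ValueError(f"cross-product matrices differ in shape: {shapes}")
    K = len(W_list)
    norms = np.array([np.linalg.norm(W) for W in W_list])
    if np.any(norms == 0):
        raise ValueError("zero-norm cross-product matrix")
    C = np.empty((K, K))
    for i in range(K):
        for j in range(i, K):
            C[i, j] = C[j, i] = np.sum(W_list[i] * W_list[j]) / (norms[i] * norms[j])
    return C


def statis_weights(C: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the RV matrix, non-negative, unit 2-norm."""
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("RV matrix must be symmetric")
    evals, evecs = np.linalg.eigh(C)
    alpha = evecs[:, -1]
    # Perron-Frobenius: for a non-negative similarity matrix the leading
    # eigenvector has constant sign; fix it to be non-negative.
    if alpha.sum() < 0:
        alpha = -alpha
    if np.any(alpha < -1e-10):
        raise ValueError("leading eigenvector is not sign-constant")
    alpha = np.clip(alpha, 0.0, None)
    return alpha / np.linalg.norm(alpha)


def compromise_eigen(
    W_list: list[np.ndarray], weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted compromise and its eigensystem.

    Returns (W, eigenvalues desc, eigenvectors, timepoint scores,
    explained variance fractions).  Tiny negative eigenvalues (within
    1e-8 of the top eigenvalue) are clipped to zero; anything more
    negative raises.
    """
    weights = np.asarray(weights, dtype=float)
    if len(W_list) != weights.size:
        raise ValueError("one weight per table required")
    W = sum(a * Wk for a, Wk in zip(weights, W_list))
    evals, evecs = np.linalg.eigh(W)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[0] <= 0:
        raise ValueError("compromise has no positive eigenvalue")
    if evals[-1] < -1e-8 * evals[0]:
        raise ValueError(f"compromise not PSD (lambda_min = {evals[-1]:.3g})")
    evals = np.clip(evals, 0.0, None)
    # Deterministic sign: largest-magnitude entry of each axis positive.
    for a in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, a]))
        if evecs[k, a] < 0:
            evecs[:, a] = -evecs[:, a]
    scores = evecs * np.sqrt(evals)[None, :]
    explained = evals / evals.sum()
    return W, evals, evecs, scores, explained


def fit_statis(scaled: ProcessedMatrix) -> StatisModel:
    """Full STATIS fit on autoscaled study data."""
    tables = build_subject_tables(scaled)
    W_list = [crossproduct_matrix(t) for t in tables]
    C = rv_matrix(W_list)
    alpha = statis_weights(C)
    W, evals, evecs, scores, explained = compromise_eigen(W_list, alpha)
    return StatisModel(
        subject_ids=[t.subject_id for t in tables],
        slot_labels=tables[0].slot_labels,
        W_list=W_list,
        C=C,
        weights=alpha,
        compromise=W,
        eigenvalues=evals,
        eigenvectors=evecs,
        timepoint_scores=scores,
        explained_variance=explained,
    )


def project_tables(model: StatisModel, n_axes: int = 2) -> pd.DataFrame:
    """Per-subject trajectories on the compromise axes.

    Subject k's coordinate on axis a is W_k u_a / sqrt(lambda_a); the
    alpha-weighted average over subjects reproduces the compromise
    scores exactly.
    """
    if np.any(model.eigenvalues[:n_axes] <= 0):
        raise ValueError("requested axis has zero eigenvalue")
    U = model.eigenvectors[:, :n_axes]
    inv_sqrt = 1.0 / np.sqrt(model.eigenvalues[:n_axes])
    records = []
    for subj, Wk in zip(model.subject_ids, model.W_list):
        proj = Wk @ U * inv_sqrt[None, :]
        for r, slot in enumerate(model.slot_labels):
            rec = {"subject_id": subj, "slot": slot}
            rec.update({f"axis{a + 1}": proj[r, a] for a in range(n_axes)})
            records.append(rec)
    return pd.DataFrame.from_records(records)


def metabolite_loadings(
    scaled: ProcessedMatrix, model: StatisModel, n_axes: int = 2
) -> pd.DataFrame:
    """Metabolite coordinates: the alpha-weighted average table projected
    on the compromise axes (X_bar' u_a / sqrt(lambda_a))."""
    if np.any(model.eigenvalues[:n_axes] <= 0):
        raise ValueError("requested axis has zero eigenvalue")
    tables = build_subject_tables(scaled)
    if [t.subject_id for t in tables] != model.subject_ids:
        raise ValueError("scaled data subjects do not match the fitted model")
    X_bar = sum(a * t.X for a, t in zip(model.weights, tables))
    U = model.eigenvectors[:, :n_axes]
    inv_sqrt = 1.0 / np.sqrt(model.eigenvalues[:n_axes])
    L = X_bar.T @ U * inv_sqrt[None, :]
    return pd.DataFrame(
        L,
        index=pd.Index(scaled.log_values.columns, name="metabolite"),
        columns=[f"axis{a + 1}" for a in range(n_axes)],
    )
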