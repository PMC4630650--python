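"""Two-class PLS-DA (treated vs untreated) with leave-one-subject-out Q².

PLS1 regression (NIPALS) of a centered 0/1 class indicator on the
autoscaled metabolite matrix.  Predictive ability is quantified by Q²
from cross-validation whose folds are *subjects*, not samples, so the
repeated measures of one individual are always held out together:

    Q²_a   = 1 − PRESS_a / RSS_{a−1}
    Q²cum_A = 1 − Π_{a≤A} (PRESS_a / RSS_{a−1})

where PRESS_a is the prediction error over held-out subjects of an
a-component model and RSS_{a−1} the residual sum of squares of y after
a−1 components of the full-data model (RSS_0 = centered total SS).  The
multiplicative accumulation is the convention of mainstream chemometrics
software; the plain 1 − PRESS_A/SS_0 figure is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PlsdaModel:
    n_components: int
    x_weights: np.ndarray   # W (p, A)
    x_loadings: np.ndarray  # P (p, A)
    y_loadings: np.ndarray  # c (A,)
    scores: np.ndarray      # T (n, A)
    y_mean: float
    classes: tuple = (0, 1)
    r2y: np.ndarray = field(default=None)
    q2_per_component: np.ndarray | None = None
    q2_cum: np.ndarray | None = None

    @property
    def coef(self) -> np.ndarray:
        """Regression vector b with y_hat = X b + y_mean."""
        W, P, c = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, c)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.x_weights.shape[0]:
            raise ValueError(
                f"expected {self.x_weights.shape[0]} metabolites, got {X.shape[1]}"
            )
        return X @ self.coef + self.y_mean


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS for a single centered response: returns W, P, c, T.

    With one response the weight step is exact (w = X'y normalized), so
    each component is a single pass; X and y are deflated per component.
    """
    X = X.copy()
    y = y.copy()
    n, p = X.shape
    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    c = np.zeros(A)
    T = np.zeros((n, A))
    for a in range(A):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"component {a + 1}: residual X'y is zero")
        w /= norm
        t = X @ w
        tt = t @ t
        if tt == 0:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        p_a = X.T @ t / tt
        c_a = y @ t / tt
        X -= np.outer(t, p_a)
        y = y - c_a * t
        W[:, a], P[:, a], c[a], T[:, a] = w, p_a, c_a, t
    return W, P, c, T


def fit_plsda(
    X: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    n_components: int = 2,
) -> PlsdaModel:
    """Fit PLS-DA on autoscaled X and a two-class label vector."""
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(labels).astype(float)
    uniq = np.unique(y01)
    if uniq.size != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    y01 = (y01 == uniq[1]).astype(float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    y_mean = y01.mean()
    y = y01 - y_mean
    W, P, c, T = _nipals_pls1(X, y, n_components)
    ss0 = float(y @ y)
    r2y = np.array([c[a] ** 2 * (T[:, a] @ T[:, a]) / ss0 for a in range(n_components)])
    return PlsdaModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=c,
        scores=T,
        y_mean=y_mean,
        classes=tuple(uniq),
        r2y=r2y,
    )


def classify(model: PlsdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous predicted class score and the 0.5-threshold class."""
    score = model.predict_score(X)
    predicted = np.where(score >= 0.5, model.classes[1], model.classes[0])
    return predicted, score


def q2_loso(
    X: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Leave-one-subject-out Q² per component and cumulative.

    Folds holding only one class are skipped with a note; an all-skipped
    cross-validation raises.  Returns (q2_per_component, q2_cum, info)
    where info carries RSS/PRESS bookkeeping and skipped folds.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(labels).astype(float)
    uniq = np.unique(y01)
    if uniq.size != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    y01 = (y01 == uniq[1]).astype(float)
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if subjects.size < 3:
        raise ValueError("leave-one-subject-out needs >= 3 subjects")

    A = n_components
    press = np.zeros(A)
    skipped = []
    n_used = 0
    for subj in subjects:
        test = subject_ids == subj
        train = ~test
        y_train = y01[train]
        if np.unique(y_train).size < 2:
            skipped.append(str(subj))
            continue
        y_mean = y_train.mean()
        W, P, c, _ = _nipals_pls1(X[train], y_train - y_mean, A)
        Xt = X[test].copy()
        resid = y01[test] - y_mean
        for a in range(A):
            t = Xt @ W[:, a]
            resid = resid - c[a] * t
            Xt -= np.outer(t, P[:, a])
            press[a] += float(resid @ resid)
        n_used += 1
    if n_used == 0:
        raise ValueError("every fold had a single class; Q2 undefined")

    # Full-data RSS after a components (RSS_0 = centered total SS).
    y = y01 - y01.mean()
    _, _, c_full, T_full = _nipals_pls1(X, y, A)
    rss = np.zeros(A + 1)
    rss[0] = float(y @ y)
    resid = y.copy()
    for a in range(A):
        resid = resid - c_full[a] * T_full[:, a]
        rss[a + 1] = float(resid @ resid)

    q2 = 1.0 - press / rss[:A]
    q2_cum = 1.0 - np.cumprod(press / rss[:A])
    info = {
        "press": press,
        "rss": rss,
        "skipped_folds": skipped,
        "n_folds_used": n_used,
        "q2_simple": 1.0 - press / rss[0],
    }
    return q2, q2_cum, info


def treated_labels(sample_meta: pd.DataFrame) -> np.ndarray:
    """0/1 treated indicator for study samples."""
    return sample_meta["treated"].to_numpy().astype(int)
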