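"""Partial least squares regression from adhesion to migration/invasion.

Rows are conditions (per-condition means): the unit of prediction is an ECM
condition, matching the experimental design in which a model trained on
known ECM proteins is asked about a new one. X and Y are autoscaled (mean 0,
unit variance per column) to nondimensionalize metrics with different units;
components are extracted by NIPALS, each maximizing X-Y covariance, with X
and Y deflated per component.

Diagnostics follow chemometrics practice: R² is the cumulative fraction of
(scaled) Y variance captured; Q² is the leave-one-condition-out predictive
fraction 1 - PRESS/TSS with TSS about the training-fold means; a permutation
test refits the model on row-scrambled Y to build a null Q² distribution;
VIP scores summarize each predictor's contribution, with sum(VIP²) equal to
the number of predictors and VIP > 1 conventionally flagging important
predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "Diagnostics",
    "PermutationResult",
    "PredictionReport",
    "fit_pls",
    "predict",
    "r2_per_component",
    "q2_loocv",
    "permutation_test",
    "vip_scores",
    "choose_components",
    "predict_new_condition",
    "augment_and_refit",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """A fitted NIPALS PLS(2) model plus its training data and scaling."""

    x_columns: list[str]
    y_columns: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    W: np.ndarray           # (p, A) X weights
    P: np.ndarray           # (p, A) X loadings
    Q: np.ndarray           # (m, A) Y loadings
    T: np.ndarray           # (n, A) scores of the training rows
    A: int
    X_train: pd.DataFrame = field(repr=False, default=None)
    Y_train: pd.DataFrame = field(repr=False, default=None)
    dropped_columns: list[str] = field(default_factory=list)

    def coefficients(self, A: int | None = None) -> np.ndarray:
        """Regression coefficients B (p, m) on the autoscaled scale."""
        A = self.A if A is None else A
        W, P, Q = self.W[:, :A], self.P[:, :A], self.Q[:, :A]
        R = W @ np.linalg.pinv(P.T @ W)
        return R @ Q.T


@dataclass
class Diagnostics:
    R2_per_A: np.ndarray
    Q2_per_A: np.ndarray
    chosen_A: int | None = None


@dataclass
class PermutationResult:
    observed_q2: float
    null_q2: np.ndarray
    p_value: float


@dataclass
class PredictionReport:
    condition: str
    predicted: dict[str, float]
    actual: dict[str, float] | None = None
    percent_error: dict[str, float] | None = None


def _autoscale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    return (M - mean) / scale, mean, scale


def fit_pls(X: pd.DataFrame, Y: pd.DataFrame, A: int) -> PLSModel:
    """Fit a NIPALS PLS model with ``A`` components.

    ``X`` and ``Y`` are condition x variable tables sharing an index.
    Zero-variance predictor columns are dropped with a warning; ``A`` is
    truncated to the available rank with a warning. The NIPALS start vector
    is the (scaled) Y column of largest variance, making the fit
    deterministic.
    """
    X = pd.DataFrame(X).astype(float)
    Y = pd.DataFrame(Y).astype(float)
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same rows")
    if len(X) < 3:
        raise ValueError("PLS needs at least 3 condition rows")
    if X.isna().any().any() or Y.isna().any().any():
        raise ValueError("missing values are not allowed")
    if A < 1:
        raise ValueError("A must be >= 1")

    dropped = [c for c in X.columns if X[c].std(ddof=1) == 0.0]
    if dropped:
        warnings.warn(f"zero-variance predictors dropped: {dropped}")
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no predictor with nonzero variance")
    for c in Y.columns:
        if Y[c].std(ddof=1) == 0.0:
            raise ValueError(f"response {c!r} has zero variance")

    Xs, x_mean, x_scale = _autoscale(X.to_numpy())
    Ys, y_mean, y_scale = _autoscale(Y.to_numpy())
    n, p = Xs.shape
    m = Ys.shape[1]
    max_A = min(n - 1, p)
    if A > max_A:
        warnings.warn(f"A={A} exceeds the available rank; truncated to {max_A}")
        A = max_A

    E, F = Xs.copy(), Ys.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    T = np.zeros((n, A))
    n_extracted = 0
    for a in range(A):
        if np.linalg.norm(E) < 1e-12 or np.linalg.norm(F) < 1e-12:
            warnings.warn(f"X or Y exhausted after {a} components; truncating")
            break
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            w = E.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm < 1e-15:
                break
            w /= w_norm
            t = E @ w
            q = F.T @ t / (t @ t)
            if m == 1:
                break  # single response: one pass is exact
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        w = E.T @ u
        w_norm = np.linalg.norm(w)
        if w_norm < 1e-15:
            warnings.warn(f"degenerate component {a + 1}; truncating")
            break
        w /= w_norm
        t = E @ w
        tt = t @ t
        p_load = E.T @ t / tt
        q_load = F.T @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q_load, t
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, q_load)
        n_extracted += 1

    A = n_extracted
    return PLSModel(
        x_columns=list(X.columns), y_columns=list(Y.columns),
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        W=W[:, :A], P=P[:, :A], Q=Q[:, :A], T=T[:, :A], A=A,
        X_train=X, Y_train=Y, dropped_columns=dropped,
    )


def predict(model: PLSModel, X_new: pd.DataFrame, A: int | None = None) -> pd.DataFrame:
    """Predict responses in original units for new condition rows."""
    missing = [c for c in model.x_columns if c not in X_new.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    Xs = (X_new[model.x_columns].to_numpy(float) - model.x_mean) / model.x_scale
    Ys = Xs @ model.coefficients(A)
    Y = Ys * model.y_scale + model.y_mean
    return pd.DataFrame(Y, index=X_new.index, columns=model.y_columns)


def r2_per_component(X: pd.DataFrame, Y: pd.DataFrame, A_max: int) -> np.ndarray:
    """Cumulative fraction of scaled-Y variance captured at 1..A_max."""
    model = fit_pls(X, Y, A_max)
    Ys = (model.Y_train.to_numpy() - model.y_mean) / model.y_scale
    tss = float((Ys**2).sum())
    out = []
    for a in range(1, model.A + 1):
        resid = Ys - model.T[:, :a] @ model.Q[:, :a].T
        out.append(1.0 - float((resid**2).sum()) / tss)
    return np.array(out)


def q2_loocv(X: pd.DataFrame, Y: pd.DataFrame, A_max: int) -> np.ndarray:
    """Leave-one-condition-out Q² for 1..A_max components.

    Each held-out row is predicted from a model refit on the remaining rows
    with the scaling recomputed on that training fold; Q² = 1 - PRESS/TSS
    where TSS measures the held-out responses about the training-fold means.
    """
    X = pd.DataFrame(X)
    Y = pd.DataFrame(Y)
    n = len(X)
    if n < 4:
        raise ValueError("leave-one-out Q² needs at least 4 rows")
    press = np.zeros(A_max)
    tss = 0.0
    actual_A = A_max
    for i in range(n):
        tr = np.arange(n) != i
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X.iloc[tr], Y.iloc[tr], A_max)
        actual_A = min(actual_A, model.A)
        y_true = Y.iloc[[i]].to_numpy(float)
        # errors on the scaled axis so responses are comparable
        y_true_s = (y_true - model.y_mean) / model.y_scale
        tss += float((y_true_s**2).sum())
        for a in range(1, model.A + 1):
            y_hat = predict(model, X.iloc[[i]], A=a).to_numpy()
            y_hat_s = (y_hat - model.y_mean) / model.y_scale
            press[a - 1] += float(((y_true_s - y_hat_s) ** 2).sum())
    return 1.0 - press[:actual_A] / tss


def permutation_test(
    X: pd.DataFrame, Y: pd.DataFrame, A: int, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Null distribution of Q² from models fit on row-scrambled Y.

    The empirical p-value uses the add-one correction
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = float(q2_loocv(X, Y, A)[A - 1])
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(Y)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(Y))
        Yp = pd.DataFrame(Y.to_numpy()[perm], index=Y.index, columns=Y.columns)
        null[b] = q2_loocv(X, Yp, A)[A - 1]
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed_q2=observed, null_q2=null, p_value=p)


def vip_scores(model: PLSModel, response: str | None = None) -> pd.Series:
    """Variable importance in projection, per predictor.

    ``VIP_j = sqrt(p * sum_a SSY_a * (w_ja / ||w_a||)² / sum_a SSY_a)`` where
    ``SSY_a`` is the Y variance explained by component a — summed over all
    responses by default, or weighted by a single response's q loadings when
    ``response`` is given. The identity sum_j VIP_j² = p holds either way.
    """
    W, Q, T = model.W, model.Q, model.T
    tt = (T**2).sum(axis=0)                       # (A,)
    if response is None:
        ssy = tt * (Q**2).sum(axis=0)             # variance explained per component
    else:
        k = model.y_columns.index(response)
        ssy = tt * Q[k, :] ** 2
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    vip = np.sqrt(p * contrib / ssy.sum())
    return pd.Series(vip, index=model.x_columns, name="VIP")


def choose_components(diag: Diagnostics, delta: float = 0.02) -> int:
    """Pick the smallest component count near the best Q² without overfitting.

    Returns the smallest A whose Q² is within ``delta`` of the maximum,
    refusing any A at which Q² has dropped by more than ``delta`` from the
    previous count. If every Q² is negative the model is overfit at any size
    and 1 is returned with a warning.
    """
    q2 = np.asarray(diag.Q2_per_A, float)
    if len(q2) < 2:
        raise ValueError("need diagnostics for at least 2 component counts")
    if np.all(q2 < 0):
        warnings.warn("overfitting: Q² negative at every component count")
        diag.chosen_A = 1
        return 1
    best = float(q2.max())
    for a in range(1, len(q2) + 1):
        if a > 1 and q2[a - 1] < q2[a - 2] - delta:
            break
        if q2[a - 1] >= best - delta:
            diag.chosen_A = a
            return a
    diag.chosen_A = int(np.argmax(q2)) + 1
    return diag.chosen_A


def predict_new_condition(
    model: PLSModel,
    x_new: pd.DataFrame,
    y_actual: pd.DataFrame | None = None,
) -> list[PredictionReport]:
    """Predict one or more new conditions and report percent errors.

    Percent error is 100 * |pred - actual| / |actual|; an actual value of 0
    leaves that entry undefined (NaN) rather than infinite.
    """
    preds = predict(model, x_new)
    out = []
    for idx, row in preds.iterrows():
        actual = None
        perc = None
        if y_actual is not None and idx in y_actual.index:
            actual = {c: float(y_actual.loc[idx, c]) for c in model.y_columns}
            perc = {
                c: (100.0 * abs(row[c] - actual[c]) / abs(actual[c])
                    if actual[c] != 0 else float("nan"))
                for c in model.y_columns
            }
        out.append(PredictionReport(
            condition=str(idx),
            predicted={c: float(row[c]) for c in model.y_columns},
            actual=actual,
            percent_error=perc,
        ))
    return out


def augment_and_refit(
    model: PLSModel,
    X_new_rows: pd.DataFrame,
    Y_new_rows: pd.DataFrame,
) -> PLSModel:
    """Extend the training set with rows from another cell line and refit.

    The new rows must share the model's predictor and response columns;
    scaling is recomputed over the extended matrix and the model refit at the
    same number of components. With zero new rows the model is returned
    unchanged.
    """
    if len(X_new_rows) == 0:
        return model
    missing_x = [c for c in model.x_columns if c not in X_new_rows.columns]
    missing_y = [c for c in model.y_columns if c not in Y_new_rows.columns]
    if missing_x or missing_y:
        raise ValueError(f"schema mismatch: missing {missing_x + missing_y}")
    X_all = pd.concat([model.X_train, X_new_rows[model.x_columns]])
    Y_all = pd.concat([model.Y_train, Y_new_rows[model.y_columns]])
    return fit_pls(X_all, Y_all, model.A)
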