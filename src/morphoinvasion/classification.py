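"""Low/high response labeling and boosted-stump classification.

Conditions are labeled low or high from their mean response: 2D migration is
high when mean speed strictly exceeds 0.5 µm/min; 3D invasion is high when
the mean spheroid fold change strictly exceeds 10 (mesenchymal,
MDA-MB-231-like) or 8 (epithelial, MDA-MB-468-like). Cells inherit their
condition's label, and discrete AdaBoost over decision stumps is trained on
per-cell feature vectors. Classifier quality is scored by AUROC in its
Mann-Whitney form; generalization uses leave-one-condition-out folds so a
held-out ECM condition is never seen in training.

AdaBoost here is the original discrete (Freund-Schapire) variant: at each
round the weighted-error-minimizing stump is found by exhaustive search over
(feature, midpoint threshold, polarity), its vote weight is
``alpha = lr * 0.5 * ln((1 - eps) / eps)``, and sample weights are updated
multiplicatively by ``exp(-alpha * y * h(x))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import FEATURE_NAMES

__all__ = [
    "SPEED_THRESHOLD",
    "INVASION_THRESHOLD_MESENCHYMAL",
    "INVASION_THRESHOLD_EPITHELIAL",
    "FEATURE_GROUPS",
    "MIGRATION_GROUPS",
    "BinaryLabeling",
    "Stump",
    "BoostModel",
    "ClassifierReport",
    "label_conditions",
    "train_adaboost",
    "auroc",
    "rank_single_features",
    "evaluate_feature_groups",
    "grid_search",
]

SPEED_THRESHOLD = 0.5                  # µm/min
INVASION_THRESHOLD_MESENCHYMAL = 10.0  # fold change, MDA-MB-231-like
INVASION_THRESHOLD_EPITHELIAL = 8.0    # fold change, MDA-MB-468-like

#: The three empirical families of adhesion features.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "all": FEATURE_NAMES,
    "size": ("area", "perimeter", "mean_radius", "min_feret", "max_feret"),
    "irregularity": ("solidity", "extent", "form_factor"),
    "elongation": ("eccentricity", "aspect_ratio", "compactness"),
}

MIGRATION_GROUPS: dict[str, tuple[str, ...]] = {
    "speed": ("speed",),
    "persistence": ("persistence",),
    "speed+persistence": ("speed", "persistence"),
}


@dataclass(frozen=True)
class BinaryLabeling:
    response: str                  # "speed" or "invasion"
    threshold: float
    labels: dict[str, str]         # condition -> "low" | "high"

    def sign(self, condition: str) -> int:
        return +1 if self.labels[condition] == "high" else -1


def label_conditions(summaries, response: str, threshold: float | None = None) -> BinaryLabeling:
    """Label each condition low/high by its mean response.

    ``summaries`` is a list of ConditionSummary. "Above" is strict: a mean
    exactly at the threshold is low.
    """
    if response == "speed":
        thr = SPEED_THRESHOLD if threshold is None else threshold
        get = lambda s: s.mean_speed
    elif response == "invasion":
        thr = INVASION_THRESHOLD_MESENCHYMAL if threshold is None else threshold
        get = lambda s: s.mean_invasion
    else:
        raise ValueError(f"unknown response {response!r}")
    if thr <= 0:
        raise ValueError("threshold must be positive")
    labels = {s.condition: ("high" if get(s) > thr else "low") for s in summaries}
    return BinaryLabeling(response=response, threshold=thr, labels=labels)


@dataclass(frozen=True)
class Stump:
    """Decision stump: predicts ``polarity`` where x[feature] > threshold."""

    feature: int
    threshold: float
    polarity: int  # +1 or -1

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(X[:, self.feature] > self.threshold, self.polarity, -self.polarity)


@dataclass
class BoostModel:
    stumps: list[Stump]
    alphas: list[float]
    learning_rate: float
    n_estimators: int
    feature_names: tuple[str, ...] = ()

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        F = np.zeros(len(X))
        for stump, alpha in zip(self.stumps, self.alphas):
            F += alpha * stump.predict(X)
        return F

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[Stump, float]:
    """Exhaustive weighted-error-minimizing stump.

    Thresholds are midpoints between consecutive sorted unique values of each
    feature (plus one threshold below all values). Ties in weighted error are
    broken by smaller threshold, then lower feature index; polarity +1 is
    preferred on exact ties.
    """
    n, p = X.shape
    w = w / w.sum()
    best: tuple[float, float, int, int] | None = None  # (err, thr, feature, -pol)
    for j in range(p):
        xj = X[:, j]
        order = np.argsort(xj, kind="mergesort")
        xs, ws, ys = xj[order], w[order], y[order]
        cpos = np.concatenate([[0.0], np.cumsum(np.where(ys > 0, ws, 0.0))])
        cneg = np.concatenate([[0.0], np.cumsum(np.where(ys < 0, ws, 0.0))])
        # split after the first k samples; k=0 puts the threshold below all
        valid = np.concatenate([[True], xs[:-1] < xs[1:]])
        k = np.nonzero(valid)[0]
        thr = np.where(k == 0, xs[0] - 1.0, (xs[np.maximum(k - 1, 0)] + xs[k]) / 2.0)
        # "predict +1 where x > thr" misclassifies positives at/below and
        # negatives above the threshold
        err_pos = cpos[k] + (cneg[-1] - cneg[k])
        errs = np.concatenate([err_pos, 1.0 - err_pos])
        # snap float-noise-level differences so tie-breaks are stable
        errs = np.round(errs, 12)
        thrs = np.concatenate([thr, thr])
        pols = np.concatenate([np.ones(len(k), int), -np.ones(len(k), int)])
        i = np.lexsort((-pols, thrs, errs))[0]
        cand = (float(errs[i]), float(thrs[i]), j, -int(pols[i]))
        if best is None or cand < best:
            best = cand
    err, thr, j, neg_pol = best
    return Stump(feature=j, threshold=thr, polarity=-neg_pol), err


def train_adaboost(
    X: np.ndarray,
    y: np.ndarray,
    n_estimators: int = 50,
    learning_rate: float = 1.0,
    feature_names: tuple[str, ...] = (),
) -> BoostModel:
    """Discrete AdaBoost over decision stumps.

    ``y`` holds +/-1 labels with both classes present. Initial weights are
    uniform per cell. Training stops early when a round's weighted error
    reaches 0 (the perfect stump is recorded with a large finite vote) or
    0.5 (no weak learner better than chance remains).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with one label per row")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.bincount((y > 0).astype(int)).min() < 2:
        raise ValueError("need at least 2 cells per class")
    n = len(X)
    w = np.full(n, 1.0 / n)
    stumps: list[Stump] = []
    alphas: list[float] = []
    eps_floor = 1e-12
    for _ in range(n_estimators):
        stump, err = _best_stump(X, y, w)
        if err >= 0.5:
            break
        alpha = learning_rate * 0.5 * np.log((1.0 - err) / max(err, eps_floor))
        stumps.append(stump)
        alphas.append(float(alpha))
        if err <= eps_floor:
            break  # perfect stump recorded; nothing left to reweight
        pred = stump.predict(X)
        w = w * np.exp(-alpha * y * pred)
        w = w / w.sum()
    return BoostModel(
        stumps=stumps, alphas=alphas, learning_rate=learning_rate,
        n_estimators=n_estimators, feature_names=tuple(feature_names),
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) with ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels > 0]
    neg = scores[labels < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUROC")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


@dataclass
class ClassifierReport:
    feature_set: str
    auroc_train: float
    auroc_cv: float                      # pooled leave-one-condition-out
    fold_aurocs: dict[str, float] = field(default_factory=dict)
    n_cells: int = 0


def _cells_and_labels(
    cells: pd.DataFrame, labeling: BinaryLabeling, features: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = cells[cells["condition"].isin(labeling.labels)].reset_index(drop=True)
    X = df[list(features)].to_numpy(float)
    y = np.array([labeling.sign(c) for c in df["condition"]])
    return X, y, df["condition"].to_numpy()


def _loco_scores(
    X: np.ndarray, y: np.ndarray, cond: np.ndarray,
    n_estimators: int, learning_rate: float,
) -> tuple[np.ndarray, dict[str, float]]:
    """Leave-one-condition-out decision scores plus per-fold AUROCs.

    Held-out scores are centered on the training fold's mean decision score
    before pooling: training folds are class-imbalanced (a whole condition is
    missing), which offsets the decision scale per fold and would otherwise
    bias the pooled AUROC even for pure-noise features. Folds whose training
    split loses a class, or whose held-out cells are single-class, have no
    per-fold AUROC; the pooled scores still count.
    """
    scores = np.zeros(len(X))
    fold_auc: dict[str, float] = {}
    for held in np.unique(cond):
        test = cond == held
        train = ~test
        if len(np.unique(y[train])) < 2:
            scores[test] = 0.0
            continue
        model = train_adaboost(X[train], y[train], n_estimators, learning_rate)
        s = model.decision_function(X[test]) - model.decision_function(X[train]).mean()
        scores[test] = s
        if len(np.unique(y[test])) == 2:
            fold_auc[str(held)] = auroc(s, y[test])
    return scores, fold_auc


def rank_single_features(
    cells: pd.DataFrame,
    labeling: BinaryLabeling,
    features: tuple[str, ...] = FEATURE_NAMES,
    n_estimators: int = 50,
    learning_rate: float = 1.0,
) -> pd.DataFrame:
    """Rank features by their training-set AUROC as one-feature classifiers.

    Sorted by descending AUROC with a deterministic alphabetical tie-break.
    """
    rows = []
    for name in features:
        X, y, _ = _cells_and_labels(cells, labeling, (name,))
        model = train_adaboost(X, y, n_estimators, learning_rate)
        rows.append((name, auroc(model.decision_function(X), y)))
    df = pd.DataFrame(rows, columns=["feature", "auroc"])
    return df.sort_values(
        ["auroc", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def evaluate_feature_groups(
    cells: pd.DataFrame,
    labeling: BinaryLabeling,
    groups: dict[str, tuple[str, ...]] | None = None,
    n_estimators: int = 50,
    learning_rate: float = 1.0,
) -> list[ClassifierReport]:
    """Train one boosted model per feature group and score it.

    Reports the training-set AUROC side by side with the pooled
    leave-one-condition-out AUROC. Duplicate features within a group are
    deduplicated with a warning; an empty group is an error.
    """
    if groups is None:
        groups = FEATURE_GROUPS
    out = []
    for name, feats in groups.items():
        if not feats:
            raise ValueError(f"feature group {name!r} is empty")
        seen: list[str] = []
        for f in feats:
            if f in seen:
                warnings.warn(f"duplicate feature {f!r} in group {name!r} ignored")
            else:
                seen.append(f)
        X, y, cond = _cells_and_labels(cells, labeling, tuple(seen))
        model = train_adaboost(X, y, n_estimators, learning_rate)
        auc_train = auroc(model.decision_function(X), y)
        cv_scores, fold_auc = _loco_scores(X, y, cond, n_estimators, learning_rate)
        out.append(ClassifierReport(
            feature_set=name,
            auroc_train=auc_train,
            auroc_cv=auroc(cv_scores, y),
            fold_aurocs=fold_auc,
            n_cells=len(X),
        ))
    return out


def grid_search(
    cells: pd.DataFrame,
    labeling: BinaryLabeling,
    rates: tuple[float, ...] = (0.5, 1.0, 1.5),
    estimator_counts: tuple[int, ...] = (10, 50, 100),
    features: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Full factorial hyperparameter grid of leave-one-condition-out AUROC.

    One row per (learning_rate, n_estimators) cell; the recommended default
    (1.0, 50) is flagged in the ``default`` column.
    """
    if not rates or not estimator_counts:
        raise ValueError("grids must be non-empty")
    X, y, cond = _cells_and_labels(cells, labeling, features)
    rows = []
    for lr in rates:
        for ne in estimator_counts:
            cv_scores, _ = _loco_scores(X, y, cond, ne, lr)
            rows.append((lr, ne, auroc(cv_scores, y), lr == 1.0 and ne == 50))
    return pd.DataFrame(rows, columns=["learning_rate", "n_estimators", "auroc_cv", "default"])
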