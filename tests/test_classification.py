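"""Labeling rules, discrete AdaBoost, AUROC and feature-group analyses."""

import numpy as np
import pandas as pd
import pytest

from morphoinvasion.classification import (
    FEATURE_GROUPS,
    BinaryLabeling,
    auroc,
    evaluate_feature_groups,
    grid_search,
    label_conditions,
    rank_single_features,
    train_adaboost,
)
from morphoinvasion.classification import _best_stump
from morphoinvasion.condition_stats import ConditionSummary
from morphoinvasion.morphometry import FEATURE_NAMES


def summary(name, speed=0.4, invasion=5.0):
    return ConditionSummary(
        condition=name, cell_line="231",
        mean_features=dict.fromkeys(FEATURE_NAMES, 1.0),
        mean_speed=speed, mean_persistence=0.3,
        mean_invasion=invasion, n_cells=10,
    )


class TestLabeling:
    def test_speed_above_half_micron_per_minute_is_high(self):
        lab = label_conditions([summary("a", speed=0.6)], "speed")
        assert lab.labels["a"] == "high"

    def test_boundary_equality_is_low(self):
        lab = label_conditions([summary("a", speed=0.5)], "speed")
        assert lab.labels["a"] == "low"

    def test_invasion_thresholds(self):
        s = [summary("a", invasion=12.0), summary("b", invasion=9.0)]
        lab10 = label_conditions(s, "invasion", 10.0)
        assert lab10.labels == {"a": "high", "b": "low"}
        lab8 = label_conditions(s, "invasion", 8.0)
        assert lab8.labels == {"a": "high", "b": "high"}

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError):
            label_conditions([summary("a")], "area")


class TestAdaBoost:
    def test_separable_1d_needs_one_stump(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        model = train_adaboost(X, y)
        assert len(model.stumps) == 1
        assert np.array_equal(model.predict(X), y)

    def test_alpha_closed_form(self):
        """A round-1 weighted error of 1/4 gives alpha = ln(3)/2."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([-1, 1, -1, 1])
        model = train_adaboost(X, y, n_estimators=1)
        assert model.alphas[0] == pytest.approx(0.5 * np.log(3.0))

    def test_learning_rate_scales_alpha(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([-1, 1, -1, 1])
        a1 = train_adaboost(X, y, n_estimators=1, learning_rate=1.0).alphas[0]
        a05 = train_adaboost(X, y, n_estimators=1, learning_rate=0.5).alphas[0]
        assert a05 == pytest.approx(0.5 * a1)

    def test_round1_stump_matches_exhaustive_search(self):
        """On 20-point data the first stump equals a brute-force enumeration
        of every (feature, midpoint threshold, polarity) triple."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.normal(size=(20, 2))
            y = np.where(rng.uniform(size=20) > 0.4, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            w = np.full(20, 1 / 20)
            stump, err = _best_stump(X, y, w.copy())
            best = None
            for j in range(2):
                u = np.unique(X[:, j])
                for thr in np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2]):
                    pred = np.where(X[:, j] > thr, 1, -1)
                    e = float(w[pred != y].sum())
                    for pol, e_pol in ((1, e), (-1, 1 - e)):
                        key = (round(e_pol, 12), thr, j, -pol)
                        if best is None or key < best:
                            best = key
            assert (err, stump.threshold, stump.feature, -stump.polarity) == pytest.approx(best)

    def test_exponential_loss_non_increasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 3))
        y = np.where(X[:, 0] + rng.normal(0, 1.2, 80) > 0, 1, -1)
        model = train_adaboost(X, y, n_estimators=30)
        F = np.zeros(80)
        losses = []
        for stump, alpha in zip(model.stumps, model.alphas):
            F += alpha * stump.predict(X)
            losses.append(np.exp(-y * F).sum())
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_full_model_matches_brute_force_reimplementation(self):
        """Training predictions of the boosted model agree with an
        independent re-implementation that enumerates stumps per round."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 2))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.8, 25) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        model = train_adaboost(X, y, n_estimators=10)

        # independent discrete AdaBoost
        w = np.full(len(y), 1.0 / len(y))
        F = np.zeros(len(y))
        for _ in range(10):
            best = None
            for j in range(2):
                u = np.unique(X[:, j])
                for thr in np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2]):
                    for pol in (1, -1):
                        pred = np.where(X[:, j] > thr, pol, -pol)
                        e = float(w[pred != y].sum())
                        key = (round(e, 12), thr, j, -pol)
                        if best is None or key < best[0]:
                            best = (key, pred, e)
            _, pred, e = best
            if e >= 0.5:
                break
            alpha = 0.5 * np.log((1 - e) / max(e, 1e-12))
            F += alpha * pred
            if e <= 1e-12:
                break
            w = w * np.exp(-alpha * y * pred)
            w /= w.sum()
        assert np.array_equal(np.sign(model.decision_function(X)), np.sign(F))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_adaboost(np.zeros((4, 1)), np.ones(4, dtype=int))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, -1, -1])) == 1.0

    def test_hand_pair_count(self):
        """3 of 4 (pos, neg) pairs correctly ordered."""
        assert auroc(np.array([0.8, 0.3, 0.6, 0.1]), np.array([1, 1, -1, -1])) == 0.75

    def test_all_ties_give_half(self):
        assert auroc(np.ones(6), np.array([1, 1, 1, -1, -1, -1])) == 0.5

    def test_matches_sklearn_and_label_flip_symmetry(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        s = rng.normal(size=300)
        y = np.where(rng.uniform(size=300) > 0.5, 1, -1)
        a = auroc(s, y)
        assert a == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert auroc(s, -y) == pytest.approx(1 - a, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=100)
        y = np.where(rng.uniform(size=100) > 0.5, 1, -1)
        assert auroc(np.exp(s), y) == pytest.approx(auroc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.array([1.0, 2.0]), np.array([1, 1]))


def _signal_cells(rng, n_per_cond=30, signal_feature="eccentricity"):
    """Six conditions where only one feature separates low from high."""
    rows = []
    for c in range(6):
        high = c >= 3
        for _ in range(n_per_cond):
            feats = {f: rng.normal(0, 1) for f in FEATURE_NAMES}
            feats[signal_feature] = rng.normal(3.0 if high else 0.0, 1.0)
            rows.append({"condition": f"c{c}", **feats})
    labels = {f"c{c}": ("high" if c >= 3 else "low") for c in range(6)}
    return pd.DataFrame(rows), BinaryLabeling("speed", 0.5, labels)


class TestRanking:
    def test_signal_feature_ranked_first(self):
        cells, labeling = _signal_cells(np.random.default_rng(2))
        ranking = rank_single_features(cells, labeling)
        assert ranking.iloc[0]["feature"] == "eccentricity"
        assert ranking.iloc[0]["auroc"] > 0.95

    def test_noise_features_near_chance(self):
        rng = np.random.default_rng(3)
        rows = [{"condition": f"c{c}", **{f: rng.normal() for f in FEATURE_NAMES}}
                for c in range(4) for _ in range(50)]
        labeling = BinaryLabeling("speed", 0.5,
                                  {f"c{c}": ("high" if c >= 2 else "low") for c in range(4)})
        ranking = rank_single_features(pd.DataFrame(rows), labeling)
        # training AUROC of a boosted one-feature model is optimistically
        # biased on noise, but leave-one-condition-out stays near chance
        reports = evaluate_feature_groups(
            pd.DataFrame(rows), labeling, {"one": ("area",)})
        assert abs(reports[0].auroc_cv - 0.5) < 0.2
        assert set(ranking["feature"]) == set(FEATURE_NAMES)

    def test_ranking_invariant_to_column_order(self):
        cells, labeling = _signal_cells(np.random.default_rng(4))
        shuffled = cells[["condition", *reversed(FEATURE_NAMES)]]
        r1 = rank_single_features(cells, labeling)
        r2 = rank_single_features(shuffled, labeling)
        assert list(r1["feature"]) == list(r2["feature"])


class TestGroupsAndGrid:
    def test_all_features_beat_chance_on_linked_data(self):
        cells, labeling = _signal_cells(np.random.default_rng(5))
        reports = evaluate_feature_groups(cells, labeling)
        by_name = {r.feature_set: r for r in reports}
        assert by_name["all"].auroc_cv >= 0.9
        assert by_name["elongation"].auroc_cv >= 0.9
        assert by_name["all"].auroc_cv > by_name["size"].auroc_cv

    def test_duplicate_feature_deduplicated_with_warning(self):
        cells, labeling = _signal_cells(np.random.default_rng(6))
        with pytest.warns(UserWarning, match="duplicate"):
            reports = evaluate_feature_groups(
                cells, labeling, {"dup": ("area", "area")})
        assert reports[0].feature_set == "dup"

    def test_empty_group_rejected(self):
        cells, labeling = _signal_cells(np.random.default_rng(7))
        with pytest.raises(ValueError, match="empty"):
            evaluate_feature_groups(cells, labeling, {"none": ()})

    def test_one_by_one_grid_matches_group_evaluation(self):
        cells, labeling = _signal_cells(np.random.default_rng(8))
        grid = grid_search(cells, labeling, rates=(1.0,), estimator_counts=(50,))
        reports = evaluate_feature_groups(cells, labeling, {"all": FEATURE_NAMES})
        assert len(grid) == 1
        assert grid.iloc[0]["auroc_cv"] == pytest.approx(reports[0].auroc_cv)
        assert bool(grid.iloc[0]["default"])

    def test_grid_robust_on_separable_data(self):
        cells, labeling = _signal_cells(np.random.default_rng(9))
        grid = grid_search(cells, labeling, rates=(0.5, 1.0),
                           estimator_counts=(10, 50))
        assert (grid["auroc_cv"] >= 0.9).all()
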