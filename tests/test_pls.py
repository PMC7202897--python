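"""NIPALS PLS: oracles, diagnostics, permutation null, VIP, prediction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from morphoinvasion.pls import (
    Diagnostics,
    augment_and_refit,
    choose_components,
    fit_pls,
    permutation_test,
    predict,
    predict_new_condition,
    q2_loocv,
    r2_per_component,
    vip_scores,
)


def latent_data(seed=0, n=8, p=6, m=3, rank=2, noise=0.0):
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(n, rank))
    X = T @ rng.normal(size=(rank, p)) + noise * rng.normal(size=(n, p))
    Y = T @ rng.normal(size=(rank, m)) + noise * rng.normal(size=(n, m))
    return (pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]),
            pd.DataFrame(Y, columns=[f"y{i}" for i in range(m)]))


class TestFit:
    def test_exact_latent_model_fully_captured(self):
        X, Y = latent_data()
        assert r2_per_component(X, Y, 2)[-1] >= 0.999

    def test_single_predictor_reduces_to_univariate_regression(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = 2.5 * x + rng.normal(0, 0.1, 10)
        X = pd.DataFrame({"x": x})
        Y = pd.DataFrame({"y": y})
        model = fit_pls(X, Y, 1)
        slope_scaled = model.coefficients()[0, 0]
        slope = slope_scaled * model.y_scale[0] / model.x_scale[0]
        ols = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(ols, abs=1e-9)

    def test_first_weight_vector_matches_eigen_oracle(self):
        """w1 is the dominant eigenvector of Xs' Ys Ys' Xs."""
        X, Y = latent_data(seed=3, n=6, p=4, m=2, noise=0.3)
        model = fit_pls(X, Y, 1)
        Xs = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        Ys = ((Y - Y.mean()) / Y.std(ddof=1)).to_numpy()
        M = Xs.T @ Ys @ Ys.T @ Xs
        evals, evecs = np.linalg.eigh(M)
        v = evecs[:, -1]
        assert min(np.abs(model.W[:, 0] - v).max(),
                   np.abs(model.W[:, 0] + v).max()) < 1e-6

    def test_scores_orthogonal(self):
        X, Y = latent_data(seed=4, noise=0.5)
        model = fit_pls(X, Y, 3)
        G = model.T.T @ model.T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_zero_variance_column_dropped_with_warning(self):
        X, Y = latent_data(seed=5)
        X = X.assign(const=1.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_pls(X, Y, 2)
        assert "const" not in model.x_columns

    def test_rank_truncation_warns(self):
        X, Y = latent_data(seed=6, n=4, p=6)
        with pytest.warns(UserWarning, match="truncated"):
            model = fit_pls(X, Y, 5)
        assert model.A <= 3

    def test_predictor_scale_invariance(self):
        """Multiplying a predictor column by a constant changes nothing."""
        X, Y = latent_data(seed=7, noise=0.2)
        m1 = fit_pls(X, Y, 2)
        X2 = X.copy()
        X2["x0"] = X2["x0"] * 137.0
        m2 = fit_pls(X2, Y, 2)
        assert np.allclose(predict(m1, X).to_numpy(), predict(m2, X2).to_numpy(), atol=1e-9)
        assert np.allclose(vip_scores(m1).to_numpy(), vip_scores(m2).to_numpy(), atol=1e-9)


class TestDiagnostics:
    def test_q2_high_for_noise_free_latent_link(self):
        X, Y = latent_data(seed=8, n=8, noise=0.0)
        q2 = q2_loocv(X, Y, 2)
        assert q2[-1] >= 0.95

    def test_q2_le_r2_and_r2_monotone(self):
        X, Y = latent_data(seed=9, noise=0.8)
        r2 = r2_per_component(X, Y, 3)
        q2 = q2_loocv(X, Y, 3)
        assert np.all(np.diff(r2) >= -1e-12)
        assert np.all(q2 <= r2 + 1e-9)

    def test_pure_noise_q2_negative_on_average(self):
        """LOOCV on unrelated X and Y is negatively biased: mean Q² <= 0
        over 50 draws."""
        vals = []
        for s in range(50):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(size=(8, 6)))
            Y = pd.DataFrame(rng.normal(size=(8, 2)))
            vals.append(q2_loocv(X, Y, 2)[-1])
        assert np.mean(vals) <= 0.0

    def test_fold_mean_reference_is_zero_q2_anchor(self):
        """Predicting each held-out row by the training-fold mean gives
        Q² ~ 0 by construction (slightly negative for finite n)."""
        rng = np.random.default_rng(10)
        Y = pd.DataFrame(rng.normal(size=(30, 2)))
        n = len(Y)
        press = tss = 0.0
        for i in range(n):
            tr = np.arange(n) != i
            mu = Y[tr].mean()
            sd = Y[tr].std(ddof=1)
            resid = ((Y.iloc[i] - mu) / sd) ** 2
            press += resid.sum()
            tss += resid.sum()
        assert 1 - press / tss == pytest.approx(0.0, abs=1e-12)

    def test_too_few_rows_rejected(self):
        X, Y = latent_data(n=3)
        with pytest.raises(ValueError):
            q2_loocv(X, Y, 1)


class TestPermutation:
    def test_strong_link_is_significant(self):
        X, Y = latent_data(seed=11, n=8, noise=0.1)
        res = permutation_test(X, Y, 2, n_perm=200, seed=0)
        assert res.p_value <= 0.05

    def test_null_p_values_calibrated(self):
        """On pure-noise responses the p-value is roughly uniform: its mean
        over 20 repeats lies in [0.3, 0.7]."""
        ps = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            X = pd.DataFrame(rng.normal(size=(8, 4)))
            Y = pd.DataFrame(rng.normal(size=(8, 1)))
            ps.append(permutation_test(X, Y, 1, n_perm=100, seed=s).p_value)
        assert 0.3 <= np.mean(ps) <= 0.7

    def test_fixed_seed_reproducible(self):
        X, Y = latent_data(seed=12, noise=0.5)
        a = permutation_test(X, Y, 1, n_perm=100, seed=3)
        b = permutation_test(X, Y, 1, n_perm=100, seed=3)
        assert np.array_equal(a.null_q2, b.null_q2)


class TestVip:
    def test_equal_weights_give_unit_vips(self):
        """A single component with equal |w_j| makes every VIP exactly 1."""
        rng = np.random.default_rng(13)
        t = rng.normal(size=12)
        X = pd.DataFrame({f"x{i}": t + rng.normal(0, 1e-8, 12) for i in range(4)})
        Y = pd.DataFrame({"y": 2 * t})
        model = fit_pls(X, Y, 1)
        assert np.allclose(vip_scores(model).to_numpy(), 1.0, atol=1e-3)

    def test_sum_of_squares_identity(self):
        for s in range(5):
            X, Y = latent_data(seed=20 + s, noise=0.7)
            model = fit_pls(X, Y, 3)
            v = vip_scores(model)
            assert (v**2).sum() == pytest.approx(len(model.x_columns), abs=1e-6)
            for resp in model.y_columns:
                vr = vip_scores(model, response=resp)
                assert (vr**2).sum() == pytest.approx(len(model.x_columns), abs=1e-6)

    def test_hand_model_matches_direct_formula(self):
        """VIPs recomputed by independent scalar arithmetic from W, Q, T."""
        X, Y = latent_data(seed=30, n=6, p=4, m=2, noise=0.4)
        model = fit_pls(X, Y, 2)
        p = 4
        ssy = [float((model.T[:, a] ** 2).sum() * (model.Q[:, a] ** 2).sum())
               for a in range(2)]
        expected = []
        for j in range(p):
            acc = sum(ssy[a] * (model.W[j, a] ** 2 / (model.W[:, a] ** 2).sum())
                      for a in range(2))
            expected.append(np.sqrt(p * acc / sum(ssy)))
        assert np.allclose(vip_scores(model).to_numpy(), expected, atol=1e-10)


class TestChooseComponents:
    def test_within_delta_rule(self):
        assert choose_components(Diagnostics(None, np.array([0.3, 0.7, 0.71, 0.65]))) == 2

    def test_monotone_q2_takes_maximum(self):
        assert choose_components(Diagnostics(None, np.array([0.2, 0.4, 0.6]))) == 3

    def test_plateau_after_two_components(self):
        """A Q² profile that rises to ~0.75 at two components and flattens
        selects two."""
        assert choose_components(Diagnostics(None, np.array([0.4, 0.75, 0.74]))) == 2

    def test_all_negative_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="overfit"):
            assert choose_components(Diagnostics(None, np.array([-0.2, -0.5]))) == 1


class TestPrediction:
    def test_training_row_recovered_in_exact_model(self):
        X, Y = latent_data(seed=31, noise=0.0)
        model = fit_pls(X, Y, 2)
        reports = predict_new_condition(model, X.iloc[[0]], Y.iloc[[0]])
        assert all(e < 1e-6 for e in reports[0].percent_error.values())

    def test_column_means_map_to_response_means(self):
        X, Y = latent_data(seed=32, noise=0.5)
        model = fit_pls(X, Y, 2)
        x_mean = pd.DataFrame([X.mean()], index=["mean"])
        pred = predict(model, x_mean)
        assert np.allclose(pred.to_numpy()[0], Y.mean().to_numpy(), atol=1e-9)

    def test_zero_actual_gives_nan_percent_error(self):
        X, Y = latent_data(seed=33)
        model = fit_pls(X, Y, 2)
        y0 = Y.iloc[[0]].copy()
        y0.iloc[0, 0] = 0.0
        rep = predict_new_condition(model, X.iloc[[0]], y0)[0]
        assert np.isnan(rep.percent_error[model.y_columns[0]])

    def test_missing_predictor_rejected(self):
        X, Y = latent_data(seed=34)
        model = fit_pls(X, Y, 1)
        with pytest.raises(ValueError, match="missing"):
            predict(model, X.drop(columns=["x0"]))


class TestAugmentation:
    def test_zero_rows_is_identity(self):
        X, Y = latent_data(seed=35)
        model = fit_pls(X, Y, 2)
        assert augment_and_refit(model, X.iloc[:0], Y.iloc[:0]) is model

    def test_added_rows_predicted_after_refit(self):
        X, Y = latent_data(seed=36, n=10, noise=0.0)
        model = fit_pls(X.iloc[:7], Y.iloc[:7], 2)
        model2 = augment_and_refit(model, X.iloc[7:], Y.iloc[7:])
        reports = predict_new_condition(model2, X.iloc[7:], Y.iloc[7:])
        for rep in reports:
            assert all(e < 1.0 for e in rep.percent_error.values())

    def test_schema_mismatch_rejected(self):
        X, Y = latent_data(seed=37)
        model = fit_pls(X, Y, 1)
        with pytest.raises(ValueError, match="schema"):
            augment_and_refit(model, X.rename(columns={"x0": "zz"}), Y)


def test_permutation_null_contains_scrambled_observation():
    """Fitting on already-scrambled Y gives an observed Q² that falls inside
    the null's central 95% band in most repeats."""
    hits = 0
    reps = 20
    for s in range(reps):
        rng = np.random.default_rng(200 + s)
        X = pd.DataFrame(rng.normal(size=(8, 4)))
        Y = pd.DataFrame(rng.normal(size=(8, 1)))
        res = permutation_test(X, Y, 1, n_perm=100, seed=s)
        lo, hi = np.quantile(res.null_q2, [0.025, 0.975])
        hits += lo <= res.observed_q2 <= hi
    assert hits >= int(0.9 * reps)
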