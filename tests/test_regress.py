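import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaphorspace.errors import InsufficientDataError
from metaphorspace.regress import (
    FeatureMatrix,
    accuracy_metric,
    fisher_r_to_z_test,
    loo_linear_cv,
    loo_logistic_ovr_cv,
    permutation_test,
    rank_single_features,
    standardize_features,
    vif_select,
)


def fm(arr, columns=None, standardized=False):
    df = pd.DataFrame(np.asarray(arr, dtype=float), columns=columns)
    return FeatureMatrix(df, standardized=standardized)


class TestStandardize:
    def test_symmetric_triple(self):
        out = standardize_features(fm([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.data.to_numpy().ravel(), [-1.0, 0.0, 1.0])
        assert out.standardized

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_features(fm([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(out.data.iloc[:, 0] == 0.0)

    def test_moment_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 6)) * rng.uniform(0.5, 4, 6) + rng.uniform(-3, 3, 6)
        Z = standardize_features(fm(X)).data.to_numpy()
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            standardize_features(fm([[1.0]]))


class TestLooLinear:
    def test_noiseless_linear_target_recovers_r_of_one(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 4))
        y = X @ np.array([2.0, -1.0, 0.5, 3.0]) + 1.5
        F = standardize_features(fm(X))
        cv = loo_linear_cv(F, y)
        assert cv.summary == pytest.approx(1.0, abs=1e-9)
        assert len(cv.predictions) == 30

    def test_three_row_toy_matches_hand_solution(self):
        F = fm([[0.0], [1.0], [2.0]], standardized=True)
        cv = loo_linear_cv(F, np.array([0.0, 1.0, 4.0]))
        assert np.allclose(cv.predictions, [-2.0, 2.0, 2.0], atol=1e-10)

    def test_pure_noise_target_gives_near_zero_r(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 5))
        y = rng.standard_normal(200)
        cv = loo_linear_cv(standardize_features(fm(X)), y)
        assert abs(cv.summary) < 0.2

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.standard_normal(40)
        F = standardize_features(fm(X))
        cv = loo_linear_cv(F, y)
        perm = rng.permutation(40)
        Fp = FeatureMatrix(
            F.data.iloc[perm].reset_index(drop=True), standardized=True
        )
        cvp = loo_linear_cv(Fp, y[perm])
        assert np.allclose(cvp.predictions, cv.predictions[perm], atol=1e-9)
        assert cvp.summary == pytest.approx(cv.summary, abs=1e-10)

    def test_parameter_recovery_low_noise(self):
        rng = np.random.default_rng(5)
        n, p = 200, 8
        X = rng.standard_normal((n, p))
        beta = rng.uniform(-2, 2, p)
        sigma = 0.1
        y = X @ beta + sigma * rng.standard_normal(n)
        F = FeatureMatrix(pd.DataFrame(X), standardized=True)
        cv = loo_linear_cv(F, y)
        assert cv.summary >= 0.9
        # all-in OLS coefficients within 3 SE of truth
        A = np.column_stack([np.ones(n), X])
        bhat, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ bhat
        s2 = resid @ resid / (n - p - 1)
        cov = s2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))[1:]
        assert np.all(np.abs(bhat[1:] - beta) <= 3 * se)

    def test_unstandardized_input_warns(self):
        with pytest.warns(UserWarning, match="not standardized"):
            loo_linear_cv(fm([[0.0], [1.0], [2.0]]), np.array([0.0, 1.0, 2.0]))

    def test_fold_standardization_close_to_global_on_clean_signal(self):
        # leakage-free per-fold standardization barely moves the summary
        # when the signal is strong, and needs no global pre-processing
        rng = np.random.default_rng(21)
        X = rng.standard_normal((80, 4)) * [1.0, 5.0, 0.2, 2.0]
        y = X @ np.array([1.0, -0.4, 3.0, 0.7]) + 0.3 * rng.standard_normal(80)
        global_cv = loo_linear_cv(standardize_features(fm(X)), y)
        fold_cv = loo_linear_cv(fm(X), y, fold_standardize=True)
        assert fold_cv.summary == pytest.approx(global_cv.summary, abs=0.02)
        assert fold_cv.summary >= 0.9


class TestLooLogisticOvr:
    def test_perfectly_separable_classes(self):
        rng = np.random.default_rng(6)
        centers = {"literal": (-6, 0), "conventional": (0, 6), "novel": (6, 0)}
        X, labels = [], []
        for cls, (cx, cy) in centers.items():
            X.append(rng.standard_normal((12, 2)) * 0.3 + [cx, cy])
            labels += [cls] * 12
        F = standardize_features(fm(np.vstack(X)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = loo_logistic_ovr_cv(F, np.array(labels))
        assert cv.summary == 1.0

    def test_shuffled_labels_accuracy_in_null_band(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((228, 10))
        labels = np.array(["literal", "conventional", "novel"] * 76)
        rng.shuffle(labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = loo_logistic_ovr_cv(standardize_features(fm(X)), labels)
        assert 0.15 <= cv.summary <= 0.5

    def test_requires_two_classes(self):
        F = fm([[0.0], [1.0]], standardized=True)
        with pytest.raises(ValueError):
            loo_logistic_ovr_cv(F, np.array(["a", "a"]))


class TestRankSingleFeatures:
    def test_identical_and_negated_targets(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(30)
        X = np.column_stack([y, -y, rng.standard_normal(30)])
        ranked = rank_single_features(fm(X, columns=["same", "neg", "noise"]), y)
        # |r| = 1 for both; lexicographic tie-break puts "neg" first
        assert [name for name, _ in ranked[:2]] == ["neg", "same"]
        assert ranked[0][1] == pytest.approx(-1.0)
        assert ranked[1][1] == pytest.approx(1.0)
        assert ranked[2][0] == "noise"

    def test_zero_variance_feature_warns_r_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            ranked = rank_single_features(
                fm(X, columns=["const", "lin"]), np.arange(10.0)
            )
        assert dict(ranked)["const"] == 0.0

    def test_formula_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        ranked = dict(rank_single_features(fm(X), y))
        for j in range(4):
            x = X[:, j]
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert ranked[j] == pytest.approx(num / den, abs=1e-12)


class TestVifSelect:
    def test_duplicate_feature_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(40)
        F = fm(np.column_stack([x, x]), columns=["a", "a_copy"], standardized=True)
        sel = vif_select([("a", 0.9), ("a_copy", 0.9)], F)
        assert sel.selected == ["a"]
        assert "a_copy" in sel.rejected

    def test_orthogonal_features_all_accepted(self):
        rng = np.random.default_rng(11)
        Q, _ = np.linalg.qr(rng.standard_normal((60, 6)))
        cols = [f"f{j}" for j in range(6)]
        F = fm(Q, columns=cols, standardized=True)
        ranked = [(c, 0.9 - 0.1 * j) for j, c in enumerate(cols)]
        sel = vif_select(ranked, F, fac=2.0, max_features=5)
        assert sel.selected == cols[:5]  # stops at max_features

    def test_planted_r_squared_thresholds(self):
        rng = np.random.default_rng(12)
        n = 400
        x1 = rng.standard_normal(n)
        e = rng.standard_normal(n)
        e -= x1 * (x1 @ e) / (x1 @ x1)  # exactly orthogonal to x1
        x1 = (x1 - x1.mean()) / x1.std()
        e = (e - e.mean()) / e.std()
        cand_hi = math.sqrt(0.6) * x1 + math.sqrt(0.4) * e  # R^2 vs x1 ~ 0.6
        cand_lo = math.sqrt(0.4) * x1 + math.sqrt(0.6) * e  # R^2 vs x1 ~ 0.4
        F = fm(
            np.column_stack([x1, cand_hi, cand_lo]),
            columns=["x1", "hi", "lo"],
            standardized=True,
        )
        sel = vif_select([("x1", 0.9), ("hi", 0.8), ("lo", 0.7)], F, fac=2.0)
        assert "hi" in sel.rejected  # VIF = 1/(1-0.6) = 2.5 >= 2
        assert "lo" in sel.selected  # VIF = 1/(1-0.4) ~ 1.67 < 2
        assert sel.r_squared["hi"] == pytest.approx(0.6, abs=0.02)
        assert sel.r_squared["lo"] == pytest.approx(0.4, abs=0.02)

    def test_selected_set_satisfies_vif_internally(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((80, 10))
        y = X @ rng.uniform(-1, 1, 10) + rng.standard_normal(80)
        F = standardize_features(fm(X, columns=[f"f{j}" for j in range(10)]))
        ranked = rank_single_features(F, y)
        sel = vif_select(ranked, F, fac=2.0, max_features=5)
        for name in sel.selected[1:]:
            others = [s for s in sel.selected if s != name]
            Xo = F.data[others].to_numpy()
            yv = F.data[name].to_numpy()
            A = np.column_stack([np.ones(len(Xo)), Xo])
            bhat, *_ = np.linalg.lstsq(A, yv, rcond=None)
            r2 = 1 - np.sum((yv - A @ bhat) ** 2) / np.sum((yv - yv.mean()) ** 2)
            assert 1.0 / (1.0 - r2) < 2.0 + 1e-9


class TestFisherTest:
    def test_equal_correlations(self):
        z, p = fisher_r_to_z_test(0.4, 100, 0.4, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry_under_sign_flip(self):
        z1, p1 = fisher_r_to_z_test(0.5, 80, 0.3, 90)
        z2, p2 = fisher_r_to_z_test(-0.5, 80, -0.3, 90)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_closed_form_oracle(self):
        z, p = fisher_r_to_z_test(0.5, 228, 0.3, 228)
        z_expected = (math.atanh(0.5) - math.atanh(0.3)) / math.sqrt(2.0 / 225.0)
        p_expected = math.erfc(abs(z_expected) / math.sqrt(2.0))
        assert z == pytest.approx(z_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fisher_r_to_z_test(1.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            fisher_r_to_z_test(0.5, 3, 0.5, 10)


class TestPermutationTest:
    def test_identical_prediction_sets_give_p_one(self):
        labels = np.array(["a", "b", "c", "a", "b", "c"])
        preds = labels.copy()
        p = permutation_test(
            accuracy_metric, preds, labels, predictions_b=preds.copy(),
            n_perm=200, seed=0,
        )
        assert p == pytest.approx(1.0)

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(14)
        labels = np.array(["a", "b"] * 10)
        preds = labels.copy()
        preds[:4] = "b"
        p1 = permutation_test(accuracy_metric, preds, labels, n_perm=500, seed=42)
        p2 = permutation_test(accuracy_metric, preds, labels, n_perm=500, seed=42)
        assert p1 == p2

    def test_exhaustive_tiny_case_by_hand(self):
        # three distinct labels, perfect predictions: only the identity
        # permutation reaches accuracy 1, so the exact p is 1/6
        labels = np.array(["a", "b", "c"])
        p = permutation_test(accuracy_metric, labels.copy(), labels, exhaustive=True)
        assert p == pytest.approx(1.0 / 6.0)

    def test_monte_carlo_matches_exhaustive_on_six_items(self):
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        preds = np.array(["a", "b", "b", "b", "c", "a"])
        exact = permutation_test(accuracy_metric, preds, labels, exhaustive=True)
        mc = permutation_test(accuracy_metric, preds, labels, n_perm=4000, seed=1)
        assert mc == pytest.approx(exact, abs=0.04)

    def test_two_set_exhaustive_matches_sampling(self):
        labels = np.array(["a", "b", "a", "b", "a", "b"])
        pa = np.array(["a", "b", "a", "b", "b", "b"])
        pb = np.array(["a", "a", "a", "b", "a", "a"])
        exact = permutation_test(
            accuracy_metric, pa, labels, predictions_b=pb, exhaustive=True
        )
        mc = permutation_test(
            accuracy_metric, pa, labels, predictions_b=pb, n_perm=4000, seed=2
        )
        assert mc == pytest.approx(exact, abs=0.04)

    def test_null_p_values_approximately_uniform(self):
        # under a true null, permutation p-values are ~U(0,1)
        rng = np.random.default_rng(15)

        def corr_metric(pred, labels):
            return float(np.corrcoef(
                np.asarray(pred, dtype=float), np.asarray(labels, dtype=float)
            )[0, 1])

        ps = []
        for rep in range(200):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            ps.append(
                permutation_test(corr_metric, x, y, n_perm=99, seed=int(rep))
            )
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            permutation_test(
                accuracy_metric, np.array(["a"]), np.array(["a", "b"]), n_perm=10,
                seed=0,
            )
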