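"""Scaling, ROC metrics, the repeated undersampled CV protocol, RFECV,
and covariate-adjusted Spearman correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from hmvoice import evalstats as ev


class TestRobustScale:
    def test_known_column(self):
        # median 3, IQR 2 (linear-interpolation quartiles)
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        scaled, _ = ev.robust_scale(X)
        assert np.allclose(scaled.ravel(), [-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_constant_column_zeros(self):
        X = np.ones((5, 1))
        scaled, _ = ev.robust_scale(X)
        assert np.allclose(scaled, 0.0)

    def test_inverse_transform_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        scaled, scaler = ev.robust_scale(X)
        assert np.allclose(scaler.inverse_transform(scaled), X, atol=1e-12)

    def test_params_from_fit_rows_only(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        fit = np.arange(20)
        _, scaler1 = ev.robust_scale(X, fit)
        X2 = X.copy()
        X2[20:] += 100.0  # held-out rows must not influence the parameters
        _, scaler2 = ev.robust_scale(X2, fit)
        assert np.allclose(scaler1.center_, scaler2.center_)
        assert np.allclose(scaler1.scale_, scaler2.scale_)


class TestRocMetrics:
    def test_perfect_separation(self):
        auc, sens, spec, acc = ev.roc_metrics(
            [0.9, 0.8, -0.2, -0.1], [1, 1, 0, 0]
        )
        assert (auc, sens, spec, acc) == (1.0, 1.0, 1.0, 1.0)

    def test_all_ties_half(self):
        auc, *_ = ev.roc_metrics([0.3, 0.3, 0.3, 0.3], [1, 1, 0, 0])
        assert auc == 0.5

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=40)
        a1, *_ = ev.roc_metrics(s, y)
        a2, *_ = ev.roc_metrics(s, 1 - y)
        assert a1 == pytest.approx(1 - a2)

    def test_rank_auc_equals_trapezoid(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(6, 30)
            s = rng.normal(size=n)
            y = np.concatenate([np.ones(n // 2, int), np.zeros(n - n // 2, int)])
            auc, *_ = ev.roc_metrics(s, y)
            # trapezoidal integration oracle over the empirical ROC steps
            thr = np.sort(np.unique(s))[::-1]
            tpr = [0.0] + [np.mean(s[y == 1] >= t) for t in thr]
            fpr = [0.0] + [np.mean(s[y == 0] >= t) for t in thr]
            ref = np.trapezoid(tpr, fpr)
            assert auc == pytest.approx(ref, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_metrics([0.1, 0.2], [1, 1])


class TestChanceClassifier:
    def test_mean_auc_half_over_draws(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([np.ones(20, int), np.zeros(20, int)])
        aucs = [ev.roc_metrics(ev.chance_classifier(40, rng), y)[0] for _ in range(300)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_seeded_reproducibility(self):
        a = ev.chance_classifier(10, np.random.default_rng(7))
        b = ev.chance_classifier(10, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestBalancedRepeatedCV:
    def test_chance_on_null_cohort(self, null_cohort):
        table, labels = null_cohort
        s = ev.balanced_repeated_cv(
            table.to_numpy(), labels, ev.ProtocolConfig(n_iterations=25, seed=0),
            model="chance",
        )
        assert 45.0 < s.auc_pct < 55.0
        assert s.auc_ci_95[0] <= s.auc_pct <= s.auc_ci_95[1]

    def test_svm_separates_planted_cohort(self, separable_cohort):
        table, labels = separable_cohort
        s = ev.balanced_repeated_cv(
            table.to_numpy(), labels, ev.ProtocolConfig(n_iterations=10, seed=1),
            model="svm",
        )
        assert s.auc_pct >= 95.0

    def test_same_seed_identical_summary(self, null_cohort):
        table, labels = null_cohort
        cfg = ev.ProtocolConfig(n_iterations=5, seed=3)
        s1 = ev.balanced_repeated_cv(table.to_numpy(), labels, cfg, model="svm")
        s2 = ev.balanced_repeated_cv(table.to_numpy(), labels, cfg, model="svm")
        assert s1.to_jsonable() == s2.to_jsonable()

    def test_minority_smaller_than_folds_rejected(self):
        X = np.random.default_rng(5).normal(size=(10, 3))
        y = np.array([1] * 7 + [0] * 3)
        with pytest.raises(ValueError):
            ev.balanced_repeated_cv(X, y, ev.ProtocolConfig(n_iterations=1))

    def test_non_binary_labels_rejected(self):
        X = np.zeros((12, 2))
        with pytest.raises(ValueError):
            ev.balanced_repeated_cv(X, np.array([0, 1, 2] * 4))

    def test_fold_model_independent_of_test_rows(self):
        # scaler and SVM are fitted on training rows only: scoring additional
        # rows with the same training fold is consistent row-by-row
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 4))
        y = np.array([0, 1] * 20)
        train = np.arange(30)
        s1 = ev._fit_score_fold(X, y, train, np.array([30, 31]), "svm", 1.0, rng)
        s2 = ev._fit_score_fold(X, y, train, np.arange(30, 40), "svm", 1.0, rng)
        assert np.allclose(s1, s2[:2])

    def test_l1_sparsity_path_monotone(self, separable_cohort):
        from sklearn.svm import LinearSVC

        table, labels = separable_cohort
        Xs, _ = ev.robust_scale(table.to_numpy())
        nnz = []
        for C in (1.0, 0.1, 0.01, 0.001):
            clf = LinearSVC(penalty="l1", dual=False, C=C, max_iter=10000)
            clf.fit(Xs, labels)
            nnz.append(int(np.sum(np.abs(clf.coef_) > 1e-8)))
        assert np.all(np.diff(nnz) <= 0)


class TestRfecv:
    def test_single_informative_feature_selected(self):
        rng = np.random.default_rng(8)
        n = 80
        y = np.array([1] * 50 + [0] * 30)
        X = rng.normal(size=(n, 6))
        X[:, 2] += 3.0 * y
        selected, path = ev.rfecv_select(
            X, y, [f"f{i}" for i in range(6)],
            ev.ProtocolConfig(seed=0), score_iterations=5,
        )
        assert "f2" in selected
        assert path["mean_auc_pct"].max() > 90.0

    def test_all_noise_defaults_to_small_subset(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 40 + [0] * 30)
        X = rng.normal(size=(70, 8))
        selected, path = ev.rfecv_select(
            X, y, config=ev.ProtocolConfig(seed=1), score_iterations=3
        )
        assert len(selected) <= 8
        assert path["mean_auc_pct"].std() < 15.0


class TestPartialSpearman:
    def test_identity_correlation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        rho, p = ev.partial_spearman(x, x, z)
        assert rho == pytest.approx(1.0)
        assert p < 1e-10

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.normal(size=50)
            z = rng.normal(size=50)
            y = 0.4 * x + 0.6 * z + rng.normal(size=50)
            rho, _ = ev.partial_spearman(x, y, z)
            rxy = spearmanr(x, y).statistic
            rxz = spearmanr(x, z).statistic
            ryz = spearmanr(y, z).statistic
            ref = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert rho == pytest.approx(ref, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = 0.5 * x + 0.8 * z + rng.normal(size=50)
        rho, p = ev.partial_spearman(x, y, z)
        out = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z", method="spearman",
        )
        assert rho == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(out.iloc[0, out.columns.get_loc("p_val")]), rel=1e-6)

    def test_constant_covariate_reduces_to_spearman(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, _ = ev.partial_spearman(x, y, np.ones(40))
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.partial_spearman(np.ones(10), np.arange(10), np.arange(10))
        with pytest.raises(ValueError):
            ev.partial_spearman(np.arange(4), np.arange(4), np.arange(4))
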