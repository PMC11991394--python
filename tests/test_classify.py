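import numpy as np
import pytest

from fsvmd.classify import (
    FWKNN,
    EvalReport,
    evaluate_cv,
    evaluate_holdout,
    fwknn_fit_predict,
    svm_rbf_fit_predict,
)
from fsvmd.containers import FeatureTable


from tests_support_bruteforce import brute_force_fwknn  # noqa: E402


def two_gaussian_table(seed=0, n=60):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    sep = np.where(y == 0, -2.0, 2.0)
    X = np.column_stack([
        sep + 0.3 * rng.standard_normal(n),     # separating feature
        np.where(rng.random(n) < 0.5, -sep, sep),  # label-flipping noise
    ])
    return FeatureTable(X, ["good", "bad"], y)


class TestFWKNN:
    def test_equal_weights_reduce_to_plain_knn(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(0)
        for _ in range(50):
            X = rng.standard_normal((25, 4))
            y = rng.integers(0, 2, 25)
            if len(np.unique(y)) < 2:
                continue
            X_te = rng.standard_normal((8, 4))
            ours = FWKNN(k=3).fit(X, y).predict(X_te)
            mu, sd = X.mean(0), X.std(0)
            sd[sd == 0] = 1
            ref = KNeighborsClassifier(n_neighbors=3).fit((X - mu) / sd, y)
            np.testing.assert_array_equal(ours, ref.predict((X_te - mu) / sd))

    def test_zero_weight_silences_noise_feature(self):
        table = two_gaussian_table()
        preds = fwknn_fit_predict(table, table.values,
                                  weights=np.array([1.0, 0.0]), k=5)
        assert np.mean(preds == table.labels) == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(10, 31))
            f = int(rng.integers(2, 6))
            k = int(rng.choice([1, 3, 5]))
            if k > n - 2:
                continue
            X = rng.standard_normal((n, f))
            y = rng.integers(0, 3, n)
            if len(np.unique(y)) < 2:
                continue
            X_te = rng.standard_normal((5, f))
            w = rng.uniform(0, 1, f)
            ours = FWKNN(k=k, weights=w).fit(X, y).predict(X_te)
            ref = brute_force_fwknn(X, y, X_te, w, k)
            np.testing.assert_array_equal(ours, ref)

    def test_k_exceeding_train_size_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="exceeds"):
            FWKNN(k=5).fit(X, [0, 1, 0])


class TestSVMAdapter:
    def test_separable_fixture_perfect_train_accuracy(self):
        table = two_gaussian_table()
        sub = FeatureTable(table.values[:, :1], ["good"], table.labels)
        preds = svm_rbf_fit_predict(sub, sub.values)
        assert np.mean(preds == table.labels) == 1.0

    def test_single_class_rejected(self):
        table = FeatureTable(np.zeros((10, 2)), ["a", "b"], np.zeros(10))
        with pytest.raises(ValueError, match="2 classes"):
            svm_rbf_fit_predict(table, table.values)

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 4))
        y = rng.integers(0, 2, 40)
        table = FeatureTable(X, list("abcd"), y)
        X_te = rng.standard_normal((10, 4))
        perm = [2, 0, 3, 1]
        table_p = FeatureTable(X[:, perm], [table.feature_names[i] for i in perm], y)
        a = svm_rbf_fit_predict(table, X_te, gamma=0.5)
        b = svm_rbf_fit_predict(table_p, X_te[:, perm], gamma=0.5)
        np.testing.assert_array_equal(a, b)

    def test_tiny_c_underfits_noisy_fixture(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 2))
        y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        table = FeatureTable(X, ["a", "b"], y)
        acc_big = np.mean(svm_rbf_fit_predict(table, X, C=1.0) == y)
        acc_small = np.mean(svm_rbf_fit_predict(table, X, C=1e-6) == y)
        assert acc_small < acc_big


class TestHoldout:
    def test_perfect_predictor_metrics(self):
        table = two_gaussian_table()
        sub = FeatureTable(table.values[:, :1], ["good"], table.labels)
        report = evaluate_holdout(sub, FWKNN(k=3), seed=0)
        assert report.accuracy == 1.0
        assert report.kappa == 1.0

    def test_majority_predictor_on_balanced_data(self):
        from sklearn.dummy import DummyClassifier

        table = two_gaussian_table()
        report = evaluate_holdout(table, DummyClassifier(strategy="constant",
                                                         constant=1), seed=0)
        assert report.accuracy == pytest.approx(0.5)
        assert report.kappa == pytest.approx(0.0)

    def test_metrics_consistent_with_confusion_matrix(self):
        table = two_gaussian_table(seed=5)
        report = evaluate_holdout(table, FWKNN(k=3), seed=1)
        cm = np.asarray(report.confusion)
        n = cm.sum()
        acc = np.trace(cm) / n
        assert report.accuracy == pytest.approx(acc, abs=1e-12)
        tp, fn = cm[1, 1], cm[1, 0]
        fp, tn = cm[0, 1], cm[0, 0]
        assert report.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert report.specificity == pytest.approx(tn / (tn + fp), abs=1e-12)


class TestCrossValidation:
    def test_folds_disjoint_exhaustive_balanced(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat([0, 1], 51)
        X = np.random.default_rng(0).standard_normal((102, 3))
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        seen = []
        for _, te in skf.split(X, y):
            seen.extend(te)
            assert len(te) in (20, 21)
        assert sorted(seen) == list(range(102))

    def test_sd_equals_per_fold_sd(self):
        table = two_gaussian_table(seed=3, n=100)
        report = evaluate_cv(table, FWKNN(k=3), folds=5, seed=0)
        assert report.sd["accuracy"] == pytest.approx(
            np.std(report.per_fold["accuracy"]), abs=1e-12)

    def test_constant_predictor_zero_sd(self):
        from sklearn.dummy import DummyClassifier

        table = two_gaussian_table(n=100)
        report = evaluate_cv(table, DummyClassifier(strategy="constant",
                                                    constant=0), folds=5, seed=0)
        assert report.sd["accuracy"] == 0.0

    def test_row_order_robustness(self):
        # reshuffling rows changes fold membership but must not change the
        # quality of a strongly separable problem
        table = two_gaussian_table(seed=4, n=80)
        r1 = evaluate_cv(table, FWKNN(k=3), folds=5, seed=9)
        perm = np.random.default_rng(0).permutation(80)
        table_p = FeatureTable(table.values[perm], table.feature_names,
                               table.labels[perm])
        r2 = evaluate_cv(table_p, FWKNN(k=3), folds=5, seed=9)
        assert r1.accuracy == pytest.approx(r2.accuracy, abs=0.06)

    def test_label_shuffle_chance_calibration(self):
        rng = np.random.default_rng(0)
        inside = 0
        runs = 40
        for seed in range(runs):
            X = np.random.default_rng(seed).standard_normal((60, 4))
            y = np.repeat([0, 1], 30)
            y = rng.permutation(y)
            table = FeatureTable(X, list("abcd"), y)
            rep = evaluate_cv(table, FWKNN(k=5), folds=5, seed=seed)
            inside += int(0.3 <= rep.accuracy <= 0.7)
        assert inside >= int(0.9 * runs)

    def test_report_serializes(self, tmp_path):
        table = two_gaussian_table(n=40)
        report = evaluate_cv(table, FWKNN(k=3), folds=4, seed=0)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert set(data) >= {"accuracy", "kappa", "per_fold", "confusion"}
        assert 0 <= data["accuracy"] <= 1
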