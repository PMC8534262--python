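"""Split/scale/select/tune/evaluate contracts and metric identities."""

import math

import numpy as np
import pandas as pd
import pytest

from ppaeeg import classify as cl


def toy_table(rng, n_per_class=(20, 18, 10, 12), n_features=12, shift=0.0):
    """Four-group table of Gaussian features; optional planted shift on the
    first feature for non-CG groups."""
    groups = ["CG", "nfvPPA", "svPPA", "lvPPA"]
    rows, labels = {}, {}
    i = 0
    for g, n in zip(groups, n_per_class):
        for _ in range(n):
            sid = f"s{i:03d}"
            x = rng.standard_normal(n_features)
            if g != "CG":
                x[0] += shift
            rows[sid] = {f"f{j}": float(v) for j, v in enumerate(x)}
            labels[sid] = g
            i += 1
    return cl.make_table(rows, labels)


class TestTable:
    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            cl.make_table({"a": {"x": np.nan}}, {"a": "CG"})

    def test_binarize(self):
        out = cl.binarize_labels(["CG", "svPPA", "lvPPA", "nfvPPA"])
        assert list(out) == ["CG", "PPA", "PPA", "PPA"]


class TestStratifiedSplit:
    def test_paper_sized_binary_split(self, rng):
        table = toy_table(rng)
        table[cl.LABEL_COLUMN] = cl.binarize_labels(table[cl.LABEL_COLUMN]).values
        train, test = cl.stratified_split(table, seed=0)
        y = table[cl.LABEL_COLUMN]
        assert (y.loc[train] == "PPA").sum() == 32
        assert (y.loc[train] == "CG").sum() == 16
        assert (y.loc[test] == "PPA").sum() == 8
        assert (y.loc[test] == "CG").sum() == 4
        assert set(train) | set(test) == set(table.index)
        assert not set(train) & set(test)

    def test_full_train_frac_rejected(self, rng):
        with pytest.raises(ValueError):
            cl.stratified_split(toy_table(rng), train_frac=1.0)

    def test_singleton_class_rejected(self, rng):
        table = toy_table(rng, n_per_class=(5, 1, 3, 3))
        with pytest.raises(ValueError):
            cl.stratified_split(table)

    def test_determinism(self, rng):
        table = toy_table(rng)
        assert cl.stratified_split(table, seed=3) == cl.stratified_split(table, seed=3)


class TestMinMaxScale:
    def test_affine_map(self):
        train = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        test = pd.DataFrame({"a": [8.0]})
        tr, te, _ = cl.minmax_scale(train, test)
        assert list(tr["a"]) == [0.0, 0.5, 1.0]
        assert te["a"].iloc[0] == pytest.approx(1.5)  # extrapolation allowed

    def test_constant_column_maps_to_zero_with_warning(self):
        train = pd.DataFrame({"a": [3.0, 3.0]})
        test = pd.DataFrame({"a": [3.0]})
        with pytest.warns(UserWarning):
            tr, _, _ = cl.minmax_scale(train, test)
        assert (tr["a"] == 0).all()


class TestAnovaSelection:
    def test_exactly_k_retained(self, rng):
        table = toy_table(rng, n_features=309)
        X, y = cl.split_xy(table)
        selected, _ = cl.select_features_anova(X, y, k=50)
        assert len(selected) == 50

    def test_planted_features_recovered(self):
        """3 features with a 2-sd class shift beat 10 noise features in
        >= 95% of simulations."""
        hits = 0
        n_sim = 100
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            n = 30
            y = pd.Series(["A"] * n + ["B"] * n)
            X = pd.DataFrame(rng.standard_normal((2 * n, 13)),
                             columns=[f"f{j:02d}" for j in range(13)])
            planted = ["f00", "f01", "f02"]
            X.loc[y.values == "B", planted] += 2.0
            X.index = y.index
            selected, _ = cl.select_features_anova(X, y, k=3)
            hits += set(selected) == set(planted)
        assert hits >= 95

    def test_two_columns_identity(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        y = pd.Series(["A"] * 5 + ["B"] * 5)
        selected, _ = cl.select_features_anova(X, y, k=2)
        assert set(selected) == {"a", "b"}

    def test_invalid_k(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)))
        y = pd.Series(["A"] * 5 + ["B"] * 5)
        with pytest.raises(ValueError):
            cl.select_features_anova(X, y, k=0)
        with pytest.raises(ValueError):
            cl.select_features_anova(X, y, k=3)


class TestMetrics:
    def test_knn_row_identity(self):
        """Precision 0.78 with sensitivity 0.88 gives F1 = 0.83 (2 d.p.)."""
        f1 = 2 * 0.78 * 0.88 / (0.78 + 0.88)
        assert round(f1, 2) == 0.83

    def test_confusion_arithmetic(self):
        m = cl.metrics_from_confusion(tp=7, fp=2, fn=1, tn=5)
        assert m.precision == pytest.approx(7 / 9)
        assert m.sensitivity == pytest.approx(7 / 8)
        assert m.specificity == pytest.approx(5 / 7)
        assert m.f1 == pytest.approx(2 * (7 / 9) * (7 / 8) / ((7 / 9) + (7 / 8)))
        assert m.youden == pytest.approx(7 / 8 + 5 / 7 - 1)
        assert m.accuracy == pytest.approx(12 / 15)

    def test_perfect_classifier_youden_one(self):
        m = cl.metrics_from_confusion(tp=5, fp=0, fn=0, tn=5)
        assert m.youden == pytest.approx(1.0)

    def test_undefined_precision_is_nan_not_zero(self):
        m = cl.metrics_from_confusion(tp=0, fp=0, fn=3, tn=7)
        assert math.isnan(m.precision)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cl.metrics_from_confusion(-1, 0, 0, 1)

    def test_constant_positive_predictor_limits(self):
        m = cl.metrics_from_confusion(tp=8, fp=4, fn=0, tn=0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.youden == pytest.approx(0.0)

    def test_multiclass_macro_accuracy(self):
        cm = np.array([[3, 1], [1, 3]])
        m = cl.multiclass_metrics(cm)
        assert m.accuracy == pytest.approx(0.75)


class TestTuneAndTrain:
    def test_separable_knn_reaches_perfect_cv_f1(self, rng):
        n = 30
        X = pd.DataFrame({"a": np.r_[rng.normal(0, 0.1, n), rng.normal(5, 0.1, n)],
                          "b": rng.standard_normal(2 * n)})
        y = pd.Series(["CG"] * n + ["PPA"] * n)
        _, _, cv_f1, _ = cl.tune_and_train("knn", X, y, folds=5, n_iter=8, seed=0)
        assert cv_f1 == pytest.approx(1.0)

    def test_permuted_labels_give_chance_cv_f1(self):
        """Mean CV F1 under label permutation sits at the class-prior level."""
        scores = []
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            X = pd.DataFrame(rng.standard_normal((40, 5)))
            y = pd.Series(rng.permutation(["CG"] * 20 + ["PPA"] * 20))
            _, _, cv_f1, _ = cl.tune_and_train("knn", X, y, folds=4, n_iter=4, seed=s)
            scores.append(cv_f1)
        scores = np.array(scores)
        # balanced classes: a chance-level classifier's F1 is ~0.5; the
        # tuner's selection bias pushes it up but far from a real effect
        assert abs(scores.mean() - 0.5) < 3 * scores.std(ddof=1)

    def test_search_determinism(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)))
        y = pd.Series(["CG"] * 15 + ["PPA"] * 15)
        r1 = cl.tune_and_train("decision_tree", X, y, folds=3, n_iter=6, seed=5)
        r2 = cl.tune_and_train("decision_tree", X, y, folds=3, n_iter=6, seed=5)
        assert r1[1] == r2[1] and r1[2] == r2[2]

    def test_fold_fallback_warning(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 3)))
        y = pd.Series(["CG"] * 4 + ["PPA"] * 8)
        with pytest.warns(UserWarning, match="reducing folds"):
            cl.tune_and_train("gaussian_nb", X, y, folds=10, n_iter=2, seed=0)


class TestEvaluate:
    def _fit(self, X, y, kind="knn", **params):
        model = cl.build_model(kind, params or {"n_neighbors": 3})
        model.fit(X.values, y.values)
        return model

    def test_perfect_predictions(self, rng):
        X = pd.DataFrame({"a": np.r_[np.zeros(10), np.ones(10)]})
        y = pd.Series(["CG"] * 10 + ["PPA"] * 10)
        model = self._fit(X, y)
        res = cl.evaluate(model, X, y)
        assert res.metrics.f1 == 1.0 and res.metrics.accuracy == 1.0
        assert res.auc == pytest.approx(1.0)

    def test_random_scores_give_half_auc(self):
        aucs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.standard_normal((60, 3)))
            y = pd.Series(rng.permutation(["CG"] * 30 + ["PPA"] * 30))
            model = self._fit(X.iloc[:40], y.iloc[:40])
            res = cl.evaluate(model, X.iloc[40:], y.iloc[40:])
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_empty_test_rejected(self, rng):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        y = pd.Series(["CG", "PPA"])
        model = self._fit(X, y, kind="knn", n_neighbors=1)
        with pytest.raises(ValueError):
            cl.evaluate(model, X.iloc[:0], y.iloc[:0])


@pytest.fixture(scope="module")
def report():
    rng = np.random.default_rng(0)
    table = toy_table(rng, n_features=8, shift=3.0)
    return cl.run_benchmark(table, mode="binary", k=5, folds=4, n_iter=4, seed=1)


class TestBenchmark:

    def test_seven_rows(self, report):
        assert len(report.results) == 7
        assert [r.name for r in report.results] == [
            "Decision Tree", "Elastic Net", "SVM", "Random Forest",
            "kNN", "Gaussian NB", "Multinomial NB",
        ]

    def test_metric_identities_on_every_row(self, report):
        for r in report.results:
            m = r.test.metrics
            assert m.f1 == pytest.approx(
                2 * m.precision * m.sensitivity / (m.precision + m.sensitivity)
            )
            assert m.accuracy == pytest.approx(
                (m.tp + m.tn) / (m.tp + m.fp + m.fn + m.tn)
            )
            assert m.youden == pytest.approx(m.sensitivity + m.specificity - 1)

    def test_shared_split_and_selection(self, report):
        assert report.audit["scaler_fit_on"] == report.train_ids
        assert not set(report.train_ids) & set(report.test_ids)
        assert len(report.selected_features) == 5

    def test_strong_effect_recovered(self, report):
        assert report.best().test.metrics.f1 >= 0.9

    def test_multiclass_confusion_shape(self):
        rng = np.random.default_rng(4)
        table = toy_table(rng, n_features=6, shift=2.0)
        rep = cl.run_benchmark(table, mode="multiclass", k=4, folds=3, n_iter=2, seed=0)
        assert all(r.test.confusion.shape == (4, 4) for r in rep.results)
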