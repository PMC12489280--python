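"""Splitting, standardization, PCA, grid search, metrics, Shapley, regions."""

import warnings

import numpy as np
import pandas as pd
import pytest

import pollensig as ps
from pollensig import classify
from pollensig.classify import DEFAULT_GRIDS, _linear_weights, _mc_shapley
from pollensig.errors import StratificationError, UsageError


def toy_xy(n_classes=14, per_class=20, n_features=3, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c in range(n_classes):
        centre = rng.normal(scale=5.0, size=n_features)
        rows.append(centre + rng.normal(scale=0.5, size=(per_class, n_features)))
        labels += [f"c{c:02d}"] * per_class
    X = pd.DataFrame(np.vstack(rows), index=[f"r{i}" for i in range(n_classes * per_class)])
    X.columns = [f"f{j}" for j in range(n_features)]
    return X, pd.Series(labels, index=X.index)


class TestStratifiedSplit:
    def test_fourteen_by_twenty_gives_14_train_6_test_per_class(self):
        X, y = toy_xy()
        X_tr, y_tr, X_te, y_te = classify.stratified_split(X, y, seed=0)
        assert (y_tr.value_counts() == 14).all()
        assert (y_te.value_counts() == 6).all()
        assert set(y_tr.index).isdisjoint(y_te.index)
        assert set(y_tr.index) | set(y_te.index) == set(y.index)

    def test_full_train_fraction_warns_and_empties_test(self):
        X, y = toy_xy(n_classes=2, per_class=4)
        with pytest.warns(UserWarning):
            _, _, X_te, _ = classify.stratified_split(X, y, train_fraction=1.0, seed=0)
        assert len(X_te) == 0

    def test_seed_controls_the_split(self):
        X, y = toy_xy(n_classes=3, per_class=10)
        a = classify.stratified_split(X, y, seed=5)
        b = classify.stratified_split(X, y, seed=5)
        c = classify.stratified_split(X, y, seed=6)
        assert list(a[0].index) == list(b[0].index)
        assert list(a[0].index) != list(c[0].index)

    def test_singleton_class_cannot_stratify(self):
        X, y = toy_xy(n_classes=2, per_class=3)
        y.iloc[0] = "lonely"
        with pytest.raises(StratificationError):
            classify.stratified_split(X, y, seed=0)


class TestStandardize:
    def test_two_point_feature_maps_to_plus_minus_one(self):
        train = pd.DataFrame({"f": [0.0, 2.0]})
        Xs, _, st = classify.standardize(train)
        np.testing.assert_allclose(Xs["f"], [-1.0, 1.0])
        assert st.mean[0] == 1.0

    def test_constant_feature_maps_to_zero_without_error(self):
        train = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
        Xs, _, _ = classify.standardize(train)
        np.testing.assert_array_equal(Xs["f"], 0.0)

    def test_test_set_uses_train_statistics(self):
        train = pd.DataFrame({"f": [0.0, 2.0]})
        test = pd.DataFrame({"f": [4.0, 6.0]})
        _, (ts,), _ = classify.standardize(train, [test])
        np.testing.assert_allclose(ts["f"], [3.0, 5.0])
        assert ts["f"].mean() != 0.0


class TestRunPca:
    def test_near_collinear_data_loads_on_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=100)
        X = pd.DataFrame({"a": t, "b": 2 * t + rng.normal(scale=1e-4, size=100)})
        res = classify.run_pca(X, n_components=2)
        assert res.explained_variance_ratio[0] > 0.999

    def test_ratios_non_increasing_and_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 12)))
        X.columns = [f"f{j}" for j in range(12)]
        res = classify.run_pca(X, n_components=10)
        r = res.explained_variance_ratio
        assert (np.diff(r) <= 1e-12).all() and (r >= 0).all() and r.sum() <= 1 + 1e-9
        gram = res.loadings.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)

    def test_rank_deficient_input_pads_with_zero_variance(self):
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(5, 8)))
        X.columns = [f"f{j}" for j in range(8)]
        with pytest.warns(UserWarning):
            res = classify.run_pca(X, n_components=10)
        assert res.explained_variance_ratio.shape == (10,)
        assert (res.explained_variance_ratio[4:] == 0).all()

    def test_default_campaign_first_four_components_carry_85_percent(self, default_campaign):
        from pollensig.signature import dataset_xy

        _, sim = default_campaign
        X, _ = dataset_xy(sim.spectroscopy)
        res = classify.run_pca(X)
        assert res.n_components == 10
        assert res.explained_variance_ratio[:4].sum() >= 0.85


class TestGridSearch:
    def test_separable_two_class_fixture_reaches_cv_accuracy_one(self):
        X, y = toy_xy(n_classes=2, per_class=20, seed=3)
        spec = classify.grid_search_cv("SVM", X, y, seed=0)
        assert spec.cv_accuracy == 1.0
        assert spec.best_params in [
            {**{"kernel": k, "C": c, "gamma": "scale"}}
            for k in ("linear", "rbf") for c in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]

    def test_reference_optimum_is_searchable_and_returnable(self):
        # the tuned campaign model: linear kernel, C = 0.1, gamma = 'scale'
        g = DEFAULT_GRIDS["SVM"][0]
        assert "linear" in g["kernel"] and 0.1 in g["C"] and "scale" in g["gamma"]
        X, y = toy_xy(n_classes=3, per_class=12, seed=4)
        spec = classify.grid_search_cv(
            "SVM", X, y, seed=0,
            grid=[{"kernel": ["linear"], "C": [0.1], "gamma": ["scale"]}],
        )
        assert spec.best_params == {"kernel": "linear", "C": 0.1, "gamma": "scale"}

    def test_same_seed_reproduces_the_winner(self):
        X, y = toy_xy(n_classes=3, per_class=12, seed=5)
        a = classify.grid_search_cv("kNN", X, y, seed=7)
        b = classify.grid_search_cv("kNN", X, y, seed=7)
        assert a.best_params == b.best_params and a.cv_accuracy == b.cv_accuracy

    def test_empty_grid_is_usage_error(self):
        X, y = toy_xy(n_classes=2, per_class=12)
        with pytest.raises(UsageError):
            classify.grid_search_cv("SVM", X, y, grid=[])

    def test_small_classes_lower_the_fold_count(self):
        X, y = toy_xy(n_classes=3, per_class=5)
        with pytest.warns(UserWarning, match="folds"):
            classify.grid_search_cv("NaiveBayes", X, y, k=10, seed=0)


class TestMetrics:
    def test_hand_worked_two_class_report(self):
        # confusion [[2, 0], [1, 1]]: recall (1, 0.5), precision (2/3, 1), F1_0 = 0.8
        y_true = ["a", "a", "b", "b"]
        y_pred = ["a", "a", "a", "b"]
        rep = classify.compute_report(y_true, y_pred)
        np.testing.assert_array_equal(rep.confusion, [[2, 0], [1, 1]])
        np.testing.assert_allclose(rep.recall, [1.0, 0.5])
        np.testing.assert_allclose(rep.precision, [2 / 3, 1.0])
        assert rep.f1[0] == pytest.approx(0.8)
        assert rep.accuracy == 0.75

    def test_perfect_predictions_are_all_ones(self):
        y = ["a", "b", "c"] * 4
        scores = pd.get_dummies(pd.Series(y)).to_numpy(float)
        rep = classify.compute_report(y, y, scores=scores)
        assert rep.accuracy == 1.0 and rep.roc_auc_ovr == 1.0
        assert (rep.f1 == 1.0).all()

    def test_f1_is_the_harmonic_mean_of_precision_and_recall(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200).astype(str)
        y_pred = rng.integers(0, 4, 200).astype(str)
        rep = classify.compute_report(y_true, y_pred)
        for p, r, f in zip(rep.precision, rep.recall, rep.f1):
            expect = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert f == pytest.approx(expect)
            assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    def test_single_class_test_auc_is_undefined(self):
        with pytest.raises(UsageError):
            classify.compute_report(["a", "a"], ["a", "a"], scores=np.ones((2, 2)))

    def test_confusion_row_sums_are_class_counts(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 3, 60).astype(str)
        y_pred = rng.integers(0, 3, 60).astype(str)
        rep = classify.compute_report(y_true, y_pred)
        counts = pd.Series(y_true).value_counts().sort_index().to_numpy()
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), counts)


class TestBenchAll:
    def test_reports_one_row_per_family(self, sim_small):
        from pollensig.signature import dataset_xy

        _, sim = sim_small
        X, y = dataset_xy(sim.analyser)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # folds lowered on the small fixture
            bench = classify.bench_all(X, y, seed=0)
        assert list(bench.table.index) == list(classify.FAMILIES)
        assert ((bench.table["test_accuracy"] >= 0) & (bench.table["test_accuracy"] <= 1)).all()
        assert bench.table["roc_auc_ovr"].notna().all()


class TestShapley:
    def _linear_model(self, W, b, classes):
        class Lin:
            classes_ = np.asarray(classes)
            coef_ = np.asarray(W, float)
            intercept_ = np.asarray(b, float)

            def decision_function(self, Z):
                return np.asarray(Z) @ self.coef_.T + self.intercept_

        return Lin()

    def test_closed_form_matches_hand_example(self):
        # f(x) = 1*x1 + 2*x2, background mean (0, 0), x = (1, 1)
        m = self._linear_model([[1.0, 2.0], [0.0, 0.0], [0.5, 0.5]], [0, 0, 0], ["a", "b", "c"])
        X = pd.DataFrame([[1.0, 1.0]], columns=["L1_415", "L1_416"])
        bg = pd.DataFrame(np.zeros((4, 2)), columns=X.columns)
        rep = classify.shapley_attribution(m, X, bg)
        assert rep.method == "linear-exact"
        np.testing.assert_allclose(rep.phi[0, :, 0], [1.0, 2.0])
        assert rep.phi[0, :, 0].sum() == pytest.approx(3.0)  # f(x) - f(mean)

    def test_local_accuracy_exact_for_fitted_linear_model(self, sim_small):
        from pollensig.signature import dataset_xy
        from sklearn.linear_model import LogisticRegression

        _, sim = sim_small
        X, y = dataset_xy(sim.analyser)
        Xs, _, _ = classify.standardize(X)
        m = LogisticRegression(max_iter=5000).fit(Xs, y)
        rep = classify.shapley_attribution(m, Xs.iloc[:8], Xs)
        W, b = _linear_weights(m)
        f = Xs.iloc[:8].to_numpy() @ W.T + b
        f_mu = Xs.to_numpy().mean(axis=0) @ W.T + b
        np.testing.assert_allclose(rep.phi.sum(axis=1), f - f_mu, atol=1e-10)

    def test_zero_weight_feature_never_enters_the_top_list(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 6))
        W[:, 4] = 0.0
        m = self._linear_model(W, np.zeros(3), ["a", "b", "c"])
        X = pd.DataFrame(rng.normal(size=(10, 6)), columns=[f"L1_{415 + j}" for j in range(6)])
        rep = classify.shapley_attribution(m, X, X, top_k=5)
        assert np.abs(rep.phi[:, 4, :]).max() == 0.0
        assert "L1_419" not in rep.top20

    def test_monte_carlo_matches_closed_form_on_linear_scorer(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(3, 5))
        m = self._linear_model(W, rng.normal(size=3), ["a", "b", "c"])
        X = pd.DataFrame(rng.normal(size=(3, 5)), columns=[f"f{j}" for j in range(5)])
        bg = pd.DataFrame(rng.normal(size=(16, 5)), columns=X.columns)
        closed = classify.shapley_attribution(m, X, bg).phi

        class NoCoef:  # hide coef_ to force the Monte-Carlo path
            classes_ = m.classes_
            decision_function = m.decision_function

        mc = _mc_shapley(NoCoef(), X.to_numpy(), bg.to_numpy(), 512, seed=0)
        rel = np.abs(mc - closed) / np.maximum(np.abs(closed), 1e-9)
        assert rel.max() < 0.02

    def test_unfitted_model_is_usage_error(self):
        X = pd.DataFrame([[0.0]], columns=["f0"])
        with pytest.raises(UsageError):
            classify.shapley_attribution(object(), X, X)


class TestClusterRegions:
    def test_reference_wavelengths_form_three_regions(self):
        # a dense influential set spanning the three campaign regions:
        # blue 415-512 nm, red 597-658 nm, far-red 699-739 nm
        wavelengths = (415, 430, 450, 470, 490, 512, 597, 620, 640, 658, 699, 720, 739)
        names = [f"L1_{w}" for w in wavelengths]
        assert classify.cluster_regions(names) == [(415, 512), (597, 658), (699, 739)]

    def test_single_wavelength_is_a_point_region(self):
        assert classify.cluster_regions(["L3_500"]) == [(500, 500)]

    def test_forty_nm_gaps_stay_in_one_region(self):
        names = ["L1_415", "L1_455", "L1_495", "L1_535"]
        assert classify.cluster_regions(names) == [(415, 535)]

    def test_analyser_names_are_rejected(self):
        with pytest.raises(UsageError):
            classify.cluster_regions(["365r", "530g"])
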