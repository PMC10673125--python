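import numpy as np
import pytest

from metpath.modeling import (
    Autoencoder,
    EncoderSpec,
    FAMILIES,
    ModelSpec,
    SEARCH_SPACES,
    encoded_width,
    enumerate_tasks,
    fit_autoencoder,
    make_fold_plans,
    run_cv,
    stratified_folds,
    tune_hyperparameters,
)


class TestEnumerateTasks:
    def test_default_cross_is_72(self):
        assert len(enumerate_tasks()) == 72

    def test_small_cross(self):
        tasks = enumerate_tasks(["random_forest"], ["A", "B"], ["full"])
        assert len(tasks) == 2
        assert {t.category for t in tasks} == {"A", "B"}

    def test_duplicate_categories_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_tasks(["random_forest"], ["A", "A"], ["full"])

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            enumerate_tasks([], ["A"], ["full"])


class TestStratifiedFolds:
    def test_exact_stratification_forced(self):
        y = np.zeros(100, bool)
        y[:20] = True
        folds = stratified_folds(y, 10, test_frac=0.05, seed=0)
        for _, te in folds:
            assert len(te) == 5
            assert y[te].sum() == 1

    def test_same_seed_identical(self):
        y = np.arange(60) % 3 == 0
        a = stratified_folds(y, 5, seed=4)
        b = stratified_folds(y, 5, seed=4)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert (tra == trb).all() and (tea == teb).all()

    def test_folds_are_independent_draws(self):
        y = np.arange(200) % 4 == 0
        folds = stratified_folds(y, 50, seed=1)
        tests = {tuple(sorted(te)) for _, te in folds}
        assert len(tests) > 40  # fresh random subsamples, not a partition

    def test_single_class_rejected_with_name(self):
        with pytest.raises(ValueError, match="Lipid"):
            stratified_folds(np.zeros(50, bool), 3, category="Lipid metabolism")

    def test_stratification_property(self):
        rng = np.random.default_rng(9)
        y = rng.random(300) < 0.23
        prop = y.mean()
        for _, te in stratified_folds(y, 100, seed=2):
            assert abs(y[te].mean() - prop) <= 1.0 / len(te)


class TestFoldPlans:
    def test_full_training_has_three_partitions(self):
        y = np.arange(100) % 4 == 0
        amb = np.arange(100) < 10
        plans = make_fold_plans(y, amb, "full", 5, seed=0)
        for p in plans:
            assert set(p.test_partitions) == {"full", "ambiguous", "non_ambiguous"}
            te = p.test_partitions["full"]
            assert set(p.test_partitions["ambiguous"]) | set(
                p.test_partitions["non_ambiguous"]
            ) == set(te)
            assert set(p.train_idx).isdisjoint(te)

    def test_non_ambiguous_training_two_partitions(self):
        y = np.arange(100) % 4 == 0
        amb = np.arange(100) < 10
        plans = make_fold_plans(y, amb, "non_ambiguous", 5, seed=0)
        amb_idx = set(np.flatnonzero(amb))
        for p in plans:
            assert set(p.test_partitions) == {"non_ambiguous", "ambiguous_all"}
            # never trains on ambiguous entries
            assert set(p.train_idx).isdisjoint(amb_idx)
            assert set(p.test_partitions["ambiguous_all"]) == amb_idx


class TestTuning:
    def _data(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        X = rng.poisson(2.0, size=(n, 12)).astype(float)
        y = X[:, 0] + X[:, 3] > 4
        return X, y

    def test_budget_one_degenerate(self):
        X, y = self._data()
        spec = tune_hyperparameters(X, y, "random_forest", budget=1, seed=0,
                                    n_estimators=20)
        assert spec.family == "random_forest"

    @pytest.mark.parametrize("family", ["random_forest", "gradient_boosted_trees"])
    def test_returned_values_inside_declared_space(self, family):
        X, y = self._data(1)
        for seed in range(4):
            spec = tune_hyperparameters(X, y, family, budget=4, seed=seed,
                                        n_estimators=20)
            ModelSpec(family, spec.hyperparameters, seed=0)  # re-validates

    def test_budget_zero_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, "random_forest", budget=0)

    def test_spec_validation_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            ModelSpec("gradient_boosted_trees", {"max_depth": 12})
        with pytest.raises(ValueError, match="not one of"):
            ModelSpec("random_forest", {"criterion": "chi2"})
        with pytest.raises(ValueError, match="not in the"):
            ModelSpec("random_forest", {"n_trees": 7})


class TestAutoencoder:
    def test_encoded_width_examples(self):
        assert encoded_width(14656) == 1465
        assert encoded_width(100) == 10

    def test_zero_latent_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(30, 12)).astype(float)
        with pytest.raises(ValueError, match="latent width is 0"):
            Autoencoder(EncoderSpec(latent_fraction=0.05), seed=0).fit(X)

    def test_narrow_input_rejected(self):
        X = np.zeros((30, 5))
        with pytest.raises(ValueError, match="at least 10 features"):
            fit_autoencoder(X)

    def test_low_rank_reconstruction_matches_svd_oracle(self):
        """On rank-limited data the bottleneck must reconstruct almost as
        well as the optimal truncated SVD of the centered matrix."""
        rng = np.random.default_rng(5)
        r, n, p = 4, 200, 60
        X = rng.normal(size=(n, r)) @ rng.normal(size=(r, p)) * 3.0
        X += rng.normal(scale=0.01, size=X.shape)
        enc = fit_autoencoder(X, seed=0)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        m = enc.latent_width_
        svd_err = float(np.mean((Xc - U[:, :m] * S[:m] @ Vt[:m]) ** 2))
        total_var = float(Xc.var())
        assert enc.reconstruction_error(X) <= svd_err + 0.01 * total_var
        assert enc.transform(X).shape == (n, m)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EncoderSpec(latent_fraction=0.0)
        with pytest.raises(ValueError):
            EncoderSpec(layers=2)


class TestRunCV:
    def _sep_task(self, separable_dataset):
        labels = separable_dataset.labels_frame()
        cat = labels.columns[0]
        return (
            separable_dataset.features.values().astype(float),
            labels[cat].to_numpy(),
            separable_dataset.ambiguous_mask(),
            cat,
        )

    def test_separable_trees_perfect_every_fold(self, separable_dataset):
        X, y, amb, cat = self._sep_task(separable_dataset)
        plans = make_fold_plans(y, amb, "full", 5, seed=0, category=cat)
        frame, imp = run_cv(X, y, plans, ModelSpec("random_forest", {}, seed=0),
                            collect_importance=True, n_estimators=100)
        mcc = frame[(frame.metric == "mcc") & (frame.partition == "full")].value
        assert (mcc == 1.0).all()
        assert imp.shape == (5, X.shape[1])

    def test_label_shuffle_null(self, separable_dataset):
        X, y, amb, cat = self._sep_task(separable_dataset)
        rng = np.random.default_rng(11)
        y_null = rng.permutation(y)
        plans = make_fold_plans(y_null, amb, "full", 40, seed=1, category=cat)
        frame, _ = run_cv(X, y_null, plans, ModelSpec("random_forest", {}, seed=0),
                          n_estimators=30)
        mcc = frame[(frame.metric == "mcc") & (frame.partition == "full")].value
        se = mcc.std() / np.sqrt(len(mcc))
        assert abs(mcc.mean()) < 3 * max(se, 1e-9)

    def test_fit_once_score_each_partition_once(self, separable_dataset):
        X, y, amb, cat = self._sep_task(separable_dataset)
        plans = make_fold_plans(y, amb, "non_ambiguous", 3, seed=0, category=cat)
        frame, _ = run_cv(X, y, plans, ModelSpec("gradient_boosted_trees", {}, 0),
                          n_estimators=30)
        # non-ambiguous training: at most 2 partitions, each metric once per fold
        parts = frame[frame.metric == "mcc"].groupby("fold")["partition"].nunique()
        assert (parts <= 2).all()

    def test_determinism(self, separable_dataset):
        X, y, amb, cat = self._sep_task(separable_dataset)
        plans = make_fold_plans(y, amb, "full", 3, seed=5, category=cat)
        a, _ = run_cv(X, y, plans, ModelSpec("gradient_boosted_trees", {}, seed=9),
                      n_estimators=40)
        b, _ = run_cv(X, y, plans, ModelSpec("gradient_boosted_trees", {}, seed=9),
                      n_estimators=40)
        assert (a.value == b.value).all()

    def test_unknown_fold_indices_rejected(self, separable_dataset):
        X, y, amb, cat = self._sep_task(separable_dataset)
        plans = make_fold_plans(y, amb, "full", 1, seed=0, category=cat)
        plans[0].train_idx = np.array([10 ** 6])
        with pytest.raises(ValueError, match="unknown row indices"):
            run_cv(X, y, plans, ModelSpec("random_forest", {}, 0))


class TestEncodedPipeline:
    def test_encoded_and_raw_agree_on_separable_data(self, separable_dataset):
        """The 10%-width encoder must preserve the class signal: tree models
        on raw counts and the MLP on encoded features both reach MCC >= 0.95
        on every fold of a noiseless separable task."""
        ds = separable_dataset
        X = ds.features.values().astype(float)
        Xe = fit_autoencoder(X, seed=0).transform(X)
        assert Xe.shape[1] == encoded_width(X.shape[1])
        labels = ds.labels_frame()
        amb = ds.ambiguous_mask()
        for fam, XX in [("random_forest", X), ("mlp", Xe)]:
            for cat in list(labels.columns)[:2]:
                y = labels[cat].to_numpy()
                plans = make_fold_plans(y, amb, "full", 4, seed=1, category=cat)
                frame, _ = run_cv(XX, y, plans, ModelSpec(fam, {}, seed=0),
                                  n_estimators=100)
                mcc = frame[(frame.metric == "mcc") & (frame.partition == "full")].value
                assert (mcc >= 0.95).all(), (fam, cat, list(mcc))
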