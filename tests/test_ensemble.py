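"""Stacking contracts: OOF protocol, class alignment, anti-leakage,
meta-learner behaviour, uncertainty spread and consensus importance."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from biomeshift import (
    HyperParams,
    fit_base_learners,
    fit_meta_learner,
    fit_stacked_model,
    predict_probabilities,
    consensus_importance,
)
from biomeshift.ensemble import LEARNER_NAMES, OOFMatrix

RNG = np.random.default_rng(42)


def blobs(n=1000, gap=8.0, seed=0):
    """Two linearly separable Gaussian blobs in 4 features."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(half, 4)),
            rng.normal(gap, 1.0, size=(n - half, 4)),
        ]
    )
    y = np.r_[np.zeros(half, dtype=int), np.ones(n - half, dtype=int)]
    perm = rng.permutation(n)
    return X[perm], y[perm]


def random_folds(n, k, seed=0):
    rng = np.random.default_rng(seed)
    fold = np.tile(np.arange(1, k + 1), n // k + 1)[:n]
    return rng.permutation(fold)


class TestFitBaseLearners:
    def test_separable_blobs_all_learners_accurate(self, light_hp):
        hp = HyperParams(
            rf_trees=light_hp.rf_trees,
            rf_min_node=light_hp.rf_min_node,
            rf_mtry=light_hp.rf_mtry,
            gbt_rounds=light_hp.gbt_rounds,
            glm_lambda=1e-8,  # effectively unpenalized
        )
        X, y = blobs(1000)
        fold = random_folds(1000, 5)
        oof, _ = fit_base_learners(X, y, fold, hp=hp, seed=0)
        for name in LEARNER_NAMES:
            acc = np.mean(np.argmax(oof.probs[name], axis=1) == y)
            assert acc >= 0.95, name

    def test_oof_rows_are_probability_vectors(self, light_hp):
        X, y = blobs(200)
        oof, _ = fit_base_learners(X, y, random_folds(200, 4), hp=light_hp)
        for name in LEARNER_NAMES:
            np.testing.assert_allclose(oof.probs[name].sum(axis=1), 1.0, atol=1e-9)
            assert np.all(oof.probs[name] >= 0)

    def test_single_class_overall_errors(self, light_hp):
        X = RNG.normal(size=(50, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_base_learners(X, np.zeros(50, dtype=int), random_folds(50, 5), hp=light_hp)

    def test_single_class_training_partition_names_fold(self, light_hp):
        # class 1 lives only in fold 2, so the partition training fold 2's
        # predictor (folds 1+3) holds a single class -> error names fold 2
        n = 60
        fold = np.repeat(np.arange(1, 4), n // 3)
        y = np.zeros(n, dtype=int)
        y[fold == 2] = 1
        X = RNG.normal(size=(n, 3)) + y[:, None]
        with pytest.raises(ValueError, match="fold 2"):
            fit_base_learners(X, y, fold, hp=light_hp)

    def test_nonfinite_features_rejected(self, light_hp):
        X, y = blobs(100)
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_base_learners(X, y, random_folds(100, 4), hp=light_hp)

    def test_absent_class_gets_zero_column_globally_aligned(self, light_hp):
        # global legend has 3 classes but class 2 is absent from the data:
        # probability blocks stay (n, 3) with a zero column for the unseen
        # class and the remaining mass renormalized
        X, y = blobs(120)
        oof, _ = fit_base_learners(X, y, random_folds(120, 4), hp=light_hp,
                                   n_classes=3)
        assert oof.stacked().shape == (120, 9)
        for name in LEARNER_NAMES:
            assert np.all(oof.probs[name][:, 2] == 0.0)
            np.testing.assert_allclose(oof.probs[name].sum(axis=1), 1.0, atol=1e-9)

    def test_anti_leakage_oof_rows_of_fold_invariant_to_its_labels(self, light_hp):
        X, y = blobs(300, seed=5)
        fold = random_folds(300, 5, seed=5)
        f = 2
        oof_a, _ = fit_base_learners(X, y, fold, hp=light_hp, seed=1)
        y_perm = y.copy()
        idx = np.flatnonzero(fold == f)
        y_perm[idx] = np.random.default_rng(0).permutation(y[idx])
        assert not np.array_equal(y_perm, y)
        oof_b, _ = fit_base_learners(X, y_perm, fold, hp=light_hp, seed=1)
        for name in LEARNER_NAMES:
            np.testing.assert_array_equal(
                oof_a.probs[name][idx], oof_b.probs[name][idx]
            )


class TestMetaLearner:
    def one_hot_oof(self, y, K):
        n = len(y)
        hot = np.zeros((n, K))
        hot[np.arange(n), y] = 1.0
        return OOFMatrix(
            probs={name: hot.copy() for name in LEARNER_NAMES},
            fold=np.ones(n, dtype=int),
            class_list=list(range(K)),
        )

    def test_one_hot_inputs_give_perfect_training_accuracy(self):
        y = RNG.integers(0, 3, size=200)
        model = fit_meta_learner(self.one_hot_oof(y, 3), y)
        pred = np.argmax(model.meta_probabilities(self.one_hot_oof(y, 3).stacked()), axis=1)
        np.testing.assert_array_equal(pred, y)

    def test_meta_probabilities_normalized_on_random_inputs(self):
        y = RNG.integers(0, 4, size=150)
        P = RNG.dirichlet(np.ones(4), size=150)
        oof = OOFMatrix(
            probs={name: P for name in LEARNER_NAMES},
            fold=np.ones(150, dtype=int),
            class_list=list(range(4)),
        )
        model = fit_meta_learner(oof, y)
        Z = RNG.dirichlet(np.ones(12), size=50)
        np.testing.assert_allclose(model.meta_probabilities(Z).sum(axis=1), 1.0, atol=1e-9)

    def test_stack_beats_pure_noise_learner(self):
        """With one truthful and two noise base learners, the stack's
        held-out logloss must not exceed the noise learner's."""
        rng = np.random.default_rng(7)
        K, n = 3, 600
        y = rng.integers(0, K, size=n)
        truth = np.full((n, K), 0.05)
        truth[np.arange(n), y] = 0.9
        noise = rng.dirichlet(np.ones(K), size=n)
        probs = {"rf": truth, "gbt": noise, "glm": rng.dirichlet(np.ones(K), size=n)}
        oof = OOFMatrix(probs=probs, fold=np.ones(n, dtype=int), class_list=list(range(K)))
        model = fit_meta_learner(oof, y)

        y2 = rng.integers(0, K, size=300)
        truth2 = np.full((300, K), 0.05)
        truth2[np.arange(300), y2] = 0.9
        noise2 = rng.dirichlet(np.ones(K), size=300)
        Z2 = np.hstack([truth2, noise2, rng.dirichlet(np.ones(K), size=300)])
        P2 = model.meta_probabilities(Z2)

        def ll(P):
            return -np.mean(np.log(np.clip(P[np.arange(300), y2], 1e-15, None)))

        assert ll(P2) <= ll(noise2)

    def test_incomplete_oof_rejected(self):
        y = RNG.integers(0, 2, size=20)
        probs = {name: np.full((20, 2), np.nan) for name in LEARNER_NAMES}
        oof = OOFMatrix(probs=probs, fold=np.ones(20, dtype=int), class_list=[0, 1])
        with pytest.raises(ValueError, match="incomplete"):
            fit_meta_learner(oof, y)

    def test_constant_stacked_features_warn_but_fit(self):
        y = RNG.integers(0, 2, size=80)
        P = np.column_stack([np.full(80, 0.5), np.full(80, 0.5)])
        oof = OOFMatrix(probs={n: P for n in LEARNER_NAMES},
                        fold=np.ones(80, dtype=int), class_list=[0, 1])
        with pytest.warns(UserWarning, match="constant"):
            model = fit_meta_learner(oof, y)
        assert isinstance(model.meta, LogisticRegression)


@pytest.fixture(scope="module")
def fitted(small_study, light_hp):
    from biomeshift import make_spatial_folds

    folds = make_spatial_folds(small_study["blocks"], k=5, repeat_index=0, seed=0)
    return fit_stacked_model(
        small_study["X"],
        small_study["y"],
        folds,
        hp=light_hp,
        feature_names=small_study["feature_names"],
        class_list=small_study["legend"],
        seed=0,
    )


class TestPredictProbabilities:
    def test_pixel_probabilities_sum_to_100(self, fitted, small_study):
        cube, sd = predict_probabilities(fitted, small_study["stack"])
        sums = cube.values[:, ~cube.mask].sum(axis=0)
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_sd_layer_is_sample_sd_of_base_learners(self, fitted, small_study):
        cube, sd = predict_probabilities(fitted, small_study["stack"])
        X, flat_idx = small_study["stack"].feature_matrix(fitted.feature_names)
        base = fitted.base_probabilities(X)
        manual = np.stack([base[n] for n in LEARNER_NAMES]).std(axis=0, ddof=1) * 100
        rows, cols = np.unravel_index(flat_idx, small_study["grid"].shape)
        for k in range(fitted.K):
            np.testing.assert_allclose(sd[k, rows, cols], manual[:, k])

    def test_sd_formula_on_known_spread(self):
        # sample SD (ddof=1) of base probabilities 20%, 80%, 50% is 30%
        spread = np.std([0.2, 0.8, 0.5], ddof=1) * 100
        np.testing.assert_allclose(spread, 30.0)

    def test_masked_pixels_nodata_everywhere(self, fitted, small_study):
        stack = small_study["stack"].copy()
        stack.mask[0, :] = True
        for name in stack.layers:
            stack.layers[name][stack.mask] = np.nan
        cube, sd = predict_probabilities(fitted, stack)
        assert np.isnan(cube.values[:, 0, :]).all()
        assert np.isnan(sd[:, 0, :]).all()

    def test_model_archive_round_trip(self, fitted, small_study, tmp_path):
        from biomeshift import StackedModel

        path = tmp_path / "model.joblib"
        fitted.save(path)
        back = StackedModel.load(path)
        assert back.feature_names == fitted.feature_names
        assert back.class_list == fitted.class_list
        np.testing.assert_array_equal(
            back.predict_proba(small_study["X"][:50]),
            fitted.predict_proba(small_study["X"][:50]),
        )

    def test_missing_feature_layer_named(self, fitted, small_study):
        stack = small_study["stack"].copy()
        del stack.layers["elevation"], stack.kinds["elevation"]
        with pytest.raises(KeyError, match="elevation"):
            predict_probabilities(fitted, stack)


class TestConsensusImportance:
    def informative_model(self, light_hp):
        rng = np.random.default_rng(3)
        n = 600
        X = rng.normal(size=(n, 6))
        y = (X[:, 2] > 0).astype(int)  # only feature 2 carries signal
        model = fit_stacked_model(
            X, y, random_folds(n, 5), hp=light_hp,
            feature_names=[f"f{i}" for i in range(6)], seed=0,
        )
        return model

    def test_single_informative_feature_in_intersection(self, light_hp):
        model = self.informative_model(light_hp)
        assert "f2" in consensus_importance(model, top_k=3)

    def test_top_k_all_features_gives_full_intersection(self, light_hp):
        model = self.informative_model(light_hp)
        assert set(consensus_importance(model, top_k=6)) == {f"f{i}" for i in range(6)}

    def test_top_k_below_one_errors(self, light_hp):
        model = self.informative_model(light_hp)
        with pytest.raises(ValueError):
            consensus_importance(model, top_k=0)
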