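import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanorelease.exceptions import DegenerateVariableWarning, DomainError
from nanorelease.surrogate import (
    AugmentationConfig,
    ReleaseSurrogate,
    SurrogateConfig,
    SurrogateData,
    _forward,
    _n_weights,
    augment_gaussian,
    compare_augmentation_vs_cv,
    evaluate_metrics,
    fit_normalization,
    kfold_split,
    mean_relative_error,
    prepare_surrogate_data,
    records_to_xy,
    select_hidden_units,
    train_surrogate,
)


class TestNormalization:
    def test_endpoints_map_to_interval(self):
        spec = fit_normalization(np.array([[7.69], [14.29], [25.0]]), (-1, 1))
        z = spec.apply([[7.69], [25.0]])
        assert z[0, 0] == pytest.approx(-1.0)
        assert z[1, 0] == pytest.approx(1.0)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=30, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_apply_invert_identity(self, values):
        V = np.asarray(values)[:, None]
        spec = fit_normalization(V)
        np.testing.assert_allclose(spec.invert(spec.apply(V)), V, atol=1e-12)

    def test_constant_column_maps_to_midpoint(self):
        with pytest.warns(DegenerateVariableWarning):
            spec = fit_normalization(np.full((5, 1), 3.0), (0.1, 0.9))
        assert np.all(spec.apply(np.full((5, 1), 3.0)) == 0.5)


class TestAugmentation:
    def test_54_records_times_10_gives_540(self):
        X, Y = np.zeros((54, 4)), np.zeros((54, 4))
        Xa, Ya = augment_gaussian(X, Y, AugmentationConfig(seed=1))
        assert Xa.shape == (540, 4) and Ya.shape == (540, 4)

    def test_zero_sd_copies_identical(self):
        X = np.arange(12.0).reshape(3, 4)
        Xa, _ = augment_gaussian(X, X, AugmentationConfig(sd=0.0, seed=1))
        np.testing.assert_array_equal(Xa, np.repeat(X, 10, axis=0))

    def test_fixed_seed_deterministic(self):
        X = np.arange(12.0).reshape(3, 4)
        a = augment_gaussian(X, X, AugmentationConfig(seed=9))
        b = augment_gaussian(X, X, AugmentationConfig(seed=9))
        np.testing.assert_array_equal(a[0], b[0])

    def test_nonsensical_sd_rejected(self):
        with pytest.raises(DomainError):
            AugmentationConfig(sd=0.7)


class TestKFold:
    def test_54_into_10_fold_sizes(self):
        folds = kfold_split(54, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [5] * 6 + [6] * 4

    def test_folds_partition_index_set(self):
        folds = kfold_split(54, 10, seed=3)
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, np.arange(54))

    def test_same_seed_same_folds(self):
        a = kfold_split(30, 5, seed=2)
        b = kfold_split(30, 5, seed=2)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(DomainError):
            kfold_split(5, 10)


class TestTraining:
    def test_linear_map_learnable(self):
        """A noiseless linear target is learned to held-out R^2 >= 0.99."""
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (200, 4))
        Y = X @ rng.uniform(-1, 1, (4, 4))
        model = ReleaseSurrogate(X[:150], Y[:150], SurrogateConfig(seed=3)).fit()
        Pn, _ = _forward(model.weights, model.input_norm.apply(X[150:]), 4, 6, 4)
        m = evaluate_metrics(Pn, model.output_norm.apply(Y[150:]))
        assert m.r2 >= 0.99

    def test_noisy_nonlinear_map_learnable(self):
        """A smooth sum-of-sigmoids target with 1% noise reaches R^2 >= 0.95."""
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, (500, 4))
        Z = np.tanh(X @ rng.uniform(-2, 2, (4, 4)))
        Y = Z + rng.normal(0, 0.01 * Z.std(), Z.shape)
        model = ReleaseSurrogate(X[:400], Y[:400], SurrogateConfig(seed=5)).fit()
        Pn, _ = _forward(model.weights, model.input_norm.apply(X[400:]), 4, 6, 4)
        m = evaluate_metrics(Pn, model.output_norm.apply(Y[400:]))
        assert m.r2 >= 0.95

    def test_same_seed_identical_weights(self, dataset_nocurves):
        a = train_surrogate(dataset_nocurves.records, SurrogateConfig(seed=8))
        b = train_surrogate(dataset_nocurves.records, SurrogateConfig(seed=8))
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_gamma_within_weight_count(self, dataset_nocurves):
        model = train_surrogate(dataset_nocurves.records, SurrogateConfig(seed=8))
        assert 0 < model.gamma <= _n_weights(4, 6, 4)

    def test_regularization_shrinks_weight_norm(self, dataset_nocurves):
        cfg = SurrogateConfig(seed=4)
        br = train_surrogate(dataset_nocurves.records, cfg)
        un = train_surrogate(dataset_nocurves.records, replace(cfg, bayes=False))
        assert np.linalg.norm(br.weights) <= np.linalg.norm(un.weights)

    def test_too_few_records_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(DomainError):
            ReleaseSurrogate(X, X, SurrogateConfig()).fit()


class TestPrediction:
    def test_in_bounds_predictions_satisfy_invariants(self, dataset_nocurves):
        model = train_surrogate(dataset_nocurves.records, SurrogateConfig(seed=2))
        rng = np.random.default_rng(0)
        X = rng.uniform([1, 7.7, 1, 1], [2, 25, 7, 5], (50, 4))
        P = model.predict_array(X)
        assert np.all(np.isfinite(P))
        assert np.all(P[:, 0] <= P[:, 2] + 1e-9)  # br <= rtrmax
        assert np.all(P[:, 1] > 0)
        assert np.all((P[:, 3] > 0) & (P[:, 3] <= 100))

    def test_monotone_cs_effect_preserved(self, noiseless_dataset):
        """Noiseless monotone Le(CS) data yield monotone predictions in the hull."""
        model = train_surrogate(noiseless_dataset.records, SurrogateConfig(seed=2))
        cs = np.linspace(7.7, 25.0, 30)
        X = np.column_stack([np.full_like(cs, 1.625), cs,
                             np.full_like(cs, 3.667), np.full_like(cs, 3.0)])
        le = model.predict_array(X)[:, 3]
        assert np.all(np.diff(le) > -1e-6)
        assert le[-1] > le[0] + 10  # high-CS corner clearly above low-CS corner

    def test_training_point_interpolation_on_noiseless_data(self, noiseless_dataset):
        model = train_surrogate(noiseless_dataset.records, SurrogateConfig(seed=2))
        X, Y = records_to_xy(noiseless_dataset.records[:18])
        P = model.predict_array(X)
        assert np.all(np.abs(P - Y) / np.abs(Y) < 0.02)

    def test_extrapolation_warns(self, dataset_nocurves):
        from nanorelease.datamodel import FormulationParams

        model = train_surrogate(dataset_nocurves.records, SurrogateConfig(seed=2))
        with pytest.warns(UserWarning, match="training hull"):
            model.predict(FormulationParams(feeding_ratio=1.0, cs_percent=7.0,
                                            np_percent=1.0, drug_percent=1.0))

    def test_model_json_round_trip(self, dataset_nocurves, tmp_path):
        from nanorelease.surrogate import SurrogateModel

        model = train_surrogate(dataset_nocurves.records, SurrogateConfig(seed=2))
        model.to_json(tmp_path / "m.json")
        back = SurrogateModel.from_json(tmp_path / "m.json")
        X = np.array([[1.5, 15.0, 3.0, 3.0]])
        np.testing.assert_array_equal(model.predict_array(X), back.predict_array(X))


class TestMetrics:
    def test_perfect_and_mean_predictions(self):
        T = np.array([[1.0], [0.0], [0.5]])
        perfect = evaluate_metrics(T, T)
        assert perfect.mse == 0.0 and perfect.r2 == 1.0
        m = evaluate_metrics(np.full_like(T, T.mean()), T)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_case(self):
        """pairs (truth, pred) = (1, .9), (0, .1), (.5, .5)."""
        m = evaluate_metrics([0.9, 0.1, 0.5], [1.0, 0.0, 0.5])
        assert m.mse == pytest.approx(0.02 / 3)
        assert m.r2 == pytest.approx(1 - 0.02 / 0.5)

    def test_zero_variance_truths_rejected(self):
        with pytest.raises(DomainError):
            evaluate_metrics([0.1, 0.2], [0.5, 0.5])


class TestProtocol:
    def test_split_counts_and_augmentation(self, dataset_nocurves):
        data = prepare_surrogate_data(dataset_nocurves.records,
                                      AugmentationConfig(seed=1))
        assert data.n_real_train == 18
        assert data.n_augmented == 540
        assert data.X_train.shape == (558, 4)
        assert data.X_test.shape == (36, 4)

    def test_no_leakage_mode_augments_training_only(self, dataset_nocurves):
        data = prepare_surrogate_data(dataset_nocurves.records,
                                      AugmentationConfig(seed=1), leakage=False)
        assert data.n_augmented == 180

    def test_select_hidden_units_contract(self, dataset_nocurves):
        data = prepare_surrogate_data(dataset_nocurves.records,
                                      AugmentationConfig(seed=1))
        best, table = select_hidden_units(data, (5, 6), SurrogateConfig(seed=1, repeats=2))
        assert best in (5, 6)
        assert set(table.columns) >= {"hidden_units", "train_mse", "test_mse",
                                      "train_r2", "test_r2"}
        assert len(table) == 2

    def test_capacity_recovery_selects_teacher_size(self):
        """Data from a 6-unit teacher network prefer 6 units over 2."""
        rng = np.random.default_rng(0)
        w = rng.uniform(-3, 3, _n_weights(4, 6, 4))
        X = rng.uniform(-1, 1, (400, 4))
        Y, _ = _forward(w, X, 4, 6, 4)
        data = SurrogateData(X_train=X[:300], Y_train=Y[:300],
                             X_test=X[300:], Y_test=Y[300:],
                             input_norm=None, output_norm=None,
                             n_real_train=300, n_augmented=0)
        best, _ = select_hidden_units(data, (2, 6), SurrogateConfig(seed=4, repeats=2))
        assert best == 6

    def test_compare_strategies_reports_both_and_winner(self, dataset_nocurves):
        comp = compare_augmentation_vs_cv(
            dataset_nocurves.records, AugmentationConfig(seed=1),
            config=SurrogateConfig(seed=1, repeats=2))
        assert comp.winner in ("gaussian_noise", "cross_validation")
        assert comp.gaussian.mse >= 0 and comp.cross_validation.mse >= 0
        assert comp.gaussian.r2 <= 1 and comp.cross_validation.r2 <= 1

    def test_heldout_relative_error_is_small(self, dataset_nocurves):
        data = prepare_surrogate_data(dataset_nocurves.records,
                                      AugmentationConfig(seed=1))
        cfg = SurrogateConfig(seed=1)
        train_recs = [r for r in dataset_nocurves.records if r.replicate == 1]
        test_recs = [r for r in dataset_nocurves.records if r.replicate != 1]
        sur = ReleaseSurrogate(*records_to_xy(train_recs), config=cfg,
                               input_norm=data.input_norm,
                               output_norm=data.output_norm,
                               extra_normalized=(data.X_train[:540],
                                                 data.Y_train[:540]))
        model = sur.fit(seed=7)
        assert mean_relative_error(model, test_recs) < 0.15
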