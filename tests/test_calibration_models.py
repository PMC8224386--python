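"""Tests for the PLSR and feed-forward-network calibration engines."""

from __future__ import annotations

import numpy as np
import pytest

from hsifresh.calibration_models import (
    CalibratedModel,
    FnnModel,
    fit_fnn,
    fit_plsr,
    load_model,
    predict,
    save_model,
    search_fnn,
    select_n_latent,
)
from hsifresh.preprocessing import (
    PreprocessingChain,
    Normalizer,
    SpectralDataset,
    fit_normalizer,
    holdout_split,
)
from hsifresh.synthetic_data import make_planted_nonlinearity_dataset

from .conftest import make_linear_dataset


def low_rank_dataset(n=60, k=20, rank=3, seed=2):
    gen = np.random.default_rng(seed)
    T = gen.normal(size=(n, rank))
    L = gen.normal(size=(rank, k))
    y = T @ np.arange(1.0, rank + 1)
    return SpectralDataset(
        X=T @ L,
        Y=y,
        wavelengths=np.linspace(400, 1000, k),
        sample_ids=[f"s{i:03d}" for i in range(n)],
    )


class TestFitPlsr:
    def test_exact_fit_on_rank3_signal(self):
        ds = low_rank_dataset()
        model = fit_plsr(ds, 3)
        residuals = ds.Y - model.predict(ds.X)
        assert np.max(np.abs(residuals)) <= 1e-8

    def test_full_rank_matches_ols_pseudoinverse(self):
        ds = make_linear_dataset(n=30, k=10, seed=4, noise_sd=0.3)
        model = fit_plsr(ds, 10)
        Xc = ds.X - ds.X.mean(axis=0)
        beta = np.linalg.pinv(Xc) @ (ds.Y - ds.Y.mean())
        ols_pred = Xc @ beta + ds.Y.mean()
        assert np.allclose(model.predict(ds.X), ols_pred, atol=1e-6)

    def test_band_permutation_equivariance(self):
        ds = make_linear_dataset(n=40, k=8, seed=5, noise_sd=0.1)
        model = fit_plsr(ds, 4)
        perm = np.random.default_rng(0).permutation(8)
        ds_perm = SpectralDataset(
            ds.X[:, perm], ds.Y, ds.wavelengths, ds.sample_ids
        )
        model_perm = fit_plsr(ds_perm, 4)
        assert np.allclose(
            model_perm.predict(ds_perm.X), model.predict(ds.X), atol=1e-8
        )

    def test_collapsed_coefficients_match_componentwise(self):
        ds = make_linear_dataset(n=50, k=12, seed=6, noise_sd=0.5)
        model = fit_plsr(ds, 5)
        # componentwise route: scores from sequential deflation
        Xc = ds.X - model.x_mean
        pred_components = np.full(ds.n_samples, model.y_mean)
        for c in range(model.n_latent):
            t = Xc @ model.x_weights[:, c]
            pred_components += model.y_loadings[c] * t
            Xc = Xc - np.outer(t, model.x_loadings[:, c])
        assert np.allclose(model.predict(ds.X), pred_components, atol=1e-8)

    def test_n_latent_out_of_range(self):
        ds = make_linear_dataset(n=10, k=5)
        with pytest.raises(ValueError, match="n_latent"):
            fit_plsr(ds, 6)
        with pytest.raises(ValueError, match="n_latent"):
            fit_plsr(ds, 0)

    def test_zero_variance_rejected(self):
        ds = SpectralDataset(
            np.full((8, 4), 0.5), np.arange(8.0), np.linspace(400, 1000, 4),
            [f"s{i}" for i in range(8)],
        )
        with pytest.raises(ValueError, match="variance"):
            fit_plsr(ds, 1)

    def test_calibration_mean_predicts_target_mean(self):
        ds = make_linear_dataset(n=35, k=9, seed=8, noise_sd=0.2)
        model = fit_plsr(ds, 3)
        pred = model.predict(ds.X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(ds.Y.mean(), abs=1e-8)


class TestSelectNLatent:
    def test_rank3_signal_chooses_three(self):
        result = select_n_latent(low_rank_dataset(), 10, folds=5, seed=0)
        assert result.chosen_model.n_latent == 3
        assert result.press_curve.size == 10

    def test_pure_noise_chooses_one(self):
        gen = np.random.default_rng(3)
        ds = SpectralDataset(
            gen.normal(size=(60, 20)), gen.normal(size=60),
            np.linspace(400, 1000, 20), [f"s{i:03d}" for i in range(60)],
        )
        result = select_n_latent(ds, 8, folds=5, seed=0)
        assert result.chosen_model.n_latent == 1

    def test_determinism(self):
        ds = make_linear_dataset(n=40, k=10, seed=9, noise_sd=0.5)
        a = select_n_latent(ds, 6, folds=5, seed=11)
        b = select_n_latent(ds, 6, folds=5, seed=11)
        assert np.array_equal(a.press_curve, b.press_curve)
        assert a.chosen_index == b.chosen_index

    def test_tiny_folds_rejected(self):
        ds = make_linear_dataset(n=8, k=4)
        with pytest.raises(ValueError, match="fold"):
            select_n_latent(ds, 3, folds=8, seed=0)


class TestFitFnn:
    def test_constant_target_learned(self, rng):
        X = rng.normal(size=(50, 6))
        ds = SpectralDataset(
            X, np.full(50, 0.3), np.linspace(400, 1000, 6),
            [f"s{i}" for i in range(50)],
        )
        model = fit_fnn(ds, (6, 4, 1), epochs=10000, seed=1)
        assert np.max(np.abs(model.predict(X) - 0.3)) < 1e-3

    def test_linear_target_representable(self):
        ds = make_linear_dataset(n=80, k=10, seed=0)
        y_std = (ds.Y - ds.Y.mean()) / ds.Y.std()
        ds = SpectralDataset(ds.X, y_std, ds.wavelengths, ds.sample_ids)
        model = fit_fnn(ds, (10, 4, 1), epochs=3000, seed=0)
        pred = model.predict(ds.X)
        ss_res = np.sum((ds.Y - pred) ** 2)
        ss_tot = np.sum((ds.Y - ds.Y.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.999

    def test_seed_determinism(self):
        ds = make_linear_dataset(n=30, k=5, seed=1, noise_sd=0.1)
        a = fit_fnn(ds, (5, 4, 1), epochs=500, seed=7)
        b = fit_fnn(ds, (5, 4, 1), epochs=500, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))
        assert all(np.array_equal(x, y) for x, y in zip(a.biases, b.biases))

    def test_divergence_reports_epoch(self):
        ds = make_linear_dataset(n=20, k=4, seed=2)
        with pytest.raises(FloatingPointError, match="epoch"):
            fit_fnn(ds, (4, 4, 1), epochs=50, learning_rate=1e200, seed=0)

    def test_layer_size_validation(self):
        ds = make_linear_dataset(n=20, k=4)
        with pytest.raises(ValueError, match="input layer"):
            fit_fnn(ds, (5, 4, 1), epochs=10)
        with pytest.raises(ValueError, match="positive"):
            fit_fnn(ds, (4, 0, 1), epochs=10)

    def test_predict_repeatable(self):
        ds = make_linear_dataset(n=20, k=4, seed=3)
        model = fit_fnn(ds, (4, 3, 1), epochs=200, seed=0)
        assert np.array_equal(model.predict(ds.X), model.predict(ds.X))

    def test_leaky_slope_bounds(self):
        with pytest.raises(ValueError, match="leaky_slope"):
            FnnModel((3, 1), 1.5, [np.zeros((3, 1))], [np.zeros(1)], 0)


class TestSearchFnn:
    def test_singleton_grid_chosen(self):
        ds = make_linear_dataset(n=40, k=6, seed=4, noise_sd=0.2)
        result = search_fnn(ds, width_grid=[4], depth_grid=[1], folds=3, epochs=200)
        assert result.candidates[result.chosen_index] == (1, 4)

    def test_curve_length_is_grid_product(self):
        ds = make_linear_dataset(n=40, k=6, seed=4, noise_sd=0.2)
        result = search_fnn(
            ds, width_grid=[2, 4], depth_grid=[0, 1], folds=3, epochs=100
        )
        assert result.press_curve.size == 4

    def test_planted_nonlinearity_prefers_hidden_layer(self):
        ds = make_planted_nonlinearity_dataset(n=200, n_bands=20, seed=7)
        norm = fit_normalizer(ds)
        nds = SpectralDataset(
            norm.apply_x(ds.X), norm.apply_y(ds.Y), ds.wavelengths, ds.sample_ids
        )
        result = search_fnn(
            nds, width_grid=[8], depth_grid=[0, 1], folds=3, seed=0, epochs=800
        )
        depth, _ = result.candidates[result.chosen_index]
        assert depth == 1

    def test_empty_grid_rejected(self):
        ds = make_linear_dataset(n=20, k=4)
        with pytest.raises(ValueError, match="nonempty"):
            search_fnn(ds, width_grid=[], depth_grid=[1])


class TestCalibratedModel:
    def _bundle(self, ds, model):
        k = ds.n_bands
        identity = Normalizer(np.zeros(k), np.ones(k), 0.0, 1.0)
        chain = PreprocessingChain(np.arange(k), None, identity)
        return CalibratedModel("m", "tvbn", chain, model, ds.wavelengths)

    def test_back_transform_two_path_consistency(self):
        ds = make_linear_dataset(n=40, k=6, seed=5, noise_sd=0.3)
        norm = fit_normalizer(ds)
        nds = SpectralDataset(
            norm.apply_x(ds.X), norm.apply_y(ds.Y), ds.wavelengths, ds.sample_ids
        )
        model = fit_plsr(nds, 3)
        chain = PreprocessingChain(np.arange(ds.n_bands), None, norm)
        cm = CalibratedModel("m", "tvbn", chain, model, ds.wavelengths)
        via_bundle = cm.predict(ds.X)
        manual = norm.invert_y(model.predict(norm.apply_x(ds.X)))
        assert np.allclose(via_bundle, manual, atol=1e-12)

    def test_band_count_mismatch(self):
        ds = make_linear_dataset(n=20, k=6)
        cm = self._bundle(ds, fit_plsr(ds, 2))
        with pytest.raises(ValueError, match="bands"):
            cm.predict(np.zeros((2, 5)))

    @pytest.mark.parametrize("engine", ["plsr", "fnn"])
    def test_save_load_round_trip(self, tmp_path, engine):
        ds = make_linear_dataset(n=30, k=5, seed=6, noise_sd=0.2)
        if engine == "plsr":
            model = fit_plsr(ds, 3)
        else:
            model = fit_fnn(ds, (5, 4, 1), epochs=300, seed=0)
        cm = self._bundle(ds, model)
        path = save_model(cm, tmp_path / "model.json")
        back = load_model(path)
        assert np.allclose(back.predict(ds.X), cm.predict(ds.X), atol=1e-12)
        assert back.model_id == cm.model_id
        assert back.n_latent_or_width == cm.n_latent_or_width

    def test_module_level_predict_dispatch(self):
        ds = make_linear_dataset(n=20, k=4, seed=7)
        model = fit_plsr(ds, 2)
        assert np.allclose(predict(model, ds.X), model.predict(ds.X))


class TestEngineComparison:
    def test_fnn_beats_plsr_on_planted_nonlinearity(self):
        ds = make_planted_nonlinearity_dataset(n=300, n_bands=60, seed=7)
        cal, pred = holdout_split(ds, 0.85, 123)
        norm = fit_normalizer(cal)
        caln = SpectralDataset(
            norm.apply_x(cal.X), norm.apply_y(cal.Y), cal.wavelengths, cal.sample_ids
        )
        pred_Xn = norm.apply_x(pred.X)

        plsr = select_n_latent(caln, 10, folds=5, seed=0).chosen_model
        fnn = fit_fnn(caln, (ds.n_bands, 16, 1), epochs=3000, seed=0)

        def r2(yhat_norm):
            yhat = norm.invert_y(yhat_norm)
            return 1 - np.sum((pred.Y - yhat) ** 2) / np.sum(
                (pred.Y - pred.Y.mean()) ** 2
            )

        assert r2(fnn.predict(pred_Xn)) > r2(plsr.predict(pred_Xn))
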