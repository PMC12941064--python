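"""Surrogate architecture, preprocessing, splits, training, fidelity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tissuelight.surrogate import (
    SurrogateModel,
    SurrogateSpec,
    TrainingConfig,
    default_log_flags,
    evaluate_fidelity,
    fit_normalization,
    inverse_preprocess,
    kfold_splits,
    parameter_count,
    predict_reflectance,
    preprocess,
    split_dataset,
    train_surrogate,
)


class TestArchitecture:
    def test_reference_parameter_count(self):
        """15-input, 5x512 reference net has exactly 1,059,329 parameters."""
        spec = SurrogateSpec(input_dim=15)
        assert spec.n_parameters == 15 * 512 + 512 + 4 * (512**2 + 512) + 512 + 1
        assert spec.n_parameters == 1_059_329

    @given(d=st.integers(1, 40), h=st.integers(1, 80), l=st.integers(1, 6))
    def test_formula_matches_weight_enumeration(self, d, h, l):
        spec = SurrogateSpec(input_dim=d, hidden_units=h, hidden_layers=l)
        net = spec.build(np.random.default_rng(0))
        assert net.n_parameters == spec.n_parameters == parameter_count(d, h, l)

    def test_kaiming_initialization_scale(self):
        net = SurrogateSpec(input_dim=100, hidden_units=512).build(
            np.random.default_rng(0))
        std = net.weights[1].std()
        expected = np.sqrt(2.0 / (1 + 0.2**2) / 512)
        assert std == pytest.approx(expected, rel=0.1)
        assert all(np.all(b == 0) for b in net.biases)


class TestSplits:
    def test_spectrum_level_split_proportions(self):
        """10 spectra x 15 wavelengths -> 7/1/2 spectra, never split."""
        ids = np.repeat(np.arange(10), 15)
        tr, va, te = split_dataset(ids, seed=0)
        counts = [np.unique(ids[idx]).size for idx in (tr, va, te)]
        assert counts == [7, 1, 2]
        for idx in (tr, va, te):
            for sid in np.unique(ids[idx]):
                assert np.count_nonzero(ids[idx] == sid) == 15  # whole spectra

    def test_partition_properties(self):
        ids = np.repeat(np.arange(50), 3)
        tr, va, te = split_dataset(ids, seed=1)
        union = np.sort(np.concatenate([tr, va, te]))
        assert np.array_equal(union, np.arange(ids.size))
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
        tr2, va2, te2 = split_dataset(ids, seed=1)
        assert np.array_equal(tr, tr2) and np.array_equal(te, te2)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.arange(10), fractions=(0.5, 0.2, 0.2))

    def test_kfold_partitions_training_pool_only(self):
        ids = np.repeat(np.arange(20), 2)
        folds = list(kfold_splits(ids, 4, seed=3))
        assert len(folds) == 4
        held = []
        for rows in folds:
            out = set(np.unique(ids)) - set(np.unique(ids[rows]))
            held.append(out)
        # held-out spectrum groups partition the pool
        assert set().union(*held) == set(np.unique(ids))
        assert sum(len(h) for h in held) == 20


class TestPreprocessing:
    def test_log_flags_target_mu_a_mu_s_d(self):
        flags = default_log_flags(10)
        assert flags.tolist() == [True, True, False, False, True] * 2

    def test_zero_variance_feature_named(self):
        x = np.column_stack([np.full(50, 100.0), np.random.default_rng(0).random(50),
                             np.ones(50), np.ones(50), np.full(50, 2.0)])
        with pytest.raises(ValueError, match=r"\[0"):
            fit_normalization(x)

    def test_standard_normal_passthrough(self, rng):
        x = rng.normal(0, 1, (5000, 3))
        norm = fit_normalization(x, log10_transform=np.zeros(3, bool))
        assert np.allclose(norm.mean, 0, atol=0.05)
        assert np.allclose(norm.std, 1, atol=0.05)

    def test_decadic_log_range(self, rng):
        x = 10 ** rng.uniform(-2, 3, (1000, 5))
        flags = np.array([True, False, False, False, False])
        flags_x = x.copy()
        norm = fit_normalization(flags_x, log10_transform=flags)
        t = preprocess(x, norm)
        recovered = t[:, 0] * norm.std[0] + norm.mean[0]
        assert recovered.min() >= -2 - 1e-9 and recovered.max() <= 3 + 1e-9

    def test_training_means_map_to_zero(self, rng):
        x = rng.uniform(1, 5, (200, 5))
        norm = fit_normalization(x, log10_transform=np.zeros(5, bool))
        z = preprocess(x.mean(axis=0)[None, :], norm)
        assert np.allclose(z, 0, atol=1e-12)

    def test_round_trip_inverse(self, rng):
        x = 10 ** rng.uniform(-1, 2, (100, 5))
        norm = fit_normalization(x)
        assert np.allclose(inverse_preprocess(preprocess(x, norm), norm), x, rtol=1e-12)

    def test_batch_equals_rowwise(self, rng):
        x = 10 ** rng.uniform(-1, 2, (50, 5))
        norm = fit_normalization(x)
        batch = preprocess(x, norm)
        rows = np.vstack([preprocess(x[i:i + 1], norm) for i in range(50)])
        assert np.array_equal(batch, rows)

    def test_nonpositive_under_log_flag_rejected(self):
        x = np.abs(np.random.default_rng(0).normal(1, 0.1, (20, 5))) + 0.1
        norm = fit_normalization(x)
        bad = x.copy()
        bad[0, 0] = -1.0
        with pytest.raises(ValueError, match="nonpositive"):
            preprocess(bad, norm)

    def test_no_leakage_into_statistics(self, rng):
        """Normalization depends on the training rows only."""
        train = 1 + rng.random((100, 5))
        a = fit_normalization(train)
        b = fit_normalization(train)  # other data changing has no pathway in
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.std, b.std)


class TestTraining:
    def test_constant_target_is_learned(self):
        rng = np.random.default_rng(0)
        x = 1 + rng.random((600, 5))
        y = np.full(600, 0.3)
        spec = SurrogateSpec(input_dim=5, hidden_units=32, hidden_layers=2)
        cfg = TrainingConfig(seed=0, batch_size=64, patience=50, max_epochs=3000,
                             learning_rate=1e-2)
        model = train_surrogate(x[:500], y[:500], x[500:], y[500:], spec, cfg)
        pred = predict_reflectance(model, x[500:])
        assert np.max(np.abs(pred - 0.3)) < 1e-3

    def test_smooth_map_learned_to_oracle_accuracy(self, tiny_surrogate):
        """On a noise-free logistic map the generating function is the oracle."""
        model, x, y = tiny_surrogate
        report = evaluate_fidelity(model, x[3600:], y[3600:])
        assert report.mae < 1e-3

    def test_divergence_raises(self):
        rng = np.random.default_rng(1)
        x = 1 + rng.random((100, 5))
        y = rng.random(100)
        spec = SurrogateSpec(input_dim=5, hidden_units=16, hidden_layers=1)
        cfg = TrainingConfig(seed=1, learning_rate=1e6, batch_size=32,
                             patience=10, max_epochs=50)
        from tissuelight.surrogate.model import TrainingError

        with pytest.raises((TrainingError, FloatingPointError, ValueError)):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train_surrogate(x[:80], y[:80], x[80:], y[80:], spec, cfg)

    def test_metadata_recorded(self, tiny_surrogate):
        model, _, _ = tiny_surrogate
        assert model.training_meta["seed"] == 7
        assert model.training_meta["epochs_run"] == 2500
        assert np.isfinite(model.training_meta["final_val_loss"])


class TestPrediction:
    def test_outputs_in_open_unit_interval(self, tiny_surrogate, rng):
        model, x, _ = tiny_surrogate
        pred = predict_reflectance(model, x)
        assert np.all(pred > 0) and np.all(pred < 1)

    def test_deterministic_and_batch_invariant(self, tiny_surrogate):
        model, x, _ = tiny_surrogate
        a = predict_reflectance(model, x[:64])
        b = predict_reflectance(model, x[:64])
        assert np.array_equal(a, b)
        singles = np.concatenate([predict_reflectance(model, x[i:i + 1])
                                  for i in range(8)])
        assert np.allclose(a[:8], singles, atol=1e-6)

    def test_dimension_mismatch_rejected(self, tiny_surrogate):
        model, _, _ = tiny_surrogate
        with pytest.raises(ValueError, match="features"):
            predict_reflectance(model, np.ones((3, 4)))


class TestFidelity:
    def test_perfect_and_offset_errors(self, tiny_surrogate):
        model, x, y = tiny_surrogate
        pred = predict_reflectance(model, x[3600:])
        report = evaluate_fidelity(model, x[3600:], pred)  # targets = predictions
        assert report.mae == 0.0 and report.mape_percent == 0.0
        offset = evaluate_fidelity(model, x[3600:], pred - 0.01)
        assert offset.mae == pytest.approx(0.01, abs=1e-12)

    def test_relative_error_scale(self, tiny_surrogate):
        model, x, _ = tiny_surrogate
        pred = predict_reflectance(model, x[3600:])
        report = evaluate_fidelity(model, x[3600:], pred / 1.001)
        assert report.mape_percent == pytest.approx(0.1, rel=1e-3)

    def test_zero_targets_excluded_with_count(self, tiny_surrogate):
        model, x, _ = tiny_surrogate
        targets = predict_reflectance(model, x[3600:3610]).copy()
        targets[:3] = 0.0
        report = evaluate_fidelity(model, x[3600:3610], targets)
        assert report.n_mape_excluded == 3
        assert report.ape_percent.size == 7

    def test_reference_targets_override(self, tiny_surrogate):
        model, x, y = tiny_surrogate
        noisy = y[3600:] + 0.05
        ref = predict_reflectance(model, x[3600:])
        report = evaluate_fidelity(model, x[3600:], noisy, reference_targets=ref)
        assert report.mae == 0.0


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_surrogate, tmp_path):
        model, x, _ = tiny_surrogate
        path = tmp_path / "ckpt.h5"
        model.save(path)
        loaded = SurrogateModel.load(path)
        assert np.array_equal(predict_reflectance(model, x[:32]),
                              predict_reflectance(loaded, x[:32]))
        assert loaded.spec == model.spec
        assert loaded.training_meta["seed"] == model.training_meta["seed"]
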