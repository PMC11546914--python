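import numpy as np
import pytest

from metamarker.io_prep import apply_scaler, fit_scaler, preprocess
from metamarker.secondary import (
    DAEConfig,
    EnsembleConfig,
    NoiseModel,
    ReluAutoencoder,
    TrainedDAE,
    add_noise,
    detect_anomalies,
    reconstruction_errors,
    run_ensemble,
    spread_hidden_sizes,
    train_dae,
)
from metamarker.synthetic import SyntheticConfig, generate

FAST_NOISE = NoiseModel(replicates_per_profile=60)


class TestNoiseModel:
    def test_zero_noise_level_is_identity(self):
        profile = np.array([0.2, 0.8, 0.5])
        reps = add_noise(profile, NoiseModel(d=0.0, replicates_per_profile=10))
        np.testing.assert_array_equal(reps, np.tile(profile, (10, 1)))

    def test_replicate_sd_matches_closed_form(self):
        # Var(d*e) with e ~ N(0, sigma=CO) is d^2 CO^2: CO=4, d=0.25 -> SD 1
        reps = add_noise(
            np.array([4.0]), NoiseModel(d=0.25, replicates_per_profile=10_000, seed=1)
        )
        assert reps.std() == pytest.approx(1.0, rel=0.03)
        assert reps.mean() == pytest.approx(4.0, abs=0.05)

    def test_zero_value_stays_exact(self):
        reps = add_noise(np.array([0.0, 1.0]), NoiseModel(seed=2))
        assert np.all(reps[:, 0] == 0.0)

    def test_default_replicate_count_is_500(self):
        assert NoiseModel().replicates_per_profile == 500
        assert add_noise(np.array([1.0]), NoiseModel(seed=0)).shape == (500, 1)


def _scaled_controls(seed=0, n=27, p=20, blocks=(5, 5, 5)):
    cfg = SyntheticConfig(
        n_control=n, n_case=2, n_metabolites=p, block_sizes=list(blocks),
        missing_rate=0.0, seed=seed,
    )
    m = preprocess(generate(cfg)[0])
    controls = m.controls()
    return apply_scaler(fit_scaler(controls), controls).values


class TestTrainDAE:
    def test_beats_per_metabolite_mean_baseline(self):
        X = _scaled_controls()
        cfg = DAEConfig(n_features=20, hidden_size=10, seed=3)
        model = train_dae(X, cfg, NoiseModel(replicates_per_profile=200, seed=3))
        rng = np.random.default_rng(3)
        order = rng.permutation(27)
        n_train = 22
        train_X, test_X = X[order[:n_train]], X[order[n_train:]]
        dae_mse = float(np.mean((model.net.predict(test_X) - test_X) ** 2))
        baseline_mse = float(np.mean((train_X.mean(axis=0) - test_X) ** 2))
        assert dae_mse < baseline_mse

    def test_high_capacity_fits_rank_deficient_data(self):
        # 3-dimensional nonnegative data embedded in 12 features, no noise:
        # a hidden layer of width 11 can drive training loss near zero
        rng = np.random.default_rng(9)
        latent = rng.uniform(0.1, 1.0, size=(30, 3))
        basis = rng.uniform(0.0, 1.0, size=(3, 12))
        X = latent @ basis
        X /= X.max()
        cfg = DAEConfig(n_features=12, hidden_size=11, epochs=60, seed=9)
        model = train_dae(X, cfg, NoiseModel(d=0.0, replicates_per_profile=50))
        assert model.train_loss < 2e-4

    def test_identical_seed_identical_weights(self):
        X = _scaled_controls(seed=5)
        cfg = DAEConfig(n_features=20, hidden_size=8, epochs=3, seed=11)
        m1 = train_dae(X, cfg, FAST_NOISE)
        m2 = train_dae(X, cfg, FAST_NOISE)
        np.testing.assert_array_equal(m1.net.W1, m2.net.W1)
        np.testing.assert_array_equal(m1.net.W2, m2.net.W2)
        assert m1.train_loss == m2.train_loss

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            train_dae(np.ones((1, 4)), DAEConfig(n_features=4, hidden_size=2), FAST_NOISE)


def identity_model(n):
    rng = np.random.default_rng(0)
    net = ReluAutoencoder(n, n, rng)
    net.W1 = np.eye(n)
    net.b1 = np.zeros(n)
    net.W2 = np.eye(n)
    net.b2 = np.zeros(n)
    return TrainedDAE(net, DAEConfig(n_features=n, hidden_size=n - 1), 0.0, 0.0)


class TestReconstructionErrors:
    def test_identity_map_gives_zero_errors(self):
        model = identity_model(6)
        X = np.random.default_rng(1).uniform(0, 1, size=(5, 6))
        np.testing.assert_allclose(reconstruction_errors(model, X), 0.0, atol=1e-12)

    def test_sample_order_equivariance_and_duplicates(self):
        X = _scaled_controls(seed=2)
        model = train_dae(
            X, DAEConfig(n_features=20, hidden_size=8, epochs=3, seed=2), FAST_NOISE
        )
        err = reconstruction_errors(model, X)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_array_equal(reconstruction_errors(model, X[perm]), err[perm])
        dup = np.vstack([X[0], X[0]])
        err_dup = reconstruction_errors(model, dup)
        np.testing.assert_array_equal(err_dup[0], err_dup[1])

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_errors(identity_model(6), np.ones((2, 5)))


class TestDetectAnomalies:
    def test_identical_error_tables_give_no_flags(self):
        err = np.random.default_rng(0).uniform(0, 1, size=(10, 8))
        res = detect_anomalies(err, err.copy())
        assert not res["flag"].any()
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_planted_shift_is_flagged_selectively(self):
        rng = np.random.default_rng(4)
        ctrl = rng.uniform(0, 0.1, size=(27, 30))
        case = rng.uniform(0, 0.1, size=(12, 30))
        case[:, 3] += 1.0  # +10 SD shift in one metabolite's errors
        res = detect_anomalies(case, ctrl)
        assert bool(res["flag"].iloc[3])
        assert res["flag"].drop(index=3).mean() <= 0.05

    def test_flags_subset_of_raw_significance(self):
        rng = np.random.default_rng(6)
        case = rng.uniform(size=(12, 25))
        case[:, :5] += rng.uniform(0.2, 0.8, size=5)
        res = detect_anomalies(case, rng.uniform(size=(27, 25)))
        assert set(res.index[res["flag"]]) <= set(res.index[res["p"] < 0.05])


class TestEnsemble:
    def test_hidden_size_band_matches_study_shape(self):
        assert spread_hidden_sizes(210, 100) == list(range(50, 150))

    def test_consensus_counts_and_monotonicity(self):
        cfg = SyntheticConfig(
            n_metabolites=16, block_sizes=[4, 4], secondary_markers=[0],
            missing_rate=0.0, seed=8,
        )
        m = preprocess(generate(cfg)[0])
        ens = EnsembleConfig(
            n_models=3, hidden_sizes=[4, 6, 8], consensus_min=3, seed=8
        )
        res = run_ensemble(
            m, ens, dae_template=DAEConfig(n_features=16, hidden_size=4, epochs=5),
            nm=NoiseModel(replicates_per_profile=60, seed=8),
        )
        counts = res.table["consensus_count"]
        assert counts.between(0, 3).all()
        assert (res.table.loc[res.table["selected"], "consensus_count"] >= 3).all()
        # raising the consensus threshold can only shrink the selected set
        stricter = set(res.table.index[counts >= 3])
        looser = set(res.table.index[counts >= 2])
        assert stricter <= looser
        # flags and counts agree
        np.testing.assert_array_equal(
            res.flags.sum(axis=0),
            res.table.sort_index()["consensus_count"]
            .reindex(m.metabolite_ids)
            .to_numpy(),
        )

    def test_requires_imputed_matrix(self):
        cfg = SyntheticConfig(n_metabolites=8, block_sizes=[], missing_rate=0.3, seed=1)
        raw, _ = generate(cfg)
        with pytest.raises(ValueError, match="imputed"):
            run_ensemble(raw, EnsembleConfig(n_models=1, hidden_sizes=[3], consensus_min=1))
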