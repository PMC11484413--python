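"""Autoencoder architectures, losses, trainer, and checkpointing."""

import numpy as np
import pytest

from vmatqa.feature_map import FeatureTensor
from vmatqa.models import (
    ModelConfig,
    build_model,
    contractive_penalty,
    kl_divergence,
    load_model,
    loss_aperture,
    loss_dose,
    loss_total,
    reconstruct,
    regularizer,
    save_model,
    train,
)

TINY = dict(input_shape=(16, 16), channels=(2, 4, 4, 8), latent_dim=4, batch_size=16)


def tensor_from(rng, k=12, shape=(16, 16), label="regular", plan_id="t"):
    ap = (rng.random((k,) + shape) > 0.55).astype(np.uint8)
    doses = rng.uniform(2.0, 5.0, k).astype(np.float32)
    return FeatureTensor(ap, ap * doses[:, None, None], doses, plan_id, label)


class TestConfigAndBuild:
    def test_input_shape_must_be_16_divisible(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            ModelConfig(input_shape=(60, 64))

    def test_four_halvings_shape_arithmetic(self):
        model = build_model(ModelConfig(input_shape=(64, 64)))
        assert model.spatial == (4, 4)

    def test_latent_dimension_echo(self, rng):
        model = build_model(ModelConfig(epochs=0, latent_dim=32, **{k: v for k, v in TINY.items() if k != "latent_dim"}))
        x = rng.random((3, 16, 16, 1)).astype(np.float32)
        h = model.encode(x)
        assert h.shape == (3, 32)

    def test_variational_head_emits_two_sets_of_stats(self, rng):
        model = build_model(ModelConfig(model_kind="variational", **TINY))
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        mu, logvar = model.encode_stats(x)
        assert mu.shape == (2, 4) and logvar.shape == (2, 4)
        assert model.stats_head.layers[0].w.data.shape[1] == 8

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="model_kind"):
            ModelConfig(model_kind="gan")


class TestLosses:
    def test_bce_hand_cases(self):
        assert loss_aperture(
            np.array([1.0, 0.0]), np.array([0.5, 0.5])
        ) == pytest.approx(np.log(2), abs=1e-9)
        assert loss_aperture(
            np.ones((2, 2)), np.full((2, 2), 0.9)
        ) == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_bce_perfect_reconstruction_negligible(self, rng):
        a = (rng.random((4, 8, 8)) > 0.5).astype(float)
        assert loss_aperture(a, np.clip(a, 1e-7, 1 - 1e-7)) <= 1e-5

    def test_mse_hand_case_and_homogeneity(self):
        assert loss_dose(np.array([1.0, 3.0]), np.array([2.0, 2.0])) == pytest.approx(1.0)
        d = np.array([1.0, 2.0, 5.0])
        dh = np.array([1.5, 1.0, 7.0])
        assert loss_dose(d, 2 * dh - d) == pytest.approx(4 * loss_dose(d, dh))

    def test_total_weighting(self):
        assert loss_total(0.5, 0.25, 1.0) == 0.75
        assert loss_total(0.1, 0.3, 2.0) == pytest.approx(0.5)
        assert loss_total(123.0, 0.7, 0.0) == 0.7  # lambda=0 degenerates to L_D

    def test_losses_nonnegative_random(self, rng):
        for _ in range(20):
            a = (rng.random(10) > 0.5).astype(float)
            p = rng.random(10)
            assert loss_aperture(a, p) >= 0
            assert loss_dose(rng.random(5), rng.random(5)) >= 0

    def test_kl_closed_form(self):
        assert kl_divergence(np.zeros((1, 3)), np.zeros((1, 3))) == 0.0
        assert kl_divergence(np.array([[1.0]]), np.array([[0.0]])) == pytest.approx(0.5)


class TestRegularizers:
    def test_constant_encoder_has_zero_contractive_penalty(self, rng):
        model = build_model(ModelConfig(model_kind="contractive", **TINY))
        for p in model.parameters():
            p.data[...] = 0.0
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        assert contractive_penalty(model, x) == 0.0

    def test_fd_estimator_consistent_with_exact_jacobian(self, rng):
        model = build_model(ModelConfig(model_kind="contractive", contractive_gamma=1.0, **TINY))
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        exact = contractive_penalty(model, x)
        delta = 1e-3
        est = []
        for _ in range(300):
            eps = rng.standard_normal(x.shape).astype(np.float32)
            h1, _ = model.encoder.forward(x, train=False, update_stats=False)
            h2, _ = model.encoder.forward(x + delta * eps, train=False, update_stats=False)
            diff = (h2 - h1) / delta
            est.append(np.mean(np.sum(diff.astype(np.float64) ** 2, axis=1)))
        assert np.mean(est) == pytest.approx(exact, rel=0.25)

    def test_variational_regularizer_uses_closed_form(self, rng):
        model = build_model(ModelConfig(model_kind="variational", vae_beta=2.0, **TINY))
        x = rng.random((3, 16, 16, 1)).astype(np.float32)
        mu, logvar = model.encode_stats(x)
        assert regularizer(model, x) == pytest.approx(2.0 * kl_divergence(mu, logvar))

    def test_regularizer_undefined_for_plain_kinds(self, rng):
        model = build_model(ModelConfig(model_kind="multitask", **TINY))
        with pytest.raises(ValueError, match="no regularizer"):
            regularizer(model, rng.random((1, 16, 16, 1)).astype(np.float32))


class TestTrain:
    def test_zero_epochs_leaves_weights_unchanged(self, rng):
        t = tensor_from(rng)
        model = build_model(ModelConfig(epochs=0, **TINY))
        before = model.checksum()
        report = train(model, [t])
        assert model.checksum() == before == report.checksum
        assert report.baseline and all(len(v) == 0 for v in report.losses.values())

    def test_training_is_deterministic(self, rng):
        t = tensor_from(rng)
        reports = []
        for _ in range(2):
            model = build_model(ModelConfig(epochs=2, seed=5, **TINY))
            reports.append(train(model, [t]))
        assert reports[0].losses == reports[1].losses
        assert reports[0].checksum == reports[1].checksum

    def test_single_repeated_cp_overfits(self):
        # one CP repeated; 200 epochs must cut L_R by more than 10x
        ap = np.zeros((16, 32, 32), np.uint8)
        ap[:, 8:24, 10:22] = 1
        doses = np.full(16, 4.0, dtype=np.float32)
        t = FeatureTensor(ap, ap * doses[:, None, None], doses, "rep", "regular")
        cfg = ModelConfig(
            input_shape=(32, 32), channels=(4, 8, 16, 32), latent_dim=16,
            epochs=200, batch_size=4, seed=0,
        )
        model = build_model(cfg)
        report = train(model, [t])
        assert report.losses["L_R"][-1] < 0.1 * report.baseline["L_R"]

    def test_vanilla_identical_to_contractive_with_zero_gamma(self, rng):
        t = tensor_from(rng)
        runs = {}
        for kind in ("vanilla", "contractive"):
            cfg = ModelConfig(model_kind=kind, contractive_gamma=0.0, epochs=2, seed=3, **TINY)
            model = build_model(cfg)
            runs[kind] = train(model, [t]).losses["L_I"]
        assert runs["vanilla"] == runs["contractive"]

    def test_anomalous_plans_rejected_from_training(self, rng):
        t = tensor_from(rng, label="anomalous")
        model = build_model(ModelConfig(**TINY))
        with pytest.raises(ValueError, match="regular plans only"):
            train(model, [t])

    def test_empty_training_set_rejected(self):
        model = build_model(ModelConfig(**TINY))
        with pytest.raises(ValueError, match="empty"):
            train(model, [])


class TestReconstruct:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(0)
        t = tensor_from(rng, k=24)
        model = build_model(ModelConfig(epochs=1, **TINY))
        train(model, [t])
        return model, t

    def test_shapes_and_ranges(self, trained):
        model, t = trained
        r = reconstruct(model, t)
        assert r.intensity_hat.shape == t.intensities.shape
        assert r.aperture_prob.shape == t.apertures.shape
        assert r.dose_hat.shape == t.doses.shape
        assert np.all((r.aperture_prob > 0) & (r.aperture_prob < 1))

    def test_intensity_assembled_from_both_heads(self, trained):
        model, t = trained
        r = reconstruct(model, t)
        np.testing.assert_allclose(
            r.intensity_hat, r.dose_hat[:, None, None] * r.aperture_prob, rtol=1e-6
        )

    def test_baselines_return_intensity_only(self, rng):
        t = tensor_from(rng)
        for kind in ("vanilla", "contractive", "variational"):
            model = build_model(ModelConfig(model_kind=kind, epochs=0, **TINY))
            train(model, [t])
            r = reconstruct(model, t)
            assert r.aperture_prob is None and r.dose_hat is None
            assert r.intensity_hat.shape == t.intensities.shape

    def test_shape_mismatch_refused(self, trained, rng):
        model, _ = trained
        bad = tensor_from(rng, shape=(32, 32))
        with pytest.raises(ValueError, match="input\\s+shape|input shape"):
            reconstruct(model, bad)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, rng, tmp_path):
        t = tensor_from(rng)
        model = build_model(ModelConfig(epochs=1, **TINY))
        train(model, [t])
        path = tmp_path / "m.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.checksum() == model.checksum()
        assert back.dose_norm == model.dose_norm
        r0, r1 = reconstruct(model, t), reconstruct(back, t)
        np.testing.assert_array_equal(r0.intensity_hat, r1.intensity_hat)

    def test_loaded_model_refuses_mismatched_tensors(self, rng, tmp_path):
        model = build_model(ModelConfig(epochs=0, **TINY))
        train(model, [tensor_from(rng)])
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        with pytest.raises(ValueError):
            reconstruct(back, tensor_from(rng, shape=(32, 32)))
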