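"""Denoising architectures: structure, gradients, training behaviour."""

import numpy as np
import pytest

from spect_bench.models import (
    ModelSpec,
    TrainConfig,
    TrainedModel,
    build_model,
    denoise_volume,
    train,
)
from spect_bench.nn.layers import bce_with_logits, mse_loss
from spect_bench.volume import Volume


class TestBuildModel:
    def test_cnn_structure(self):
        """8 convolutional layers, 8 filters each, 3x3x3 kernels, plus a
        1-channel projection."""
        m = build_model(ModelSpec(kind="CNN"))
        assert len(m.net.convs) == 8
        for conv in m.net.convs:
            assert conv.params["W"].shape[:3] == (3, 3, 3)
            assert conv.params["W"].shape[-1] == 8
        assert m.net.proj.params["W"].shape[-1] == 1

    def test_res_replaces_blocks_with_residual_units(self):
        m = build_model(ModelSpec(kind="RES"))
        assert len(m.net.units) == 4  # conv-ReLU-conv + identity units
        for c1, _, c2, _ in m.net.units:
            assert c1.params["W"].shape[-1] == 8
            assert c2.params["W"].shape[-1] == 8

    def test_unet_levels_and_filters(self):
        m = build_model(ModelSpec(kind="UNET"))
        assert len(m.net.enc) == 3
        filters = [blk[0].params["W"].shape[-1] for blk in m.net.enc]
        assert filters == [8, 16, 32]
        assert len(m.net.ups) == 2

    def test_cgan_discriminator_structure(self):
        """Four 4x4x4 stride-2 convolutions then one fully connected unit
        whose output is squashed to a probability."""
        m = build_model(ModelSpec(kind="CGAN", patch_size=32))
        assert m.disc is not None
        assert len(m.disc.convs) == 4
        for conv in m.disc.convs:
            assert conv.k == 4 and conv.s == 2
        x = np.random.default_rng(0).standard_normal((2, 32, 32, 32, 2)).astype(np.float32)
        prob = m.disc.predict_proba(x)
        assert prob.shape == (2, 1)
        assert np.all((prob >= 0) & (prob <= 1))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            ModelSpec(kind="FOO")

    def test_unet_patch_divisibility_guard(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelSpec(kind="UNET", patch_size=30)

    def test_generators_consume_and_emit_same_patch_shape(self):
        x = np.random.default_rng(0).standard_normal((2, 16, 16, 16, 1)).astype(np.float32)
        for kind in ("CNN", "RES", "UNET", "CGAN"):
            m = build_model(ModelSpec(kind=kind, patch_size=16))
            assert m.net.forward(x).shape == x.shape


class TestGradients:
    @pytest.mark.parametrize("kind", ["CNN", "RES", "UNET", "CGAN"])
    def test_analytic_gradient_matches_finite_difference(self, kind):
        rng = np.random.default_rng(1)
        m = build_model(ModelSpec(kind=kind, n_layers=4, n_filters=2, patch_size=16),
                        seed=0)
        x = rng.standard_normal((2, 16, 16, 16, 1)).astype(np.float32)
        y = rng.standard_normal((2, 16, 16, 16, 1)).astype(np.float32)
        _, dout = mse_loss(m.net.forward(x), y)
        m.net.backward(dout)
        layers = m.net.parameters()
        layer = layers[len(layers) // 2]
        g = layer.grads["W"].copy()
        idx = np.unravel_index(np.argmax(np.abs(g)), g.shape)
        eps, W = 1e-3, layer.params["W"]
        W[idx] += eps
        l1, _ = mse_loss(m.net.forward(x), y)
        W[idx] -= 2 * eps
        l2, _ = mse_loss(m.net.forward(x), y)
        W[idx] += eps
        assert g[idx] == pytest.approx((l1 - l2) / (2 * eps), rel=0.02, abs=1e-4)

    def test_discriminator_input_gradient(self):
        rng = np.random.default_rng(2)
        m = build_model(ModelSpec(kind="CGAN", patch_size=16), seed=0)
        x = rng.standard_normal((2, 16, 16, 16, 2)).astype(np.float32)
        _, dl = bce_with_logits(m.disc.forward(x), np.ones((2, 1)))
        dx = m.disc.backward(dl.astype(np.float32))
        idx = (0, 5, 5, 5, 1)
        eps = 1e-3
        xp = x.copy()
        xp[idx] += eps
        l1, _ = bce_with_logits(m.disc.forward(xp), np.ones((2, 1)))
        xp[idx] -= 2 * eps
        l2, _ = bce_with_logits(m.disc.forward(xp), np.ones((2, 1)))
        assert dx[idx] == pytest.approx((l1 - l2) / (2 * eps), rel=0.05, abs=1e-6)


def _poisson_pairs(n, seed, size=8):
    """Smooth random intensity maps + low-count Poisson noise."""
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    clean = np.stack([
        gaussian_filter(rng.uniform(0, 6, (size,) * 3), 1.5) for _ in range(n)
    ])
    scale = clean.mean()
    noisy = rng.poisson(clean) / scale
    return noisy.astype(np.float32), (clean / scale).astype(np.float32)


class TestTrain:
    def test_identity_pairs_reduce_loss(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, (50, 8, 8, 8)).astype(np.float32)
        m = build_model(ModelSpec(kind="CNN", patch_size=8, infer_stride=4), seed=0)
        train(m, (x, x), TrainConfig(epochs=5, batch_size=16, seed=0))
        assert m.history[-1]["loss"] < m.history[0]["loss"]

    def test_denoising_gain_on_poisson_pairs(self):
        """Held-out MSE(denoised, clean) < MSE(noisy, clean) in >= 9/10 seeds."""
        wins = 0
        for seed in range(10):
            xs, ys = _poisson_pairs(150, seed)
            m = build_model(ModelSpec(kind="CNN", patch_size=8, infer_stride=4),
                            seed=seed)
            train(m, (xs[:120], ys[:120]),
                  TrainConfig(epochs=8, batch_size=8, seed=seed))
            out = m.net.forward(xs[120:, ..., None])[..., 0]
            if np.mean((out - ys[120:]) ** 2) < np.mean((xs[120:] - ys[120:]) ** 2):
                wins += 1
        assert wins >= 9

    def test_default_config_matches_protocol(self):
        cfg = TrainConfig()
        assert cfg.epochs == 100
        assert cfg.batch_size == 32
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (8, 8, 8, 8)).astype(np.float32)
        m = build_model(ModelSpec(kind="CNN", patch_size=8), seed=0)
        train(m, (x, x), TrainConfig(epochs=1, batch_size=4, seed=3))
        assert m.meta["optimizer"] == "adam"
        assert m.meta["betas"] == [0.9, 0.999]

    def test_training_is_reproducible(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (20, 8, 8, 8)).astype(np.float32)
        y = x + 0.1 * rng.standard_normal(x.shape).astype(np.float32)
        runs = []
        for _ in range(2):
            m = build_model(ModelSpec(kind="CNN", patch_size=8), seed=11)
            train(m, (x, y), TrainConfig(epochs=2, batch_size=8, seed=11))
            runs.append([h["loss"] for h in m.history])
        assert runs[0] == runs[1]

    def test_cgan_with_zero_adversarial_weight_equals_unet(self):
        """lambda = 0 reduces the cGAN generator objective to the UNET one:
        matched seeds give identical loss histories."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, (24, 16, 16, 16)).astype(np.float32)
        y = x + 0.05 * rng.standard_normal(x.shape).astype(np.float32)
        unet = build_model(ModelSpec(kind="UNET", patch_size=16), seed=21)
        cgan = build_model(ModelSpec(kind="CGAN", patch_size=16, lambda_adv=0.0),
                           seed=21)
        train(unet, (x, y), TrainConfig(epochs=2, batch_size=8, seed=21))
        train(cgan, (x, y), TrainConfig(epochs=2, batch_size=8, seed=21))
        u = [h["loss"] for h in unet.history]
        c = [h["g_l2"] for h in cgan.history]
        assert u == pytest.approx(c, rel=1e-6)

    def test_mismatched_pair_counts_rejected(self):
        x = np.zeros((4, 8, 8, 8), np.float32)
        y = np.zeros((3, 8, 8, 8), np.float32)
        m = build_model(ModelSpec(kind="CNN", patch_size=8))
        with pytest.raises(ValueError, match="mismatched"):
            train(m, (x, y), TrainConfig(epochs=1))


class TestDenoiseVolume:
    def test_identity_model_round_trip(self):
        """A model trained on identity pairs leaves a volume nearly unchanged."""
        rng = np.random.default_rng(6)
        x = rng.uniform(0.5, 1.5, (80, 8, 8, 8)).astype(np.float32)
        m = build_model(ModelSpec(kind="CNN", patch_size=8, infer_stride=4), seed=0)
        train(m, (x, x), TrainConfig(epochs=6, batch_size=16, seed=0))
        vol = Volume(rng.uniform(0.5, 1.5, (16, 16, 16)), 4.8)
        out = denoise_volume(m, vol)
        floor = m.history[-1]["loss"] * vol.data.mean() ** 2
        assert np.mean((out.data - vol.data) ** 2) <= max(5 * floor, 1e-3)

    def test_zero_volume_is_finite(self):
        m = build_model(ModelSpec(kind="CNN", patch_size=8, infer_stride=8), seed=0)
        m.history.append({"loss": 0.0})  # mark trained
        out = denoise_volume(m, Volume(np.zeros((16, 16, 16)), 4.8))
        assert np.all(np.isfinite(out.data))
        assert np.all(out.data >= 0)

    def test_untrained_model_rejected(self, random_volume):
        m = build_model(ModelSpec(kind="CNN", patch_size=8))
        with pytest.raises(ValueError, match="not been trained"):
            denoise_volume(m, random_volume)


class TestCheckpointIO:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, (8, 16, 16, 16)).astype(np.float32)
        m = build_model(ModelSpec(kind="CGAN", patch_size=16), seed=2)
        train(m, (x, x), TrainConfig(epochs=1, batch_size=4, seed=2))
        path = str(tmp_path / "model.npz")
        m.save(path)
        back = TrainedModel.load(path)
        assert back.spec == m.spec
        assert back.history == m.history
        xin = x[..., None]
        np.testing.assert_allclose(back.net.forward(xin), m.net.forward(xin),
                                   atol=1e-6)
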