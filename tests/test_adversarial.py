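"""Patch lattice, discriminator scoring, loss arithmetic in both modes,
soft labels and the training loops."""

import numpy as np
import pytest

from decontrast import adversarial as adv
from decontrast import generators as G
from decontrast.nn.tensor import Tensor
from decontrast.types import Volume3D


class TestExtractPatches:
    def test_paper_lattice_128_patch64_stride50(self):
        vol = np.zeros((128, 128, 128), dtype=np.float32)
        ps = adv.extract_patches(vol, 64, 50)
        assert len(ps.origins) == 8
        per_axis = sorted({o[0] for o in ps.origins})
        assert per_axis == [0, 50]
        assert ps.patches.shape == (8, 64, 64, 64)

    def test_whole_volume_single_patch(self, rng):
        vol = rng.random((64, 64, 64))
        ps = adv.extract_patches(vol, 64, 50)
        assert ps.origins == [(0, 0, 0)]
        np.testing.assert_array_equal(ps.patches[0], vol)

    def test_stride_64_tiles_volume_exactly(self, rng):
        vol = rng.random((32, 32, 32))
        ps = adv.extract_patches(vol, 16, 16)
        assert len(ps.origins) == 8
        rebuilt = np.zeros_like(vol)
        for patch, (i, j, k) in zip(ps.patches, ps.origins):
            rebuilt[i:i + 16, j:j + 16, k:k + 16] = patch
        np.testing.assert_array_equal(rebuilt, vol)

    def test_origins_lexicographic(self, rng):
        ps = adv.extract_patches(rng.random((20, 20, 20)), 8, 6)
        assert ps.origins == sorted(ps.origins)

    def test_oversized_patch_raises(self, rng):
        with pytest.raises(ValueError):
            adv.extract_patches(rng.random((16, 16, 16)), 32, 8)

    def test_accepts_volume3d(self, random_volume):
        ps = adv.extract_patches(random_volume, 8, 8)
        np.testing.assert_array_equal(ps.patches[0], random_volume.values[:8, :8, :8])


@pytest.fixture(scope="module")
def disc():
    return adv.build_discriminator(adv.DiscriminatorConfig(base_channels=2,
                                                           patch_size=16, seed=0))


class TestDiscriminator:
    def test_scores_in_open_unit_interval(self, disc, rng):
        x = Tensor(rng.normal(size=(3, 2, 16, 16, 16)).astype(np.float32))
        p = disc(x).numpy()
        assert p.shape == (3,)
        assert np.all(np.isfinite(p)) and np.all(p > 0) and np.all(p < 1)

    def test_deterministic(self, disc, rng):
        x = rng.normal(size=(2, 2, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(disc(Tensor(x)).numpy(), disc(Tensor(x)).numpy())

    def test_volume_score_is_mean_of_patch_scores(self, disc, rng):
        pairs = rng.normal(size=(8, 2, 16, 16, 16)).astype(np.float32)
        batch = disc(Tensor(pairs)).numpy()
        single = np.array([disc(Tensor(pairs[i:i + 1])).numpy()[0] for i in range(8)])
        np.testing.assert_allclose(batch, single, rtol=1e-5)
        assert np.isfinite(batch.mean())

    def test_wrong_channel_count_raises(self, disc, rng):
        with pytest.raises(ValueError):
            disc(Tensor(rng.normal(size=(1, 3, 16, 16, 16)).astype(np.float32)))


class TestSoftLabels:
    def test_conventional_ranges(self, rng):
        cfg = adv.SoftLabelConfig()
        assert all(0.7 <= adv.draw_soft_label("real", cfg, rng) <= 1.0 for _ in range(50))
        assert all(0.0 <= adv.draw_soft_label("fake", cfg, rng) <= 0.3 for _ in range(50))

    def test_paper_literal_swaps_ranges(self, rng):
        cfg = adv.SoftLabelConfig(mode="paper_literal")
        assert all(0.0 <= adv.draw_soft_label("real", cfg, rng) <= 0.3 for _ in range(50))
        assert all(0.7 <= adv.draw_soft_label("fake", cfg, rng) <= 1.0 for _ in range(50))

    def test_monte_carlo_mean_near_range_midpoint(self, rng):
        cfg = adv.SoftLabelConfig()
        draws = np.array([adv.draw_soft_label("real", cfg, rng) for _ in range(10_000)])
        sd = 0.3 / np.sqrt(12)
        assert abs(draws.mean() - 0.85) < 3 * sd / np.sqrt(draws.size)

    def test_unknown_kind_raises(self, rng):
        with pytest.raises(ValueError):
            adv.draw_soft_label("synthetic", adv.SoftLabelConfig(), rng)


LS = adv.TrainConfig(loss_mode="least_squares", epochs=1)
CE = adv.TrainConfig(loss_mode="cross_entropy", epochs=1)


class TestLosses:
    def test_generator_perfect_least_squares_is_zero(self, rng):
        real = rng.random((4, 4, 4))
        _, rec = adv.generator_loss(np.array([0.9, 0.9]), real, real, LS, real_label=0.9)
        assert rec.L_G == pytest.approx(0.0, abs=1e-7)

    def test_generator_l1_arithmetic(self, rng):
        real = rng.random((4, 4, 4)) * 0.5
        fake = real + 0.1
        _, rec = adv.generator_loss(np.array([1.0]), fake, real, LS, real_label=1.0)
        assert rec.adversarial_term == pytest.approx(0.0, abs=1e-7)
        assert rec.L_G == pytest.approx(0.1, rel=1e-5)
        assert rec.L1_term == pytest.approx(0.1, rel=1e-5)

    def test_generator_cross_entropy_optimum_is_zero(self, rng):
        real = rng.random((4, 4, 4))
        _, rec = adv.generator_loss(np.array([1.0]), real, real, CE)
        assert rec.L_G == pytest.approx(0.0, abs=1e-6)

    def test_discriminator_cross_entropy_optimum_is_zero(self):
        _, val = adv.discriminator_loss(np.ones(4), np.zeros(4), CE)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_discriminator_least_squares_half_half(self):
        _, val = adv.discriminator_loss(np.full(4, 0.5), np.full(4, 0.5), LS,
                                        real_label=1.0, fake_label=0.0)
        assert val == pytest.approx(0.25, rel=1e-6)

    def test_discriminator_zero_at_soft_labels(self):
        _, val = adv.discriminator_loss(np.full(3, 0.83), np.full(3, 0.12), LS,
                                        real_label=0.83, fake_label=0.12)
        assert val == pytest.approx(0.0, abs=1e-7)

    def test_losses_nonnegative_least_squares(self, rng):
        for _ in range(20):
            p_r = rng.random(5)
            p_f = rng.random(5)
            _, val = adv.discriminator_loss(p_r, p_f, LS, rng.random(), rng.random())
            assert val >= 0.0

    def test_mismatched_score_lengths_raise(self):
        with pytest.raises(ValueError):
            adv.discriminator_loss(np.ones(3), np.ones(4), LS)


def _toy_pairs(n, rng, grid=16):
    out = []
    for _ in range(n):
        y = rng.random((grid, grid, grid)) * 0.8
        x = np.clip(y + 0.15 * (y > 0.5), 0, 1)   # enhancement-like shift
        out.append((x, y))
    return out


def toy_gen_cfg(grid=16):
    return G.GeneratorConfig(variant="res", depth=2, base_channels=2,
                             input_shape=(grid, grid, grid), seed=2)


class TestTrainGeneratorOnly:
    def test_history_length_and_checkpoint_is_best(self, rng):
        pairs = _toy_pairs(4, rng)
        cfg = adv.TrainConfig(epochs=3, lr=1e-3, seed=0)
        ckpt, hist = adv.train_generator_only(pairs, toy_gen_cfg(), cfg)
        assert len(hist) == 3
        assert ckpt["best_loss"] == min(h.L1_term for h in hist)
        assert all(np.isfinite(h.L1_term) for h in hist)

    def test_two_runs_identical_trajectories(self, rng):
        pairs = _toy_pairs(4, rng)
        cfg = adv.TrainConfig(epochs=2, lr=1e-3, seed=0)
        _, h1 = adv.train_generator_only(pairs, toy_gen_cfg(), cfg)
        _, h2 = adv.train_generator_only(pairs, toy_gen_cfg(), cfg)
        assert [h.L1_term for h in h1] == [h.L1_term for h in h2]

    def test_loss_decreases_on_learnable_task(self, rng):
        pairs = _toy_pairs(8, rng)
        cfg = adv.TrainConfig(epochs=8, lr=5e-3, betas=(0.9, 0.999), seed=0)
        _, hist = adv.train_generator_only(pairs, toy_gen_cfg(), cfg)
        assert hist[-1].L1_term < hist[0].L1_term

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            adv.train_generator_only([], toy_gen_cfg(), adv.TrainConfig(epochs=1))


def _small_train_cfg(epochs, seed=0):
    return adv.TrainConfig(epochs=epochs, lr=2e-3, patch_size=8, patch_stride=8,
                           seed=seed)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(0)
    pairs = _toy_pairs(3, rng)
    gen_cfg = toy_gen_cfg()
    gen_ckpt, _ = adv.train_generator_only(pairs, gen_cfg, _small_train_cfg(1))
    disc_cfg = adv.DiscriminatorConfig(base_channels=2, patch_size=8, seed=1)
    return pairs, gen_ckpt, disc_cfg


class TestDiscriminatorPretrainAndCgan:
    def test_zero_epochs_returns_initial_weights(self, setup):
        pairs, gen_ckpt, disc_cfg = setup
        gen = adv.load_generator(gen_ckpt)
        ckpt = adv.pretrain_discriminator(pairs, gen, disc_cfg, _small_train_cfg(0))
        fresh = adv.PatchDiscriminator(disc_cfg).state_dict()
        for k, v in ckpt["state"].items():
            np.testing.assert_array_equal(v, fresh[k])

    def test_pretraining_separates_real_from_fake(self, setup):
        pairs, gen_ckpt, disc_cfg = setup
        gen = adv.load_generator(gen_ckpt)   # crude generator: fakes are easy
        ckpt = adv.pretrain_discriminator(pairs, gen, disc_cfg, _small_train_cfg(6))
        disc = adv.load_discriminator(ckpt)
        cfg = _small_train_cfg(0)
        p_real, p_fake = [], []
        for x01, y01 in ((p[0], p[1]) for p in pairs):
            x = G.to_model_range(x01)
            fake = gen(Tensor(x[None, None])).numpy()[0, 0]
            p_real.extend(disc(Tensor(adv._patch_pairs_np(x, G.to_model_range(y01), cfg))).numpy())
            p_fake.extend(disc(Tensor(adv._patch_pairs_np(x, fake, cfg))).numpy())
        assert np.mean(p_real) > np.mean(p_fake)

    def test_cgan_two_epochs_finite_history(self, setup):
        pairs, gen_ckpt, disc_cfg = setup
        gen = adv.load_generator(gen_ckpt)
        disc_ckpt = adv.pretrain_discriminator(pairs, gen, disc_cfg, _small_train_cfg(1))
        ckpt, hist = adv.train_cgan(pairs, gen_ckpt, disc_ckpt, _small_train_cfg(2))
        assert len(hist) == 2
        for h in hist:
            assert np.isfinite(h.L_G) and np.isfinite(h.L_D) and h.L1_term >= 0

    def test_large_l1_weight_makes_adversarial_term_negligible(self, setup):
        pairs, gen_ckpt, disc_cfg = setup
        gen = adv.load_generator(gen_ckpt)
        disc_ckpt = adv.pretrain_discriminator(pairs, gen, disc_cfg, _small_train_cfg(1))
        cfg = adv.TrainConfig(epochs=1, lr=2e-3, patch_size=8, patch_stride=8,
                              l1_weight=1e6, seed=0)
        _, hist = adv.train_cgan(pairs, gen_ckpt, disc_ckpt, cfg)
        h = hist[0]
        assert h.adversarial_term / h.L_G < 1e-3  # generator-only behaviour

    def test_cgan_deterministic(self, setup):
        pairs, gen_ckpt, disc_cfg = setup
        gen = adv.load_generator(gen_ckpt)
        disc_ckpt = adv.pretrain_discriminator(pairs, gen, disc_cfg, _small_train_cfg(1))
        _, h1 = adv.train_cgan(pairs, gen_ckpt, disc_ckpt, _small_train_cfg(1, seed=4))
        _, h2 = adv.train_cgan(pairs, gen_ckpt, disc_ckpt, _small_train_cfg(1, seed=4))
        assert h1[0].L_G == h2[0].L_G and h1[0].L_D == h2[0].L_D
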