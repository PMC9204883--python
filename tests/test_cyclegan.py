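"""Translation model: shape contracts, losses, training loop, checkpoints."""

import numpy as np
import pytest

from truss_seg import nn
from truss_seg.cyclegan import (
    CycleGAN,
    CycleGANResults,
    CycleGanState,
    DiscriminatorConfig,
    GeneratorConfig,
    TrainConfig,
    build_discriminator,
    build_generator,
    convert,
    cycle_losses,
    normalize_images,
    patch_output_size,
    train,
)

SMALL_GEN = GeneratorConfig(input_size=32, base_channels=4, transformer_blocks=1)
SMALL_DISC = DiscriminatorConfig(base_channels=4)


@pytest.fixture(scope="module")
def tiny_domains():
    rng = np.random.default_rng(42)
    xs = rng.integers(0, 256, size=(6, 32, 32, 3), dtype=np.uint8)
    ys = rng.integers(0, 256, size=(6, 32, 32, 3), dtype=np.uint8)
    return xs, ys


class TestArchitecture:
    @pytest.mark.parametrize("size", [32, 64])
    def test_generator_preserves_raster_shape(self, size):
        g = build_generator(
            GeneratorConfig(input_size=size, base_channels=4, transformer_blocks=1)
        )
        x = np.zeros((1, 3, size, size), np.float32)
        y, _ = g.forward(x)
        assert y.shape == x.shape

    def test_input_size_not_divisible_by_four_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(input_size=510)

    def test_default_transformer_depth_is_eight(self):
        assert GeneratorConfig().transformer_blocks == 8

    def test_residual_block_with_zero_weights_is_identity(self):
        g = build_generator(SMALL_GEN)
        block = next(l for l in g.layers if isinstance(l, nn.Residual))
        for p in block.parameters():
            if p.name == "W":
                p.value[...] = 0.0
        x = np.random.default_rng(0).standard_normal((1, 16, 8, 8)).astype(np.float32)
        y, _ = block.forward(x)
        np.testing.assert_allclose(y, x, atol=1e-6)

    def test_discriminator_prediction_field(self):
        d = build_discriminator(SMALL_DISC)
        x = np.random.default_rng(1).standard_normal((2, 3, 64, 64)).astype(np.float32)
        y, _ = d.forward(x)
        assert y.shape == (2, 1, patch_output_size(64), patch_output_size(64))
        assert np.isfinite(y).all()
        y2, _ = d.forward(x)
        np.testing.assert_array_equal(y, y2)

    def test_patch_field_extent_from_layer_arithmetic(self):
        # three stride-2 then two stride-1 4x4 convs, pad 1:
        # 512 -> 256 -> 128 -> 64 -> 63 -> 62
        assert patch_output_size(512) == 62
        assert patch_output_size(64) == 6


class _IdentityModule(nn.Module):
    def forward(self, x):
        return x, None


class _ConstantModule(nn.Module):
    def __init__(self, c):
        self.c = c

    def forward(self, x):
        return np.full_like(x, self.c), None


def _state_with(G, F):
    return CycleGanState(
        G=G, F=F,
        Dx=build_discriminator(SMALL_DISC), Dy=build_discriminator(SMALL_DISC),
        gen_config=SMALL_GEN, disc_config=SMALL_DISC,
    )


class TestCycleLosses:
    def test_identity_generators_zero_loss(self, rng):
        state = _state_with(_IdentityModule(), _IdentityModule())
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        y = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        fwd, rev = cycle_losses(x, y, state)
        assert fwd == 0.0 and rev == 0.0

    def test_constant_round_trip_closed_form(self):
        c = 0.37
        state = _state_with(_IdentityModule(), _ConstantModule(c))
        x = np.zeros((1, 3, 8, 8), np.float32)  # F(G(x)) = c everywhere
        y = np.zeros((1, 3, 8, 8), np.float32)
        fwd, _ = cycle_losses(x, y, state)
        assert fwd == pytest.approx(c, rel=1e-6)

    def test_matches_elementwise_oracle(self, rng):
        state = _state_with(
            build_generator(SMALL_GEN, np.random.default_rng(3)),
            build_generator(SMALL_GEN, np.random.default_rng(4)),
        )
        x = rng.uniform(-1, 1, (2, 3, 8, 8)).astype(np.float32)
        y = rng.uniform(-1, 1, (2, 3, 8, 8)).astype(np.float32)
        fwd, rev = cycle_losses(x, y, state)
        gx, _ = state.G.forward(x)
        fgx, _ = state.F.forward(gx)
        oracle = np.mean([abs(float(a) - float(b)) for a, b in
                          zip(fgx.ravel(), x.ravel())])
        assert fwd == pytest.approx(oracle, rel=1e-6)
        assert fwd >= 0 and rev >= 0

    def test_shape_mismatch_rejected(self, rng):
        state = _state_with(_IdentityModule(), _IdentityModule())
        with pytest.raises(ValueError):
            cycle_losses(
                np.zeros((1, 3, 8, 8), np.float32),
                np.zeros((1, 3, 16, 16), np.float32),
                state,
            )


class TestTraining:
    def test_zero_iterations_is_initialization(self, tiny_domains):
        xs, ys = tiny_domains
        state = train(xs, ys, TrainConfig(iterations=0, rng_seed=1),
                      gen_config=SMALL_GEN, disc_config=SMALL_DISC)
        assert state.loss_history == []
        assert state.iteration == 0

    def test_loss_history_per_iteration_and_finite(self, tiny_domains):
        xs, ys = tiny_domains
        state = train(xs, ys, TrainConfig(iterations=4, batch_size=2, rng_seed=1),
                      gen_config=SMALL_GEN, disc_config=SMALL_DISC)
        assert len(state.loss_history) == 4
        for rec in state.loss_history:
            for key in ("g_loss", "dx_loss", "dy_loss", "fwd_cycle", "rev_cycle"):
                assert np.isfinite(rec[key])
                assert rec[key] >= 0

    def test_seeded_training_reproducible(self, tiny_domains):
        xs, ys = tiny_domains
        cfg = TrainConfig(iterations=3, batch_size=2, rng_seed=9)
        s1 = train(xs, ys, cfg, gen_config=SMALL_GEN, disc_config=SMALL_DISC)
        s2 = train(xs, ys, cfg, gen_config=SMALL_GEN, disc_config=SMALL_DISC)
        assert s1.loss_history == s2.loss_history
        for p1, p2 in zip(s1.G.parameters(), s2.G.parameters()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_empty_dataset_rejected(self, tiny_domains):
        xs, _ = tiny_domains
        with pytest.raises(ValueError):
            train(xs, np.empty((0, 32, 32, 3), np.uint8), TrainConfig(iterations=1))

    def test_unpaired_domain_sizes_allowed(self, tiny_domains):
        xs, ys = tiny_domains
        state = train(xs[:5], ys[:3],
                      TrainConfig(iterations=2, batch_size=2, rng_seed=0),
                      gen_config=SMALL_GEN, disc_config=SMALL_DISC)
        assert state.iteration == 2

    def test_model_results_fit_summary(self, tiny_domains):
        xs, ys = tiny_domains
        model = CycleGAN(
            xs, ys, gen_config=SMALL_GEN, disc_config=SMALL_DISC,
            train_config=TrainConfig(iterations=3, batch_size=2, rng_seed=2),
        )
        res = model.fit()
        assert len(res.loss_history) == 3
        text = res.summary()
        assert "iterations" in text and "cycle loss" in text
        assert res.loss_table().shape == (3, 6)


class TestConvertAndCheckpoint:
    def test_convert_resizes_and_bounds(self, tiny_domains, rng):
        xs, ys = tiny_domains
        state = train(xs, ys, TrainConfig(iterations=1, batch_size=2, rng_seed=0),
                      gen_config=SMALL_GEN, disc_config=SMALL_DISC)
        big = rng.integers(0, 256, size=(90, 160, 3), dtype=np.uint8)
        out = convert(state, big)
        assert out.shape == (32, 32, 3)
        assert out.dtype == np.uint8
        np.testing.assert_array_equal(out, convert(state, big))

    def test_full_scale_resize_contract(self):
        """A 1600x900 frame maps to the generator's square working size."""
        cfg = GeneratorConfig(input_size=512, base_channels=2, transformer_blocks=0)
        state = CycleGanState(
            G=build_generator(cfg), F=build_generator(cfg),
            Dx=build_discriminator(SMALL_DISC), Dy=build_discriminator(SMALL_DISC),
            gen_config=cfg, disc_config=SMALL_DISC,
        )
        frame = np.zeros((900, 1600, 3), np.uint8)
        assert convert(state, frame).shape == (512, 512, 3)

    def test_non_three_channel_rejected(self, tiny_domains):
        xs, ys = tiny_domains
        state = train(xs, ys, TrainConfig(iterations=0), gen_config=SMALL_GEN,
                      disc_config=SMALL_DISC)
        with pytest.raises(ValueError):
            convert(state, np.zeros((32, 32), np.uint8))

    def test_checkpoint_round_trip_bit_identical(self, tiny_domains, tmp_path):
        xs, ys = tiny_domains
        state = train(xs, ys, TrainConfig(iterations=2, batch_size=2, rng_seed=5),
                      gen_config=SMALL_GEN, disc_config=SMALL_DISC)
        img = xs[0]
        before = convert(state, img)
        path = tmp_path / "ckpt.npz"
        state.save(path)
        loaded = CycleGanState.load(path)
        np.testing.assert_array_equal(before, convert(loaded, img))
        assert loaded.iteration == state.iteration
        assert loaded.loss_history == state.loss_history
        res = CycleGANResults.load(path)
        np.testing.assert_array_equal(before, res.convert(img))


def test_normalize_round_trip(rng):
    img = rng.integers(0, 256, size=(2, 8, 8, 3), dtype=np.uint8)
    n = normalize_images(img)
    assert n.shape == (2, 3, 8, 8)
    assert n.min() >= -1.0 and n.max() <= 1.0
    from truss_seg.cyclegan import denormalize_image

    np.testing.assert_array_equal(denormalize_image(n), img)
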