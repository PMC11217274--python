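"""Architecture contracts: shapes, output ranges, determinism, gradient flow."""

import numpy as np
import pytest

from hazecycle._autodiff import Tensor
from hazecycle.haze_physics import T_MIN
from hazecycle.networks import (DiscriminatorConfig, GeneratorConfig,
                                build_dehaze_generator,
                                build_detail_discriminator,
                                build_structure_discriminator,
                                build_translation_generator,
                                image_to_tensor, tensor_to_image)

SMALL = dict(base_channels=64, width_multiplier=0.0625, n_residual_blocks=1)


def rand_input(h, w, seed=0):
    return Tensor(np.random.default_rng(seed).uniform(
        0, 1, (1, 3, h, w)).astype(np.float32))


def conv_out(size, k, s, p):
    return (size + 2 * p - k) // s + 1


class TestDehazeGenerator:
    def test_full_resolution_output_shapes(self):
        gen = build_dehaze_generator(GeneratorConfig(**SMALL), seed=1)
        j, t = gen(rand_input(256, 256))
        assert j.shape == (1, 3, 256, 256)
        assert t.shape == (1, 1, 256, 256)

    def test_head_ranges_forced_by_activations(self):
        gen = build_dehaze_generator(GeneratorConfig(**SMALL), seed=2)
        j, t = gen(rand_input(64, 64, seed=3))
        assert np.all(j.data >= 0.0) and np.all(j.data <= 1.0)
        assert np.all(t.data >= T_MIN) and np.all(t.data <= 1.0)

    def test_repeatable_given_seed(self):
        cfg = GeneratorConfig(**SMALL)
        x = rand_input(32, 32, seed=4)
        j1, t1 = build_dehaze_generator(cfg, seed=7)(x)
        j2, t2 = build_dehaze_generator(cfg, seed=7)(x)
        np.testing.assert_array_equal(j1.data, j2.data)
        np.testing.assert_array_equal(t1.data, t2.data)

    def test_odd_sizes_padded_and_cropped(self):
        gen = build_dehaze_generator(GeneratorConfig(**SMALL), seed=1)
        j, t = gen(rand_input(30, 27))
        assert j.shape == (1, 3, 30, 27)
        assert t.shape == (1, 1, 30, 27)

    def test_composes_with_scattering_model(self):
        from hazecycle.haze_physics import apply_scattering
        gen = build_dehaze_generator(GeneratorConfig(**SMALL), seed=1)
        x = rand_input(32, 32)
        j, t = gen(x)
        recomposed = apply_scattering(tensor_to_image(j),
                                      tensor_to_image(t), 0.9)
        assert recomposed.shape == (32, 32, 3)

    def test_requires_transmission_flag(self):
        with pytest.raises(ValueError, match="emit_transmission"):
            build_dehaze_generator(
                GeneratorConfig(emit_transmission=False, **SMALL))


class TestTranslationGenerator:
    def test_output_contract(self):
        cfg = GeneratorConfig(emit_transmission=False, **SMALL)
        gen = build_translation_generator(cfg, seed=5)
        x = rand_input(64, 64, seed=6)
        y = gen(x)
        assert y.shape == (1, 3, 64, 64)
        assert np.all(y.data >= 0.0) and np.all(y.data <= 1.0)
        assert not np.allclose(y.data, x.data, atol=1e-3)

    def test_width_multiplier_scales_parameters(self):
        small = build_translation_generator(GeneratorConfig(
            emit_transmission=False, width_multiplier=0.125), seed=1)
        big = build_translation_generator(GeneratorConfig(
            emit_transmission=False, width_multiplier=0.25), seed=1)
        assert small.num_parameters() < big.num_parameters()

    def test_too_narrow_config_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            GeneratorConfig(width_multiplier=0.01)


class TestDetailDiscriminator:
    def test_emits_patch_map_not_scalar(self):
        d = build_detail_discriminator(
            DiscriminatorConfig(kind="detail", width_multiplier=0.0625),
            seed=1)
        scores = d(rand_input(256, 256))
        assert scores.shape[2] > 1 and scores.shape[3] > 1
        assert np.all(scores.data > 0.0) and np.all(scores.data < 1.0)

    def test_patch_map_matches_layer_trace_oracle(self):
        d = build_detail_discriminator(
            DiscriminatorConfig(kind="detail", width_multiplier=0.0625),
            seed=2)
        for size in (64, 96, 256):
            h = size
            for s in (2, 2, 2, 1):           # four stages, kernel 4, pad 1
                h = conv_out(h, 4, s, 1)
            h = conv_out(h, 1, 1, 0)         # 1x1 score conv
            scores = d(rand_input(size, size))
            assert scores.shape == (1, 1, h, h)

    def test_undersized_input_rejected(self):
        d = build_detail_discriminator(
            DiscriminatorConfig(kind="detail", width_multiplier=0.0625))
        with pytest.raises(ValueError, match="16x16"):
            d(rand_input(8, 8))


class TestStructureDiscriminator:
    @pytest.mark.parametrize("size", [64, 256])
    def test_always_reduces_to_4x4(self, size):
        d = build_structure_discriminator(
            DiscriminatorConfig(kind="structure", width_multiplier=0.0625,
                                input_size=size), seed=3)
        scores = d(rand_input(size, size))
        assert scores.shape == (1, 1, 4, 4)
        assert np.all(scores.data > 0.0) and np.all(scores.data < 1.0)

    def test_default_depth_is_seven_stages(self):
        d = build_structure_discriminator(
            DiscriminatorConfig(kind="structure", width_multiplier=0.0625),
            seed=1)
        assert len(d.stages._seq) == 7

    def test_wrong_input_size_names_requirement(self):
        d = build_structure_discriminator(
            DiscriminatorConfig(kind="structure", width_multiplier=0.0625,
                                input_size=64))
        with pytest.raises(ValueError, match="64x64"):
            d(rand_input(32, 32))

    def test_non_power_of_two_size_rejected(self):
        with pytest.raises(ValueError, match="power-of-two"):
            build_structure_discriminator(DiscriminatorConfig(
                kind="structure", width_multiplier=0.0625, input_size=100))


@pytest.mark.parametrize("build", [
    lambda: build_dehaze_generator(GeneratorConfig(**SMALL), seed=11),
    lambda: build_translation_generator(
        GeneratorConfig(emit_transmission=False, **SMALL), seed=12),
    lambda: build_detail_discriminator(
        DiscriminatorConfig(kind="detail", width_multiplier=0.0625), seed=13),
    lambda: build_structure_discriminator(
        DiscriminatorConfig(kind="structure", width_multiplier=0.0625,
                            input_size=32), seed=14),
], ids=["dehaze_gen", "translation_gen", "detail_disc", "structure_disc"])
def test_gradient_reaches_nearly_all_parameters(build):
    """Dead-network guard: a scalar loss must touch >= 99% of parameters."""
    net = build()
    out = net(rand_input(32, 32, seed=15))
    if isinstance(out, tuple):
        loss = out[0].mean() + out[1].mean()
    else:
        loss = out.mean()
    loss.backward()
    params = net.parameters()
    alive = sum(1 for p in params
                if p.grad is not None and np.any(p.grad != 0))
    assert alive / len(params) >= 0.99


def test_image_tensor_roundtrip():
    img = np.random.default_rng(16).uniform(0, 1, (20, 24, 3))
    back = tensor_to_image(image_to_tensor(img))
    np.testing.assert_allclose(back, img, atol=1e-6)
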