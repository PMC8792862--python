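"""Architecture contracts: shapes, probability normalization, parameter
counts (including the full-scale figures), and encoder variants."""

import numpy as np
import pytest

from ushapegan import (DiscriminatorSpec, GeneratorSpec, build_discriminator,
                       build_generator, count_parameters)
from ushapegan.networks import load_model, save_model


class TestGenerator:
    def test_output_shape_and_range(self):
        gen = build_generator(GeneratorSpec.desk(64), seed=0)
        z = np.random.default_rng(0).standard_normal((2, 100))
        out = gen(z, train=False)
        assert out.shape == (2, 1, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deterministic_in_eval_mode(self):
        gen = build_generator(GeneratorSpec.desk(32), seed=1)
        z = np.random.default_rng(3).standard_normal((2, 100))
        np.testing.assert_array_equal(gen(z, train=False), gen(z, train=False))

    def test_inconsistent_schedule_rejected(self):
        with pytest.raises(ValueError, match="channel_schedule"):
            GeneratorSpec(base_resolution=4, output_resolution=64,
                          channel_schedule=(64, 32, 16, 8))
        with pytest.raises(ValueError):
            GeneratorSpec(base_resolution=4, output_resolution=48,
                          channel_schedule=(64, 32))

    def test_full_scale_parameter_count_matches_published_figure(self):
        """Pointwise-reduced generator at 1,024² holds 1.35e7 parameters."""
        gen = build_generator(GeneratorSpec.full_scale(True))
        n = count_parameters(gen)
        assert round(n / 1e7, 2) == 1.35

    def test_pointwise_reduction_shrinks_parameters_fivefold(self):
        """Same schedule without the 1x1 reductions: >= 5x more parameters.
        The saving compounds with depth, so test at three blocks (256²) —
        cheap to build, already past the 5x mark."""
        kw = dict(base_resolution=4, output_resolution=256,
                  channel_schedule=(256, 128, 64, 32))
        on = build_generator(GeneratorSpec(**kw, pointwise_reduction=True))
        off = build_generator(GeneratorSpec(**kw, pointwise_reduction=False))
        assert count_parameters(on) <= count_parameters(off) / 5


class TestDiscriminator:
    def test_prob_map_contract(self):
        disc = build_discriminator(DiscriminatorSpec.desk(), seed=0)
        x = np.random.default_rng(0).uniform(0, 1, (2, 32, 32))
        probs = disc(x, train=False)
        assert probs.shape == (2, 3, 32, 32)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert probs.min() >= 0.0

    @pytest.mark.parametrize("res", [32, 64])
    def test_shape_equivariance(self, res):
        disc = build_discriminator(DiscriminatorSpec.desk(), seed=0)
        x = np.zeros((1, res, res))
        assert disc(x, train=False).shape == (1, 3, res, res)

    def test_all_zero_input_is_finite(self):
        disc = build_discriminator(DiscriminatorSpec.desk(), seed=0)
        probs = disc(np.zeros((1, 32, 32)), train=False)
        assert np.isfinite(probs).all()

    def test_incompatible_resolution_rejected(self):
        disc = build_discriminator(DiscriminatorSpec.desk(), seed=0)
        with pytest.raises(ValueError, match="stride"):
            disc(np.zeros((1, 40, 40)), train=False)

    def test_skip_connections_add_parameters(self):
        on = build_discriminator(DiscriminatorSpec.desk(), seed=0)
        spec = DiscriminatorSpec.desk()
        spec.skip_connections = False
        off = build_discriminator(spec, seed=0)
        assert count_parameters(on) > count_parameters(off)

    def test_resnet50_random_encoder_forward(self):
        """The ResNet-50-layout encoder needs no external weights."""
        spec = DiscriminatorSpec(encoder="resnet50-random",
                                 decoder_channel_schedule=(32, 24, 16, 12, 8))
        disc = build_discriminator(spec, seed=0)
        probs = disc(np.random.default_rng(1).uniform(0, 1, (1, 64, 64)),
                     train=False)
        assert probs.shape == (1, 3, 64, 64)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_pretrained_without_weight_file_is_rejected(self):
        spec = DiscriminatorSpec(encoder="resnet50-pretrained",
                                 decoder_channel_schedule=(32, 24, 16, 12, 8))
        with pytest.raises(ValueError, match="pretrained_weights"):
            build_discriminator(spec)


def test_checkpoint_archive_is_self_describing(tmp_path):
    gen = build_generator(GeneratorSpec.desk(32), seed=2)
    disc = build_discriminator(DiscriminatorSpec.desk(), seed=3)
    path = tmp_path / "model.npz"
    save_model(path, gen, disc, extra={"epoch": 5})
    gen2, disc2, extra = load_model(path)
    assert extra == {"epoch": 5}
    assert gen2.spec == gen.spec and disc2.spec == disc.spec
    z = np.random.default_rng(0).standard_normal((1, 100))
    np.testing.assert_array_equal(gen(z, train=False), gen2(z, train=False))
    x = np.random.default_rng(1).uniform(0, 1, (1, 32, 32))
    np.testing.assert_array_equal(disc(x, train=False), disc2(x, train=False))
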