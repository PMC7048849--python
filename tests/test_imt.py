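"""Translation core: architecture contracts, loss arithmetic, training."""

import numpy as np
import pytest

from imtkit import imt, phantom
from imtkit.imt import (
    DiscriminatorSpec,
    GeneratorSpec,
    PairedSample,
    TrainConfig,
    UNetGenerator,
)
from imtkit.nn.autograd import Tensor
from imtkit.synthio import ImageSlice


@pytest.fixture(scope="module")
def tiny_pairs():
    cohort = phantom.make_cohort(seed=21, n_subjects=4, side=32)
    return [PairedSample(given=s.images["A"], target=s.images["B"])
            for s in cohort.subjects]


class TestGeneratorSpec:
    def test_default_filter_lists_are_mutually_consistent(self):
        spec = GeneratorSpec()
        assert spec.encoder_filters == (64, 128, 256, 512, 512, 512, 512, 512)
        assert spec.decoder_filters == spec.derived_decoder_filters()

    def test_inconsistent_decoder_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(decoder_filters=(512,) * 8)

    def test_scaled_spec_divides_filters(self):
        spec = GeneratorSpec.scaled(depth=4, divide=8)
        assert spec.encoder_filters == (8, 16, 32, 64)
        assert spec.min_side == 16

    def test_incompatible_side_names_minimum(self):
        with pytest.raises(ValueError, match="16"):
            UNetGenerator(GeneratorSpec.scaled(), side=12)


class TestGeneratorForward:
    def test_output_shape_matches_input(self):
        gen = imt.build_generator(GeneratorSpec.scaled(), side=32, seed=0)
        out = gen.translate_array(np.random.default_rng(0).uniform(-1, 1, (32, 32)))
        assert out.shape == (32, 32)

    def test_outputs_bounded_by_tanh(self, rng):
        gen = imt.build_generator(GeneratorSpec.scaled(), side=32, seed=1)
        for _ in range(3):
            out = gen.translate_array(rng.uniform(-1, 1, (32, 32)), seed=3)
            assert np.all(out >= -1) and np.all(out <= 1)

    def test_zero_parameters_give_constant_tanh_of_bias(self, rng):
        gen = imt.build_generator(GeneratorSpec.scaled(depth=2), side=16, seed=0)
        for p in gen.parameters():
            p.data = np.zeros_like(p.data)
        out = gen.translate_array(rng.uniform(-1, 1, (16, 16)), dropout_active=False)
        # all conv outputs are the (zero) bias; the head is tanh(0) = 0
        np.testing.assert_allclose(out, np.tanh(0.0), atol=1e-12)


class TestDiscriminator:
    def test_scores_strictly_inside_unit_interval(self, rng):
        disc = imt.build_discriminator(DiscriminatorSpec.scaled(), seed=0)
        x = Tensor(rng.uniform(-1, 1, (1, 1, 64, 64)))
        y = Tensor(rng.uniform(-1, 1, (1, 1, 64, 64)))
        s = disc.forward(x, y, train=True).data
        assert np.all(s > 0) and np.all(s < 1)

    def test_default_receptive_field_is_70(self):
        assert imt.receptive_field(DiscriminatorSpec()) == 70

    @pytest.mark.parametrize("strides,expected", [
        ((2, 2, 2, 1), 70),
        ((1, 1, 1, 1), 16),
        ((2, 2, 2, 2), 94),
    ])
    def test_gradient_support_matches_analytic_formula(self, strides, expected):
        spec = DiscriminatorSpec(filters=(4, 8, 8, 8), strides=strides)
        assert imt.receptive_field(spec) == expected
        side = 224 if expected == 94 else 128
        assert imt.receptive_field_probe(spec, side=side) == expected

    def test_shape_mismatch_rejected(self, rng):
        disc = imt.build_discriminator(DiscriminatorSpec.scaled(), seed=0)
        with pytest.raises(ValueError):
            disc.forward(Tensor(np.zeros((1, 1, 32, 32))),
                         Tensor(np.zeros((1, 1, 16, 16))), train=True)


class TestLosses:
    def test_uniform_scores_give_two_log_two(self):
        half = np.full((4, 4), 0.5)
        d_loss, _ = imt.loss_cgan(half, half)
        assert d_loss == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_perfect_discriminator_limit(self):
        d_loss, _ = imt.loss_cgan(np.full((4, 4), 1.0), np.full((4, 4), 0.0))
        assert d_loss < 1e-5

    def test_matches_elementwise_summation_oracle(self, rng):
        r = rng.uniform(0.05, 0.95, (6, 6))
        f = rng.uniform(0.05, 0.95, (6, 6))
        d_loss, g_adv = imt.loss_cgan(r, f)
        d_oracle = -sum(np.log(v) for v in r.ravel()) / r.size \
                   - sum(np.log(1 - v) for v in f.ravel()) / f.size
        g_oracle = -sum(np.log(v) for v in f.ravel()) / f.size
        assert d_loss == pytest.approx(d_oracle, abs=1e-6)
        assert g_adv == pytest.approx(g_oracle, abs=1e-6)

    def test_saturating_variant_sign(self, rng):
        f = rng.uniform(0.05, 0.95, (4, 4))
        _, g_sat = imt.loss_cgan(np.full((4, 4), 0.5), f, saturating=True)
        assert g_sat == pytest.approx(np.log(1 - f).mean(), abs=1e-9)

    def test_extreme_scores_are_clamped_finite(self):
        d_loss, g_adv = imt.loss_cgan(np.array([[0.0]]), np.array([[1.0]]))
        assert np.isfinite(d_loss) and np.isfinite(g_adv)

    def test_l1_identities(self, rng):
        a = ImageSlice(pixels=np.ones((4, 4)), normalized=True)
        b = ImageSlice(pixels=-np.ones((4, 4)), normalized=True)
        assert imt.loss_l1(a, a) == 0.0
        assert imt.loss_l1(a, b) == 2.0
        x, y = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        oracle = sum(abs(u - v) for u, v in zip(x.ravel(), y.ravel())) / 64
        assert imt.loss_l1(x, y) == pytest.approx(oracle, abs=1e-7)

    def test_total_objective_variants(self):
        cfg = TrainConfig(lambda_l1=100.0, loss_mode="cGAN+L1")
        assert imt.total_objective(0.7, 0.01, cfg) == pytest.approx(1.7)
        cfg_l1 = TrainConfig(loss_mode="L1")
        assert imt.total_objective(123.0, 0.5, cfg_l1) == 0.5
        cfg_zero = TrainConfig(lambda_l1=0.0, loss_mode="cGAN+L1")
        cfg_cgan = TrainConfig(loss_mode="cGAN")
        assert imt.total_objective(0.7, 9.9, cfg_zero) == imt.total_objective(
            0.7, 1.1, cfg_cgan)

    def test_invalid_loss_mode_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(loss_mode="L2")


class TestTraining:
    def test_zero_epochs_returns_untrained_with_empty_history(self, tiny_pairs):
        t = imt.train(tiny_pairs, TrainConfig(loss_mode="L1", epochs=0, seed=0),
                      gen_spec=GeneratorSpec.scaled())
        assert t.history == {"g_loss": [], "d_loss": [], "l1": []}
        out = imt.translate(t, tiny_pairs[0].given)
        assert out.pixels.shape == (32, 32)

    def test_same_seed_reproduces_history(self, tiny_pairs):
        runs = [
            imt.train(tiny_pairs, TrainConfig(loss_mode="cGAN+L1", epochs=2, seed=5),
                      gen_spec=GeneratorSpec.scaled(),
                      disc_spec=DiscriminatorSpec.scaled())
            for _ in range(2)
        ]
        assert runs[0].history == runs[1].history

    def test_l1_mode_never_builds_a_discriminator(self, tiny_pairs):
        t = imt.train(tiny_pairs, TrainConfig(loss_mode="L1", epochs=1, seed=0),
                      gen_spec=GeneratorSpec.scaled())
        assert t.discriminator is None
        assert t.history["d_loss"] == [0.0]

    def test_l1_component_decreases_on_identity_task(self):
        cohort = phantom.make_cohort(seed=22, n_subjects=6, side=32)
        pairs = [PairedSample(given=s.images["A"], target=s.images["A"])
                 for s in cohort.subjects]
        t = imt.train(pairs, TrainConfig(loss_mode="L1", epochs=10, seed=0),
                      gen_spec=GeneratorSpec.scaled())
        assert t.history["l1"][-1] < t.history["l1"][0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            imt.train([], TrainConfig(epochs=1))

    def test_unnormalized_pairs_rejected(self, rng):
        raw = ImageSlice(pixels=rng.uniform(0, 255, (32, 32)))
        with pytest.raises(ValueError):
            imt.train([PairedSample(given=raw, target=raw)],
                      TrainConfig(loss_mode="L1", epochs=1),
                      gen_spec=GeneratorSpec.scaled())


class TestTranslateAndCheckpoints:
    def test_translate_deterministic_given_seed(self, tiny_pairs):
        t = imt.train(tiny_pairs, TrainConfig(loss_mode="L1", epochs=1, seed=0),
                      gen_spec=GeneratorSpec.scaled())
        a = imt.translate(t, tiny_pairs[0].given, seed=9)
        b = imt.translate(t, tiny_pairs[0].given, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = imt.translate(t, tiny_pairs[0].given, seed=10)
        assert not np.array_equal(a.pixels, c.pixels)  # dropout is live noise

    def test_translate_output_range_and_shape_checks(self, tiny_pairs, rng):
        t = imt.train(tiny_pairs, TrainConfig(loss_mode="L1", epochs=1, seed=0),
                      gen_spec=GeneratorSpec.scaled())
        out = imt.translate(t, tiny_pairs[0].given)
        assert out.normalized and np.all(np.abs(out.pixels) <= 1.0)
        with pytest.raises(ValueError):
            imt.translate(t, ImageSlice(pixels=rng.uniform(-1, 1, (16, 16)),
                                        normalized=True))

    def test_checkpoint_round_trip(self, tiny_pairs, tmp_path):
        t = imt.train(tiny_pairs, TrainConfig(loss_mode="cGAN+L1", epochs=1, seed=0),
                      gen_spec=GeneratorSpec.scaled(),
                      disc_spec=DiscriminatorSpec.scaled())
        path = tmp_path / "ckpt.npz"
        t.save(path)
        back = imt.TrainedTranslator.load(path)
        assert back.history == t.history
        a = imt.translate(t, tiny_pairs[0].given, seed=0)
        b = imt.translate(back, tiny_pairs[0].given, seed=0)
        np.testing.assert_array_equal(a.pixels, b.pixels)
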