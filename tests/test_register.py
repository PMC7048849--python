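"""Registration: warping, fusion, propagation, the demons backend."""

import numpy as np
import pytest

from imtkit import metrics, phantom, register
from imtkit.register import (
    AtlasSet,
    AtlasSubject,
    DeformationField,
    FixedSpace,
    FusionConfig,
)
from imtkit.synthio import ImageSlice, LabelMap


def identity_backend(moving, fixed, **opts):
    return DeformationField(disp=np.zeros(fixed.pixels.shape + (2,)))


register.register_backend("identity", identity_backend)


class TestWarp:
    def test_identity_field_preserves_pixels(self, rng):
        img = ImageSlice(pixels=rng.uniform(-1, 1, (16, 16)), normalized=True)
        phi = DeformationField(disp=np.zeros((16, 16, 2)))
        np.testing.assert_array_equal(register.warp_image(img, phi).pixels, img.pixels)

    def test_constant_shift_moves_impulse(self):
        px = -np.ones((16, 16))
        px[8, 8] = 1.0
        img = ImageSlice(pixels=px, normalized=True)
        phi = DeformationField(disp=np.broadcast_to([0.0, 2.0], (16, 16, 2)).copy())
        out = register.warp_image(img, phi)
        # backward warp: output(p) = moving(p + (0,2)), so the peak shifts left
        assert np.unravel_index(np.argmax(out.pixels), (16, 16)) == (8, 6)

    def test_label_warp_never_invents_classes(self, rng):
        lm = LabelMap(classes=rng.integers(0, 3, (24, 24)), class_names=("a", "b", "c"))
        phi = phantom.make_deformation(3, 24, 2.5)
        out = register.warp_image(lm, phi)
        assert set(np.unique(out.classes)) <= set(np.unique(lm.classes)) | {0}

    def test_shape_mismatch_rejected(self, rng):
        img = ImageSlice(pixels=rng.uniform(-1, 1, (8, 8)), normalized=True)
        with pytest.raises(ValueError):
            register.warp_image(img, DeformationField(disp=np.zeros((16, 16, 2))))


class TestFusion:
    def test_degenerate_weights_return_inputs_exactly(self, rng):
        a = DeformationField(disp=rng.normal(size=(8, 8, 2)))
        b = DeformationField(disp=rng.normal(size=(8, 8, 2)))
        np.testing.assert_array_equal(
            register.fuse_deformations(a, b, FusionConfig(w=0.0)).disp, a.disp)
        np.testing.assert_array_equal(
            register.fuse_deformations(a, b, FusionConfig(w=1.0)).disp, b.disp)

    def test_equal_fields_are_a_fixed_point(self, rng):
        a = DeformationField(disp=rng.normal(size=(8, 8, 2)))
        for w in (0.0, 0.3, 0.77, 1.0):
            fused = register.fuse_deformations(
                a, DeformationField(disp=a.disp.copy()), FusionConfig(w=w))
            np.testing.assert_allclose(fused.disp, a.disp, atol=1e-12)

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(w=1.2)


class TestBuiltinBackend:
    def test_self_registration_is_near_identity(self):
        c = phantom.make_cohort(seed=31, n_subjects=1, side=64)
        img = c.subjects[0].images["A"]
        phi = register.register_pair(img, img)
        assert phi.norms().mean() < 0.1

    def test_warping_raises_similarity_on_every_subject(self, small_cohort):
        subs = small_cohort.subjects[:3]
        fixed = subs[0].images["A"]
        for sub in subs[1:]:
            moving = sub.images["A"]
            phi = register.register_pair(moving, fixed)
            warped = register.warp_image(moving, phi)

            def ncc(a, b):
                a, b = a - a.mean(), b - b.mean()
                return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

            assert ncc(warped.pixels, fixed.pixels) > ncc(moving.pixels, fixed.pixels)

    def test_unknown_backend_rejected(self, small_cohort):
        img = small_cohort.subjects[0].images["A"]
        with pytest.raises(ValueError, match="unknown"):
            register.register_pair(img, img, backend="ants")

    def test_rotation_recovered(self):
        # a rotated copy of the same subject must register back
        c = phantom.make_cohort(seed=33, n_subjects=1, side=128,
                                profiles=phantom.low_contrast_profiles())
        s = c.subjects[0]
        rot = phantom.make_deformation(0, 128, 0.0, angle=30.0)
        fixed_img = register.warp_image(s.images["A"], rot)
        fixed_lab = register.warp_image(s.label, rot)
        pre = metrics.dice(s.label, fixed_lab, 1)
        phi = register.register_pair(s.images["A"], fixed_img)
        post = metrics.dice(register.warp_image(s.label, phi), fixed_lab, 1)
        assert post > pre


class TestPropagation:
    def _atlases(self, labels):
        img = ImageSlice(pixels=np.zeros((8, 8)), normalized=True)
        return AtlasSet(subjects=[
            AtlasSubject(given=img, other=img,
                         label=LabelMap(classes=lab, class_names=("bg", "fg")))
            for lab in labels])

    def _fixed(self):
        img = ImageSlice(pixels=np.zeros((8, 8)), normalized=True)
        return FixedSpace(given=img, translated=img)

    def test_single_atlas_identity_returns_its_label(self, rng):
        lab = rng.integers(0, 2, (8, 8))
        final, probs = register.propagate_and_average(
            self._atlases([lab]), self._fixed(), FusionConfig(backend="identity"))
        np.testing.assert_array_equal(final.classes, lab)
        assert set(np.unique(probs)) <= {0.0, 1.0}

    def test_unanimous_vote(self, rng):
        lab = rng.integers(0, 2, (8, 8))
        final, probs = register.propagate_and_average(
            self._atlases([lab] * 3), self._fixed(), FusionConfig(backend="identity"))
        np.testing.assert_array_equal(final.classes, lab)
        assert set(np.unique(probs)) <= {0.0, 1.0}

    def test_three_to_one_vote_gives_075(self):
        ones = np.ones((8, 8), dtype=int)
        zeros = np.zeros((8, 8), dtype=int)
        final, probs = register.propagate_and_average(
            self._atlases([ones, ones, ones, zeros]), self._fixed(),
            FusionConfig(backend="identity"))
        assert probs[1, 4, 4] == pytest.approx(0.75)
        assert final.classes[4, 4] == 1

    def test_probabilities_sum_to_one_everywhere(self, rng):
        labs = [rng.integers(0, 2, (8, 8)) for _ in range(3)]
        _, probs = register.propagate_and_average(
            self._atlases(labs), self._fixed(), FusionConfig(backend="identity"))
        np.testing.assert_allclose(probs.sum(axis=0), 1.0)

    def test_empty_atlas_set_rejected(self):
        with pytest.raises(ValueError):
            AtlasSet(subjects=[])


class TestSelectWeight:
    def test_pure_noise_translation_gets_low_weight(self):
        cohort = phantom.make_cohort(seed=41, n_subjects=4, side=64,
                                     profiles=phantom.low_contrast_profiles())
        noise_rng = np.random.default_rng(0)

        def noisy_translate(s):
            return ImageSlice(pixels=noise_rng.uniform(-1, 1, s.pixels.shape),
                              normalized=True)

        w = register.select_weight(cohort, FusionConfig(cv_folds=2), noisy_translate,
                                   given="A", other="B", target_class=1)
        assert w <= 0.1

    def test_returned_weight_on_grid(self):
        cohort = phantom.make_cohort(seed=42, n_subjects=3, side=64,
                                     profiles=phantom.low_contrast_profiles())
        # translated channel = copy of the given image (uninformative but valid)
        w = register.select_weight(cohort, FusionConfig(cv_folds=2), lambda s: s,
                                   given="A", other="B", target_class=1)
        assert 0.0 <= w <= 1.0
        assert any(abs(w - g) < 1e-9 for g in register.WEIGHT_GRID)
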