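"""Synthetic cohort generator: anatomy, rendering, deformations, landmarks."""

import numpy as np
import pytest

from imtkit import phantom
from imtkit.phantom import BG, CSF, GM, TUMOR, WM, ContrastProfile


class TestAnatomy:
    def test_deterministic_for_seed(self):
        a = phantom.make_anatomy(3, 64)
        b = phantom.make_anatomy(3, 64)
        np.testing.assert_array_equal(a.tissues, b.tissues)

    def test_tumor_flag(self):
        assert (phantom.make_anatomy(5, 64, with_tumor=False).tissues == TUMOR).sum() == 0
        assert (phantom.make_anatomy(5, 64, with_tumor=True).tissues == TUMOR).sum() > 0

    def test_all_tissues_present_across_many_seeds(self):
        # exhaustive class census over a large seed sweep
        for seed in range(1000):
            present = set(np.unique(phantom.make_anatomy(seed, 32).tissues))
            assert {BG, WM, GM, CSF} <= present, f"seed {seed} missing a tissue"

    def test_nesting_invariants(self):
        from scipy.ndimage import binary_dilation
        for seed in range(20):
            with_t = phantom.make_anatomy(seed, 96, with_tumor=True).tissues
            plain = phantom.make_anatomy(seed, 96, with_tumor=False).tissues
            # csf (ventricles) strictly inside the wm core: every pixel
            # bordering csf is wm or csf
            border = binary_dilation(plain == CSF) & (plain != CSF)
            assert set(np.unique(plain[border])) <= {WM}
            # wm strictly inside the gm ring (it never touches background)
            wm_border = binary_dilation(plain == WM) & (plain != WM)
            assert BG not in set(np.unique(plain[wm_border]))
            # tumor only overwrites wm/gm
            tumor = with_t == TUMOR
            assert tumor.sum() > 0
            assert set(np.unique(plain[tumor])) <= {WM, GM}

    def test_side_too_small_rejected(self):
        with pytest.raises(ValueError):
            phantom.make_anatomy(0, 16)


class TestRenderModality:
    def test_noiseless_rendering_is_piecewise_constant(self):
        a = phantom.make_anatomy(1, 64)
        p = ContrastProfile(means={"background": 0.0, "wm": 0.6, "gm": 0.4, "csf": 0.9},
                            noise_sd=0.0, bias_amp=0.0)
        img = phantom.render_modality(a, p, seed=0)
        unit = (img.pixels + 1) / 2
        for tissue, mean in ((WM, 0.6), (GM, 0.4), (CSF, 0.9)):
            vals = unit[a.tissues == tissue]
            assert vals.std() < 1e-12
            assert vals[0] == pytest.approx(mean, abs=1e-12)

    def test_swapped_means_anticorrelate(self):
        a = phantom.make_anatomy(2, 64)
        p1 = ContrastProfile(means={"background": 0.0, "wm": 0.8, "gm": 0.4, "csf": 0.2},
                             noise_sd=0.0, bias_amp=0.0)
        p2 = ContrastProfile(means={"background": 0.0, "wm": 0.2, "gm": 0.4, "csf": 0.8},
                             noise_sd=0.0, bias_amp=0.0)
        i1 = phantom.render_modality(a, p1, seed=0).pixels
        i2 = phantom.render_modality(a, p2, seed=0).pixels
        both = (a.tissues == WM) | (a.tissues == CSF)
        r = np.corrcoef(i1[both], i2[both])[0, 1]
        assert r < -0.99

    def test_noise_sd_matches_model(self):
        # Monte-Carlo check of the additive-noise model at n >= 5000 pixels
        a = phantom.make_anatomy(3, 192)
        p = ContrastProfile(means={"background": 0.3, "wm": 0.6, "gm": 0.45, "csf": 0.9},
                            noise_sd=0.02, bias_amp=0.0)
        img = phantom.render_modality(a, p, seed=7)
        unit = (img.pixels + 1) / 2
        for tissue in (WM, GM):
            vals = unit[a.tissues == tissue]
            assert len(vals) >= 5000
            assert 0.015 <= vals.std() <= 0.025

    def test_missing_tissue_mean_rejected(self):
        a = phantom.make_anatomy(1, 64)
        with pytest.raises(ValueError, match="csf"):
            phantom.render_modality(
                a, ContrastProfile(means={"background": 0.0, "wm": 0.6, "gm": 0.4}), 0)

    def test_profile_mean_separation_enforced(self):
        with pytest.raises(ValueError):
            ContrastProfile(means={"wm": 0.50, "gm": 0.52})


class TestDeformation:
    def test_zero_bound_gives_identity_field(self):
        d = phantom.make_deformation(1, 32, 0.0)
        np.testing.assert_array_equal(d.disp, 0.0)

    def test_random_field_norm_bound(self):
        d = phantom.make_deformation(1, 64, 3.0)
        assert d.norms().max() <= 3.0 + 1e-9
        assert d.norms().max() > 1.0  # scaled up to the bound

    def test_rotation_fixed_point_at_center(self):
        d = phantom.make_deformation(0, 129, 0.0, angle=30.0)
        c = (129 - 1) // 2
        assert np.linalg.norm(d.disp[c, c]) < 1e-9

    def test_rotation_composed_with_inverse_is_identity(self):
        side = 128
        fwd = phantom.make_deformation(0, side, 0.0, angle=30.0)
        inv = phantom.make_deformation(0, side, 0.0, angle=-30.0)
        # compose: p -> p + inv(p) -> + fwd evaluated there (fields are exact,
        # evaluate analytically by interpolation)
        from scipy.ndimage import map_coordinates
        rr, cc = np.mgrid[0:side, 0:side].astype(float)
        qr, qc = rr + inv.disp[..., 0], cc + inv.disp[..., 1]
        fr = map_coordinates(fwd.disp[..., 0], [qr, qc], order=1)
        fc = map_coordinates(fwd.disp[..., 1], [qr, qc], order=1)
        total = np.stack([inv.disp[..., 0] + fr, inv.disp[..., 1] + fc], axis=-1)
        # evaluate only where the rotated position stays on the grid
        c = (side - 1) / 2.0
        radius = np.sqrt((rr - c) ** 2 + (cc - c) ** 2)
        norms = np.sqrt((total ** 2).sum(axis=-1))
        assert norms[radius <= side / 2 - 4].max() < 0.5


class TestCohort:
    def test_cardinality_and_shared_labels(self):
        c = phantom.make_cohort(seed=4, n_subjects=8, side=64)
        assert len(c) == 8
        for s in c.subjects:
            assert len(s.images) == 2
            shapes = {img.pixels.shape for img in s.images.values()}
            assert shapes == {(64, 64)}
            assert s.label.classes.shape == (64, 64)

    def test_landmark_L5_lies_in_csf(self, small_cohort):
        for s in small_cohort.subjects:
            x, y, _ = s.landmarks.points["L5"]
            assert s.anatomy.tissues[int(y), int(x)] == CSF

    def test_seven_landmarks_named_L1_to_L7(self, small_cohort):
        assert set(small_cohort.subjects[0].landmarks.points) == {
            f"L{i}" for i in range(1, 8)}

    def test_cross_modality_alignment(self):
        # noiseless renderings of one anatomy under two profiles induce the
        # same partition of the image into constant regions
        a = phantom.make_anatomy(6, 64)
        p1 = ContrastProfile(means={"background": 0.0, "wm": 0.7, "gm": 0.5, "csf": 0.9},
                             noise_sd=0.0, bias_amp=0.0)
        p2 = ContrastProfile(means={"background": 0.1, "wm": 0.3, "gm": 0.8, "csf": 0.2},
                             noise_sd=0.0, bias_amp=0.0)
        i1 = phantom.render_modality(a, p1, 0).pixels
        i2 = phantom.render_modality(a, p2, 0).pixels

        def partition(img):
            _, inv = np.unique(img.round(12), return_inverse=True)
            return inv.reshape(img.shape)

        part1, part2 = partition(i1), partition(i2)
        # same regions: boundary maps (where the label changes) coincide
        for axis in (0, 1):
            np.testing.assert_array_equal(np.diff(part1, axis=axis) != 0,
                                          np.diff(part2, axis=axis) != 0)

    def test_byte_identical_serialization(self, tmp_path):
        for sub in ("x", "y"):
            c = phantom.make_cohort(seed=9, n_subjects=2, side=48)
            phantom.save_cohort(c, tmp_path / sub)
        files_x = sorted((tmp_path / "x").rglob("*"))
        files_y = sorted((tmp_path / "y").rglob("*"))
        assert [f.name for f in files_x] == [f.name for f in files_y]
        for fx, fy in zip(files_x, files_y):
            if fx.is_file():
                assert fx.read_bytes() == fy.read_bytes(), fx.name

    def test_save_load_round_trip(self, tmp_path):
        c = phantom.make_cohort(seed=9, n_subjects=2, side=48, task="tumor",
                                profiles=phantom.faint_tumor_profiles())
        phantom.save_cohort(c, tmp_path / "c")
        back = phantom.load_cohort(tmp_path / "c")
        assert len(back) == 2
        np.testing.assert_array_equal(back.subjects[0].label.classes,
                                      c.subjects[0].label.classes)
        np.testing.assert_allclose(back.subjects[0].images["A"].pixels,
                                   c.subjects[0].images["A"].pixels, atol=1e-4)

    def test_linear_contrast_preset_is_affine(self):
        a, b = phantom.linear_contrast_profiles(slope=0.6, intercept=0.2)
        for k, v in a.means.items():
            assert b.means[k] == pytest.approx(0.6 * v + 0.2)
        assert b.noise_sd == 0.0 and b.bias_amp == 0.0

    def test_invalid_subject_count(self):
        with pytest.raises(ValueError):
            phantom.make_cohort(seed=0, n_subjects=0, side=64)
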