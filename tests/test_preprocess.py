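"""Standardization chain: slice selection, centring, normalizations, mask."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from datspect import phantom, preprocess, roi_quant
from datspect.types import FeatureLabelSet, SpectVolume


class TestSelectSummedSlice:
    def test_peak_slice_window(self, normal_clean_subject, clean_params):
        """The striatal axial profile peaks at the central slice; the summed
        image is the sum of that slice and its two neighbours."""
        vol = normal_clean_subject.volume
        summed, idx = preprocess.select_summed_slice(vol)
        z0 = clean_params.n_slices // 2
        assert idx == z0
        np.testing.assert_allclose(
            summed, vol.counts[z0 - 1] + vol.counts[z0] + vol.counts[z0 + 1])

    def test_independent_argmax_oracle(self, normal_clean_subject, clean_params):
        """Chosen index equals an argmax of per-slice striatal sums computed
        directly from the generating masks."""
        vol = normal_clean_subject.volume
        cau, put = phantom.striatum_masks(clean_params, "left", grow=2)
        cau2, put2 = phantom.striatum_masks(clean_params, "right", grow=2)
        striatal = cau | put | cau2 | put2
        sums = [sl[striatal].sum() for sl in vol.counts]
        _, idx = preprocess.select_summed_slice(vol)
        assert idx == int(np.argmax(sums))

    def test_constant_volume_tie_break(self):
        vol = SpectVolume(np.full((7, 16, 16), 5.0))
        summed, idx = preprocess.select_summed_slice(vol)
        assert idx == 1  # lowest qualifying index, clamped into range
        np.testing.assert_allclose(summed, 15.0)

    def test_scale_invariance_of_choice(self, small_cohort):
        vol = small_cohort[0].volume
        _, i1 = preprocess.select_summed_slice(vol)
        _, i2 = preprocess.select_summed_slice(SpectVolume(vol.counts * 7.5))
        assert i1 == i2

    def test_errors(self):
        with pytest.raises(ValueError, match="3 slices"):
            preprocess.select_summed_slice(SpectVolume(np.ones((2, 8, 8))))
        with pytest.raises(ValueError, match="no counts"):
            preprocess.select_summed_slice(SpectVolume(np.zeros((5, 8, 8))))


class TestTrimAndCenter:
    def test_striatal_centroid_near_frame_centre(self, normal_clean_subject):
        summed, _ = preprocess.select_summed_slice(normal_clean_subject.volume)
        frame, prov = preprocess.trim_and_center(summed)
        assert frame.shape == (70, 70)
        # recompute the striatal centroid inside the frame and compare with
        # the frame centre
        hot = frame >= 0.5 * frame.max()
        r, c = ndimage.center_of_mass(np.where(hot, frame, 0.0))
        assert abs(r - 34.5) <= 1.0 and abs(c - 34.5) <= 1.0

    def test_translation_invariance(self, normal_clean_subject):
        summed, _ = preprocess.select_summed_slice(normal_clean_subject.volume)
        shifted = np.roll(summed, (4, -5), axis=(0, 1))
        f0, _ = preprocess.trim_and_center(summed)
        f1, _ = preprocess.trim_and_center(shifted)
        # identical up to interpolation/rounding at the crop boundary
        assert np.abs(f0 - f1).max() <= 1e-6 * max(f0.max(), 1.0) + 1e-9 or \
            np.abs(f0 - f1).mean() < 0.01 * f0.mean()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess.trim_and_center(np.zeros((64, 64)))


class TestNormalizeMax:
    def test_max_is_one_and_scale_invariant(self, small_cohort_images):
        frame, _ = small_cohort_images["frames"][0]
        a = preprocess.normalize_max(frame)
        b = preprocess.normalize_max(frame * 3.7)
        assert a.pixels.max() == 1.0
        np.testing.assert_allclose(a.pixels, b.pixels)

    def test_identity_when_already_normalized(self):
        frame = np.zeros((70, 70))
        frame[30:40, 30:40] = 1.0
        out = preprocess.normalize_max(frame)
        np.testing.assert_array_equal(out.pixels, frame)

    def test_zero_frame_rejected(self):
        with pytest.raises(ValueError):
            preprocess.normalize_max(np.zeros((70, 70)))


class TestNormalizeBackground:
    def test_background_mean_exact(self, small_cohort_images):
        mask = small_cohort_images["mask"]
        for img in small_cohort_images["background"][:10]:
            region = (img.pixels > 0) & ~ndimage.binary_dilation(mask.mask)
            assert img.pixels[region].mean() == pytest.approx(0.15, abs=1e-9)

    def test_idempotent(self, small_cohort_images):
        mask = small_cohort_images["mask"]
        frame, _ = small_cohort_images["frames"][0]
        once = preprocess.normalize_background(frame, mask)
        twice = preprocess.normalize_background(once.pixels, mask)
        np.testing.assert_allclose(once.pixels, twice.pixels, rtol=1e-12)

    def test_known_scaling(self, small_cohort_images):
        """A frame whose background mean is 0.30 is scaled by exactly 0.5."""
        mask = small_cohort_images["mask"]
        frame, _ = small_cohort_images["frames"][0]
        out0 = preprocess.normalize_background(frame, mask)
        doubled = preprocess.normalize_background(out0.pixels * 2.0, mask)
        np.testing.assert_allclose(doubled.pixels, out0.pixels, rtol=1e-12)

    def test_striatal_mean_matches_contrast(self, clean_params, small_cohort_images):
        """Noiseless phantom at contrast 5: after background normalization the
        striatal specific mean is (5-1) x 0.15 above nothing, i.e. the caudate
        core sits at 5 x 0.15 = 0.75."""
        rec = phantom.generate_subject(clean_params, FeatureLabelSet(), 70, seed=4)
        frame, _ = preprocess.preprocess_volume(rec.volume)
        img = preprocess.normalize_background(frame, small_cohort_images["mask"])
        tpl = roi_quant.default_template(clean_params)
        fitted, _ = roi_quant.fit_template(img, tpl)
        cau = img.pixels[fitted.caudate_mask("left")].mean()
        # background region of this subject's own frame
        bg = img.pixels[fitted.background_mask(img.pixels)].mean()
        assert cau / bg == pytest.approx(clean_params.uptake_contrast_high, rel=0.01)


class TestGroupMask:
    def test_flat_images_degenerate(self):
        flat = [np.ones((10, 10)), np.ones((10, 10))]
        mask = preprocess.build_group_striatal_mask(flat)
        assert mask.mask.all()

    def test_cutoff_one_keeps_only_argmax(self):
        img = np.zeros((10, 10))
        img[4, 4] = 1.0
        img[2, 2] = 0.5
        mask = preprocess.build_group_striatal_mask([img, img], cutoff=1.0)
        assert mask.mask.sum() == 1 and mask.mask[4, 4]

    def test_dice_overlap_with_truth(self, small_cohort_images, default_params):
        """Group mask recovers the generating striatal footprint (Dice >= 0.7
        at default noise)."""
        mask = preprocess.build_group_striatal_mask(
            preprocess.augment_flip(small_cohort_images["max"]))
        tpl = roi_quant.default_template(default_params, margin=0.0)
        true = tpl.striatal_mask("left") | tpl.striatal_mask("right")
        inter = (mask.mask & true).sum()
        dice = 2 * inter / (mask.mask.sum() + true.sum())
        assert dice >= 0.7

    def test_symmetric_when_built_from_augmented_set(self, small_cohort_images):
        mask = preprocess.build_group_striatal_mask(
            preprocess.augment_flip(small_cohort_images["max"]))
        np.testing.assert_array_equal(mask.mask, mask.mask[:, ::-1])

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            preprocess.build_group_striatal_mask([np.ones((5, 5))])


class TestAugmentFlip:
    def test_doubles_and_preserves_labels(self, small_cohort_images):
        imgs = small_cohort_images["max"][:5]
        out, labels = preprocess.augment_flip(imgs, [1, 0, 1, 0, 1])
        assert len(out) == 10 and labels == [1, 0, 1, 0, 1, 1, 0, 1, 0, 1]

    def test_involution(self, small_cohort_images):
        img = small_cohort_images["max"][0]
        np.testing.assert_array_equal(img.flipped().flipped().pixels, img.pixels)

    def test_symmetric_image_fixed_point(self):
        img = preprocess.normalize_max(np.ones((6, 6)))
        np.testing.assert_array_equal(img.flipped().pixels, img.pixels)


class TestMirrorEndToEnd:
    def test_mirrored_volume_gives_mirrored_frame(self, normal_clean_subject):
        """Preprocessing a horizontally mirrored volume yields the mirror of
        the original standardized frame (within interpolation tolerance)."""
        vol = normal_clean_subject.volume
        mirrored = SpectVolume(vol.counts[:, :, ::-1].copy())
        f0, _ = preprocess.preprocess_volume(vol)
        f1, _ = preprocess.preprocess_volume(mirrored)
        assert np.abs(f0 - f1[:, ::-1]).max() <= 1e-6 * f0.max()
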