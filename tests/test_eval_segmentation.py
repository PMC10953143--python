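"""Tissue segmentation stand-in, binarisation, volumes, AVD/VD/Dice."""

import numpy as np
import pytest

from decontrast import eval_segmentation as es
from decontrast.phantom import PhantomParams, make_phantom
from decontrast.types import TISSUES, TissueMaps, Volume3D


def truth_labels(sample):
    stack = sample.tissue_truth.stack()
    return np.argmax(stack, axis=0), stack.sum(axis=0) > 0


class TestSegmenter:
    def test_noise_free_phantom_recovered_exactly(self, clean_sample):
        maps = es.segment_tissues_simple(clean_sample.t1nce, clean_sample.brain_mask)
        got = es.binarize_maxprob(maps)
        want = clean_sample.tissue_truth.probabilities
        for t in TISSUES:
            m = clean_sample.brain_mask
            np.testing.assert_array_equal(got[t][m], want[t][m] > 0)

    def test_noisy_phantom_above_95_percent_agreement(self):
        s = make_phantom(PhantomParams(noise_sigma=0.02, seed=11))
        maps = es.segment_tissues_simple(s.t1nce, s.brain_mask)
        got = es.binarize_maxprob(maps)
        lab, _ = truth_labels(s)
        pred = np.argmax(maps.stack(), axis=0)
        agree = (pred == lab)[s.brain_mask].mean()
        assert agree > 0.95

    def test_permuted_initialisation_same_labelling(self, default_sample):
        a = es.segment_tissues_simple(default_sample.t1nce, default_sample.brain_mask,
                                      init_quantiles=(15, 55, 85))
        b = es.segment_tissues_simple(default_sample.t1nce, default_sample.brain_mask,
                                      init_quantiles=(85, 15, 55))
        for t in TISSUES:
            np.testing.assert_allclose(a.probabilities[t], b.probabilities[t],
                                       atol=1e-8)

    def test_two_mode_image_flagged_degenerate(self):
        vals = np.where(np.arange(12 ** 3).reshape(12, 12, 12) % 2 == 0, 0.2, 0.8)
        maps = es.segment_tissues_simple(Volume3D(vals.astype(float)),
                                         np.ones((12, 12, 12), bool))
        assert maps.degenerate

    def test_well_separated_fit_not_flagged(self, default_sample):
        maps = es.segment_tissues_simple(default_sample.t1nce, default_sample.brain_mask)
        assert not maps.degenerate

    def test_empty_mask_raises(self, random_volume):
        with pytest.raises(ValueError):
            es.segment_tissues_simple(random_volume,
                                      np.zeros(random_volume.shape, bool))


class TestBinarize:
    def make_maps(self, gm, wm, csf):
        shape = np.asarray(gm).shape
        return TissueMaps({"GM": np.asarray(gm, float),
                           "WM": np.asarray(wm, float),
                           "CSF": np.asarray(csf, float)}, voxel_size_mm=1.0)

    def test_argmax_assignment(self):
        maps = self.make_maps(np.full((1, 1, 1), 0.6), np.full((1, 1, 1), 0.3),
                              np.full((1, 1, 1), 0.1))
        out = es.binarize_maxprob(maps)
        assert out["GM"][0, 0, 0] and not out["WM"][0, 0, 0]

    def test_tie_broken_by_fixed_tissue_order(self):
        maps = self.make_maps(np.full((1, 1, 1), 0.4), np.full((1, 1, 1), 0.4),
                              np.full((1, 1, 1), 0.2))
        out = es.binarize_maxprob(maps)
        assert out["GM"][0, 0, 0] and not out["WM"][0, 0, 0]

    def test_masks_disjoint_and_cover_tissue_voxels(self, default_sample):
        maps = default_sample.tissue_truth
        out = es.binarize_maxprob(maps)
        total = sum(out[t].astype(int) for t in TISSUES)
        assert total.max() <= 1
        any_tissue = maps.stack().sum(axis=0) > 0
        np.testing.assert_array_equal(total > 0, any_tissue)


class TestVolumesAndDifferences:
    def test_voxel_count_arithmetic(self):
        mask = np.zeros((20, 20, 20), bool)
        mask.ravel()[:1000] = True
        assert es.tissue_volume(mask, 1.0) == pytest.approx(1.0)
        assert es.tissue_volume(np.zeros((4, 4, 4), bool), 1.0) == 0.0
        assert es.tissue_volume(mask, 2.0) == pytest.approx(8.0)

    def test_tiv_is_sum_of_tissue_volumes(self, default_sample):
        tv = es.tissue_volumes(default_sample.tissue_truth)
        assert tv.tiv == pytest.approx(sum(tv.volumes_cm3.values()), abs=1e-9)

    def test_avd_normalisation_cancels_at_reference_tiv(self):
        assert es.avd(500.0, 480.0, 1400.0, 1400.0) == pytest.approx(20.0)

    def test_vd_sign_and_rescaled_example(self):
        assert es.vd(480.0, 500.0, 1400.0, 1400.0) < 0.0
        assert es.vd(500.0, 480.0, 1400.0, 1450.0) == pytest.approx(20 / 1400 * 1450)

    def test_avd_identities_on_random_tuples(self, rng):
        for _ in range(1000):
            v_i, v_j = rng.uniform(10, 1000, 2)
            tiv_i = rng.uniform(500, 2000)
            tiv_bar = rng.uniform(500, 2000)
            a = es.avd(v_i, v_j, tiv_i, tiv_bar)
            assert a == pytest.approx(abs(es.vd(v_i, v_j, tiv_i, tiv_bar)))
            c = rng.uniform(0.1, 3.0)
            assert es.avd(v_i, v_j, tiv_i, c * tiv_bar) == pytest.approx(c * a)

    def test_avd_requires_positive_reference_tiv(self):
        with pytest.raises(ValueError):
            es.avd(1.0, 2.0, 0.0, 1000.0)


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        a = rng.random((6, 6, 6)) > 0.5
        assert es.dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        assert es.dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert es.dice(a, b) == pytest.approx(0.5)

    def test_brute_force_oracle(self, rng):
        a = rng.random((8, 8, 8)) > 0.5
        b = rng.random((8, 8, 8)) > 0.5
        inter = sum(1 for i, j, k in np.ndindex(8, 8, 8) if a[i, j, k] and b[i, j, k])
        assert es.dice(a, b) == pytest.approx(2 * inter / (a.sum() + b.sum()))

    def test_both_empty_raise(self):
        with pytest.raises(ValueError):
            es.dice(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool))


class TestResampleBack:
    def test_back_to_segmentation_grid(self):
        v = Volume3D(np.random.default_rng(0).random((16, 16, 16)))
        out = es.resample_back(v, (21, 26, 22))
        assert out.shape == (21, 26, 22)

    def test_constant_round_trip(self):
        v = Volume3D(np.full((12, 12, 12), 0.3))
        out = es.resample_back(es.resample_back(v, (8, 8, 8)), (12, 12, 12))
        np.testing.assert_allclose(out.values, 0.3, atol=1e-9)


def test_compare_segmentations_self_comparison_is_exact(default_sample):
    maps = default_sample.tissue_truth
    tiv = es.tissue_volumes(maps).tiv
    comp = es.compare_segmentations(maps, maps, tiv_bar=tiv)
    for t in TISSUES:
        assert comp.avd_cm3[t] == 0.0
        assert comp.vd_cm3[t] == 0.0
        assert comp.dice[t] == 1.0
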