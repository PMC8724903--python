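"""Per-modality tumor-volume and hot-spot segmentation methods."""

import numpy as np
import pytest

from gbmpar import (BinaryMask, VolumeImage, contralateral_stats, flab_seg,
                    hotspot_seg, percent_max_seg, ratio_seg,
                    stat_threshold_seg, suv_map)
from gbmpar.segmentation import ContralateralStats


def dice(a, b):
    inter = (a & b).sum()
    return 2 * inter / (a.sum() + b.sum())


class TestContralateralStats:
    def test_constant_map(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        stats = contralateral_stats(make_map(np.full(shape, 5.0)),
                                    make_mask(np.ones(shape, bool)))
        assert stats.mean == 5.0
        assert stats.sd == 0.0

    def test_hand_arithmetic(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        vals = np.zeros(shape)
        vals[0, 0, :3] = [1.0, 2.0, 3.0]
        sel = np.zeros(shape, bool)
        sel[0, 0, :3] = True
        stats = contralateral_stats(make_map(vals), make_mask(sel))
        assert stats.mean == pytest.approx(2.0)
        assert stats.sd == pytest.approx(1.0)  # sample SD, ddof=1
        assert stats.n_voxels == 3

    def test_monte_carlo_recovery(self, rng):
        vals = rng.normal(1.5, 0.2, size=(40, 40, 25))
        img = VolumeImage(vals, spacing=(1, 1, 1))
        mask = BinaryMask(np.ones(vals.shape, bool), spacing=(1, 1, 1))
        stats = contralateral_stats(img, mask)
        n = vals.size
        assert abs(stats.mean - 1.5) <= 3 * 0.2 / np.sqrt(n)
        assert abs(stats.sd - 0.2) <= 3 * 0.2 / np.sqrt(2 * n)

    def test_empty_mask_errors(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        with pytest.raises(ValueError):
            contralateral_stats(make_map(), make_mask())


class TestStatThreshold:
    def test_map_at_mean_gives_empty_mask(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        stats = ContralateralStats(mean=2.0, sd=0.5, n_voxels=100)
        res = stat_threshold_seg(make_map(np.full(shape, 2.0)), stats, k=1.96)
        assert res.mask.count == 0
        assert res.threshold_value == pytest.approx(2.0 + 1.96 * 0.5)

    def test_restrict_mask_intersected(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        stats = ContralateralStats(mean=0.0, sd=1.0, n_voxels=100)
        sel = np.zeros(shape, bool)
        sel[:2] = True
        res = stat_threshold_seg(make_map(np.full(shape, 10.0)), stats,
                                 k=1.96, restrict=make_mask(sel))
        assert np.array_equal(res.mask.voxels, sel)

    def test_mask_reproducible_from_recorded_threshold(self, rng):
        vals = rng.normal(1.0, 0.3, (20, 20, 10))
        img = VolumeImage(vals, spacing=(1, 1, 1))
        stats = ContralateralStats(mean=1.0, sd=0.3, n_voxels=100)
        res = stat_threshold_seg(img, stats, k=1.96)
        assert np.array_equal(res.mask.voxels, vals > res.threshold_value)

    def test_monotone_in_k(self, rng):
        vals = rng.normal(1.0, 0.3, (20, 20, 10))
        img = VolumeImage(vals, spacing=(1, 1, 1))
        stats = ContralateralStats(mean=1.0, sd=0.3, n_voxels=100)
        counts = [stat_threshold_seg(img, stats, k=k).mask.count
                  for k in (1.0, 1.96, 3.3)]
        assert counts == sorted(counts, reverse=True)

    def test_nan_voxels_never_selected(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        vals = np.full(shape, 10.0)
        vals[0, 0, 0] = np.nan
        stats = ContralateralStats(mean=0.0, sd=1.0, n_voxels=100)
        res = stat_threshold_seg(make_map(vals), stats, k=1.0)
        assert not res.mask.voxels[0, 0, 0]


class TestPercentMax:
    def test_threshold_is_fraction_of_max(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        vals = np.zeros(shape)
        vals[0, 0, 0] = 10.0
        res = percent_max_seg(make_map(vals), 0.4,
                              make_mask(np.ones(shape, bool)))
        assert res.threshold_value == pytest.approx(4.0)

    def test_constant_map_selects_whole_search_region(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        res = percent_max_seg(make_map(np.full(shape, 3.0)), 0.4,
                              make_mask(np.ones(shape, bool)))
        assert res.mask.count == np.prod(shape)

    def test_enumeration_1_to_100(self):
        vals = np.arange(1, 101, dtype=float).reshape(10, 5, 2)
        img = VolumeImage(vals, spacing=(1, 1, 1))
        search = BinaryMask(np.ones(vals.shape, bool), spacing=(1, 1, 1))
        res = percent_max_seg(img, 0.4, search)
        assert res.mask.count == 61  # values 40..100 inclusive
        assert vals[res.mask.voxels].min() == 40.0

    def test_empty_search_errors(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        with pytest.raises(ValueError, match="empty"):
            percent_max_seg(make_map(), 0.4, make_mask())


class TestRatio:
    def test_tissue_to_blood_example(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        vals = np.zeros(shape)
        vals[0, 0, 0] = 2.3
        vals[0, 0, 1] = 2.5
        res = ratio_seg(make_map(vals), reference_value=2.0, factor=1.2)
        assert res.threshold_value == pytest.approx(2.4)
        assert not res.mask.voxels[0, 0, 0]
        assert res.mask.voxels[0, 0, 1]

    def test_agrees_with_stat_threshold_absolute_oracle(self, rng):
        # ratio with threshold T == stat threshold with mean=T, sd-free rule
        for _ in range(50):
            vals = rng.random((10, 10, 5)) * 4
            img = VolumeImage(vals, spacing=(1, 1, 1))
            ref, factor = rng.uniform(0.5, 2), rng.uniform(1.0, 3.0)
            res = ratio_seg(img, ref, factor)
            assert np.array_equal(res.mask.voxels, vals > factor * ref)

    def test_separable_rcbv_phantom(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        vals = np.ones(shape)
        tumor = np.zeros(shape, bool)
        tumor[4:8] = True
        vals[tumor] = 3.0
        res = ratio_seg(make_map(vals), reference_value=1.0, factor=2.0)
        assert np.array_equal(res.mask.voxels, tumor)

    def test_nonpositive_reference_errors(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        with pytest.raises(ValueError):
            ratio_seg(make_map(), 0.0, 1.2)


class TestFlab:
    def _two_class(self, rng, shape=(30, 30, 12), frac=0.1,
                   lo=(1.0, 0.1), hi=(3.0, 0.2)):
        vals = rng.normal(*lo, size=shape)
        truth = np.zeros(shape, bool)
        cube = int(np.ceil((frac * np.prod(shape)) ** (1 / 3)))
        truth[5:5 + cube, 5:5 + cube, 2:2 + cube] = True
        vals[truth] = rng.normal(*hi, size=truth.sum())
        return VolumeImage(vals, spacing=(1, 1, 1)), truth

    def test_two_class_recovery(self, rng):
        img, truth = self._two_class(rng)
        roi = BinaryMask(np.ones(img.shape, bool), spacing=(1, 1, 1))
        res = flab_seg(img, 2, roi)
        assert dice(res.mask.voxels, truth) >= 0.95

    def test_three_class_recovers_highest(self, rng):
        shape = (30, 30, 12)
        vals = rng.normal(1.0, 0.15, shape)
        mid = np.zeros(shape, bool)
        mid[4:16, 4:16, 2:10] = True
        top = np.zeros(shape, bool)
        top[7:13, 7:13, 4:8] = True
        mid &= ~top
        vals[mid] = rng.normal(2.0, 0.15, mid.sum())
        vals[top] = rng.normal(4.0, 0.15, top.sum())
        img = VolumeImage(vals, spacing=(1, 1, 1))
        roi = BinaryMask(np.ones(shape, bool), spacing=(1, 1, 1))
        res = flab_seg(img, 3, roi)
        assert dice(res.mask.voxels, top) >= 0.90

    def test_constant_map_is_degenerate(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        with pytest.raises(ValueError, match="constant"):
            flab_seg(make_map(np.full(shape, 2.0)), 2,
                     make_mask(np.ones(shape, bool)))

    def test_deterministic_given_seed(self, rng):
        img, _ = self._two_class(rng)
        roi = BinaryMask(np.ones(img.shape, bool), spacing=(1, 1, 1))
        a = flab_seg(img, 2, roi, seed=4)
        b = flab_seg(img, 2, roi, seed=4)
        assert np.array_equal(a.mask.voxels, b.mask.voxels)

    def test_agreement_with_stat_threshold(self, rng):
        img, truth = self._two_class(rng)
        contra = BinaryMask(~truth, spacing=(1, 1, 1))
        stats = contralateral_stats(img, contra)
        roi = BinaryMask(np.ones(img.shape, bool), spacing=(1, 1, 1))
        stat = stat_threshold_seg(img, stats, k=3.3)
        flab = flab_seg(img, 2, roi)
        assert dice(stat.mask.voxels, flab.mask.voxels) >= 0.9


class TestHotspot:
    def test_percentile_1_to_100(self):
        vals = np.arange(1, 101, dtype=float).reshape(10, 5, 2)
        img = VolumeImage(vals, spacing=(1, 1, 1))
        flair = BinaryMask(np.ones(vals.shape, bool), spacing=(1, 1, 1))
        res = hotspot_seg(img, flair)
        assert res.threshold_value == pytest.approx(95.05)
        assert res.mask.count == 5
        assert vals[res.mask.voxels].min() == 96.0

    def test_thousand_distinct_values_top_fifty(self, rng):
        vals = rng.permutation(1000).astype(float).reshape(10, 10, 10)
        img = VolumeImage(vals, spacing=(1, 1, 1))
        flair = BinaryMask(np.ones((10, 10, 10), bool), spacing=(1, 1, 1))
        res = hotspot_seg(img, flair)
        assert res.mask.count == 50
        assert set(vals[res.mask.voxels]) == set(range(950, 1000))

    def test_constant_roi_gives_full_hotspot(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        flair = np.zeros(shape, bool)
        flair[:4] = True
        res = hotspot_seg(make_map(np.full(shape, 2.0)), make_mask(flair))
        assert res.mask.count == flair.sum()

    def test_subset_of_flair_always(self, rng):
        for _ in range(20):
            vals = rng.random((12, 12, 6))
            flair = rng.random((12, 12, 6)) < 0.4
            if not flair.any():
                continue
            res = hotspot_seg(VolumeImage(vals, spacing=(1, 1, 1)),
                              BinaryMask(flair, spacing=(1, 1, 1)))
            assert not (res.mask.voxels & ~flair).any()

    def test_monotone_in_percentile(self, rng):
        vals = rng.random((12, 12, 6))
        img = VolumeImage(vals, spacing=(1, 1, 1))
        flair = BinaryMask(np.ones((12, 12, 6), bool), spacing=(1, 1, 1))
        counts = [hotspot_seg(img, flair, percentile=p).mask.count
                  for p in (80, 90, 95, 99)]
        assert counts == sorted(counts, reverse=True)


class TestSuvMap:
    def test_standard_dosing_arithmetic(self, unit_grid):
        # 5 kBq/mL tissue, 350 MBq injected into 70 kg -> SUV 1.0
        shape, make_mask, make_map = unit_grid
        act = make_map(np.full(shape, 5.0), units="kBq/mL")
        suv = suv_map(act, injected_activity_kbq=350_000,
                      body_weight_g=70_000)
        assert np.allclose(suv.voxels, 1.0)
        assert suv.units == "SUV g/mL"

    def test_weight_proportionality(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        act = make_map(np.full(shape, 5.0))
        a = suv_map(act, 350_000, 70_000)
        b = suv_map(act, 350_000, 140_000)
        assert np.allclose(b.voxels, 2 * a.voxels)

    def test_nonpositive_inputs_error(self, unit_grid):
        shape, make_mask, make_map = unit_grid
        with pytest.raises(ValueError):
            suv_map(make_map(), 0, 70_000)
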