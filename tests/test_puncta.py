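"""Maxima detection, binary ER threshold, association, colocalization, ROI means."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pmquant.imgcore import ChannelImage
from pmquant.puncta import (classify_association, coloc_overlap,
                            derive_binary_threshold, find_maxima,
                            roi_mean_intensity)
from pmquant.synthgen import FieldParams, generate_field

from .oracles import maxima_oracle


def _img(arr):
    a = np.zeros((max(8, arr.shape[0]), max(8, arr.shape[1])))
    a[:arr.shape[0], :arr.shape[1]] = arr
    return ChannelImage(a, "t")


def _pad_img(arr):
    """Embed a small test array into the minimum 8x8 frame, zero-padded."""
    return _img(np.asarray(arr, dtype=float))


class TestFindMaxima:
    def test_constant_image_empty(self):
        assert len(find_maxima(ChannelImage(np.full((16, 16), 3.0)), 1.0)) == 0

    def test_single_gaussian_spot(self):
        y, x = np.mgrid[0:32, 0:32].astype(float)
        spot = 100.0 * np.exp(-((x - 15) ** 2 + (y - 11) ** 2) / (2 * 2.0 ** 2))
        ms = find_maxima(ChannelImage(spot), 50.0)
        assert len(ms) == 1
        px, py = ms.points[0]
        assert abs(px - 15) <= 1 and abs(py - 11) <= 1

    def test_two_spots_merge_under_large_tolerance(self):
        img = np.zeros((16, 16))
        img[4, 4] = 100.0
        img[4, 8] = 90.0
        img[4, 5:8] = 85.0           # shallow saddle between the two
        ms_small = find_maxima(ChannelImage(img), 4.0)
        ms_large = find_maxima(ChannelImage(img), 20.0)
        assert len(ms_small) == 2
        assert len(ms_large) == 1 and ms_large.points[0] == (4, 4)

    def test_plateau_yields_single_centroid_point(self):
        img = np.zeros((16, 16))
        img[6:9, 5:10] = 50.0
        ms = find_maxima(ChannelImage(img), 10.0)
        assert len(ms) == 1
        assert ms.points[0] == (7, 7)

    def test_additive_invariance_and_scale_equivariance(self, rng):
        base = rng.integers(0, 30, (20, 20)).astype(float)
        ms = find_maxima(ChannelImage(base), 5.0)
        shifted = find_maxima(ChannelImage(base + 40.0), 5.0)
        scaled = find_maxima(ChannelImage(base * 3.0), 15.0)
        assert ms.points == shifted.points == scaled.points

    @given(hnp.arrays(np.int64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                 min_side=6, max_side=10),
                      elements=st.integers(0, 4)),
           st.integers(1, 5))
    def test_matches_path_criterion_oracle(self, arr, tol):
        img = _pad_img(arr)
        ms = find_maxima(img, float(tol))
        got = sorted(ms.points, key=lambda p: (p[1], p[0]))
        assert got == maxima_oracle(img.pixels, float(tol))


class TestBinaryThreshold:
    def test_midpoint_arithmetic(self):
        img = np.zeros((8, 16))
        img[:, :8] = np.linspace(200, 400, 64).reshape(8, 8)
        img[:, 8:] = np.linspace(0, 100, 64).reshape(8, 8)
        er_mask = np.zeros((8, 16), dtype=bool)
        er_mask[:, :8] = True
        thr, mn, bg = derive_binary_threshold(
            ChannelImage(img), er_mask, ~er_mask,
            low_percentile=0.0, high_percentile=100.0)
        assert (thr, mn, bg) == (150.0, 200.0, 100.0)

    def test_overlapping_ranges_not_separable(self):
        img = np.zeros((8, 16))
        img[:, :8] = 50.0
        img[:, 8:] = np.linspace(0, 100, 64).reshape(8, 8)
        er_mask = np.zeros((8, 16), dtype=bool)
        er_mask[:, :8] = True
        with pytest.raises(ValueError, match="not separable"):
            derive_binary_threshold(ChannelImage(img), er_mask, ~er_mask)

    def test_masks_must_be_disjoint_and_nonempty(self):
        img = ChannelImage(np.random.default_rng(0).random((8, 8)) * 100)
        full = np.ones((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            derive_binary_threshold(img, full, full)
        with pytest.raises(ValueError, match="nonempty"):
            derive_binary_threshold(img, np.zeros((8, 8), bool), full)

    def test_recovers_generator_separation(self):
        channels, truth = generate_field(FieldParams(n_maxima=20, seed=3))
        thr, mn, bg = derive_binary_threshold(
            channels["er"], truth.er_mask, ~truth.er_mask)
        assert thr == pytest.approx(150.0, abs=10.0)


class TestClassifyAssociation:
    def _spots(self):
        channels, truth = generate_field(
            FieldParams(n_maxima=60, assoc_fraction_true=0.5, seed=4))
        ms = find_maxima(channels["puncta"], 250.0)
        return ms, channels["er"]

    def test_zero_threshold_all_associated(self):
        ms, er = self._spots()
        assert classify_association(ms, er, 0.0).fraction == 1.0

    def test_above_max_threshold_none_associated(self):
        ms, er = self._spots()
        assert classify_association(ms, er, er.pixels.max() + 1).fraction == 0.0

    def test_fraction_monotone_in_threshold(self):
        ms, er = self._spots()
        fracs = [classify_association(ms, er, t).fraction
                 for t in np.linspace(0, er.pixels.max() + 1, 25)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_maxima_set_errors(self):
        from pmquant.puncta import MaximaSet
        _, er = self._spots()
        with pytest.raises(ValueError, match="empty"):
            classify_association(MaximaSet([], np.array([]), 1.0), er, 10.0)


class TestColocOverlap:
    def test_identical_images(self, rng):
        img = ChannelImage(rng.random((16, 16)) * 100)
        res = coloc_overlap(img, img, 50.0, 50.0)
        assert (res.frac_A_in_B, res.frac_B_in_A) == (1.0, 1.0)

    def test_disjoint_positive_sets(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        a[:4, :4] = 100.0
        b[8:, 8:] = 100.0
        res = coloc_overlap(ChannelImage(a), ChannelImage(b), 50.0, 50.0)
        assert (res.frac_A_in_B, res.frac_B_in_A) == (0.0, 0.0)

    def test_subset_counting(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        a.ravel()[:100] = 100.0
        b.ravel()[:50] = 100.0
        res = coloc_overlap(ChannelImage(a), ChannelImage(b), 50.0, 50.0)
        assert (res.frac_A_in_B, res.frac_B_in_A) == (0.5, 1.0)

    def test_empty_denominator_reported_missing(self):
        a = ChannelImage(np.zeros((16, 16)))
        b = ChannelImage(np.full((16, 16), 100.0))
        res = coloc_overlap(a, b, 50.0, 50.0)
        assert res.frac_A_in_B is None and res.frac_B_in_A == 0.0

    def test_translation_invariance(self, rng):
        a = rng.random((20, 20)) * 100
        b = rng.random((20, 20)) * 100
        r1 = coloc_overlap(ChannelImage(a), ChannelImage(b), 60.0, 60.0)
        r2 = coloc_overlap(ChannelImage(np.roll(a, (3, 5), (0, 1))),
                           ChannelImage(np.roll(b, (3, 5), (0, 1))), 60.0, 60.0)
        assert (r1.frac_A_in_B, r1.frac_B_in_A) == (r2.frac_A_in_B, r2.frac_B_in_A)


class TestRoiMean:
    def test_constant_image(self):
        img = ChannelImage(np.full((16, 16), 42.0))
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:7, 3:7] = True
        assert roi_mean_intensity(img, mask) == 42.0

    def test_two_pixel_mean(self):
        img = np.zeros((8, 8))
        img[0, 0] = 10.0
        img[0, 1] = 30.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, :2] = True
        assert roi_mean_intensity(ChannelImage(img), mask) == 20.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean_intensity(ChannelImage(np.zeros((8, 8))),
                               np.zeros((8, 8), dtype=bool))
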