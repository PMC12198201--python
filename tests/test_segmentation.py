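"""Thresholding and mask-cleanup behavior against independent oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import filters as skfilters

from vmoquant import segmentation as seg


def ce_oracle(img, t):
    """Cross-entropy objective computed from its definition (values + 1)."""
    v = np.asarray(img, dtype=np.float64).ravel() + 1.0
    lo, hi = v[v < t + 1.0], v[v >= t + 1.0]
    out = 0.0
    for part in (lo, hi):
        if part.size:
            out -= part.sum() * np.log(part.mean())
    return out


def brute_force_threshold(img):
    """Exhaustive scan of the criterion over all candidate gray levels."""
    vals = np.unique(img)
    cands = vals[1:]
    ces = [ce_oracle(img, float(c)) for c in cands]
    return float(cands[int(np.argmin(ces))]), min(ces)


class TestLiThreshold:
    def test_matches_exhaustive_scan_on_bimodal(self, bimodal_image):
        res = seg.li_threshold(bimodal_image)
        t_brute, ce_min = brute_force_threshold(bimodal_image)
        assert ce_oracle(bimodal_image, res.t) <= ce_min + 1e-6
        # identical induced classification
        assert np.array_equal(bimodal_image >= res.t, bimodal_image >= t_brute)
        assert 60 <= res.t <= 150

    def test_two_level_image(self):
        img = np.array([[10] * 8 + [200] * 8], dtype=np.uint8).reshape(4, 4)
        res = seg.li_threshold(img)
        assert 10 < res.t <= 200
        t_brute, _ = brute_force_threshold(img)
        assert np.array_equal(img >= res.t, img >= t_brute)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scan_on_random_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        m0, m1 = rng.uniform(20, 80), rng.uniform(120, 230)
        s = rng.uniform(5, 25)
        frac = rng.uniform(0.3, 0.7)
        n = 4096
        img = np.concatenate([rng.normal(m0, s, int(n * frac)),
                              rng.normal(m1, s, n - int(n * frac))])
        img = np.clip(np.round(img), 0, 255).astype(np.uint8).reshape(64, 64)
        res = seg.li_threshold(img)
        t_brute, ce_min = brute_force_threshold(img)
        assert ce_oracle(img, res.t) <= ce_min + 1e-6
        assert np.array_equal(img >= res.t, img >= t_brute)

    def test_agrees_with_reference_implementation(self, bimodal_image):
        res = seg.li_threshold(bimodal_image)
        assert abs(res.t - skfilters.threshold_li(bimodal_image)) < 2.0

    def test_constant_image_raises(self):
        with pytest.raises(seg.DegenerateImageError):
            seg.li_threshold(np.full((10, 10), 42, np.uint8))
        with pytest.raises(seg.DegenerateImageError):
            seg.li_threshold(np.zeros((10, 10), np.uint8))

    def test_threshold_within_intensity_range(self, bimodal_image):
        res = seg.li_threshold(bimodal_image)
        assert bimodal_image.min() < res.t <= bimodal_image.max()


class TestApplyThreshold:
    def test_tie_is_foreground(self):
        img = np.array([[10, 100, 200]])
        mask = seg.apply_threshold(img, 100)
        assert mask.values.tolist() == [[False, True, True]]

    def test_min_threshold_gives_all_true(self, bimodal_image):
        mask = seg.apply_threshold(bimodal_image, int(bimodal_image.min()))
        assert mask.values.all()

    def test_monotone_in_threshold(self, bimodal_image):
        prev = None
        for t in (40, 80, 120, 200):
            cur = seg.apply_threshold(bimodal_image, t).values
            if prev is not None:
                assert not (cur & ~prev).any()  # mask(t2) subset of mask(t1)
            prev = cur

    def test_foreground_fraction_tracks_bright_mix(self, bimodal_image):
        res = seg.li_threshold(bimodal_image)
        frac = seg.apply_threshold(bimodal_image, res.t).values.mean()
        assert abs(frac - 0.5) < 0.05


def _ring(hole_r):
    yy, xx = np.mgrid[0:60, 0:60]
    d2 = (yy - 30) ** 2 + (xx - 30) ** 2
    return seg.BinaryMask((d2 <= 25 * 25) & (d2 > hole_r * hole_r))


class TestFillHoles:
    def test_small_hole_filled(self):
        m = _ring(3)          # ~29 px hole
        hole_area = int((~m.values).sum() - (~_ring(0).values).sum())
        assert hole_area <= 50
        out = seg.fill_holes(m, 50)
        assert out.values.sum() > m.values.sum()
        yy, xx = np.mgrid[0:60, 0:60]
        assert out.values[(yy - 30) ** 2 + (xx - 30) ** 2 <= 25 * 25].all()

    def test_large_hole_untouched(self):
        m = _ring(6)          # ~109 px hole
        out = seg.fill_holes(m, 50)
        assert np.array_equal(out.values, m.values)

    def test_border_cavity_is_not_a_hole(self):
        m = np.ones((20, 20), bool)
        m[0:10, 9:12] = False          # notch open to the border
        out = seg.fill_holes(seg.BinaryMask(m), 500)
        assert np.array_equal(out.values, m)

    def test_never_decreases_and_idempotent(self):
        rng = np.random.default_rng(3)
        m = seg.BinaryMask(rng.random((50, 50)) > 0.4)
        out = seg.fill_holes(m, 20)
        assert (out.values | m.values).sum() == out.values.sum()
        again = seg.fill_holes(out, 20)
        assert np.array_equal(again.values, out.values)

    def test_empty_mask(self):
        out = seg.fill_holes(seg.BinaryMask(np.zeros((5, 5), bool)), 50)
        assert not out.values.any()


class TestRemoveSmall:
    def _blob(self, area, offset):
        m = np.zeros((80, 80), bool)
        cols = int(np.ceil(area / 5))
        m[offset:offset + 5, offset:offset + cols] = True
        m.flat[np.flatnonzero(m)[area:]] = False
        return m

    def test_keep_is_inclusive_at_cutoff(self):
        nine = seg.BinaryMask(self._blob(9, 2))
        ten = seg.BinaryMask(self._blob(10, 2))
        assert not seg.remove_small(nine, 10).values.any()
        assert seg.remove_small(ten, 10).values.sum() == 10

    def test_mixed_sizes(self):
        m = np.zeros((100, 100), bool)
        m[2:3, 2:7] = True                 # 5 px
        m[20:25, 20:30] = True             # 50 px
        m[50:70, 50:75] = True             # 500 px
        out = seg.remove_small(seg.BinaryMask(m), 10)
        _, n = ndi.label(out.values, structure=np.ones((3, 3)))
        assert n == 2

    def test_idempotent_and_never_increases(self):
        rng = np.random.default_rng(5)
        m = seg.BinaryMask(rng.random((60, 60)) > 0.55)
        out = seg.remove_small(m, 8)
        assert out.values.sum() <= m.values.sum()
        assert np.array_equal(seg.remove_small(out, 8).values, out.values)


class TestEdmPrune:
    def test_identity_at_zero(self):
        rng = np.random.default_rng(2)
        m = seg.BinaryMask(rng.random((40, 40)) > 0.5)
        assert np.array_equal(seg.edm_prune(m, 0).values, m.values)

    def test_spur_removed_trunk_kept(self):
        m = np.zeros((60, 120), bool)
        m[20:40, 10:110] = True            # 20-px trunk
        m[29:31, 0:10] = True              # 2-px-wide spur
        out = seg.edm_prune(seg.BinaryMask(m), 3)
        assert not out.values[29:31, 0:8].any()
        assert out.values[21:39, 15:105].all()

    @pytest.mark.parametrize("s", range(20))
    def test_equals_opening_with_open_disk(self, s):
        rng = np.random.default_rng(s)
        m = np.zeros((150, 150), bool)
        yy, xx = np.mgrid[0:150, 0:150]
        for _ in range(8):
            y, x, rad = rng.integers(25, 125), rng.integers(25, 125), rng.integers(3, 16)
            m |= (yy - y) ** 2 + (xx - x) ** 2 <= rad * rad
        mine = seg.edm_prune(seg.BinaryMask(m), 3).values
        oracle = ndi.binary_opening(m, structure=seg.open_disk(3))
        assert np.array_equal(mine, oracle)
        assert not (mine & ~m).any()        # subset of input

    def test_square_area_bound(self):
        m = np.zeros((80, 80), bool)
        m[10:60, 10:60] = True
        out = seg.edm_prune(seg.BinaryMask(m), 3)
        assert 2500 - 4 * 50 * 2 * 3 <= out.values.sum() <= 2500


class TestExternalMask(object):
    def test_encoding_round_trip(self, tmp_path):
        import tifffile

        rng = np.random.default_rng(0)
        pattern = rng.random((30, 30)) > 0.5
        p255 = tmp_path / "m255.tif"
        p1 = tmp_path / "m1.tif"
        tifffile.imwrite(p255, pattern.astype(np.uint8) * 255)
        tifffile.imwrite(p1, pattern.astype(np.uint8))
        a = seg.load_external_mask(p255)
        b = seg.load_external_mask(p1)
        assert np.array_equal(a.values, pattern)
        assert np.array_equal(a.values, b.values)
        assert a.provenance == "external"

    def test_dimension_mismatch_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "m.tif"
        tifffile.imwrite(p, np.zeros((10, 10), np.uint8))
        with pytest.raises(ValueError, match="dims"):
            seg.load_external_mask(p, np.zeros((20, 20)))

    def test_nonbinary_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "m.tif"
        tifffile.imwrite(p, np.arange(9, dtype=np.uint8).reshape(3, 3))
        with pytest.raises(ValueError, match="distinct"):
            seg.load_external_mask(p)
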