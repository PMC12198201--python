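"""Skeleton morphometry recovery against drawn ground truth."""

import numpy as np
import pytest

from vmoquant import segmentation as seg
from vmoquant import synthetic as syn
from vmoquant import vessels as ves
from vmoquant.synthetic import _seg_point_dist


def analyze_scene(spec, params=None):
    img, truth = syn.generate_vessel_scene(spec)
    t = seg.li_threshold(img)
    mask = seg.apply_threshold(img, t.t)
    metrics, branches, cleaned = ves.analyze_vessels(img, mask, params)
    return img, truth, metrics, branches, cleaned


def match_branch_widths(branches, segments):
    """Pair each measured branch with the drawn segment nearest its midpoint."""
    out = []
    for b in branches:
        mid = b.path[len(b.path) // 2]
        d = [float(_seg_point_dist(s, np.array([mid[1]]), np.array([mid[0]]))[0])
             for s in segments]
        out.append((b, segments[int(np.argmin(d))]))
    return out


class TestSkeletonize:
    def test_bar_gives_single_path(self):
        m = np.zeros((40, 120), bool)
        m[15:26, 10:110] = True           # 11-px-wide bar
        sk = ves.skeletonize(seg.BinaryMask(m))
        assert (sk.neighbor_count[sk.image] <= 2).all()
        assert abs(sk.image.sum() - 100) < 15

    def test_disk_collapses_to_near_point(self, disk_mask):
        sk = ves.skeletonize(disk_mask)
        assert sk.image.sum() <= 10

    def test_component_preservation(self):
        from scipy import ndimage as ndi

        m = np.zeros((60, 120), bool)
        m[10:18, 10:110] = True
        m[40:48, 10:110] = True
        sk = ves.skeletonize(seg.BinaryMask(m))
        _, n = ndi.label(sk.image, structure=np.ones((3, 3)))
        assert n == 2

    def test_unit_width(self, y_scene):
        img, _ = y_scene
        t = seg.li_threshold(img)
        cleaned = ves.clean_vessel_mask(seg.apply_threshold(img, t.t))
        sk = ves.skeletonize(cleaned)
        # no 2x2 block is fully skeleton
        s = sk.image
        assert not (s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()


class TestJunctionsAndBranches:
    @pytest.mark.parametrize("spec_fn,n_j,n_e,n_b", [
        (syn.y_spec, 1, 3, 3),
        (syn.plus_spec, 1, 4, 4),
        (syn.h_spec, 2, 4, 5),
    ])
    def test_motif_counts(self, spec_fn, n_j, n_e, n_b):
        _, truth, m, _, _ = analyze_scene(spec_fn(seed=1))
        assert (truth.n_junctions, truth.n_endpoints, truth.n_branches) == (n_j, n_e, n_b)
        assert (m.n_junctions, m.n_endpoints, m.n_segments) == (n_j, n_e, n_b)

    def test_straight_line_counts_and_length(self):
        spec = syn.bar_spec(width=9, length=160, seed=2)
        _, truth, m, branches, _ = analyze_scene(spec)
        assert m.n_junctions == 0 and m.n_endpoints == 2 and m.n_segments == 1
        # skeleton ends retract by about the tube radius at each cap
        assert abs(branches[0].length_px - 160) <= 12

    def test_ladder_counts(self):
        _, truth, m, _, _ = analyze_scene(syn.ladder_spec(n_rungs=6, seed=3))
        assert truth.n_junctions == 12
        assert (m.n_junctions, m.n_endpoints, m.n_segments) == (
            truth.n_junctions, truth.n_endpoints, truth.n_branches)

    def test_merge_dist_monotonicity(self):
        img, _ = syn.generate_vessel_scene(syn.ladder_spec(n_rungs=6, seed=3))
        t = seg.li_threshold(img)
        cleaned = ves.clean_vessel_mask(seg.apply_threshold(img, t.t))
        sk = ves.skeletonize(cleaned)
        counts = [len(ves.find_junctions(sk, d)[0]) for d in (1, 5, 10, 25, 60)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBranchFilter:
    def test_dim_branches_dropped(self):
        spec = syn.ladder_spec(n_rungs=6, seed=4)
        dim_idx = {3, 5, 7}               # three of the six rungs
        spec.segments = [
            syn.Segment(s.a, s.b, s.width, dim=(i in dim_idx))
            for i, s in enumerate(spec.segments)]
        img, truth = syn.generate_vessel_scene(spec)
        mask = seg.BinaryMask(truth.mask)
        m, branches, _ = ves.analyze_vessels(img, mask)
        assert m.n_segments_prefilter - m.n_segments == 3

    def test_constant_region_threshold(self):
        path = np.column_stack([np.full(20, 5), np.arange(20)])
        b_lo = ves.Branch(path=path, length_px=19.0, endpoints=((5, 0), (5, 19)))
        b_hi = ves.Branch(path=path, length_px=19.0, endpoints=((5, 0), (5, 19)))
        dim = np.full((10, 30), 30, np.uint8)
        bright = np.full((10, 30), 200, np.uint8)
        assert ves.filter_branches([b_lo], dim, 50) == []
        assert ves.filter_branches([b_hi], bright, 50) == [b_hi]


class TestDiameters:
    @pytest.mark.parametrize("width", [5, 7, 11, 17, 25])
    def test_bar_width_recovery(self, width):
        _, truth, m, branches, _ = analyze_scene(syn.bar_spec(width=width, seed=1))
        assert len(branches) == 1
        assert abs(branches[0].mean_diameter_px - width) <= 1.0

    def test_single_pixel_line(self):
        m = np.zeros((20, 60), bool)
        m[10, 5:55] = True
        mask = seg.BinaryMask(m)
        sk = ves.skeletonize(mask)
        js, _ = ves.find_junctions(sk)
        br = ves.measure_diameters(ves.decompose_branches(sk, js), mask, js)
        assert abs(br[0].mean_diameter_px - 1) <= 1.0

    def test_crossed_bars_distinct_widths(self):
        cx = 128.0
        spec = syn.VesselSceneSpec(shape=(256, 256), segments=[
            syn.Segment((20, cx), (236, cx), 15),
            syn.Segment((cx, 20), (cx, 236), 7)], seed=5)
        img, truth = syn.generate_vessel_scene(spec)
        mask = seg.BinaryMask(truth.mask)
        m, branches, _ = ves.analyze_vessels(img, mask)
        widths = sorted(b.mean_diameter_px for b in branches)
        for got, want in zip(widths, sorted([7, 7, 15, 15])):
            assert abs(got - want) <= 1.0


class TestSummaryAndInvariance:
    def test_y_scene_summary(self, y_scene):
        img, truth = y_scene
        t = seg.li_threshold(img)
        m, _, _ = ves.analyze_vessels(img, seg.apply_threshold(img, t.t))
        assert (m.n_junctions, m.n_endpoints, m.n_segments) == (1, 3, 3)
        # each arm retracts by about the tube radius at its free cap
        assert m.total_length_px == pytest.approx(truth.total_length, rel=0.10)

    def test_empty_mask_zero_metrics(self):
        mask = seg.BinaryMask(np.zeros((50, 50), bool))
        m, branches, _ = ves.analyze_vessels(np.zeros((50, 50), np.uint8), mask)
        assert (m.total_area_px, m.n_junctions, m.n_endpoints, m.n_segments) == (0, 0, 0, 0)
        assert m.total_length_px == 0

    def test_rotation_robustness(self):
        spec = syn.random_tree_spec(4, n_branches=9)
        img, truth = syn.generate_vessel_scene(spec)
        mask = seg.BinaryMask(truth.mask)
        m0, _, _ = ves.analyze_vessels(img, mask)
        img90 = np.rot90(img).copy()
        mask90 = seg.BinaryMask(np.rot90(truth.mask).copy())
        m90, _, _ = ves.analyze_vessels(img90, mask90)
        assert (m0.n_junctions, m0.n_endpoints, m0.n_segments) == (
            m90.n_junctions, m90.n_endpoints, m90.n_segments)
        assert m90.total_length_px == pytest.approx(m0.total_length_px, rel=0.01)
        assert m90.mean_diameter_px == pytest.approx(m0.mean_diameter_px, rel=0.01)

    def test_translation_invariance(self):
        spec = syn.y_spec(width=9, seed=6)
        img, truth = syn.generate_vessel_scene(spec)
        mask = seg.BinaryMask(truth.mask)
        m0, _, _ = ves.analyze_vessels(img, mask)
        sh = (11, -7)
        m1, _, _ = ves.analyze_vessels(np.roll(img, sh, (0, 1)),
                                       seg.BinaryMask(np.roll(truth.mask, sh, (0, 1))))
        assert m1.total_area_px == m0.total_area_px
        assert m1.total_length_px == pytest.approx(m0.total_length_px, abs=1e-9)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ves.MorphometryParams(hole_fill_max=-1)
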