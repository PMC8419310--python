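import numpy as np
import pytest

from neuromre.contrast import ContrastImagePair
from neuromre.masks import (ATLAS_N_SLICES, ATLAS_SPAN_MM, LesionMaskSet,
                            dilate_mask, gd_mask_from_change, incidence_map,
                            make_exclusive, percent_change_si,
                            regional_incidence, resample_slices,
                            vsop_mask_from_hypointensity)

SP3 = (0.8, 0.18, 0.18)


def pair_from(pre, post, modality="t1_gbca"):
    return ContrastImagePair(pre=np.asarray(pre, float),
                             post=np.asarray(post, float),
                             modality=modality, pixel_spacing_mm=SP3)


def full(shape, v):
    return np.full(shape, float(v))


class TestPercentChange:
    def test_basic_arithmetic(self):
        brain = np.ones((1, 2, 2), bool)
        m = percent_change_si(pair_from(full((1, 2, 2), 100), full((1, 2, 2), 120)), brain)
        assert np.allclose(m, 20.0)
        m = percent_change_si(pair_from(full((1, 2, 2), 50), full((1, 2, 2), 50)), brain)
        assert np.allclose(m, 0.0)

    def test_restricted_to_brain_and_invalid_pre(self):
        brain = np.zeros((1, 2, 2), bool)
        brain[0, 0, :] = True
        pre = full((1, 2, 2), 100.0)
        pre[0, 0, 1] = 0.0
        m = percent_change_si(pair_from(pre, full((1, 2, 2), 110)), brain)
        assert np.isclose(m[0, 0, 0], 10.0)
        assert np.isnan(m[0, 0, 1])       # pre == 0 flagged invalid
        assert np.isnan(m[0, 1, :]).all()  # outside brain


class TestThresholdMasks:
    def test_zero_map_gives_empty_mask(self):
        assert not gd_mask_from_change(np.zeros((1, 5, 5))).any()

    def test_exact_region_recovered_and_small_components_removed(self):
        m = np.zeros((1, 10, 12))
        m[0, 2:5, 2:7] = 30.0      # 15 px region
        m[0, 8, 10] = 30.0         # isolated pixel
        mask = gd_mask_from_change(m, threshold_pct=15.0, min_size_px=5)
        expect = m >= 15.0
        expect[0, 8, 10] = False
        assert np.array_equal(mask, expect)

    def test_vsop_ratio_threshold(self):
        brain = np.ones((1, 8, 8), bool)
        pre = full((1, 8, 8), 100.0)
        post = pre.copy()
        post[0, 2:5, 2:5] = 60.0
        mask = vsop_mask_from_hypointensity(pair_from(pre, post, "t2star_vsop"),
                                            brain, ratio_threshold=0.8)
        assert np.array_equal(mask, post < 100)
        assert not vsop_mask_from_hypointensity(pair_from(pre, pre, "t2star_vsop"),
                                                brain, 0.8).any()
        # threshold 0 is unsatisfiable -> empty mask
        assert not vsop_mask_from_hypointensity(pair_from(pre, post, "t2star_vsop"),
                                                brain, 0.0).any()
        with pytest.raises(ValueError):
            vsop_mask_from_hypointensity(pair_from(pre, post, "t2star_vsop"),
                                         brain, 1.0)


class TestDilation:
    def test_zero_iterations_is_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((2, 10, 10)) > 0.7
        assert np.array_equal(dilate_mask(m, 0), m)

    def test_two_pixel_dilation_of_point_is_13_pixel_diamond(self):
        """Brute force: 4-connected dilation twice = L1 ball of radius 2."""
        m = np.zeros((1, 9, 9), bool)
        m[0, 4, 4] = True
        d = dilate_mask(m, 2)
        brute = np.zeros_like(m)
        for r in range(9):
            for c in range(9):
                brute[0, r, c] = abs(r - 4) + abs(c - 4) <= 2
        assert np.array_equal(d, brute)
        assert d.sum() == 13

    def test_dilation_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = rng.random((1, 12, 12)) > 0.85
            d1 = dilate_mask(m, 1)
            d2 = dilate_mask(m, 2)
            assert (m <= d1).all() and (d1 <= d2).all()

    def test_inplane_only(self):
        m = np.zeros((3, 5, 5), bool)
        m[1, 2, 2] = True
        d = dilate_mask(m, 1)
        assert not d[0].any() and not d[2].any()


class TestExclusion:
    def grids(self, ns=1, nr=8, nc=8):
        brain = np.ones((ns, nr, nc), bool)
        vent = np.zeros_like(brain)
        return brain, vent

    def mask_with(self, coords, shape=(1, 8, 8)):
        m = np.zeros(shape, bool)
        for s, r, c in coords:
            m[s, r, c] = True
        return m

    def test_overlap_removed_from_both(self):
        brain, vent = self.grids()
        gd = self.mask_with([(0, 1, 1), (0, 2, 2)])
        vs = self.mask_with([(0, 2, 2), (0, 3, 3)])
        ms = make_exclusive(LesionMaskSet(gd, vs, vent, brain, state="dilated"))
        assert np.array_equal(ms.gd, self.mask_with([(0, 1, 1)]))
        assert np.array_equal(ms.vsop, self.mask_with([(0, 3, 3)]))
        assert ms.state == "final"

    def test_disjoint_masks_unchanged(self):
        brain, vent = self.grids()
        gd = self.mask_with([(0, 1, 1)])
        vs = self.mask_with([(0, 5, 5)])
        ms = make_exclusive(LesionMaskSet(gd, vs, vent, brain, state="dilated"))
        assert np.array_equal(ms.gd, gd) and np.array_equal(ms.vsop, vs)

    def test_vsop_inside_gd_vanishes(self):
        brain, vent = self.grids()
        gd = self.mask_with([(0, r, c) for r in range(2, 6) for c in range(2, 6)])
        vs = self.mask_with([(0, 3, 3), (0, 4, 4)])
        ms = make_exclusive(LesionMaskSet(gd, vs, vent, brain, state="dilated"))
        assert not ms.vsop.any()
        assert np.array_equal(ms.gd, gd & ~vs)

    def test_requires_dilated_state_and_checks_invariants(self):
        brain, vent = self.grids()
        gd = self.mask_with([(0, 1, 1)])
        with pytest.raises(ValueError, match="dilated"):
            make_exclusive(LesionMaskSet(gd, gd.copy(), vent, brain, state="raw"))
        with pytest.raises(ValueError):
            LesionMaskSet(gd, gd.copy(), vent, brain, state="final")

    def test_randomized_algebra_against_set_oracle(self):
        """1000 random mask triples; python-set operations are the oracle."""
        rng = np.random.default_rng(42)
        shape = (1, 10, 14)
        for _ in range(1000):
            brain = rng.random(shape) > 0.2
            gd = (rng.random(shape) > 0.8) & brain
            vs = (rng.random(shape) > 0.8) & brain
            vent = (rng.random(shape) > 0.93) & brain
            ms = make_exclusive(LesionMaskSet(gd, vs, vent, brain, state="dilated"))
            G = set(map(tuple, np.argwhere(gd)))
            V = set(map(tuple, np.argwhere(vs)))
            VEN = set(map(tuple, np.argwhere(vent)))
            B = set(map(tuple, np.argwhere(brain)))
            gd_oracle = (G - V - VEN) & B
            vs_oracle = (V - G - VEN) & B
            assert set(map(tuple, np.argwhere(ms.gd))) == gd_oracle
            assert set(map(tuple, np.argwhere(ms.vsop))) == vs_oracle
            assert not (ms.gd & ms.vsop).any()
            assert not ((ms.gd | ms.vsop) & vent).any()


class TestResampling:
    def test_identity_when_grids_match(self):
        rng = np.random.default_rng(1)
        img = rng.random((7, 4, 5))
        for method in ("nearest", "linear"):
            out = resample_slices(img, 0.8, n_target=7, target_span_mm=5.6,
                                  method=method)
            assert np.allclose(out, img)

    def test_constant_preserved(self):
        img = np.full((7, 3, 3), 2.5)
        out = resample_slices(img, 0.8, method="linear", fill=np.nan)
        vals = out[~np.isnan(out)]
        assert np.allclose(vals, 2.5)

    def test_seven_slices_populate_about_58_atlas_slices(self):
        """7 x 0.8 mm onto the 215-slice atlas span -> 58 +- 1 carrying data."""
        img = np.ones((7, 2, 2))
        out = resample_slices(img, 0.8, n_target=ATLAS_N_SLICES,
                              target_span_mm=ATLAS_SPAN_MM, method="nearest",
                              fill=0)
        populated = int((out.reshape(ATLAS_N_SLICES, -1) > 0).any(axis=1).sum())
        assert abs(populated - 58) <= 1

    def test_bad_geometry_rejected(self):
        img = np.ones((3, 2, 2))
        with pytest.raises(ValueError):
            resample_slices(img, -0.8)
        with pytest.raises(ValueError):
            resample_slices(img, 0.8, method="cubic")


class TestIncidence:
    def test_simple_counts(self):
        masks = [np.zeros((1, 2, 2), bool) for _ in range(4)]
        masks[0][0, 0, 0] = masks[1][0, 0, 0] = True
        for m in masks:
            m[0, 1, 1] = True
        inc = incidence_map(masks, "gd")
        assert inc.percent[0, 0, 0] == 50.0
        assert inc.percent[0, 1, 1] == 100.0
        assert inc.n_animals == 4

    def test_randomized_exact_counting(self):
        """Exact equality with brute-force voxel counting on random cohorts."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            masks = [rng.random((2, 6, 7)) > 0.6 for _ in range(n)]
            inc = incidence_map(masks, "vsop")
            brute = 100.0 * sum(m.astype(int) for m in masks) / n
            assert np.array_equal(inc.percent, brute)
            grid_vals = {round(100.0 * k / n, 10) for k in range(n + 1)}
            assert all(round(v, 10) in grid_vals for v in np.unique(inc.percent))

    def test_regional_incidence_matches_table_formatting(self):
        """15 of 19 animals intersecting a region reads 78.9."""
        atlas = np.zeros((1, 4, 4), np.int16)
        atlas[0, :2] = 1
        atlas[0, 2:] = 2
        masks = []
        for i in range(19):
            m = np.zeros((1, 4, 4), bool)
            if i < 15:
                m[0, 0, 0] = True  # region 1
            m[0, 3, 3] = True      # region 2, all animals
            masks.append(m)
        df = regional_incidence(masks, atlas, {1: "brain_stem", 2: "fiber_tracts"})
        vals = dict(zip(df.anatomical_label, df.incidence_pct))
        assert vals["brain_stem"] == 78.9
        assert vals["fiber_tracts"] == 100.0

    def test_zero_incidence_and_unknown_label(self):
        atlas = np.ones((1, 2, 2), np.int16)
        masks = [np.zeros((1, 2, 2), bool)]
        df = regional_incidence(masks, atlas, {1: "cortex"})
        assert df.incidence_pct.iloc[0] == 0.0
        atlas[0, 0, 0] = 7
        with pytest.raises(ValueError, match="unknown"):
            regional_incidence(masks, atlas, {1: "cortex"})

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            incidence_map([np.zeros((1, 2, 2), bool), np.zeros((1, 3, 3), bool)], "gd")
        with pytest.raises(ValueError):
            incidence_map([], "gd")
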