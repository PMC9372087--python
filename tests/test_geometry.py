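"""Overlap and surface-distance metrics against hand counts and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import cdist

from contoureval.geometry import (
    dice,
    evaluate_geometry,
    extract_surface,
    hausdorff,
    jaccard,
)
from contoureval.grids import (
    BinaryMask,
    EmptyStructureError,
    Geometry,
    GeometryError,
    StructureSet,
)

from conftest import random_mask


def brute_force_surface(mask: BinaryMask) -> np.ndarray:
    """Independent surface definition: true voxel with a false 6-neighbor or on the border."""
    v = mask.voxels
    pts = []
    for i, j, k in np.argwhere(v):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            outside = not (0 <= ni < v.shape[0] and 0 <= nj < v.shape[1] and 0 <= nk < v.shape[2])
            if outside or not v[ni, nj, nk]:
                pts.append((i, j, k))
                break
    return mask.geometry.indices_to_physical(np.array(pts))


def brute_force_hausdorff(a: BinaryMask, b: BinaryMask, percentile: float) -> float:
    """Exhaustive all-pairs oracle for the percentile Hausdorff distance."""
    pa = brute_force_surface(a)
    pb = brute_force_surface(b)
    d = cdist(pa, pb)
    to_a = d.min(axis=0)  # per point of B
    to_b = d.min(axis=1)  # per point of A
    return max(np.percentile(to_a, percentile), np.percentile(to_b, percentile))


def _mask_from_indices(geom, indices):
    vox = np.zeros(geom.shape, bool)
    for idx in indices:
        vox[idx] = True
    return BinaryMask(geom, vox)


class TestSurface:
    def test_single_voxel_single_surface_point(self, geom_iso):
        m = _mask_from_indices(geom_iso, [(5, 5, 5)])
        pts = extract_surface(m).points
        assert pts.shape == (1, 3)
        assert np.allclose(pts[0], (5.0, 5.0, 5.0))

    def test_solid_cube_surface_has_26_points(self, geom_iso):
        vox = np.zeros(geom_iso.shape, bool)
        vox[4:7, 4:7, 4:7] = True
        pts = extract_surface(BinaryMask(geom_iso, vox)).points
        assert len(pts) == 26  # all but the center voxel of the 3x3x3 block

    def test_one_voxel_thick_slab_is_all_surface(self, geom_iso):
        vox = np.zeros(geom_iso.shape, bool)
        vox[:, :, 6] = True
        pts = extract_surface(BinaryMask(geom_iso, vox)).points
        assert len(pts) == geom_iso.shape[0] * geom_iso.shape[1]

    def test_volume_border_counts_as_outside(self):
        g = Geometry((3, 3, 3), (1, 1, 1))
        m = BinaryMask(g, np.ones(g.shape, bool))
        assert len(extract_surface(m).points) == 26

    def test_matches_brute_force_definition(self, geom_iso):
        rng = np.random.default_rng(7)
        m = random_mask(geom_iso, rng)
        got = extract_surface(m).points
        want = brute_force_surface(m)
        assert np.array_equal(np.sort(got, axis=0), np.sort(want, axis=0))

    def test_empty_mask_raises(self, geom_iso):
        with pytest.raises(EmptyStructureError):
            extract_surface(BinaryMask(geom_iso, np.zeros(geom_iso.shape, bool)))


class TestOverlap:
    def test_identical_masks_are_perfect(self, geom_iso):
        rng = np.random.default_rng(0)
        m = random_mask(geom_iso, rng)
        assert dice(m, m) == 1.0
        assert jaccard(m, m) == 1.0
        assert hausdorff(m, m, 100) == 0.0
        assert hausdorff(m, m, 95) == 0.0

    def test_disjoint_masks_have_zero_overlap(self, geom_iso):
        a = _mask_from_indices(geom_iso, [(1, 1, 1)])
        b = _mask_from_indices(geom_iso, [(8, 8, 8)])
        assert dice(a, b) == 0.0
        assert jaccard(a, b) == 0.0

    def test_hand_counted_partial_overlap(self, geom_iso):
        # |A| = 1, |B| = 2, one shared voxel
        a = _mask_from_indices(geom_iso, [(5, 5, 5)])
        b = _mask_from_indices(geom_iso, [(5, 5, 5), (5, 5, 6)])
        assert dice(a, b) == pytest.approx(2.0 / 3.0)
        assert jaccard(a, b) == pytest.approx(1.0 / 2.0)

    def test_symmetry(self, geom_iso):
        rng = np.random.default_rng(1)
        a, b = random_mask(geom_iso, rng), random_mask(geom_iso, rng)
        assert dice(a, b) == dice(b, a)
        assert jaccard(a, b) == jaccard(b, a)
        assert hausdorff(a, b, 95) == hausdorff(b, a, 95)

    @pytest.mark.parametrize("seed", range(10))
    def test_dsc_jc_identity(self, geom_iso, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask(geom_iso, rng), random_mask(geom_iso, rng)
        d, j = dice(a, b), jaccard(a, b)
        assert abs(d - 2 * j / (1 + j)) <= 1e-12

    def test_both_empty_raises(self, geom_iso):
        e = BinaryMask(geom_iso, np.zeros(geom_iso.shape, bool))
        with pytest.raises(EmptyStructureError):
            dice(e, e)
        with pytest.raises(EmptyStructureError):
            jaccard(e, e)

    def test_mismatched_geometry_raises(self):
        a = BinaryMask(Geometry((4, 4, 4), (1, 1, 1)), np.ones((4, 4, 4), bool))
        b = BinaryMask(Geometry((4, 4, 4), (1, 1, 2)), np.ones((4, 4, 4), bool))
        with pytest.raises(GeometryError):
            dice(a, b)

    def test_translation_invariance(self, geom_iso):
        rng = np.random.default_rng(5)
        vox_a = rng.random((6, 6, 6)) < 0.4
        vox_b = rng.random((6, 6, 6)) < 0.4
        vox_a[0, 0, 0] = vox_b[0, 0, 0] = True
        def place(vox, off):
            full = np.zeros(geom_iso.shape, bool)
            full[off[0]:off[0] + 6, off[1]:off[1] + 6, off[2]:off[2] + 6] = vox
            return BinaryMask(geom_iso, full)
        ref = (dice(place(vox_a, (0, 0, 0)), place(vox_b, (0, 0, 0))),
               hausdorff(place(vox_a, (0, 0, 0)), place(vox_b, (0, 0, 0)), 95))
        shifted = (dice(place(vox_a, (3, 2, 1)), place(vox_b, (3, 2, 1))),
                   hausdorff(place(vox_a, (3, 2, 1)), place(vox_b, (3, 2, 1)), 95))
        assert ref == shifted


@st.composite
def mask_pairs(draw):
    shape = (6, 6, 4)
    a = draw(hnp.arrays(bool, shape))
    b = draw(hnp.arrays(bool, shape))
    g = Geometry(shape, (1.0, 2.0, 5.0))
    return BinaryMask(g, a), BinaryMask(g, b)


class TestOverlapProperties:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(mask_pairs())
    def test_dsc_jc_bounds_identity_and_symmetry(self, pair):
        a, b = pair
        if a.is_empty() and b.is_empty():
            return
        d, j = dice(a, b), jaccard(a, b)
        assert 0.0 <= j <= d <= 1.0
        assert abs(d - 2 * j / (1 + j)) <= 1e-12
        assert dice(b, a) == d and jaccard(b, a) == j

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(mask_pairs())
    def test_hd95_never_exceeds_hd(self, pair):
        a, b = pair
        if a.is_empty() or b.is_empty():
            return
        assert hausdorff(a, b, 95) <= hausdorff(a, b, 100) + 1e-12


class TestHausdorff:
    def test_single_pair_distance_respects_spacing(self):
        g = Geometry((4, 4, 4), (1.0, 1.0, 3.0))
        a = _mask_from_indices(g, [(1, 1, 1)])
        b = _mask_from_indices(g, [(1, 1, 2)])  # adjacent along z => 3 mm
        assert hausdorff(a, b, 100) == pytest.approx(3.0)

    def test_anisotropic_z_neighbors_are_5mm_apart(self, geom_aniso):
        a = _mask_from_indices(geom_aniso, [(4, 4, 2)])
        b = _mask_from_indices(geom_aniso, [(4, 4, 3)])
        assert hausdorff(a, b, 100) == pytest.approx(5.0)

    def test_percentile_monotone(self, geom_iso):
        rng = np.random.default_rng(11)
        a, b = random_mask(geom_iso, rng), random_mask(geom_iso, rng)
        values = [hausdorff(a, b, p) for p in (25, 50, 75, 90, 95, 100)]
        assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))

    def test_percentile_validation(self, geom_iso):
        rng = np.random.default_rng(12)
        a = random_mask(geom_iso, rng)
        with pytest.raises(ValueError):
            hausdorff(a, a, 0.0)
        with pytest.raises(ValueError):
            hausdorff(a, a, 100.1)

    def test_outlier_trimmed_by_95th_percentile(self):
        # a line of near-coincident points plus one 10 mm outlier
        g = Geometry((40, 3, 3), (1.0, 1.0, 1.0))
        idx_a = [(i, 1, 1) for i in range(20)]
        idx_b = [(i, 2, 1) for i in range(19)] + [(29, 1, 1)]  # last point 10 mm off
        a = _mask_from_indices(g, idx_a)
        b = _mask_from_indices(g, idx_b)
        assert hausdorff(a, b, 100) == pytest.approx(brute_force_hausdorff(a, b, 100))
        assert hausdorff(a, b, 95) == pytest.approx(brute_force_hausdorff(a, b, 95))
        assert hausdorff(a, b, 95) < hausdorff(a, b, 100)

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("percentile", [50.0, 95.0, 100.0])
    def test_matches_all_pairs_oracle(self, geom_iso, geom_aniso, seed, percentile):
        geom = geom_iso if seed % 2 else geom_aniso
        rng = np.random.default_rng(seed)
        a, b = random_mask(geom, rng, 0.2), random_mask(geom, rng, 0.2)
        assert hausdorff(a, b, percentile) == pytest.approx(
            brute_force_hausdorff(a, b, percentile), abs=1e-12)


class TestEvaluateGeometry:
    def _sets(self, geom, rng, names):
        masks = {n: random_mask(geom, rng) for n in names}
        return StructureSet(masks, "manual")

    def test_identical_sets_give_perfect_rows(self, geom_iso):
        rng = np.random.default_rng(3)
        ref = self._sets(geom_iso, rng, ["a", "b", "c"])
        test = StructureSet(dict(ref.structures), "auto")
        out = evaluate_geometry(ref, test)
        ok = out[out.status == "ok"]
        assert len(ok) == 3
        assert (ok.dsc == 1.0).all()
        assert (ok.jc == 1.0).all()
        assert (ok.hd95_mm == 0.0).all()

    def test_missing_structures_flagged_not_dropped(self, geom_iso):
        rng = np.random.default_rng(4)
        ref = self._sets(geom_iso, rng, ["a", "b"])
        test = StructureSet({"a": ref["a"], "extra": random_mask(geom_iso, rng)}, "auto")
        out = evaluate_geometry(ref, test)
        assert set(out.structure) == {"a", "b", "extra"}
        assert out.loc[out.structure == "b", "status"].item() == "missing_in_test"
        assert out.loc[out.structure == "extra", "status"].item() == "missing_in_ref"

    def test_no_common_structures_raises(self, geom_iso):
        rng = np.random.default_rng(5)
        ref = self._sets(geom_iso, rng, ["a"])
        test = StructureSet({"z": random_mask(geom_iso, rng)}, "auto")
        with pytest.raises(ValueError):
            evaluate_geometry(ref, test)
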