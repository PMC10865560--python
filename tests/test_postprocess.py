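import numpy as np
import pytest

import perisinus as ps
from perisinus.postprocess import RegionBoundaries


def _lab(data, spacing=1.0, space="template", centered=True):
    data = np.asarray(data)
    aff = np.diag([spacing] * 3 + [1.0])
    if centered:
        aff[:3, 3] = -spacing * (np.array(data.shape) - 1) / 2
    return ps.LabelMap(data.astype(np.int16), (spacing,) * 3, aff, space)


def flood_fill_components(mask, connectivity):
    """Independent brute-force connected components (stack-based)."""
    mask = np.asarray(mask) > 0
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                 for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in neigh:
                w = tuple(np.add(v, d))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


class TestCloseMask:
    def test_fills_single_interior_hole(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        m[3, 3, 3] = False
        out = ps.close_mask(m, 1)
        assert out[3, 3, 3]

    def test_idempotent_and_extensive(self, rng):
        for _ in range(25):
            m = rng.random((10, 10, 10)) < 0.3
            once = ps.close_mask(m, 1)
            assert (once | m).sum() == once.sum()          # extensive
            np.testing.assert_array_equal(ps.close_mask(once, 1), once)

    def test_empty_stays_empty(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        assert not ps.close_mask(m, 1).any()


class TestTopologyCorrection:
    def test_removes_disconnected_fragment(self):
        data = np.zeros((12, 12, 12), dtype=int)
        data[2:6, 2:6, 2:6] = 2
        data[10, 10, 10] = 3     # isolated speck far from the main complex
        out = ps.apply_topology_correction(_lab(data), radius_voxels=1)
        assert out.data[10, 10, 10] == 0
        assert (np.asarray(out.data)[2:6, 2:6, 2:6] == 2).all()

    def test_added_voxels_take_nearest_label(self):
        data = np.zeros((9, 9, 9), dtype=int)
        data[2:7, 2:7, 2:4] = 1
        data[2:7, 2:7, 5:7] = 2
        out = ps.apply_topology_correction(_lab(data), radius_voxels=1)
        gained = (np.asarray(out.data) > 0) & (data == 0)
        assert set(np.unique(np.asarray(out.data)[gained])) <= {1, 2}


class TestAGInstances:
    def test_phantom_instances_match_truth(self, small_phantom):
        _, _, lab, truth = small_phantom
        stats = ps.extract_ag_instances(lab, connectivity=26, min_volume_mm3=0)
        assert stats.count == truth.ag_count
        got = sorted(v for _, v, _ in stats.instances)
        want = sorted(a["volume_mm3"] for a in truth.ag_instances)
        np.testing.assert_allclose(got, want)

    def test_no_ag_empty_stats(self):
        stats = ps.extract_ag_instances(_lab(np.zeros((4, 4, 4))))
        assert stats.count == 0 and stats.total_volume == 0.0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_touching_cases_against_flood_fill(self, connectivity):
        corner = np.zeros((5, 5, 5), dtype=int)
        corner[0:2, 0:2, 0:2] = 3
        corner[2:4, 2:4, 2:4] = 3       # touch only at the (2,2,2) corner
        face = np.zeros((5, 5, 5), dtype=int)
        face[0:2, :2, :2] = 3
        face[2:4, :2, :2] = 3           # share a face at x=1|2
        for grid in (corner, face):
            stats = ps.extract_ag_instances(_lab(grid), connectivity)
            oracle = flood_fill_components(grid == 3, connectivity)
            assert stats.count == len(oracle)

    def test_random_grids_match_flood_fill(self, rng):
        for _ in range(30):
            grid = (rng.random((3, 3, 3)) < 0.4).astype(int) * 3
            for conn in (6, 26):
                stats = ps.extract_ag_instances(_lab(grid), conn)
                assert stats.count == len(flood_fill_components(grid == 3, conn))

    def test_min_volume_floor(self, small_phantom):
        _, _, lab, truth = small_phantom
        biggest = max(a["volume_mm3"] for a in truth.ag_instances)
        stats = ps.extract_ag_instances(lab, min_volume_mm3=biggest + 1)
        assert stats.count < truth.ag_count


class TestRefineAGTopology:
    def _complex(self):
        """Lumen slab with an embedded AG and a rim speck."""
        data = np.zeros((16, 16, 16), dtype=int)
        data[4:12, 4:12, 4:8] = 1       # lumen
        data[4:12, 4:12, 8:11] = 2      # psd above it
        data[6:9, 6:9, 5:7] = 3         # AG fully inside the lumen
        return data

    def test_embedded_ag_kept(self):
        lab = _lab(self._complex())
        out = ps.refine_ag_topology(lab)
        assert (np.asarray(out.data) == 3).sum() == (np.asarray(lab.data) == 3).sum()

    def test_interface_speck_relabeled_psd(self):
        data = self._complex()
        data[10, 10, 7] = 3     # two-voxel speck straddling the
        data[10, 10, 8] = 3     # lumen-psd interface (~50% lumen ring)
        out = ps.refine_ag_topology(_lab(data))
        assert out.data[10, 10, 7] == 2 and out.data[10, 10, 8] == 2
        assert (np.asarray(out.data) == 3).sum() >= 18   # real AG survives

    def test_relabeling_conserves_foreground(self):
        data = self._complex()
        data[10, 10, 7] = 3
        data[10, 10, 8] = 3
        before = (np.asarray(data) > 0).sum()
        out = ps.refine_ag_topology(_lab(data))
        assert (np.asarray(out.data) > 0).sum() == before

    def test_no_ag_noop(self):
        data = np.zeros((6, 6, 6), dtype=int)
        data[2:4] = 1
        out = ps.refine_ag_topology(_lab(data))
        np.testing.assert_array_equal(out.data, data)


class TestCropMidline:
    def test_inside_30mm_unchanged(self, small_phantom):
        _, _, lab, _ = small_phantom
        out = ps.crop_midline(lab, 30.0)
        np.testing.assert_array_equal(out.data, lab.data)

    def test_voxel_beyond_halfwidth_removed(self):
        data = np.zeros((81, 5, 5), dtype=int)
        data[40, 2, 2] = 2   # world x = 0
        data[71, 2, 2] = 2   # world x = +31 mm with 1 mm spacing, centered
        out = ps.crop_midline(_lab(data), 30.0)
        assert out.data[40, 2, 2] == 2 and out.data[71, 2, 2] == 0

    def test_infinite_halfwidth_identity(self, small_phantom):
        _, _, lab, _ = small_phantom
        out = ps.crop_midline(lab, np.inf)
        np.testing.assert_array_equal(out.data, lab.data)

    def test_native_space_rejected(self):
        lab = _lab(np.zeros((4, 4, 4)), space="native")
        with pytest.raises(ValueError):
            ps.crop_midline(lab)


class TestSubdivide:
    def test_exact_partition(self, small_phantom):
        _, _, lab, truth = small_phantom
        b = RegionBoundaries(truth.central_plane_mm,
                             truth.parieto_occipital_plane_mm)
        regions = ps.subdivide_regions(lab, b)
        total = np.zeros_like(np.asarray(lab.data))
        for r in regions.values():
            assert not ((total > 0) & (np.asarray(r.data) > 0)).any()
            total = total + np.asarray(r.data)
        np.testing.assert_array_equal(total, lab.data)
        for code in (1, 2, 3):
            assert sum(int((np.asarray(r.data) == code).sum())
                       for r in regions.values()) \
                == int((np.asarray(lab.data) == code).sum())

    def test_all_anterior_degenerate(self):
        data = np.zeros((9, 9, 9), dtype=int)
        data[:, 8, :] = 2      # world y = +4 with centered 1 mm grid
        regions = ps.subdivide_regions(_lab(data), RegionBoundaries(0.0, -2.0))
        assert (np.asarray(regions["frontal"].data) == data).all()
        assert not np.asarray(regions["parietal"].data).any()
        assert not np.asarray(regions["occipital"].data).any()

    def test_on_plane_voxel_goes_anterior(self):
        data = np.zeros((5, 5, 5), dtype=int)
        data[2, 2, 2] = 2      # world y = 0 on the centered grid
        regions = ps.subdivide_regions(_lab(data), RegionBoundaries(0.0, -1.0))
        assert regions["frontal"].data[2, 2, 2] == 2

    def test_invalid_boundaries(self):
        with pytest.raises(ValueError):
            RegionBoundaries(-5.0, 5.0)
        with pytest.raises(ValueError):
            RegionBoundaries(5.0, -5.0, midline_halfwidth=0.0)
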