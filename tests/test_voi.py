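import numpy as np
import pytest

from mviradiomics.voi import (
    build_region_set,
    consensus_mask,
    dice,
    expand_region,
    vessel_caliber_filter,
)

from oracles import brute_expand_region


def blob_mask(shape, n_true, seed):
    rng = np.random.default_rng(seed)
    m = np.zeros(shape, bool)
    idx = rng.choice(np.prod(shape), size=n_true, replace=False)
    m.flat[idx] = True
    return m


class TestDice:
    def test_identity(self):
        m = blob_mask((5, 5, 5), 20, 0)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a.flat[:4] = True
        b.flat[2:6] = True
        assert dice(a, b) == pytest.approx(0.5)  # 2*2/(4+4)

    def test_symmetry(self):
        a = blob_mask((6, 6), 10, 1)
        b = blob_mask((6, 6), 12, 2)
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            dice(np.ones((2, 2), bool), np.ones((3, 3), bool))
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool))


class TestConsensus:
    def _pair(self, n_common, n_each):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a.flat[:n_common] = True
        b.flat[:n_common] = True
        a.flat[50 : 50 + n_each] = True
        b.flat[70 : 70 + n_each] = True
        return a, b

    def test_identical_masks_returned_unchanged(self):
        m = blob_mask((6, 6), 12, 3)
        res = consensus_mask(m, m)
        assert res.agreed and np.array_equal(res.mask, m)

    def test_low_dice_flags_disagreement(self):
        a, b = self._pair(17, 3)  # dice = 34/40 = 0.85
        res = consensus_mask(a, b)
        assert res.dice == pytest.approx(0.85)
        assert not res.agreed and res.mask is None

    def test_high_dice_union_rule(self):
        a, b = self._pair(19, 1)  # dice = 38/40 = 0.95
        res = consensus_mask(a, b)
        assert res.agreed
        assert np.array_equal(res.mask, a | b)
        inter = consensus_mask(a, b, rule="intersection")
        assert np.array_equal(inter.mask, a & b)


def straight_tube(shape, radius_vox, axis_pos=None):
    """Axis-aligned tube along x with the given perpendicular radius."""
    m = np.zeros(shape, bool)
    cy, cz = axis_pos or (shape[1] // 2, shape[2] // 2)
    yy, zz = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    disk = (yy - cy) ** 2 + (zz - cz) ** 2 <= radius_vox**2
    m[:, disk] = True
    return m


class TestVesselCaliberFilter:
    def test_thick_tube_retained(self):
        tube = straight_tube((10, 9, 9), 1.5)  # ~3 mm diameter at 1 mm spacing
        out = vessel_caliber_filter(tube, (1, 1, 1), 2.0)
        assert np.array_equal(out, tube)

    def test_thin_tube_removed(self):
        tube = straight_tube((10, 9, 9), 0)  # single-voxel (1 mm) tube
        out = vessel_caliber_filter(tube, (1, 1, 1), 2.0)
        assert not out.any()

    def test_mixed_calibers_filtered_per_component(self):
        thick = straight_tube((10, 20, 20), 1.5, axis_pos=(5, 5))
        thin = straight_tube((10, 20, 20), 0, axis_pos=(15, 15))
        out = vessel_caliber_filter(thick | thin, (1, 1, 1), 2.0)
        assert np.array_equal(out, thick)

    def test_empty_input(self):
        assert not vessel_caliber_filter(np.zeros((4, 4, 4), bool), (1, 1, 1)).any()


class TestExpandRegion:
    def _center_core(self, shape=(9, 9, 9)):
        core = np.zeros(shape, bool)
        core[tuple(s // 2 for s in shape)] = True
        return core

    def test_zero_distance_empty_ring(self):
        core = self._center_core()
        ring = expand_region(core, np.ones_like(core), None, (1, 1, 1), 0)
        assert not ring.any()

    def test_discrete_ball_count(self):
        # 2 mm at 1 mm isotropic spacing: 33-voxel discrete ball minus core
        core = self._center_core()
        ring = expand_region(core, np.ones_like(core), None, (1, 1, 1), 2)
        assert int(ring.sum()) == 32

    def test_barrier_plane_excluded(self):
        core = self._center_core()
        barrier = np.zeros_like(core)
        barrier[5, :, :] = True  # plane one voxel from the core at index 4
        ring = expand_region(core, np.ones_like(core), barrier, (1, 1, 1), 2)
        assert not (ring & barrier).any()
        assert int(ring.sum()) < 32

    def test_anisotropic_spacing_limits_axial_reach(self):
        # 2 mm expansion with 3 mm slices never leaves the core's slice
        core = self._center_core()
        ring = expand_region(core, np.ones_like(core), None, (3, 1, 1), 2)
        assert ring.any()
        assert set(np.argwhere(ring)[:, 0]) == {4}

    def test_geodesic_blocks_propagation_through_barrier(self):
        core = self._center_core((7, 7, 7))
        liver = np.ones_like(core)
        barrier = np.zeros_like(core)
        barrier[4, :, :] = True  # full wall between core slice and beyond
        euclid = expand_region(core, liver, barrier, (1, 1, 1), 3)
        geo = expand_region(core, liver, barrier, (1, 1, 1), 3,
                            method="geodesic")
        # euclidean metric sees through the wall, the geodesic does not
        assert euclid[5].any()
        assert not geo[5:].any()
        assert geo.sum() < euclid.sum()
        assert (geo & ~euclid).sum() == 0

    def test_errors(self):
        core = np.zeros((4, 4, 4), bool)
        with pytest.raises(ValueError, match="empty"):
            expand_region(core, np.ones_like(core), None, (1, 1, 1), 2)
        core[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            expand_region(core, np.zeros_like(core), None, (1, 1, 1), 2)


class TestExpandOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_all_pairs_distance(self, seed):
        """EDT-based expansion equals brute-force all-pairs physical distance,
        with anisotropic spacing and barrier exclusion."""
        rng = np.random.default_rng(seed)
        shape = tuple(int(rng.integers(8, 17)) for _ in range(3))
        spacing = tuple(rng.choice([0.7, 1.0, 1.5, 3.0]) for _ in range(3))
        liver = rng.random(shape) < 0.9
        core = np.zeros(shape, bool)
        c = tuple(s // 2 for s in shape)
        core[c] = True
        core[tuple(min(x + 1, s - 1) for x, s in zip(c, shape))] = True
        liver |= core
        barrier = (rng.random(shape) < 0.05) & ~core
        for dist in (2.0, 4.0, 6.5):
            got = expand_region(core, liver, barrier, spacing, dist)
            want = brute_expand_region(core, liver, barrier, spacing, dist)
            assert np.array_equal(got, want), f"distance {dist}"


@pytest.fixture(scope="module")
def regions():
    shape = (24, 24, 24)
    core = np.zeros(shape, bool)
    core[10:14, 10:14, 10:14] = True
    liver = np.zeros(shape, bool)
    liver[2:22, 2:22, 2:22] = True
    rng = np.random.default_rng(0)
    barrier = (rng.random(shape) < 0.03) & ~core
    return build_region_set(core, liver, barrier, (1.0, 1.0, 1.0)), barrier


class TestRegionSet:

    def test_seven_rings_and_combined(self, regions):
        rs, _ = regions
        assert len(rs.rings) == 7 and len(rs.combined) == 7
        assert rs.distances == (2, 4, 6, 8, 10, 12, 14)

    def test_rings_disjoint_from_core_and_nested(self, regions):
        rs, _ = regions
        sizes = []
        for d, ring in rs.rings.items():
            assert not (ring & rs.core).any()
            sizes.append(int(ring.sum()))
        assert sizes == sorted(sizes)
        assert (rs.rings[2.0] & ~rs.rings[14.0]).sum() == 0  # nesting

    def test_combined_is_disjoint_union(self, regions):
        rs, _ = regions
        for d in rs.distances:
            assert np.array_equal(rs.combined[d], rs.core | rs.rings[d])
            assert int(rs.combined[d].sum()) == int(rs.core.sum()) + int(
                rs.rings[d].sum()
            )

    def test_barrier_soundness(self, regions):
        rs, barrier = regions
        for ring in rs.rings.values():
            assert not (ring & barrier).any()

    def test_region_lookup(self, regions):
        rs, _ = regions
        assert np.array_equal(rs.get("core"), rs.core)
        assert np.array_equal(rs.get("ring:12"), rs.rings[12.0])
        assert np.array_equal(rs.get("combined:12"), rs.combined[12.0])
        with pytest.raises(KeyError):
            rs.get("ring:13")
        ids = rs.region_ids()
        assert len(ids) == 15 and ids[0] == "core"
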