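"""Solvent-shell mask construction and A* surface distances."""

import numpy as np
import pytest

from solvmap.grids import ScalarGrid3D
from solvmap.structure import AtomRecord, MolecularStructure
from solvmap.surface import (
    SurfaceDistanceMatrix,
    TraversableMask,
    build_traversable_mask,
    dijkstra_reference_distance,
    pairwise_surface_distances,
    surface_distance,
)


def single_atom(radius=1.7, position=(0.0, 0.0, 0.0)):
    a = AtomRecord(element="C", position=np.asarray(position, float), chain_id="A",
                   residue_number=1, residue_name="TOY", record_kind="ATOM", radius=radius)
    return MolecularStructure(atoms=[a])


def open_mask(shape=(31, 31, 31), spacing=0.5):
    return TraversableMask(origin=np.zeros(3), spacing=np.full(3, spacing),
                           mask=np.ones(shape, dtype=bool), probe_radius=1.4, shell_max=3.0)


def random_maze_mask(rng, shape=(20, 20, 20), p_open=0.55, spacing=0.5):
    return TraversableMask(origin=np.zeros(3), spacing=np.full(3, spacing),
                           mask=rng.random(shape) < p_open, probe_radius=1.4, shell_max=3.0)


class TestTraversableMask:
    def test_single_atom_band_definition_matches_brute_force(self):
        geometry = ScalarGrid3D(origin=(-8, -8, -8), spacing=0.5, values=np.zeros((33, 33, 33)))
        mask = build_traversable_mask(single_atom(), geometry, probe_radius=1.4, shell_max=3.0)
        centers = geometry.voxel_centers()
        d = np.linalg.norm(centers, axis=1)
        expected = (d >= 3.1) & (d <= 6.1)  # r + probe = 3.1; + shell = 6.1
        np.testing.assert_array_equal(mask.mask.ravel(), expected)

    def test_voxel_inside_atom_not_traversable(self):
        geometry = ScalarGrid3D(origin=(-2, -2, -2), spacing=0.5, values=np.zeros((9, 9, 9)))
        mask = build_traversable_mask(single_atom(), geometry)
        assert not mask.mask[4, 4, 4]  # the voxel at the atom center

    def test_mask_exported_as_binary_grid(self):
        geometry = ScalarGrid3D(origin=(-4, -4, -4), spacing=1.0, values=np.zeros((9, 9, 9)))
        g = build_traversable_mask(single_atom(), geometry).as_grid()
        assert set(np.unique(g.values)) <= {0.0, 1.0}


class TestSurfaceDistance:
    def test_axis_aligned_path_length(self, open_shell_mask):
        d = surface_distance((2.0, 5.0, 5.0), (7.0, 5.0, 5.0), open_shell_mask)
        assert d == pytest.approx(5.0, abs=1e-9)

    def test_diagonal_lattice_metric(self, open_shell_mask):
        # displacement (3, 4, 0) at 0.5 spacing: 6 diagonal + 2 straight steps
        d = surface_distance((2.0, 2.0, 5.0), (5.0, 6.0, 5.0), open_shell_mask)
        expected = 6 * 0.5 * np.sqrt(2) + 2 * 0.5
        assert d == pytest.approx(expected, abs=1e-9)

    def test_identical_snapped_endpoints_give_zero(self, open_shell_mask):
        assert surface_distance((2.0, 2.0, 2.0), (2.1, 2.05, 1.95), open_shell_mask) == 0.0

    def test_endpoint_beyond_snap_max_unreachable(self, open_shell_mask):
        d = surface_distance((-10.0, 0.0, 0.0), (5.0, 5.0, 5.0), open_shell_mask, snap_max=2.0)
        assert np.isinf(d)

    def test_walled_off_region_unreachable(self):
        m = np.ones((11, 11, 11), dtype=bool)
        m[5, :, :] = False  # full wall
        mask = TraversableMask(origin=np.zeros(3), spacing=np.full(3, 0.5), mask=m,
                               probe_radius=1.4, shell_max=3.0)
        assert np.isinf(surface_distance((0.5, 2.5, 2.5), (5.0, 2.5, 2.5), mask, snap_max=0.4))

    def test_astar_equals_dijkstra_on_random_mazes(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            mask = random_maze_mask(rng)
            open_idx = np.argwhere(mask.mask)
            a, b = open_idx[rng.integers(len(open_idx))], open_idx[rng.integers(len(open_idx))]
            pa, pb = a * 0.5, b * 0.5
            d_astar = surface_distance(pa, pb, mask, snap_max=0.1)
            d_ref = dijkstra_reference_distance(pa, pb, mask, snap_max=0.1)
            if np.isinf(d_ref):
                assert np.isinf(d_astar)
            else:
                assert d_astar == pytest.approx(d_ref, abs=1e-9)

    def test_surface_distance_at_least_euclidean(self):
        rng = np.random.default_rng(3)
        mask = random_maze_mask(rng, p_open=0.7)
        open_idx = np.argwhere(mask.mask)
        for _ in range(20):
            a = open_idx[rng.integers(len(open_idx))] * 0.5
            b = open_idx[rng.integers(len(open_idx))] * 0.5
            d = surface_distance(a, b, mask, snap_max=0.1)
            if np.isfinite(d):
                assert d >= np.linalg.norm(a - b) - 1e-9

    def test_shrinking_shell_never_shortens_paths(self):
        structure = single_atom()
        geometry = ScalarGrid3D(origin=(-8, -8, -8), spacing=0.5, values=np.zeros((33, 33, 33)))
        wide = build_traversable_mask(structure, geometry, shell_max=3.0)
        narrow = build_traversable_mask(structure, geometry, shell_max=1.0)
        a, b = np.array([3.5, 0.0, 0.0]), np.array([-3.5, 0.0, 0.0])
        d_wide = surface_distance(a, b, wide)
        d_narrow = surface_distance(a, b, narrow)
        assert d_narrow >= d_wide - 1e-9

    def test_rigid_translation_invariance(self):
        shift = np.array([3.7, -2.1, 5.4])
        geometry = ScalarGrid3D(origin=(-7, -7, -7), spacing=0.5, values=np.zeros((29, 29, 29)))
        geometry2 = ScalarGrid3D(origin=geometry.origin + shift, spacing=0.5,
                                 values=np.zeros((29, 29, 29)))
        m1 = build_traversable_mask(single_atom(), geometry)
        m2 = build_traversable_mask(single_atom(position=shift), geometry2)
        a, b = np.array([3.5, 0.0, 0.0]), np.array([0.0, 3.5, 0.0])
        assert surface_distance(a, b, m1) == pytest.approx(
            surface_distance(a + shift, b + shift, m2), abs=1e-9
        )


class TestPairwiseDistances:
    class FakeHotspot:
        def __init__(self, hid, position):
            self.id = hid
            self.position = np.asarray(position, float)

    def test_single_conformation_matches_direct_astar(self, open_shell_mask):
        hs = [self.FakeHotspot(0, (2, 2, 2)), self.FakeHotspot(1, (7, 2, 2)),
              self.FakeHotspot(2, (2, 7, 2))]
        dmat = pairwise_surface_distances(hs, [open_shell_mask])
        for i in range(3):
            for j in range(i + 1, 3):
                expected = surface_distance(hs[i].position, hs[j].position, open_shell_mask)
                assert dmat.distances[i, j] == pytest.approx(expected, abs=1e-9)

    def test_conformation_opening_a_wall_takes_minimum(self):
        walled = np.ones((21, 21, 11), dtype=bool)
        walled[10, :, :] = False
        open_m = np.ones((21, 21, 11), dtype=bool)
        kw = dict(origin=np.zeros(3), spacing=np.full(3, 0.5), probe_radius=1.4, shell_max=3.0)
        mask_wall = TraversableMask(mask=walled, **kw)
        mask_open = TraversableMask(mask=open_m, **kw)
        hs = [self.FakeHotspot(0, (1.0, 2.5, 2.5)), self.FakeHotspot(1, (9.0, 2.5, 2.5))]
        closed_d = pairwise_surface_distances(hs, [mask_wall], snap_max=0.4).distances[0, 1]
        combined = pairwise_surface_distances(hs, [mask_wall, mask_open], snap_max=0.4)
        open_d = pairwise_surface_distances(hs, [mask_open], snap_max=0.4).distances[0, 1]
        assert np.isinf(closed_d)
        assert combined.distances[0, 1] == pytest.approx(open_d, abs=1e-9)

    def test_unreachable_everywhere_is_inf(self, open_shell_mask):
        hs = [self.FakeHotspot(0, (2, 2, 2)), self.FakeHotspot(1, (200.0, 0.0, 0.0))]
        dmat = pairwise_surface_distances(hs, [open_shell_mask])
        assert np.isinf(dmat.distances[0, 1])

    def test_horizon_reports_far_pairs_as_inf_but_near_exact(self, open_shell_mask):
        hs = [self.FakeHotspot(0, (2, 2, 2)), self.FakeHotspot(1, (4, 2, 2)),
              self.FakeHotspot(2, (13, 13, 13))]
        dmat = pairwise_surface_distances(hs, [open_shell_mask], max_distance=5.0)
        assert dmat.distances[0, 1] == pytest.approx(2.0, abs=1e-9)
        assert np.isinf(dmat.distances[0, 2])

    def test_matrix_invariants(self, open_shell_mask):
        hs = [self.FakeHotspot(i, (2 + 2 * i, 3, 3)) for i in range(4)]
        dmat = pairwise_surface_distances(hs, [open_shell_mask])
        assert np.allclose(np.diag(dmat.distances), 0)
        assert np.allclose(dmat.distances, dmat.distances.T)
        d = dmat.distances
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    if np.isfinite(d[i, j]) and np.isfinite(d[j, k]):
                        assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_tsv_export(self, open_shell_mask, tmp_path):
        hs = [self.FakeHotspot(0, (2, 2, 2)), self.FakeHotspot(1, (7, 2, 2))]
        dmat = pairwise_surface_distances(hs, [open_shell_mask])
        p = tmp_path / "d.tsv"
        dmat.to_tsv(p)
        lines = p.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["hotspot_id_a", "hotspot_id_b", "distance_A"]
        assert len(lines) == 2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            SurfaceDistanceMatrix(ids=[0, 1], distances=np.array([[0.0, 1.0], [2.0, 0.0]]))
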