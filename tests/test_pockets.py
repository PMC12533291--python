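"""Pocket assembly, volume estimation, ligandability filters and ranking."""

import numpy as np
import pytest

from solvmap.hotspots import Hotspot
from solvmap.pockets import (
    AssemblyConfig,
    PocketCandidate,
    apply_filters,
    assemble_pockets,
    buriedness,
    pocket_report,
    pocket_volume,
    rank_pockets,
    summarize_screen,
)
from solvmap.structure import AtomRecord, MolecularStructure
from solvmap.surface import SurfaceDistanceMatrix


def hotspot(hid, position, energy=-2.0, channel="hydrophobic"):
    return Hotspot(id=hid, channel=channel, position=np.asarray(position, float),
                   energy=energy, n_voxels=3, voxel_indices=[])


def dmat_from_positions(hotspots, far=100.0):
    """Distance matrix using Euclidean distances (adequate for rule tests)."""
    n = len(hotspots)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.linalg.norm(hotspots[i].position - hotspots[j].position)
    return SurfaceDistanceMatrix(ids=[h.id for h in hotspots], distances=d)


def carbon_structure(positions):
    atoms = [
        AtomRecord(element="C", position=np.asarray(p, float), chain_id="A",
                   residue_number=i + 1, residue_name="TOY", record_kind="ATOM", radius=1.7)
        for i, p in enumerate(positions)
    ]
    return MolecularStructure(atoms=atoms)


class TestAssembly:
    def test_chain_of_four_within_link_distance_forms_one_candidate(self):
        hs = [hotspot(i, (5.0 * i, 0, 0)) for i in range(4)]
        cands = assemble_pockets(hs, dmat_from_positions(hs))
        assert len(cands) == 1
        assert cands[0].hotspot_ids == [0, 1, 2, 3]

    def test_three_mutually_close_hotspots_below_density_rule(self):
        hs = [hotspot(i, (2.0 * i, 0, 0)) for i in range(3)]
        assert assemble_pockets(hs, dmat_from_positions(hs)) == []

    def test_gap_above_link_distance_splits_components(self):
        hs = [hotspot(i, (5.0 * i, 0, 0)) for i in range(4)]
        hs += [hotspot(4 + i, (40.0 + 5.0 * i, 0, 0)) for i in range(4)]
        cands = assemble_pockets(hs, dmat_from_positions(hs))
        assert [c.hotspot_ids for c in cands] == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_merge_accepted_within_volume_cap_and_rejected_above(self):
        # two 4-hotspot clusters, inter-cluster distance 7 A (merge-eligible)
        hs = [hotspot(i, (3.0 * i, 0, 0)) for i in range(4)]  # spans 0..9
        hs += [hotspot(4 + i, (16.0 + 3.0 * i, 0, 0)) for i in range(4)]  # 16..25
        cfg_loose = AssemblyConfig(volume_cap=400.0)
        merged = assemble_pockets(hs, dmat_from_positions(hs), cfg_loose)
        assert len(merged) == 1 and merged[0].hotspot_ids == list(range(8))
        assert merged[0].merged_from == [[0, 1, 2, 3], [4, 5, 6, 7]]
        cfg_tight = AssemblyConfig(volume_cap=230.0)
        unmerged = assemble_pockets(hs, dmat_from_positions(hs), cfg_tight)
        assert len(unmerged) == 2

    def test_oversized_component_split_rejected(self):
        hs = [hotspot(i, (5.0 * i, 0, 0)) for i in range(10)]  # 50 A chain
        cands = assemble_pockets(hs, dmat_from_positions(hs), AssemblyConfig(volume_cap=200.0))
        assert cands == []

    def test_merging_preserves_total_hotspot_count_and_dg_sum(self):
        hs = [hotspot(i, (3.0 * i, 0, 0), energy=-1.0 - 0.1 * i) for i in range(4)]
        hs += [hotspot(4 + i, (16.0 + 3.0 * i, 0, 0), energy=-2.0) for i in range(4)]
        (cand,) = assemble_pockets(hs, dmat_from_positions(hs), AssemblyConfig(volume_cap=400.0))
        assert len(cand.hotspots) == 8
        structure = carbon_structure([(0, 0, -50)])
        pocket = apply_filters(cand, structure)
        assert pocket.dg_sum == pytest.approx(sum(h.energy for h in hs))

    def test_assembly_invariant_to_input_order(self):
        hs = [hotspot(i, (4.0 * i, 0, 0)) for i in range(5)]
        a = assemble_pockets(hs, dmat_from_positions(hs))
        b = assemble_pockets(list(reversed(hs)), dmat_from_positions(hs))
        assert [c.hotspot_ids for c in a] == [c.hotspot_ids for c in b]

    def test_missing_ids_in_matrix_raise(self):
        hs = [hotspot(i, (i, 0, 0)) for i in range(4)]
        dmat = dmat_from_positions(hs[:3])
        with pytest.raises(ValueError, match="cover"):
            assemble_pockets(hs, dmat)


class TestPocketVolume:
    def test_single_sphere_matches_analytic(self):
        v = pocket_volume([(0.0, 0.0, 0.0)], sphere_radius=2.0, spacing=0.25)
        assert v == pytest.approx(4 / 3 * np.pi * 8, abs=2.0)

    def test_coincident_spheres_count_once(self):
        v1 = pocket_volume([(0, 0, 0)], 2.0, 0.25)
        v2 = pocket_volume([(0, 0, 0), (0, 0, 0)], 2.0, 0.25)
        assert v2 == v1

    def test_disjoint_spheres_add(self):
        v = pocket_volume([(0, 0, 0), (100.0, 0, 0)], 2.0, 0.25)
        assert v == pytest.approx(2 * 4 / 3 * np.pi * 8, abs=4.0)

    def test_translation_with_anchor_is_invariant(self):
        shift = np.array([13.2, -4.4, 8.8])
        v1 = pocket_volume([(0, 0, 0), (2, 1, 0)], 2.0, 0.25, origin=(0, 0, 0))
        v2 = pocket_volume([shift, shift + (2, 1, 0)], 2.0, 0.25, origin=shift)
        assert v1 == v2

    def test_empty_input_is_zero(self):
        assert pocket_volume(np.empty((0, 3)), 2.0) == 0.0


class TestFilters:
    def _candidate(self, channels, positions=None):
        positions = positions or [(i * 2.0, 0, 0) for i in range(len(channels))]
        hs = [hotspot(i, p, channel=c) for i, (p, c) in enumerate(zip(positions, channels))]
        return PocketCandidate(hotspots=hs, volume=100.0)

    def test_single_channel_pocket_fails_polarity(self):
        cand = self._candidate(["hydrophobic"] * 4)
        pocket = apply_filters(cand, carbon_structure([(0, 0, -50)]))
        assert not pocket.passed_polarity

    def test_balanced_pocket_passes_polarity(self):
        cand = self._candidate(["hydrophobic", "hydrophobic", "polar", "polar"])
        pocket = apply_filters(cand, carbon_structure([(0, 0, -50)]))
        assert pocket.passed_polarity

    def test_minority_fraction_below_threshold_fails(self):
        cand = self._candidate(["hydrophobic"] * 9 + ["polar"])  # minority 0.1 < 0.2
        pocket = apply_filters(cand, carbon_structure([(0, 0, -50)]))
        assert not pocket.passed_polarity

    def test_centroid_in_open_space_has_zero_buriedness(self):
        cand = self._candidate(["hydrophobic", "polar", "hydrophobic", "polar"])
        pocket = apply_filters(cand, carbon_structure([(0, 0, -100.0)]))
        assert pocket.buriedness == 0.0
        assert not pocket.passed_geometry

    def test_hemispherical_cavity_passes_and_matches_ray_oracle(self):
        # wall of atoms on the lower hemisphere of radius 5 around the centroid
        rng = np.random.default_rng(11)
        pts = []
        while len(pts) < 400:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if v[2] < -0.05:
                pts.append(5.0 * v)
        structure = carbon_structure(pts)
        channels = ["hydrophobic", "hydrophobic", "polar", "polar"]
        positions = [(0.2, 0, 0), (-0.2, 0, 0), (0, 0.2, 0), (0, -0.2, 0)]
        pocket = apply_filters(self._candidate(channels, positions), structure)
        assert pocket.passed_polarity and pocket.passed_geometry

        # independent brute-force ray casting: sample points along each ray
        from solvmap.pockets import _fibonacci_sphere

        dirs = _fibonacci_sphere(146)
        coords, radii = structure.coordinates, structure.radii
        hits = 0
        for u in dirs:
            ts = np.linspace(0.0, 8.0, 400)
            pts_on_ray = pocket.centroid + ts[:, None] * u
            d = np.linalg.norm(pts_on_ray[:, None, :] - coords[None, :, :], axis=2)
            if np.any(d <= radii[None, :]):
                hits += 1
        assert pocket.buriedness == pytest.approx(hits / 146, abs=0.05)

    def test_buriedness_approaches_one_inside_closed_cavity(self):
        rng = np.random.default_rng(13)
        pts = []
        while len(pts) < 500:
            v = rng.normal(size=3)
            pts.append(4.0 * v / np.linalg.norm(v))
        assert buriedness((0, 0, 0), carbon_structure(pts)) > 0.9


class TestRanking:
    def _pocket(self, energies, start_id=0, channels=None):
        channels = channels or ["hydrophobic", "polar"] * (len(energies) // 2 + 1)
        hs = [hotspot(start_id + i, (start_id * 50.0 + 2.0 * i, 0, 0), energy=e, channel=c)
              for i, (e, c) in enumerate(zip(energies, channels))]
        cand = PocketCandidate(hotspots=hs, volume=100.0)
        return apply_filters(cand, carbon_structure([(0, 0, -50)]))

    def test_sum_and_efficiency(self):
        p = self._pocket([-2.0, -2.0, -2.0, -2.0])
        assert p.dg_sum == pytest.approx(-8.0)
        assert p.efficiency == pytest.approx(-2.0)

    def test_most_negative_sum_ranks_first(self):
        deep = self._pocket([-2.2, -2.2, -2.2, -2.2], start_id=0)  # -8.8
        shallow = self._pocket([-1.325, -1.325, -1.325, -1.325], start_id=10)  # -5.3
        ranked = rank_pockets([shallow, deep])
        assert ranked[0].dg_sum == pytest.approx(-8.8)
        assert [p.label for p in ranked] == ["A", "B"]

    def test_equal_sums_better_efficiency_first(self):
        small = self._pocket([-2.0, -2.0, -2.0, -2.0], start_id=0)  # -8, eff -2
        big = self._pocket([-1.0] * 8, start_id=10)  # -8, eff -1
        ranked = rank_pockets([big, small])
        assert ranked[0].hotspot_ids == small.hotspot_ids

    def test_rank_invariant_to_input_order(self):
        ps = [self._pocket([-1.0 - 0.2 * k] * 4, start_id=10 * k) for k in range(4)]
        labels_fwd = [(p.label, tuple(p.hotspot_ids)) for p in rank_pockets(list(ps))]
        labels_rev = [(p.label, tuple(p.hotspot_ids)) for p in rank_pockets(list(reversed(ps)))]
        assert labels_fwd == labels_rev

    def test_merged_efficiency_between_parts(self):
        hs_a = [hotspot(i, (3.0 * i, 0, 0), energy=-2.0) for i in range(4)]
        hs_b = [hotspot(4 + i, (16.0 + 3.0 * i, 0, 0), energy=-1.0) for i in range(4)]
        (cand,) = assemble_pockets(hs_a + hs_b, dmat_from_positions(hs_a + hs_b),
                                   AssemblyConfig(volume_cap=400.0))
        pocket = apply_filters(cand, carbon_structure([(0, 0, -50)]))
        assert -2.0 <= pocket.efficiency <= -1.0


class TestReportAndScreen:
    def test_report_round_trip_to_three_decimals(self, tmp_path):
        import pandas as pd

        hs = [hotspot(i, (4.0 * i, 0, 0), energy=-1.234567, channel="polar" if i % 2 else "hydrophobic")
              for i in range(4)]
        cand = PocketCandidate(hotspots=hs, volume=123.456789)
        pocket = rank_pockets([apply_filters(cand, carbon_structure([(0, 0, -50)]))])[0]
        p = tmp_path / "pockets.tsv"
        pocket_report([pocket], p)
        df = pd.read_csv(p, sep="\t")
        assert df.shape[0] == 1
        assert df.loc[0, "dg_sum"] == pytest.approx(round(pocket.dg_sum, 3), abs=1e-9)
        assert df.loc[0, "volume"] == pytest.approx(round(pocket.volume, 3), abs=1e-9)

    def test_empty_report_is_header_only(self, tmp_path):
        p = tmp_path / "empty.tsv"
        pocket_report([], p)
        assert len(p.read_text().strip().splitlines()) == 1

    @pytest.mark.parametrize("tested,positive,expected", [(41, 9, 22), (10, 0, 0), (4, 4, 100)])
    def test_screen_hit_rate(self, tested, positive, expected):
        assert summarize_screen(tested, positive) == expected

    def test_screen_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            summarize_screen(0, 0)
        with pytest.raises(ValueError):
            summarize_screen(5, 6)
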