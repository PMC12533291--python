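"""Shared fixtures: synthetic systems and their analysis products.

The expensive fixtures (generated occupancy systems and their full analysis)
are session-scoped so every test module reuses one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from solvmap.grids import occupancy_to_energy
from solvmap.hotspots import Hotspot, extract_hotspots
from solvmap.pockets import AssemblyConfig, Pocket, apply_filters, assemble_pockets, rank_pockets
from solvmap.surface import TraversableMask, build_traversable_mask, pairwise_surface_distances
from solvmap.synthetic import (
    single_site_system,
    triple_cluster_system,
    two_pocket_system,
)

TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

PDB_WITH_WATERS = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
HETATM    4  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
HETATM    5  O   HOH A 102       6.000   5.000   5.000  1.00  0.00           O
HETATM    6  O   HOH A 103       7.000   5.000   5.000  1.00  0.00           O
HETATM    7  O   HOH A 104       8.000   5.000   5.000  1.00  0.00           O
HETATM    8  O   HOH A 105       9.000   5.000   5.000  1.00  0.00           O
END
"""


@dataclass
class AnalyzedSystem:
    """A synthetic system plus every intermediate analysis product."""

    system: object
    hotspots: list[Hotspot]
    mask: TraversableMask
    dmat: object
    candidates: list
    pockets: list[Pocket]
    geometry: object
    cfg: AssemblyConfig


def analyze(system, cfg: AssemblyConfig | None = None, max_distance: float = 12.0) -> AnalyzedSystem:
    """Run the in-memory analysis chain on a synthetic system."""
    cfg = cfg or AssemblyConfig()
    hotspots: list[Hotspot] = []
    for channel in ("polar", "hydrophobic"):
        energy = occupancy_to_energy(system.occupancy[channel])
        hotspots.extend(extract_hotspots(energy, id_start=len(hotspots)))
    geometry = system.occupancy["polar"].grid
    mask = build_traversable_mask(system.structure, geometry)
    dmat = pairwise_surface_distances(hotspots, [mask], max_distance=max_distance)
    candidates = assemble_pockets(hotspots, dmat, cfg, geometry)
    pockets = rank_pockets([apply_filters(c, system.structure, cfg) for c in candidates])
    return AnalyzedSystem(
        system=system,
        hotspots=hotspots,
        mask=mask,
        dmat=dmat,
        candidates=candidates,
        pockets=pockets,
        geometry=geometry,
        cfg=cfg,
    )


@pytest.fixture(scope="session")
def two_pocket_analysis() -> AnalyzedSystem:
    return analyze(two_pocket_system(seed=7))


@pytest.fixture(scope="session")
def triple_cluster_analysis() -> AnalyzedSystem:
    return analyze(triple_cluster_system(seed=3))


@pytest.fixture(scope="session")
def single_site() -> tuple:
    system = single_site_system(seed=1)
    energy = occupancy_to_energy(system.occupancy["hydrophobic"])
    hotspots = sorted(extract_hotspots(energy), key=lambda h: h.energy)
    return system, hotspots


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def waters_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(PDB_WITH_WATERS)
    return p


@pytest.fixture(scope="session")
def open_shell_mask():
    """A fully traversable 0.5 Å lattice (no protein) for path geometry."""
    shape = (31, 31, 31)
    return TraversableMask(
        origin=np.zeros(3),
        spacing=np.full(3, 0.5),
        mask=np.ones(shape, dtype=bool),
        probe_radius=1.4,
        shell_max=3.0,
    )
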