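"""Hotspot extraction: top-fraction voxel selection and spatial clustering.

The most favorable fraction of voxels (default: top 0.02 % per channel,
most-negative ΔG first) is partitioned into 26-connected components; each
component of at least ``min_voxels`` voxels becomes a discrete interaction
hotspot whose energy is the Boltzmann average of its member voxels and whose
position is their Boltzmann-weighted centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import R_KCAL, DEFAULT_TEMPERATURE_K
from .grids import EnergyGrid, boltzmann_average

__all__ = ["Hotspot", "extract_hotspots", "write_hotspots_pdb", "write_hotspots_tsv", "read_hotspots_tsv"]

#: residue names used when hotspots are written as PDB pseudo-atoms
_CHANNEL_RESNAME = {"polar": "POL", "hydrophobic": "HYD"}
_RESNAME_CHANNEL = {v: k for k, v in _CHANNEL_RESNAME.items()}


@dataclass
class Hotspot:
    """A clustered favorable region of one probe channel."""

    id: int
    channel: str
    position: np.ndarray
    energy: float  # kcal/mol, Boltzmann average over member voxels
    n_voxels: int
    voxel_indices: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.energy >= 0:
            raise ValueError(f"hotspot energy must be favorable (< 0), got {self.energy}")
        if self.n_voxels < 1:
            raise ValueError("hotspot must contain at least one voxel")


def select_top_voxels(energy: EnergyGrid, top_fraction: float) -> np.ndarray:
    """Boolean mask of exactly ceil(top_fraction · n_voxels) voxels.

    Selection is by most-negative energy; ties at the threshold are broken
    deterministically by lower flat (C-order) index.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    values = energy.grid.values.ravel()
    n_select = math.ceil(top_fraction * values.size)
    order = np.argsort(values, kind="stable")  # stable sort ⇒ ties by flat index
    mask = np.zeros(values.size, dtype=bool)
    mask[order[:n_select]] = True
    return mask.reshape(energy.grid.shape)


def extract_hotspots(
    energy: EnergyGrid,
    top_fraction: float = 2e-4,
    min_voxels: int = 1,
    temperature_K: float | None = None,
    id_start: int = 0,
) -> list[Hotspot]:
    """Extract hotspots from one channel's energy grid.

    The top ``top_fraction`` of voxels is selected (ceiling rule, ties by
    flat index), split into 26-connected components, and components with at
    least ``min_voxels`` voxels — and a favorable Boltzmann-averaged
    energy — become hotspots, sorted by energy ascending. Ids are assigned
    ``id_start, id_start+1, …`` in that order, letting a caller keep ids
    globally unique across channels.

    Raises
    ------
    ValueError
        If the grid contains no favorable (ΔG < 0) voxel at all.
    """
    if temperature_K is None:
        temperature_K = energy.temperature_K
    if not np.any(energy.grid.values < 0):
        raise ValueError("energy grid has no favorable voxels (all at/above zero)")
    selected = select_top_voxels(energy, top_fraction)
    labels, n_components = ndimage.label(selected, structure=np.ones((3, 3, 3), dtype=int))
    rt = R_KCAL * temperature_K

    hotspots: list[Hotspot] = []
    values = energy.grid.values
    for comp in range(1, n_components + 1):
        idx = np.argwhere(labels == comp)
        if idx.shape[0] < min_voxels:
            continue
        e = values[idx[:, 0], idx[:, 1], idx[:, 2]]
        avg = boltzmann_average(e, temperature_K)
        if avg >= 0:
            continue  # background-level component, not a favorable site
        w = np.exp(-(e - e.min()) / rt)
        centers = energy.grid.origin + idx * energy.grid.spacing
        position = (centers * w[:, None]).sum(axis=0) / w.sum()
        hotspots.append(
            Hotspot(
                id=-1,
                channel=energy.channel,
                position=position,
                energy=float(avg),
                n_voxels=int(idx.shape[0]),
                voxel_indices=[tuple(map(int, i)) for i in idx],
            )
        )
    hotspots.sort(key=lambda h: (h.energy, h.position[0], h.position[1], h.position[2]))
    for i, h in enumerate(hotspots):
        h.id = id_start + i
    return hotspots


def write_hotspots_pdb(hotspots: list[Hotspot], path) -> None:
    """Write hotspots as HETATM pseudo-atoms for visualization.

    Occupancy column carries the voxel count (capped at the 999.99 field
    limit), the B-factor column the hotspot energy; polar and hydrophobic
    hotspots are distinguished by residue names POL and HYD.
    """
    if not hotspots:
        raise ValueError("no hotspots to write")
    with open(path, "w") as fh:
        for h in hotspots:
            resname = _CHANNEL_RESNAME[h.channel]
            occ = min(float(h.n_voxels), 999.99)
            fh.write(
                "HETATM%5d %4s %3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
                % (
                    (h.id + 1) % 100000,
                    " C  ",
                    resname,
                    "X",
                    (h.id + 1) % 10000,
                    h.position[0],
                    h.position[1],
                    h.position[2],
                    occ,
                    h.energy,
                    " C",
                )
            )
        fh.write("END\n")


def write_hotspots_tsv(hotspots: list[Hotspot], path) -> None:
    """Tabular hotspot export (id, channel, x, y, z, energy, n_voxels)."""
    df = pd.DataFrame(
        {
            "id": [h.id for h in hotspots],
            "channel": [h.channel for h in hotspots],
            "x": [round(h.position[0], 3) for h in hotspots],
            "y": [round(h.position[1], 3) for h in hotspots],
            "z": [round(h.position[2], 3) for h in hotspots],
            "energy": [round(h.energy, 4) for h in hotspots],
            "n_voxels": [h.n_voxels for h in hotspots],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_hotspots_tsv(path) -> list[Hotspot]:
    """Read a hotspot table written by :func:`write_hotspots_tsv`.

    Voxel membership is not stored in the table; ``voxel_indices`` comes
    back empty.
    """
    df = pd.read_csv(path, sep="\t")
    return [
        Hotspot(
            id=int(r.id),
            channel=str(r.channel),
            position=np.array([r.x, r.y, r.z]),
            energy=float(r.energy),
            n_voxels=int(r.n_voxels),
            voxel_indices=[],
        )
        for r in df.itertuples()
    ]
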