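"""Pharmacophore restraint and docking-cavity export.

A pocket's strongest hotspots per channel become restraint features for
pharmacophore-guided docking: polar (hydroxyl-derived) hotspots carry a
0.5 Å tolerance, hydrophobic (alkyl-derived) ones 1.0 Å. The docking cavity
is defined by reference point(s) with an 8 Å radius around the hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import R_KCAL, DEFAULT_TEMPERATURE_K
from .hotspots import Hotspot
from .pockets import Pocket

__all__ = [
    "PharmacophoreFeature",
    "CavityDefinition",
    "pocket_to_pharmacophores",
    "write_docking_prep",
    "read_restraints",
]

POLAR_TOLERANCE = 0.5
HYDROPHOBIC_TOLERANCE = 1.0
DEFAULT_CAVITY_RADIUS = 8.0

_FEATURE_TYPES = ("Don", "Acc", "Any", "Hyd")


@dataclass
class PharmacophoreFeature:
    """One exported restraint point."""

    position: np.ndarray
    feature_type: str  # Don | Acc | Any | Hyd
    tolerance: float
    source_hotspot_id: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.feature_type not in _FEATURE_TYPES:
            raise ValueError(f"feature_type must be one of {_FEATURE_TYPES}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class CavityDefinition:
    """Docking cavity: reference center(s) plus an inclusion radius."""

    centers: np.ndarray  # (n, 3)
    radius: float = DEFAULT_CAVITY_RADIUS

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.radius <= 0:
            raise ValueError("cavity radius must be positive")


def pocket_to_pharmacophores(
    pocket: Pocket,
    hotspots: Sequence[Hotspot],
    k_per_channel: int = 2,
    polar_mode: str = "Any",
    polar_tolerance: float = POLAR_TOLERANCE,
    hydrophobic_tolerance: float = HYDROPHOBIC_TOLERANCE,
) -> list[PharmacophoreFeature]:
    """Convert a pocket's strongest hotspots into restraint features.

    The ``k_per_channel`` most favorable hotspots of each channel become
    features, ordered by (energy, id). The polar probe (a hydroxyl) is both
    donor and acceptor, so polar features default to type "Any"; pass
    ``polar_mode`` = "Don" or "Acc" to force a direction.
    """
    if polar_mode not in ("Don", "Acc", "Any"):
        raise ValueError("polar_mode must be 'Don', 'Acc' or 'Any'")
    members = sorted(
        (h for h in hotspots if h.id in set(pocket.hotspot_ids)),
        key=lambda h: (h.energy, h.id),
    )
    if not members:
        raise ValueError("pocket has no hotspots to export")
    features: list[PharmacophoreFeature] = []
    for channel, ftype, tol in (
        ("polar", polar_mode, polar_tolerance),
        ("hydrophobic", "Hyd", hydrophobic_tolerance),
    ):
        for h in [h for h in members if h.channel == channel][:k_per_channel]:
            features.append(
                PharmacophoreFeature(
                    position=h.position, feature_type=ftype, tolerance=tol, source_hotspot_id=h.id
                )
            )
    return features


def cavity_from_pocket(
    pocket: Pocket,
    hotspots: Sequence[Hotspot],
    radius: float = DEFAULT_CAVITY_RADIUS,
    per_hotspot: bool = False,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> CavityDefinition:
    """Docking cavity for a pocket.

    By default a single reference point at the Boltzmann-weighted hotspot
    centroid; with ``per_hotspot`` every member hotspot becomes a reference
    point (radius applies around each).
    """
    members = [h for h in hotspots if h.id in set(pocket.hotspot_ids)]
    if not members:
        raise ValueError("pocket has no hotspots")
    if per_hotspot:
        centers = np.array([h.position for h in members])
    else:
        e = np.array([h.energy for h in members])
        w = np.exp(-(e - e.min()) / (R_KCAL * temperature_K))
        pos = np.array([h.position for h in members])
        centers = ((pos * w[:, None]).sum(axis=0) / w.sum())[None, :]
    return CavityDefinition(centers=centers, radius=radius)


def write_docking_prep(
    features: Sequence[PharmacophoreFeature],
    cavity: CavityDefinition,
    out_dir,
    stem: str = "pocket",
) -> tuple[Path, Path]:
    """Write the restraint and cavity files for one pocket.

    Restraint file: one feature per line, ``x y z tolerance type`` with
    fixed 3-decimal coordinates. Cavity file: one reference center per
    line, then the inclusion radius. Both are byte-stable across reruns.
    Returns (restraints path, cavity path).
    """
    if not features:
        raise ValueError("no pharmacophore features to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    restraints = out_dir / f"{stem}_restraints.txt"
    with open(restraints, "w") as fh:
        for f in features:
            fh.write(
                "%.3f %.3f %.3f %.3f %s\n"
                % (f.position[0], f.position[1], f.position[2], f.tolerance, f.feature_type)
            )
    cavity_path = out_dir / f"{stem}_cavity.txt"
    with open(cavity_path, "w") as fh:
        for c in cavity.centers:
            fh.write("CENTER %.3f %.3f %.3f\n" % (c[0], c[1], c[2]))
        fh.write("RADIUS %.3f\n" % cavity.radius)
    return restraints, cavity_path


def read_restraints(path) -> list[PharmacophoreFeature]:
    """Parse a restraint file written by :func:`write_docking_prep`."""
    features = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        x, y, z, tol = map(float, parts[:4])
        features.append(
            PharmacophoreFeature(
                position=np.array([x, y, z]), feature_type=parts[4], tolerance=tol, source_hotspot_id=-1
            )
        )
    return features
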