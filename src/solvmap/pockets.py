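"""Pocket assembly: surface-distance clustering of hotspots, volume-capped
merging, ligandability filters and energy ranking.

Stage 1 links hotspots whose surface distance is at most ``link_distance``
(default 6 Å) and keeps connected components with at least ``min_density``
hotspots (default 4). Stage 2 greedily merges nearby candidates in
ascending inter-candidate distance, accepting a merge only while the merged
union-of-spheres volume stays within ``volume_cap`` (default 500 ų).
Candidates then pass two ligandability filters — polar/hydrophobic balance
and ray-casting buriedness — and are ranked by summed hotspot energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .constants import R_KCAL, DEFAULT_TEMPERATURE_K
from .grids import ScalarGrid3D
from .hotspots import Hotspot
from .structure import MolecularStructure
from .surface import SurfaceDistanceMatrix

__all__ = [
    "AssemblyConfig",
    "PocketCandidate",
    "Pocket",
    "assemble_pockets",
    "pocket_volume",
    "apply_filters",
    "rank_pockets",
    "pocket_report",
    "summarize_screen",
]


@dataclass
class AssemblyConfig:
    """Tunable parameters of pocket assembly and filtering.

    Distances in Å, volumes in ų. The link distance, minimum density and
    volume cap are the method's published operating point; the remainder
    parameterize steps the method leaves open (merge eligibility, volume
    estimation, what counts as balanced or buried).
    """

    link_distance: float = 6.0
    min_density: int = 4
    volume_cap: float = 500.0
    merge_distance: float = 8.0
    sphere_radius: float = 2.0
    polarity_min_fraction: float = 0.2
    buriedness_threshold: float = 0.5
    ray_count: int = 146
    ray_reach: float = 8.0

    def __post_init__(self) -> None:
        numeric = {
            "link_distance": self.link_distance,
            "min_density": self.min_density,
            "volume_cap": self.volume_cap,
            "merge_distance": self.merge_distance,
            "sphere_radius": self.sphere_radius,
            "buriedness_threshold": self.buriedness_threshold,
            "ray_count": self.ray_count,
            "ray_reach": self.ray_reach,
        }
        for name, v in numeric.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 <= self.polarity_min_fraction <= 0.5:
            raise ValueError("polarity_min_fraction must be in [0, 0.5]")


@dataclass
class PocketCandidate:
    """A linked hotspot group before filtering; tracks merge provenance."""

    hotspots: list[Hotspot]
    volume: float
    merged_from: list[list[int]] = field(default_factory=list)

    @property
    def hotspot_ids(self) -> list[int]:
        return sorted(h.id for h in self.hotspots)

    @property
    def min_id(self) -> int:
        return min(h.id for h in self.hotspots)


@dataclass
class Pocket:
    """A ranked, filtered pocket."""

    label: str
    hotspot_ids: list[int]
    n_polar: int
    n_hydrophobic: int
    dg_sum: float
    efficiency: float
    volume: float
    buriedness: float
    centroid: np.ndarray
    passed_polarity: bool
    passed_geometry: bool
    merged_from: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)

    @property
    def n_hotspots(self) -> int:
        return len(self.hotspot_ids)

    @property
    def ligandable(self) -> bool:
        return self.passed_polarity and self.passed_geometry


def pocket_volume(
    positions,
    sphere_radius: float,
    spacing: float | np.ndarray = 0.25,
    origin=(0.0, 0.0, 0.0),
) -> float:
    """Union-of-spheres volume (ų) by voxel counting.

    Each hotspot contributes a sphere of ``sphere_radius`` around its
    position; overlap is counted once. The counting lattice is anchored at
    ``origin`` with the given ``spacing`` so results are deterministic for a
    fixed analysis geometry and invariant under joint translation of
    positions and origin.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        return 0.0
    spacing = np.asarray(spacing, dtype=float)
    spacing = np.full(3, float(spacing)) if spacing.size == 1 else spacing.reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    lo = np.floor((positions.min(axis=0) - sphere_radius - origin) / spacing).astype(int) - 1
    hi = np.ceil((positions.max(axis=0) + sphere_radius - origin) / spacing).astype(int) + 1
    axes = [origin[d] + spacing[d] * np.arange(lo[d], hi[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    covered = np.zeros(centers.shape[0], dtype=bool)
    r2 = sphere_radius**2
    for p in positions:
        covered |= np.einsum("ij,ij->i", centers - p, centers - p) <= r2
    return float(covered.sum() * np.prod(spacing))


def _candidate_volume(hotspots: Sequence[Hotspot], cfg: AssemblyConfig, geometry: ScalarGrid3D | None) -> float:
    spacing = geometry.spacing if geometry is not None else 0.25
    origin = geometry.origin if geometry is not None else (0.0, 0.0, 0.0)
    return pocket_volume([h.position for h in hotspots], cfg.sphere_radius, spacing, origin)


def _min_inter_distance(a: PocketCandidate, b: PocketCandidate, dmat: SurfaceDistanceMatrix) -> float:
    return min(dmat.get(ha.id, hb.id) for ha in a.hotspots for hb in b.hotspots)


def assemble_pockets(
    hotspots: Sequence[Hotspot],
    dmat: SurfaceDistanceMatrix,
    cfg: AssemblyConfig | None = None,
    geometry: ScalarGrid3D | None = None,
) -> list[PocketCandidate]:
    """Group hotspots into pocket candidates along the surface.

    Stage 1: connected components of the ≤ ``link_distance`` surface-distance
    graph with at least ``min_density`` members. Components already larger
    than ``volume_cap`` are rejected outright. Stage 2: repeatedly merge the
    closest candidate pair within ``merge_distance`` whose merged volume
    stays within the cap; ties broken by the smaller lowest hotspot id, so
    assembly is deterministic and independent of input ordering.
    """
    cfg = cfg or AssemblyConfig()
    by_id = {h.id: h for h in hotspots}
    missing = [h.id for h in hotspots if h.id not in dmat.ids]
    if missing:
        raise ValueError(f"distance matrix does not cover hotspot ids {missing}")

    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for i, a in enumerate(dmat.ids):
        for j in range(i + 1, len(dmat.ids)):
            b = dmat.ids[j]
            if a in by_id and b in by_id and dmat.distances[i, j] <= cfg.link_distance:
                graph.add_edge(a, b)

    candidates: list[PocketCandidate] = []
    for comp in nx.connected_components(graph):
        if len(comp) < cfg.min_density:
            continue
        members = sorted((by_id[i] for i in comp), key=lambda h: h.id)
        vol = _candidate_volume(members, cfg, geometry)
        if vol > cfg.volume_cap:
            continue  # oversized before any merge: split-rejected
        candidates.append(PocketCandidate(hotspots=members, volume=vol))
    candidates.sort(key=lambda c: c.min_id)

    # stage 2: greedy ascending-distance merging under the volume cap
    while True:
        best: tuple[float, int, int, int] | None = None
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                d = _min_inter_distance(candidates[i], candidates[j], dmat)
                if d > cfg.merge_distance:
                    continue
                tie = min(candidates[i].min_id, candidates[j].min_id)
                key = (d, tie, i, j)
                if best is None or key < best:
                    merged_vol = _candidate_volume(
                        candidates[i].hotspots + candidates[j].hotspots, cfg, geometry
                    )
                    if merged_vol <= cfg.volume_cap:
                        best = key
                        best_vol = merged_vol
        if best is None:
            break
        _, _, i, j = best
        a, b = candidates[i], candidates[j]
        merged = PocketCandidate(
            hotspots=sorted(a.hotspots + b.hotspots, key=lambda h: h.id),
            volume=best_vol,
            merged_from=(a.merged_from or [a.hotspot_ids]) + (b.merged_from or [b.hotspot_ids]),
        )
        candidates = [c for k, c in enumerate(candidates) if k not in (i, j)] + [merged]
        candidates.sort(key=lambda c: c.min_id)
    return candidates


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def buriedness(
    point,
    structure: MolecularStructure,
    ray_count: int = 146,
    ray_reach: float = 8.0,
) -> float:
    """Fraction of quasi-uniform rays from ``point`` that hit an atom sphere
    within ``ray_reach`` Å — a simple enclosure measure: ~0 in open solvent,
    ~0.5 just above a flat wall, →1 deep inside a cavity."""
    point = np.asarray(point, dtype=float)
    coords = structure.coordinates
    radii = structure.radii
    near = np.linalg.norm(coords - point, axis=1) <= ray_reach + radii
    if not near.any():
        return 0.0
    coords, radii = coords[near], radii[near]
    dirs = _fibonacci_sphere(ray_count)  # (R, 3)
    rel = coords - point  # (M, 3)
    t = rel @ dirs.T  # (M, R) projection of atom center on each ray
    tc = np.clip(t, 0.0, ray_reach)
    # squared distance from each atom center to the closest point of the segment
    d2 = (rel**2).sum(axis=1)[:, None] - 2 * tc * t + tc**2
    hit = (d2 <= (radii**2)[:, None]).any(axis=0)
    return float(hit.mean())


def _boltzmann_centroid(hotspots: Sequence[Hotspot], temperature_K: float) -> np.ndarray:
    e = np.array([h.energy for h in hotspots])
    w = np.exp(-(e - e.min()) / (R_KCAL * temperature_K))
    pos = np.array([h.position for h in hotspots])
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def apply_filters(
    candidate: PocketCandidate,
    structure: MolecularStructure,
    cfg: AssemblyConfig | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> Pocket:
    """Evaluate ligandability filters on a candidate.

    Polarity balance passes iff the pocket has at least one hotspot of each
    channel and the minority channel makes up at least
    ``polarity_min_fraction`` of the hotspots. Geometry passes iff the
    ray-casting buriedness at the pocket's Boltzmann-weighted centroid
    reaches ``buriedness_threshold``. Both outcomes are recorded;
    ``ligandable`` is their conjunction. The label is assigned later by
    :func:`rank_pockets`.
    """
    cfg = cfg or AssemblyConfig()
    n_polar = sum(1 for h in candidate.hotspots if h.channel == "polar")
    n_hydro = len(candidate.hotspots) - n_polar
    total = len(candidate.hotspots)
    passed_polarity = (
        n_polar >= 1 and n_hydro >= 1 and min(n_polar, n_hydro) / total >= cfg.polarity_min_fraction
    )
    centroid = _boltzmann_centroid(candidate.hotspots, temperature_K)
    burial = buriedness(centroid, structure, cfg.ray_count, cfg.ray_reach)
    dg_sum = float(sum(h.energy for h in candidate.hotspots))
    return Pocket(
        label="",
        hotspot_ids=candidate.hotspot_ids,
        n_polar=n_polar,
        n_hydrophobic=n_hydro,
        dg_sum=dg_sum,
        efficiency=dg_sum / total,
        volume=candidate.volume,
        buriedness=burial,
        centroid=centroid,
        passed_polarity=passed_polarity,
        passed_geometry=burial >= cfg.buriedness_threshold,
        merged_from=candidate.merged_from,
    )


def _rank_label(i: int) -> str:
    """0 → A, 25 → Z, 26 → AA (spreadsheet-style)."""
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def rank_pockets(pockets: Sequence[Pocket]) -> list[Pocket]:
    """Rank pockets by summed hotspot energy, most favorable first.

    Sorted ascending by ΔG sum (most negative = best), ties broken by
    efficiency (ΔG per hotspot), then by lowest hotspot id; labels A, B, …
    are assigned in rank order.
    """
    ranked = sorted(pockets, key=lambda p: (p.dg_sum, p.efficiency, min(p.hotspot_ids)))
    out = []
    for i, p in enumerate(ranked):
        p.label = _rank_label(i)
        out.append(p)
    return out


def pocket_report(pockets: Sequence[Pocket], path) -> None:
    """Write the ranked pocket table as TSV (deterministic formatting)."""
    df = pd.DataFrame(
        {
            "label": [p.label for p in pockets],
            "n_hotspots": [p.n_hotspots for p in pockets],
            "n_polar": [p.n_polar for p in pockets],
            "n_hydrophobic": [p.n_hydrophobic for p in pockets],
            "dg_sum": [round(p.dg_sum, 3) for p in pockets],
            "efficiency": [round(p.efficiency, 3) for p in pockets],
            "volume": [round(p.volume, 3) for p in pockets],
            "buriedness": [round(p.buriedness, 3) for p in pockets],
            "passed_polarity": [p.passed_polarity for p in pockets],
            "passed_geometry": [p.passed_geometry for p in pockets],
            "ligandable": [p.ligandable for p in pockets],
            "hotspot_ids": [",".join(map(str, p.hotspot_ids)) for p in pockets],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def summarize_screen(n_tested: int, n_positive: int) -> int:
    """Hit rate of a binding screen as a whole-number percentage."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_positive <= n_tested:
        raise ValueError("n_positive must be between 0 and n_tested")
    return round(100 * n_positive / n_tested)
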