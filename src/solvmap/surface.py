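"""Solvent-shell surface graph and A* geodesic distances between hotspots.

A voxel is *traversable* when its center lies outside the protein's
vdW + probe surface but no more than ``shell_max`` above it. Surface
distance between two points is the length of the shortest 26-connected
lattice path through traversable voxels (edge weight = Euclidean distance
between voxel centers), found with A* under the straight-line heuristic —
admissible and consistent, so A* returns the same optimal lengths as
Dijkstra. Restricting paths to the shell is what makes this a *surface*
distance: the path may neither tunnel through the protein nor shortcut
through bulk solvent.

A scipy.sparse.csgraph Dijkstra on an explicitly built adjacency matrix is
included as an independent reference implementation for testing.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import cKDTree

from .grids import ScalarGrid3D
from .structure import MolecularStructure

__all__ = [
    "TraversableMask",
    "SurfaceDistanceMatrix",
    "build_traversable_mask",
    "surface_distance",
    "pairwise_surface_distances",
    "dijkstra_reference_distance",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SHELL_MAX = 3.0
DEFAULT_SNAP_MAX = 2.0

#: the 26 neighbor offsets of a voxel (faces, edges, corners)
NEIGHBOR_OFFSETS: np.ndarray = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=int
)


@dataclass
class TraversableMask:
    """Boolean solvent-shell mask sharing geometry with the analysis grids.

    ``clearance`` stores, per voxel, the signed distance from the voxel
    center to the vdW surface (min over atoms of |x − a| − r_atom); it is
    kept so bulk-region estimation can reuse it.
    """

    origin: np.ndarray
    spacing: np.ndarray
    mask: np.ndarray
    probe_radius: float
    shell_max: float
    clearance: np.ndarray | None = None
    _kdtree: cKDTree | None = field(default=None, repr=False, compare=False)
    _voxel_flat: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.asarray(self.spacing, dtype=float)
        self.spacing = np.full(3, float(spacing)) if spacing.size == 1 else spacing.reshape(3)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def traversable_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers, flat indices) of traversable voxels, cached."""
        if self._voxel_flat is None:
            idx = np.argwhere(self.mask)
            self._voxel_flat = np.ravel_multi_index(idx.T, self.shape)
            self._centers = self.origin + idx * self.spacing
        return self._centers, self._voxel_flat

    def snap(self, point, snap_max: float = DEFAULT_SNAP_MAX) -> int | None:
        """Flat index of the nearest traversable voxel within ``snap_max`` Å,
        or None if the point is farther than that from the shell."""
        centers, flat = self.traversable_centers()
        if centers.shape[0] == 0:
            return None
        if self._kdtree is None:
            self._kdtree = cKDTree(centers)
        d, i = self._kdtree.query(np.asarray(point, dtype=float))
        if d > snap_max:
            return None
        return int(flat[i])

    def as_grid(self) -> ScalarGrid3D:
        """0/1 grid for writing the mask out as DX for inspection."""
        return ScalarGrid3D(origin=self.origin, spacing=self.spacing, values=self.mask.astype(float))


@dataclass
class SurfaceDistanceMatrix:
    """Symmetric hotspot-to-hotspot surface distances (Å, +inf = unreachable)."""

    ids: list[int]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        n = len(self.ids)
        if self.distances.shape != (n, n):
            raise ValueError("distance matrix shape disagrees with id list")
        if not np.allclose(np.diag(self.distances), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.distances)
        if not np.allclose(
            np.where(finite, self.distances, 0), np.where(finite.T, self.distances.T, 0), atol=1e-6
        ):
            raise ValueError("distance matrix must be symmetric")

    def get(self, id_a: int, id_b: int) -> float:
        ia, ib = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.distances[ia, ib])

    def to_tsv(self, path) -> None:
        rows = []
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                if j <= i:
                    continue
                d = self.distances[i, j]
                rows.append((a, b, "inf" if not np.isfinite(d) else round(float(d), 3)))
        pd.DataFrame(rows, columns=["hotspot_id_a", "hotspot_id_b", "distance_A"]).to_csv(
            path, sep="\t", index=False
        )


def compute_clearance(structure: MolecularStructure, geometry: ScalarGrid3D) -> np.ndarray:
    """Per-voxel distance from voxel center to the vdW surface.

    clearance(x) = min over atoms of (|x − a_i| − r_i). Atoms are grouped by
    radius so each group is a single KD-tree nearest-neighbor query.
    """
    coords = structure.coordinates
    radii = structure.radii
    centers = geometry.voxel_centers()
    clearance = np.full(centers.shape[0], np.inf)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        d, _ = tree.query(centers, workers=-1)
        clearance = np.minimum(clearance, d - r)
    return clearance.reshape(geometry.shape)


def build_traversable_mask(
    structure: MolecularStructure,
    geometry: ScalarGrid3D,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    shell_max: float = DEFAULT_SHELL_MAX,
) -> TraversableMask:
    """Build the solvent-shell mask over the geometry of an analysis grid.

    A voxel center x is traversable iff for every atom i,
    |x − a_i| ≥ r_i + probe_radius, and its height above the vdW + probe
    surface is at most ``shell_max``.
    """
    if len(structure) == 0:
        raise ValueError("cannot build a surface around an empty structure")
    clearance = compute_clearance(structure, geometry)
    height = clearance - probe_radius  # above the vdW+probe surface
    mask = (height >= 0) & (height <= shell_max)
    return TraversableMask(
        origin=geometry.origin,
        spacing=geometry.spacing,
        mask=mask,
        probe_radius=probe_radius,
        shell_max=shell_max,
        clearance=clearance,
    )


def _neighbor_steps(spacing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    steps = np.linalg.norm(NEIGHBOR_OFFSETS * spacing, axis=1)
    return NEIGHBOR_OFFSETS, steps


def _astar(mask: TraversableMask, start_flat: int, goal_flat: int) -> float:
    """Optimal lattice path length between two traversable voxels."""
    shape = mask.shape
    m = mask.mask
    offsets, steps = _neighbor_steps(mask.spacing)
    goal_idx = np.array(np.unravel_index(goal_flat, shape))
    gi, gj, gk = map(int, goal_idx)
    sx, sy, sz = map(float, mask.spacing)
    offs = offsets.tolist()
    step_list = steps.tolist()

    g = np.full(m.size, np.inf)
    g[start_flat] = 0.0
    closed = np.zeros(m.size, dtype=bool)
    start_idx = np.array(np.unravel_index(start_flat, shape))
    h0 = float(np.linalg.norm((start_idx - goal_idx) * mask.spacing))
    heap: list[tuple[float, int, int, int, int]] = [(h0, start_flat, *map(int, start_idx))]
    nx, ny, nz = shape
    while heap:
        f, flat, i, j, k = heapq.heappop(heap)
        if flat == goal_flat:
            return float(g[flat])
        if closed[flat]:
            continue
        closed[flat] = True
        gc = g[flat]
        for (di, dj, dk), step in zip(offs, step_list):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                continue
            if not m[ni, nj, nk]:
                continue
            nflat = (ni * ny + nj) * nz + nk
            if closed[nflat]:
                continue
            tentative = gc + step
            if tentative < g[nflat]:
                g[nflat] = tentative
                h = (((ni - gi) * sx) ** 2 + ((nj - gj) * sy) ** 2 + ((nk - gk) * sz) ** 2) ** 0.5
                heapq.heappush(heap, (tentative + h, nflat, ni, nj, nk))
    return np.inf


def _uniform_cost_to_targets(
    mask: TraversableMask,
    start_flat: int,
    target_flats: set[int],
    max_distance: float = np.inf,
) -> dict[int, float]:
    """Single-source optimal lattice distances to a set of targets.

    Plain uniform-cost search (A* with zero heuristic), stopping once every
    target has been settled or the search front exceeds ``max_distance``
    (targets beyond the horizon report +inf).
    """
    shape = mask.shape
    m = mask.mask
    offsets, steps = _neighbor_steps(mask.spacing)
    steps = steps.tolist()
    offs = offsets.tolist()
    nx, ny, nz = shape
    remaining = set(target_flats)
    out: dict[int, float] = {}
    g = np.full(m.size, np.inf)
    g[start_flat] = 0.0
    closed = np.zeros(m.size, dtype=bool)
    si, sj, sk = map(int, np.unravel_index(start_flat, shape))
    heap: list[tuple[float, int, int, int, int]] = [(0.0, start_flat, si, sj, sk)]
    while heap and remaining:
        d, flat, i, j, k = heapq.heappop(heap)
        if closed[flat]:
            continue
        if d > max_distance:
            break
        closed[flat] = True
        if flat in remaining:
            out[flat] = d
            remaining.discard(flat)
            if not remaining:
                break
        for (di, dj, dk), step in zip(offs, steps):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                continue
            if not m[ni, nj, nk]:
                continue
            nflat = (ni * ny + nj) * nz + nk
            if closed[nflat]:
                continue
            tentative = d + step
            if tentative < g[nflat]:
                g[nflat] = tentative
                heapq.heappush(heap, (tentative, nflat, ni, nj, nk))
    for t in remaining:
        out[t] = np.inf
    return out


def surface_distance(a, b, mask: TraversableMask, snap_max: float = DEFAULT_SNAP_MAX) -> float:
    """Surface (solvent-shell geodesic) distance between two points in Å.

    Endpoints are snapped to the nearest traversable voxel within
    ``snap_max``; points farther than that from the shell — e.g. buried
    deeper than the probe can reach — are unreachable (+inf), as is any pair
    with no traversable path between them.
    """
    sa = mask.snap(a, snap_max)
    sb = mask.snap(b, snap_max)
    if sa is None or sb is None:
        return np.inf
    if sa == sb:
        return 0.0
    return _astar(mask, sa, sb)


def build_lattice_graph(mask: TraversableMask) -> tuple[coo_matrix, np.ndarray]:
    """Sparse adjacency of the traversable 26-connected lattice.

    Returns (graph over all voxels as a sparse matrix, flat indices of
    traversable voxels). Used by the scipy Dijkstra reference path.
    """
    m = mask.mask
    shape = mask.shape
    n = m.size
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    # half the offsets; symmetry handled by directed=False downstream
    for off in NEIGHBOR_OFFSETS[: len(NEIGHBOR_OFFSETS) // 2]:
        step = float(np.linalg.norm(off * mask.spacing))
        src_slices = tuple(slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape))
        dst_slices = tuple(slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape))
        both = m[src_slices] & m[dst_slices]
        src_idx = np.argwhere(both) + np.array([max(0, -o) for o in off])
        if src_idx.size == 0:
            continue
        dst_idx = src_idx + off
        rows.append(np.ravel_multi_index(src_idx.T, shape))
        cols.append(np.ravel_multi_index(dst_idx.T, shape))
        data.append(np.full(src_idx.shape[0], step))
    if rows:
        graph = coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    return graph, np.flatnonzero(m.ravel())


def dijkstra_reference_distance(a, b, mask: TraversableMask, snap_max: float = DEFAULT_SNAP_MAX) -> float:
    """Reference surface distance via scipy.sparse.csgraph Dijkstra.

    Built on an explicit sparse adjacency matrix — an independent code path
    from the hand-written A* — and used as its correctness oracle.
    """
    sa = mask.snap(a, snap_max)
    sb = mask.snap(b, snap_max)
    if sa is None or sb is None:
        return np.inf
    graph, _ = build_lattice_graph(mask)
    d = _csgraph_dijkstra(graph.tocsr(), directed=False, indices=sa)
    return float(d[sb])


def pairwise_surface_distances(
    hotspots,
    masks: list[TraversableMask],
    snap_max: float = DEFAULT_SNAP_MAX,
    max_distance: float = np.inf,
) -> SurfaceDistanceMatrix:
    """All-pairs hotspot surface distances, minimized over conformations.

    For each conformation's mask the full pairwise matrix is computed
    (single-source uniform-cost searches, one per hotspot); matrices from
    multiple conformations are combined element-wise by minimum — a pocket
    reachable in any sampled conformation counts.

    ``max_distance`` bounds each search: pairs farther apart than this
    horizon report +inf. Pocket assembly only discriminates distances up to
    its merge-eligibility threshold, so a horizon slightly above it yields
    identical pockets at a fraction of the search cost.
    """
    if not masks:
        raise ValueError("need at least one traversable mask")
    if not hotspots:
        raise ValueError("need at least one hotspot")
    ids = [h.id for h in hotspots]
    n = len(hotspots)
    combined = np.full((n, n), np.inf)
    np.fill_diagonal(combined, 0.0)
    for mask in masks:
        snapped = [mask.snap(h.position, snap_max) for h in hotspots]
        for i in range(n):
            if snapped[i] is None:
                continue
            targets = {snapped[j] for j in range(i + 1, n) if snapped[j] is not None}
            if not targets:
                continue
            dists = _uniform_cost_to_targets(mask, snapped[i], targets, max_distance)
            for j in range(i + 1, n):
                sj = snapped[j]
                if sj is None:
                    continue
                d = 0.0 if sj == snapped[i] else dists[sj]
                if d < combined[i, j]:
                    combined[i, j] = combined[j, i] = d
    return SurfaceDistanceMatrix(ids=ids, distances=combined)
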