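"""Synthetic structures and occupancy grids with planted ground truth.

The generator emulates what a mixed-solvent MD occupancy analysis sees,
without running any dynamics: a toy "protein" built from carbon pseudo-atoms
on a lattice, Poisson count noise at bulk solvent density in the solvent
region, zero counts inside the protein, and localized enrichment blobs whose
depth encodes a target ΔG through the Boltzmann relation. The blob is
Gaussian in *energy* — E(x) = ΔG_target · exp(−d²/2w²) — so the expected
count bulk·exp(−E/RT) at the blob center inverse-Boltzmann-converts exactly
back to the target, making parameter recovery measurable.

Preset systems (``two_pocket_system`` etc.) provide the fixed study
conditions used by the test suite and worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import R_KCAL, DEFAULT_TEMPERATURE_K
from .grids import OccupancyGrid, ScalarGrid3D
from .pockets import Pocket
from .structure import AtomRecord, MolecularStructure
from .surface import DEFAULT_PROBE_RADIUS, compute_clearance

__all__ = [
    "PlantedSite",
    "SyntheticSystem",
    "RecoveryResult",
    "make_toy_protein",
    "default_grid_geometry",
    "generate_synthetic_system",
    "evaluate_recovery",
    "single_site_system",
    "two_pocket_system",
    "triple_cluster_system",
    "background_system",
]

#: defaults of the emulated study conditions
DEFAULT_SPACING = 0.5  # Å
DEFAULT_BULK_EXPECTED = 20.0  # counts per voxel over the pooled frames
DEFAULT_N_FRAMES = 15000  # three 50 ns replicas at 10 ps saving
DEFAULT_KERNEL_WIDTH = 2.0  # Å; energy-basin width ≈ probe heavy-atom footprint
DEFAULT_MARGIN = 7.0  # Å of grid padding beyond the atom bounding box


@dataclass
class PlantedSite:
    """A ground-truth enrichment blob for one channel."""

    position: np.ndarray
    channel: str
    target_dg: float  # kcal/mol, < 0
    kernel_width: float = DEFAULT_KERNEL_WIDTH

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.target_dg >= 0:
            raise ValueError("target_dg must be favorable (< 0)")
        if self.channel not in ("polar", "hydrophobic"):
            raise ValueError("channel must be 'polar' or 'hydrophobic'")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")


@dataclass
class SyntheticSystem:
    """A generated structure + occupancy pair with its ground truth."""

    structure: MolecularStructure
    occupancy: dict[str, OccupancyGrid]  # channel → grid
    truth: list[list[PlantedSite]]  # sites grouped into intended pockets
    seed: int

    @property
    def all_sites(self) -> list[PlantedSite]:
        return [s for group in self.truth for s in group]


@dataclass
class RecoveryResult:
    """Detection quality of a pipeline run against planted truth."""

    precision: float
    recall: float
    energy_rmse: float  # kcal/mol over matched pairs; nan if none matched
    n_detected: int
    n_truth: int
    n_matched: int
    matches: list[tuple[str, int, float]] = field(default_factory=list)  # (label, truth idx, dist)


def make_toy_protein(
    shape: str = "sphere-with-groove",
    radius: float = 11.0,
    lattice: float = 1.2,
    groove_radius: float = 6.0,
    groove_centers: Sequence | None = None,
    slab_half_extent: float = 12.0,
    slab_thickness: float = 8.0,
    channel_radius: float = 4.0,
) -> MolecularStructure:
    """Deterministic toy protein: carbon pseudo-atoms (r = 1.70 Å) on a
    cubic lattice filling a solid minus carved solvent-accessible grooves.

    ``sphere-with-groove``: a sphere of ``radius`` with hemispherical
    grooves of ``groove_radius`` carved at each of ``groove_centers``
    (default: one at the +z pole). ``slab-channel``: a slab with a
    half-cylindrical channel of ``channel_radius`` carved along y into the
    top face.
    """
    if lattice <= 0:
        raise ValueError("lattice constant must be positive")
    if shape == "sphere-with-groove":
        if radius <= 0:
            raise ValueError("sphere radius must be positive")
        if groove_centers is None:
            groove_centers = [np.array([0.0, 0.0, radius])]
        groove_centers = [np.asarray(c, dtype=float) for c in groove_centers]
        n = int(np.floor(radius / lattice))
        ax = lattice * np.arange(-n, n + 1)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        keep = np.linalg.norm(pts, axis=1) <= radius
        for c in groove_centers:
            keep &= np.linalg.norm(pts - c, axis=1) > groove_radius
        pts = pts[keep]
    elif shape == "slab-channel":
        if slab_half_extent <= 0 or slab_thickness <= 0:
            raise ValueError("slab dimensions must be positive")
        nxy = int(np.floor(slab_half_extent / lattice))
        nz = int(np.floor(slab_thickness / 2 / lattice))
        axy = lattice * np.arange(-nxy, nxy + 1)
        az = lattice * np.arange(-nz, nz + 1)
        gx, gy, gz = np.meshgrid(axy, axy, az, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        top = slab_thickness / 2
        keep = np.sqrt(pts[:, 0] ** 2 + (pts[:, 2] - top) ** 2) > channel_radius
        pts = pts[keep]
    else:
        raise ValueError(f"unknown toy shape {shape!r}")
    if pts.shape[0] == 0:
        raise ValueError("degenerate dimensions: toy protein has no atoms")
    atoms = [
        AtomRecord(
            element="C",
            position=p,
            chain_id="A",
            residue_number=i + 1,
            residue_name="TOY",
            record_kind="ATOM",
            name="C",
            radius=1.70,
        )
        for i, p in enumerate(pts)
    ]
    return MolecularStructure(atoms=atoms, conformer_label=f"toy-{shape}")


def default_grid_geometry(
    structure: MolecularStructure,
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
) -> ScalarGrid3D:
    """Empty analysis grid covering the structure plus ``margin`` Å."""
    coords = structure.coordinates
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return ScalarGrid3D(origin=lo, spacing=np.full(3, spacing), values=np.zeros(shape))


def generate_synthetic_system(
    protein: MolecularStructure,
    sites: Sequence[PlantedSite] | Sequence[Sequence[PlantedSite]],
    n_frames: int = DEFAULT_N_FRAMES,
    bulk_expected: float = DEFAULT_BULK_EXPECTED,
    seed: int = 0,
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> SyntheticSystem:
    """Generate per-channel occupancy grids with planted enrichment.

    Per solvent voxel the count is Poisson with mean
    bulk_expected · exp(−E(x)/RT), where E(x) sums the channel's planted
    Gaussian energy bumps; voxels inside the protein (closer than
    ``probe_radius`` to the vdW surface) have zero mean. ``sites`` may be a
    flat list (one intended pocket) or a list of groups. Identical seeds
    reproduce bit-identical grids.

    Raises
    ------
    ValueError
        If a planted site lies inside the protein (unreachable by solvent).
    """
    if n_frames <= 0 or bulk_expected <= 0:
        raise ValueError("n_frames and bulk_expected must be positive")
    if sites and isinstance(sites[0], PlantedSite):
        groups: list[list[PlantedSite]] = [list(sites)]  # type: ignore[arg-type]
    else:
        groups = [list(g) for g in sites]  # type: ignore[union-attr]
    flat_sites = [s for g in groups for s in g]

    coords = protein.coordinates
    radii = protein.radii
    for s in flat_sites:
        clearance = np.min(np.linalg.norm(coords - s.position, axis=1) - radii)
        if clearance < probe_radius:
            raise ValueError(
                f"planted site at {s.position} is inside the protein "
                f"(clearance {clearance:.2f} Å < probe {probe_radius} Å)"
            )

    geometry = default_grid_geometry(protein, spacing=spacing, margin=margin)
    clearance_grid = compute_clearance(protein, geometry)
    solvent = clearance_grid >= probe_radius
    centers = geometry.voxel_centers()
    rt = R_KCAL * temperature_K

    rng = np.random.default_rng(seed)
    occupancy: dict[str, OccupancyGrid] = {}
    for channel in ("polar", "hydrophobic"):
        energy = np.zeros(centers.shape[0])
        for s in flat_sites:
            if s.channel != channel:
                continue
            d2 = np.einsum("ij,ij->i", centers - s.position, centers - s.position)
            energy += s.target_dg * np.exp(-d2 / (2.0 * s.kernel_width**2))
        mean = bulk_expected * np.exp(-energy / rt)
        mean = np.where(solvent.ravel(), mean, 0.0)
        counts = rng.poisson(mean).astype(float).reshape(geometry.shape)
        occupancy[channel] = OccupancyGrid(
            grid=geometry.with_values(counts),
            channel=channel,
            n_frames=n_frames,
            bulk_expected_per_voxel=bulk_expected,
        )
    return SyntheticSystem(structure=protein, occupancy=occupancy, truth=groups, seed=seed)


def evaluate_recovery(
    detected: Sequence[Pocket],
    truth: Sequence[Sequence[PlantedSite]],
    match_radius: float = 4.0,
) -> RecoveryResult:
    """Match detected pockets to planted pocket groups and score them.

    A detection matches a truth group when the pocket centroid is within
    ``match_radius`` Å of the group's site centroid; matching is greedy
    one-to-one in ascending distance. Precision = matched / detected
    (reported 0 with the n_detected flag when nothing was detected),
    recall = matched / truth, energy RMSE compares pocket ΔG sums with the
    groups' summed targets over matched pairs.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    truth_centroids = [np.mean([s.position for s in g], axis=0) for g in truth]
    truth_sums = [float(sum(s.target_dg for s in g)) for g in truth]

    pairs = []
    for d_i, p in enumerate(detected):
        for t_i, c in enumerate(truth_centroids):
            dist = float(np.linalg.norm(p.centroid - c))
            if dist <= match_radius:
                pairs.append((dist, d_i, t_i))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[str, int, float]] = []
    sq_errs = []
    for dist, d_i, t_i in pairs:
        if d_i in used_d or t_i in used_t:
            continue
        used_d.add(d_i)
        used_t.add(t_i)
        matches.append((detected[d_i].label, t_i, dist))
        sq_errs.append((detected[d_i].dg_sum - truth_sums[t_i]) ** 2)
    n_matched = len(matches)
    precision = n_matched / len(detected) if detected else 0.0
    recall = n_matched / len(truth) if truth else 1.0
    rmse = float(np.sqrt(np.mean(sq_errs))) if sq_errs else float("nan")
    return RecoveryResult(
        precision=precision,
        recall=recall,
        energy_rmse=rmse,
        n_detected=len(detected),
        n_truth=len(truth),
        n_matched=n_matched,
        matches=matches,
    )


# ---------------------------------------------------------------------------
# Preset systems (fixed study conditions for tests, examples and the CLI)


def _cavity_ring_sites(
    cavity_center: np.ndarray,
    channels: list[str],
    target_dg: float,
    ring_radius: float,
    kernel_width: float,
) -> list[PlantedSite]:
    """Sites evenly spaced on a ring inside a carved cavity.

    The ring lies in the plane through the cavity center perpendicular to
    its outward (mouth) direction, so all sites are solvent-reachable yet
    well below the cavity rim. Adjacent-site separation is
    2·ring_radius·sin(π/n); keep that above ~3 kernel widths so the summed
    energy basins stay distinct minima.
    """
    cavity_center = np.asarray(cavity_center, dtype=float)
    outward = cavity_center / np.linalg.norm(cavity_center)
    ref = np.array([1.0, 0.0, 0.0]) if abs(outward[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(outward, ref)
    u /= np.linalg.norm(u)
    v = np.cross(outward, u)
    n = len(channels)
    sites = []
    for k, ch in enumerate(channels):
        theta = 2.0 * np.pi * k / n
        offset = ring_radius * (np.cos(theta) * u + np.sin(theta) * v)
        sites.append(
            PlantedSite(
                position=cavity_center + offset,
                channel=ch,
                target_dg=target_dg,
                kernel_width=kernel_width,
            )
        )
    return sites


#: kernel width (Å) of clustered preset sites: narrow enough that basins
#: ~3.3 Å apart remain distinct minima after their energies sum
_CLUSTER_KERNEL = 1.0


def single_site_system(seed: int = 1, target_dg: float = -2.0) -> SyntheticSystem:
    """One hydrophobic site of ``target_dg`` at the center of a buried
    cavity — the parameter-recovery fixture."""
    center = np.array([0.0, 0.0, 6.5])
    protein = make_toy_protein(radius=9.0, groove_radius=5.5, groove_centers=[center])
    site = PlantedSite(position=center, channel="hydrophobic", target_dg=target_dg)
    return generate_synthetic_system(protein, [[site]], seed=seed)


def two_pocket_system(seed: int = 7) -> SyntheticSystem:
    """Two five-site pockets in buried cavities at opposite poles (surface
    distance between them far above the link distance) — the end-to-end
    fixture. Cavity mouths are narrower than a hemisphere, so the pockets
    are genuinely buried (ray-cast buriedness well above one half)."""
    centers = [np.array([0.0, 0.0, 8.0]), np.array([0.0, 0.0, -8.0])]
    protein = make_toy_protein(radius=11.0, groove_radius=6.0, groove_centers=centers)
    group_a = _cavity_ring_sites(
        centers[0],
        ["hydrophobic", "hydrophobic", "hydrophobic", "polar", "polar"],
        -2.0,
        ring_radius=2.8,
        kernel_width=_CLUSTER_KERNEL,
    )
    group_b = _cavity_ring_sites(
        centers[1],
        ["polar", "polar", "polar", "hydrophobic", "hydrophobic"],
        -2.0,
        ring_radius=2.8,
        kernel_width=_CLUSTER_KERNEL,
    )
    return generate_synthetic_system(protein, [group_a, group_b], seed=seed)


def triple_cluster_system(seed: int = 3) -> SyntheticSystem:
    """A three-site cluster — below the minimum pocket density of four, so
    a correct pipeline reports no pocket."""
    center = np.array([0.0, 0.0, 6.5])
    protein = make_toy_protein(radius=9.0, groove_radius=5.5, groove_centers=[center])
    sites = _cavity_ring_sites(
        center,
        ["hydrophobic", "polar", "hydrophobic"],
        -2.0,
        ring_radius=2.2,
        kernel_width=_CLUSTER_KERNEL,
    )
    return generate_synthetic_system(protein, [sites], seed=seed)


def background_system(seed: int = 0) -> SyntheticSystem:
    """Bulk noise only — no planted enrichment anywhere."""
    protein = make_toy_protein(radius=9.0, groove_radius=5.5, groove_centers=[np.array([0.0, 0.0, 6.5])])
    return generate_synthetic_system(protein, [], seed=seed)
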