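"""Volumetric grid model, I/O, replica pooling and grid thermodynamics.

The central objects are :class:`ScalarGrid3D` (a dense scalar field on a
regular lattice, index order (i, j, k) = (x, y, z), origin at the center of
voxel (0, 0, 0)), :class:`OccupancyGrid` (probe counts per voxel for one
channel) and :class:`EnergyGrid` (per-voxel binding free energy from the
inverse-Boltzmann relation ΔG_i = −RT·ln(n_i / n_bulk)).

OpenDX files are handled by gridData; the ASCII XPLOR/CNS map dialect has a
small built-in reader/writer. XPLOR indexes the lattice on integer cell
fractions, so origins are rounded to the nearest multiple of the spacing on
write — use DX when lossless geometry matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from gridData import Grid as _DXGrid

from .constants import R_KCAL, DEFAULT_TEMPERATURE_K, STANDARD_CONCENTRATION_M

__all__ = [
    "ScalarGrid3D",
    "OccupancyGrid",
    "EnergyGrid",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "pool_replicas",
    "occupancy_to_energy",
    "boltzmann_average",
    "affinity_convert",
]

DEFAULT_CAP_KCAL = 3.0


class GridFormatError(ValueError):
    """Raised for malformed or unrecognized volumetric map files."""


@dataclass
class ScalarGrid3D:
    """Dense scalar field on a regular 3-D lattice.

    ``origin`` is the Cartesian position (Å) of the *center* of voxel
    (0, 0, 0); ``spacing`` is the per-axis voxel edge length (Å).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.asarray(self.spacing, dtype=float)
        if spacing.size == 1:
            spacing = np.full(3, float(spacing))
        self.spacing = spacing.reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 3-D array")
        if not np.all(self.spacing > 0):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("grid origin must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates."""
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d]) for d in range(3)
        )  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) voxel-center coordinates in C (flat-index) order."""
        ax, ay, az = self.axis_coordinates()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def index_to_position(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def same_geometry(self, other: "ScalarGrid3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "ScalarGrid3D":
        return ScalarGrid3D(origin=self.origin.copy(), spacing=self.spacing.copy(), values=values)


@dataclass
class OccupancyGrid:
    """Per-voxel probe counts for one channel, pooled over frames.

    ``bulk_expected_per_voxel`` is the expected count per voxel at bulk
    solvent density over the same number of frames; it is the n_bulk
    reference of the inverse-Boltzmann conversion.
    """

    grid: ScalarGrid3D
    channel: str  # "polar" | "hydrophobic"
    n_frames: int
    bulk_expected_per_voxel: float

    def __post_init__(self) -> None:
        if self.channel not in ("polar", "hydrophobic"):
            raise ValueError(f"channel must be 'polar' or 'hydrophobic', got {self.channel!r}")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not self.bulk_expected_per_voxel > 0:
            raise ValueError("bulk_expected_per_voxel must be positive")
        v = self.grid.values
        if np.any(v < 0) or not np.allclose(v, np.round(v)):
            raise ValueError("occupancy counts must be non-negative integers")


@dataclass
class EnergyGrid:
    """Per-voxel binding free energy (kcal/mol) for one channel.

    Unobserved voxels carry exactly ``+cap_kcal``; no voxel exceeds it.
    """

    grid: ScalarGrid3D
    channel: str
    temperature_K: float = DEFAULT_TEMPERATURE_K
    cap_kcal: float = DEFAULT_CAP_KCAL

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.cap_kcal <= 0:
            raise ValueError("energy cap must be positive")
        if np.any(self.grid.values > self.cap_kcal + 1e-9):
            raise ValueError("energy grid exceeds its declared cap")


# ---------------------------------------------------------------------------
# File I/O


def _read_dx(path: Path) -> ScalarGrid3D:
    try:
        g = _DXGrid(str(path))
    except Exception as exc:
        raise GridFormatError(f"malformed DX file {path}: {exc}") from exc
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diagonal(delta)
    return ScalarGrid3D(origin=np.asarray(g.origin, float), spacing=delta, values=np.asarray(g.grid, float))


def _write_dx(grid: ScalarGrid3D, path: Path) -> None:
    g = _DXGrid(grid.values, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), file_format="DX", typequote='"')


def _read_xplor(path: Path) -> ScalarGrid3D:
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines) and not lines[i].strip():
        i += 1
    try:
        ntitle = int(lines[i].split()[0])
        i += 1 + ntitle
        ints = [int(x) for x in lines[i].split()]
        na, amin, amax, nb, bmin, bmax, nc, cmin, cmax = ints
        i += 1
        cell = [float(lines[i][j * 12 : (j + 1) * 12]) for j in range(6)]
        i += 1
        order = lines[i].strip().upper()
        i += 1
    except (ValueError, IndexError) as exc:
        raise GridFormatError(f"malformed XPLOR header in {path}: {exc}") from exc
    if order != "ZYX":
        raise GridFormatError(f"unsupported XPLOR section order {order!r} (only ZYX)")
    nx, ny, nz = amax - amin + 1, bmax - bmin + 1, cmax - cmin + 1
    spacing = np.array([cell[0] / na, cell[1] / nb, cell[2] / nc])
    origin = np.array([amin, bmin, cmin]) * spacing
    values = np.empty((nx, ny, nz), dtype=float)
    per_section = nx * ny
    for k in range(nz):
        i += 1  # section-index line
        vals: list[float] = []
        while len(vals) < per_section:
            if i >= len(lines):
                raise GridFormatError(f"truncated XPLOR map {path}")
            line = lines[i]
            vals.extend(float(line[j * 12 : (j + 1) * 12]) for j in range(len(line.rstrip()) // 12))
            i += 1
        # rows over y, x fastest
        values[:, :, k] = np.asarray(vals[:per_section]).reshape(ny, nx).T
    return ScalarGrid3D(origin=origin, spacing=spacing, values=values)


def _write_xplor(grid: ScalarGrid3D, path: Path) -> None:
    nx, ny, nz = grid.shape
    start = np.rint(grid.origin / grid.spacing).astype(int)
    cell = grid.spacing * np.array([nx, ny, nz])
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("%8d !NTITLE\n" % 1)
        fh.write(" REMARKS scalar map\n")
        fh.write(
            "%8d%8d%8d%8d%8d%8d%8d%8d%8d\n"
            % (nx, start[0], start[0] + nx - 1, ny, start[1], start[1] + ny - 1, nz, start[2], start[2] + nz - 1)
        )
        fh.write("%12.5E%12.5E%12.5E%12.5E%12.5E%12.5E\n" % (cell[0], cell[1], cell[2], 90.0, 90.0, 90.0))
        fh.write("ZYX\n")
        for k in range(nz):
            fh.write("%8d\n" % k)
            section = grid.values[:, :, k].T.ravel()  # rows over y, x fastest
            for ofs in range(0, section.size, 6):
                chunk = section[ofs : ofs + 6]
                fh.write("".join("%12.5E" % v for v in chunk) + "\n")
        fh.write("%8d\n" % -9999)


def _sniff_dialect(path: Path) -> str:
    head = path.read_text().splitlines()[:40] if path.exists() else []
    for line in head:
        if "gridpositions" in line or line.lstrip().startswith("object"):
            return "DX"
        if line.strip().upper() == "ZYX":
            return "XPLOR"
    raise GridFormatError(f"unrecognized grid dialect in {path}")


def read_grid(path) -> ScalarGrid3D:
    """Read an OpenDX or XPLOR/CNS map, auto-detecting the dialect.

    Values and geometry are returned in (x, y, z) index order regardless of
    the file's storage order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"grid file not found: {path}")
    dialect = _sniff_dialect(path)
    return _read_dx(path) if dialect == "DX" else _read_xplor(path)


def write_grid(grid: ScalarGrid3D, path, dialect: str | None = None) -> None:
    """Write a grid as OpenDX (``DX``) or XPLOR/CNS (``XPLOR``).

    If ``dialect`` is omitted it is taken from the file extension
    (.dx → DX; .xplor/.cns → XPLOR).
    """
    path = Path(path)
    if dialect is None:
        dialect = {"dx": "DX", "xplor": "XPLOR", "cns": "XPLOR"}.get(path.suffix.lstrip(".").lower())
        if dialect is None:
            raise GridFormatError(f"cannot infer grid dialect from extension of {path}")
    dialect = dialect.upper()
    if dialect == "DX":
        _write_dx(grid, path)
    elif dialect == "XPLOR":
        _write_xplor(grid, path)
    else:
        raise GridFormatError(f"unknown grid dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Pooling and thermodynamics


def pool_replicas(grids: Sequence[OccupancyGrid]) -> OccupancyGrid:
    """Pool replica occupancy grids by summing counts voxel-wise.

    Counts, frame numbers and bulk expectations are additive; pooling raw
    counts before the log conversion is better behaved at low counts than
    averaging per-replica energies.
    """
    if not grids:
        raise ValueError("need at least one occupancy grid")
    first = grids[0]
    for g in grids[1:]:
        if not first.grid.same_geometry(g.grid):
            raise ValueError("replica grids disagree in geometry")
        if g.channel != first.channel:
            raise ValueError(f"replica channel mismatch: {g.channel} vs {first.channel}")
    values = np.sum([g.grid.values for g in grids], axis=0)
    return OccupancyGrid(
        grid=first.grid.with_values(values),
        channel=first.channel,
        n_frames=sum(g.n_frames for g in grids),
        bulk_expected_per_voxel=float(sum(g.bulk_expected_per_voxel for g in grids)),
    )


def occupancy_to_energy(
    occ: OccupancyGrid,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    cap_kcal: float = DEFAULT_CAP_KCAL,
) -> EnergyGrid:
    """Inverse-Boltzmann conversion of occupancy to binding free energy.

    Observed voxels get ΔG_i = −RT·ln(n_i / n_bulk), clipped to at most
    ``+cap_kcal``; voxels never visited by the probe (n_i = 0) get exactly
    ``+cap_kcal`` so the grid stays finite and writable.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    rt = R_KCAL * temperature_K
    counts = occ.grid.values
    with np.errstate(divide="ignore"):
        energy = -rt * np.log(counts / occ.bulk_expected_per_voxel)
    energy = np.where(counts > 0, np.minimum(energy, cap_kcal), cap_kcal)
    return EnergyGrid(
        grid=occ.grid.with_values(energy),
        channel=occ.channel,
        temperature_K=temperature_K,
        cap_kcal=cap_kcal,
    )


def boltzmann_average(energies: Iterable[float], temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Boltzmann-weighted mean Σ E_i·w_i / Σ w_i with w_i = exp(−E_i/RT).

    Always lies in [min E, max E] and never exceeds the arithmetic mean —
    favorable (more negative) energies dominate the weight.
    """
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise ValueError("boltzmann_average of an empty list")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    rt = R_KCAL * temperature_K
    w = np.exp(-(e - e.min()) / rt)  # shifted for numerical stability
    return float(np.sum(e * w) / np.sum(w))


def affinity_convert(
    value: float,
    direction: str,
    temperature_K: float = 298.15,
) -> float:
    """Convert between dissociation constant and binding free energy.

    ΔG = RT·ln(Kd / 1 M); Kd in molar, ΔG in kcal/mol. ``direction`` is
    ``"kd_to_dg"`` or ``"dg_to_kd"``. Round-tripping is the identity to
    better than 1e-6 relative error.
    """
    rt = R_KCAL * temperature_K
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    if direction == "kd_to_dg":
        if value <= 0:
            raise ValueError("Kd must be positive")
        return rt * math.log(value / STANDARD_CONCENTRATION_M)
    if direction == "dg_to_kd":
        if not math.isfinite(value):
            raise ValueError("ΔG must be finite")
        return STANDARD_CONCENTRATION_M * math.exp(value / rt)
    raise ValueError(f"direction must be 'kd_to_dg' or 'dg_to_kd', got {direction!r}")
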