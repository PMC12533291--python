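"""Protein structure input and van der Waals radius assignment.

Structures are read from fixed-column PDB files (v3.3 ATOM/HETATM records)
with Bio.PDB and flattened into a simple ordered atom list — the rest of the
pipeline only needs element, coordinates and a vdW radius per atom. Radii
come from the Bondi (1964) compilation with a configurable fallback for
elements outside the table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "RadiusTable",
    "BONDI_RADII",
    "read_structure",
    "assign_radii",
    "write_structure",
]

#: Bondi (1964) van der Waals radii in Å, plus common biologically relevant
#: metals. Keys are capitalized element symbols.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Se": 1.90,
    "B": 1.92,
    "Si": 2.10,
    "Na": 2.27,
    "K": 2.75,
    "Mg": 1.73,
    "Ca": 2.31,
    "Zn": 1.39,
    "Cu": 1.40,
    "Ni": 1.63,
    "Fe": 1.52,
    "Mn": 1.61,
}


@dataclass
class AtomRecord:
    """One atom of a structure.

    ``radius`` is None until :func:`assign_radii` has run.
    """

    element: str
    position: np.ndarray
    chain_id: str
    residue_number: int
    residue_name: str
    record_kind: str  # "ATOM" or "HETATM"
    name: str = ""
    insertion_code: str = ""
    radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position!r}")
        if not self.element:
            raise ValueError("atom element must be non-empty after parsing")


@dataclass
class MolecularStructure:
    """An ordered list of atoms from a single conformation."""

    atoms: list[AtomRecord]
    conformer_label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a structure needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(n_atoms,) array of vdW radii; raises if radii are unassigned."""
        r = [a.radius for a in self.atoms]
        if any(x is None for x in r):
            raise ValueError("structure has unassigned radii; call assign_radii first")
        return np.array(r, dtype=float)

    def translated(self, shift) -> "MolecularStructure":
        """Rigidly translated copy (used by invariance tests and fixtures)."""
        shift = np.asarray(shift, dtype=float)
        atoms = [replace(a, position=a.position + shift) for a in self.atoms]
        return MolecularStructure(atoms=atoms, conformer_label=self.conformer_label)


@dataclass
class RadiusTable:
    """Element → vdW radius map with a default for unknown elements."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = 1.50

    def __post_init__(self) -> None:
        for el, r in {**self.radii, "<default>": self.default_radius}.items():
            if not (0.5 < r < 3.0):
                raise ValueError(f"vdW radius for {el} out of the plausible (0.5, 3.0) Å range: {r}")

    def lookup(self, element: str) -> tuple[float, bool]:
        """Return (radius, known). Lookup is case-normalized ('ZN' → 'Zn')."""
        key = element.strip().capitalize()
        if key in self.radii:
            return self.radii[key], True
        return self.default_radius, False


def _infer_element(bio_atom) -> str:
    """Element column (cols 77–78) when present, else first alphabetic
    character of the atom name."""
    el = (bio_atom.element or "").strip()
    if el and el != "X":
        return el.capitalize()
    for ch in bio_atom.get_name():
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(path, keep_het: bool = False, conformer_label: str | None = None) -> MolecularStructure:
    """Read a PDB file into a :class:`MolecularStructure`.

    Parameters
    ----------
    path:
        PDB file with fixed-column ATOM/HETATM records. Only the first MODEL
        is used; alternate conformations are supplied as separate files.
    keep_het:
        If False (default), waters and all other HETATM records are dropped —
        the surface analysis concerns the protein (and any adaptor chains,
        which are ordinary ATOM records) only.

    Raises
    ------
    ValueError
        If the file cannot be parsed or contains zero atoms after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            bio = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # Bio.PDB raises a mix of exception types
            raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    models = list(bio)
    if not models:
        raise ValueError(f"zero atoms read from {path}")
    model = models[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            is_het = hetflag.strip() != ""
            if is_het and not keep_het:
                continue
            for bio_atom in residue:
                element = _infer_element(bio_atom)
                if not element:
                    logger.warning("skipping atom with no inferable element: %s", bio_atom)
                    continue
                atoms.append(
                    AtomRecord(
                        element=element,
                        position=bio_atom.get_coord().astype(float),
                        chain_id=chain.id,
                        residue_number=int(resseq),
                        residue_name=residue.get_resname().strip(),
                        record_kind="HETATM" if is_het else "ATOM",
                        name=bio_atom.get_name(),
                        insertion_code=icode.strip(),
                    )
                )
    if not atoms:
        raise ValueError(f"zero atoms after filtering in {path}")
    return MolecularStructure(atoms=atoms, conformer_label=conformer_label or path.stem)


def write_structure(structure: MolecularStructure, path) -> None:
    """Write a structure as fixed-column PDB ATOM/HETATM records.

    Coordinates are written to 3 decimals (the PDB precision), so a
    read → write → read round trip is lossless at that precision.
    """
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            name = a.name or a.element
            # standard alignment: 1-letter element names start in column 14
            name_field = f" {name:<3s}" if len(a.element) == 1 and len(name) <= 3 else f"{name:<4s}"
            fh.write(
                "%-6s%5d %4s %3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
                % (
                    a.record_kind,
                    i % 100000,
                    name_field,
                    a.residue_name[:3],
                    (a.chain_id or "A")[:1],
                    a.residue_number % 10000,
                    a.insertion_code[:1],
                    a.position[0],
                    a.position[1],
                    a.position[2],
                    1.0,
                    0.0,
                    a.element.upper()[:2],
                )
            )
        fh.write("END\n")


def assign_radii(structure: MolecularStructure, table: RadiusTable | None = None) -> MolecularStructure:
    """Assign a vdW radius to every atom (in place; the structure is returned).

    Unknown elements receive ``table.default_radius`` and a logged warning.
    Idempotent: re-running with the same table leaves radii unchanged.
    """
    table = table or RadiusTable()
    unknown: set[str] = set()
    for atom in structure.atoms:
        radius, known = table.lookup(atom.element)
        atom.radius = radius
        if not known:
            unknown.add(atom.element)
    for el in sorted(unknown):
        logger.warning(
            "element %r not in radius table; using default %.2f Å", el, table.default_radius
        )
    return structure
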