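"""Protein structures and solvent-accessible surface area.

The surface/buried call that drives candidate selection comes from an
in-house Shrake-Rupley implementation: each atom's sphere (vdW radius +
probe) is sampled on a deterministic golden-spiral lattice and the fraction
of points not occluded by any neighbouring expanded sphere gives the
accessible area. Relative accessibility is the residue total divided by a
tabulated per-residue-type maximum; residues at or above a threshold
fraction are classified as surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .tables import ELEMENT_RADII, MAX_ASA, THREE_TO_ONE

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960
DEFAULT_SURFACE_THRESHOLD = 0.25  # relative SASA at/above which a residue is "surface"


class StructureError(ValueError):
    """Raised for empty or malformed structures."""


class AtomTypingError(StructureError):
    """Raised when an atom's element has no radius in the table."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str  # three-letter code, upper case
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}:{self.number}{icode}"

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """One model's coordinates: chains -> residues -> atoms, author numbering."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        if not any(r.atoms for r in self.residues):
            raise StructureError("structure contains no atoms")

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coordinates(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom_residue_index(self) -> np.ndarray:
        """Residue index (into self.residues) of each atom, in atom order."""
        idx = []
        for i, r in enumerate(self.residues):
            idx.extend([i] * len(r.atoms))
        return np.asarray(idx, dtype=int)


@dataclass
class ResidueRecord:
    """Per-residue SASA summary used by the design stage."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    sasa: float  # Å²
    relative_sasa: float | None  # None for residue types absent from the max-ASA table
    is_surface: bool

    @property
    def key(self) -> str:
        return f"{self.chain_id}:{self.number}{self.insertion_code.strip()}"


def _infer_element(atom_name: str) -> str:
    """Fall back element guess from a PDB atom name (e.g. ' CA ' -> C)."""
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    # two-letter elements only when the name itself is a known symbol
    if stripped[:2].upper() in ELEMENT_RADII and len(stripped) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def read_structure(
    path,
    model_index: int = 0,
    chains: set[str] | None = None,
    drop_heteroatoms: bool = True,
    radii: dict[str, float] | None = None,
) -> Structure:
    """Read one model from a PDB file.

    Waters and HETATM records are dropped when ``drop_heteroatoms`` is set.
    Alternate locations are resolved to the highest-occupancy conformer,
    ties going to altloc 'A'. Raises :class:`AtomTypingError` if any kept
    atom's element has no entry in the radii table (the SASA step needs a
    radius for every atom).
    """
    from Bio.PDB import PDBParser

    radii = {**ELEMENT_RADII, **(radii or {})}
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure("s", str(path))
    models = list(bio_structure.get_models())
    if not models:
        raise StructureError(f"no coordinate models in {path}")
    if model_index >= len(models):
        raise StructureError(
            f"model_index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    residues: list[Residue] = []
    untyped: list[str] = []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain:
            hetfield, resseq, icode = res.id
            if drop_heteroatoms and hetfield.strip():
                continue
            residue = Residue(
                chain_id=chain.id,
                number=resseq,
                insertion_code=icode if icode.strip() else "",
                name=res.get_resname().strip().upper(),
            )
            for bio_atom in res:
                if bio_atom.is_disordered():
                    # highest occupancy wins; equal occupancies -> altloc 'A'
                    alts = sorted(
                        bio_atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    bio_atom = alts[0]
                element = (bio_atom.element or "").strip().upper()
                if element not in radii:
                    element = _infer_element(bio_atom.get_name())
                if element not in radii:
                    untyped.append(f"{residue.key}/{bio_atom.get_name()}")
                    continue
                residue.atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        element=element,
                        coord=np.asarray(bio_atom.get_coord(), dtype=float),
                    )
                )
            if residue.atoms:
                residues.append(residue)
    if untyped:
        raise AtomTypingError(
            "no radius for atoms: " + ", ".join(untyped[:10])
            + ("..." if len(untyped) > 10 else "")
        )
    if not residues:
        raise StructureError(f"no ATOM records retained from {path}")
    return Structure(residues=residues)


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (no RNG)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def atom_radii(structure: Structure, radii: dict[str, float] | None = None) -> np.ndarray:
    table = {**ELEMENT_RADII, **(radii or {})}
    out = []
    for atom in structure.atoms:
        try:
            out.append(table[atom.element])
        except KeyError:
            raise AtomTypingError(f"no radius for element {atom.element!r} ({atom.name})")
    return np.asarray(out, dtype=float)


def shrake_rupley(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Each atom's accessible area is the unoccluded fraction of ``n_points``
    golden-spiral samples on its expanded sphere times 4π(r+probe)².
    Occlusion is tested against every neighbour whose expanded sphere can
    reach the atom's, found with a KD-tree.
    """
    if n_points < 32:
        raise ValueError("n_points < 32: quadrature too coarse for a meaningful SASA")
    coords = structure.coordinates()
    expanded = atom_radii(structure, radii) + probe_radius
    n_atoms = len(coords)
    unit_sphere = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    sasa = np.empty(n_atoms, dtype=float)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit_sphere
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], expanded[i] + max_reach / 2.0)
            if j != i
            and np.dot(coords[j] - coords[i], coords[j] - coords[i])
            < (expanded[i] + expanded[j]) ** 2
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= expanded[j] ** 2
            if not accessible.any():
                break
        sasa[i] = accessible.mean() * 4.0 * math.pi * expanded[i] ** 2
    return sasa


def residue_sasa(structure: Structure, per_atom: np.ndarray) -> list[float]:
    """Sum per-atom SASA into per-residue totals (exact partition)."""
    idx = structure.atom_residue_index()
    totals = np.zeros(len(structure.residues))
    np.add.at(totals, idx, per_atom)
    return totals.tolist()


def relative_sasa(
    sasa: float, residue_name: str, max_asa: dict[str, float] | None = None
) -> float | None:
    """Residue SASA divided by the type's theoretical maximum.

    Returns None for residue types absent from the table (nonstandard
    residues are excluded from surface classification rather than guessed).
    """
    table = {**MAX_ASA, **(max_asa or {})}
    ref = table.get(residue_name.upper())
    if ref is None:
        return None
    return sasa / ref


def classify_surface(
    structure: Structure,
    threshold: float = DEFAULT_SURFACE_THRESHOLD,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
    max_asa: dict[str, float] | None = None,
    per_atom_sasa: np.ndarray | None = None,
) -> list[ResidueRecord]:
    """Per-residue SASA records with the surface flag set at ``threshold``.

    A residue is surface iff its relative SASA is defined and >= threshold.
    Pass ``per_atom_sasa`` to reuse a previous Shrake-Rupley run.
    """
    if per_atom_sasa is None:
        per_atom_sasa = shrake_rupley(structure, probe_radius, n_points, radii)
    totals = residue_sasa(structure, per_atom_sasa)
    records = []
    for res, total in zip(structure.residues, totals):
        rel = relative_sasa(total, res.name, max_asa)
        records.append(
            ResidueRecord(
                chain_id=res.chain_id,
                number=res.number,
                insertion_code=res.insertion_code,
                name=res.name,
                sasa=float(total),
                relative_sasa=rel,
                is_surface=(rel is not None and rel >= threshold),
            )
        )
    return records


def sasa_report_tsv(records: list[ResidueRecord]) -> str:
    lines = ["residue\tname\tsasa_A2\trelative_sasa\tsurface"]
    for r in records:
        rel = "NA" if r.relative_sasa is None else f"{r.relative_sasa:.4f}"
        lines.append(f"{r.key}\t{r.name}\t{r.sasa:.3f}\t{rel}\t{int(r.is_surface)}")
    return "\n".join(lines) + "\n"
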