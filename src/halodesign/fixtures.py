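"""Deterministic toy fixtures: peptides, alignments, ion trajectories.

These are geometric idealisations built to exercise the detectors — planted
salt bridges, chelation oxygen clusters, variable alignment columns, ion
shells at stated radii — not physical models. Side chains are pseudo-atoms
carrying the atom names the detectors key on. Every generator is a pure
function of its arguments and seed.
"""

from __future__ import annotations

import numpy as np

from .msa import Alignment
from .rdf import Trajectory
from .structure import Atom, Residue, Structure
from .tables import AMINO_ACIDS, ONE_TO_THREE

CA_SPACING = 3.8  # Å, consecutive Cα distance in the extended geometry


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Structures


def _backbone(residue: Residue, ca: np.ndarray, direction: np.ndarray) -> None:
    """Idealised N-CA-C=O backbone around a Cα position."""
    d = direction / np.linalg.norm(direction)
    up = np.array([0.0, 0.0, 1.0])
    residue.atoms.extend(
        [
            Atom("N", "N", ca - 1.46 * d),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + 1.52 * d),
            Atom("O", "O", ca + 1.52 * d + 1.23 * up),
        ]
    )


_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    # offsets from Cα, roughly stacked outward along +y
    "ALA": [("CB", "C", (0.0, 1.5, 0.0))],
    "SER": [("CB", "C", (0.0, 1.5, 0.0)), ("OG", "O", (0.0, 2.9, 0.0))],
    "LEU": [
        ("CB", "C", (0.0, 1.5, 0.0)),
        ("CG", "C", (0.0, 3.0, 0.0)),
        ("CD1", "C", (-0.9, 4.1, 0.0)),
        ("CD2", "C", (0.9, 4.1, 0.0)),
    ],
    "ASP": [
        ("CB", "C", (0.0, 1.5, 0.0)),
        ("CG", "C", (0.0, 3.0, 0.0)),
        ("OD1", "O", (-1.1, 3.7, 0.0)),
        ("OD2", "O", (1.1, 3.7, 0.0)),
    ],
    "GLU": [
        ("CB", "C", (0.0, 1.5, 0.0)),
        ("CG", "C", (0.0, 3.0, 0.0)),
        ("CD", "C", (0.0, 4.5, 0.0)),
        ("OE1", "O", (-1.1, 5.2, 0.0)),
        ("OE2", "O", (1.1, 5.2, 0.0)),
    ],
    "LYS": [
        ("CB", "C", (0.0, 1.5, 0.0)),
        ("CG", "C", (0.0, 3.0, 0.0)),
        ("CD", "C", (0.0, 4.5, 0.0)),
        ("CE", "C", (0.0, 6.0, 0.0)),
        ("NZ", "N", (0.0, 7.4, 0.0)),
    ],
    "ARG": [
        ("CB", "C", (0.0, 1.5, 0.0)),
        ("CG", "C", (0.0, 3.0, 0.0)),
        ("CD", "C", (0.0, 4.5, 0.0)),
        ("NE", "N", (0.0, 5.9, 0.0)),
        ("NH1", "N", (-1.0, 7.0, 0.0)),
        ("NH2", "N", (1.0, 7.0, 0.0)),
    ],
    "GLY": [],
}


def _add_side_chain(residue: Residue, name: str, ca: np.ndarray) -> None:
    for atom_name, element, offset in _SIDE_CHAINS.get(name, [("CB", "C", (0.0, 1.5, 0.0))]):
        residue.atoms.append(Atom(atom_name, element, ca + np.asarray(offset)))


def make_peptide(
    n_residues: int,
    geometry: str = "extended",
    residue_names: dict[int, str] | None = None,
    salt_bridges: list[tuple[int, int, float]] | None = None,
    chelation_plants: list[tuple[int, int]] | None = None,
    hydrophobic_pairs: list[tuple[int, int]] | None = None,
    chain_id: str = "A",
) -> Structure:
    """Idealised peptide with optional planted interactions.

    Residues are numbered from 1. ``residue_names`` overrides the default
    GLY/SER alternation at given positions. Plants (1-based positions):

    - salt_bridges [(acidic_pos, basic_pos, O-N distance Å)]: acidic position
      becomes ASP, basic becomes LYS, with NZ placed exactly the stated
      distance from OD1.
    - chelation_plants [(glu_pos, carbonyl_pos)]: glu_pos becomes GLU with
      its carboxylate oxygens moved next to carbonyl_pos's backbone O,
      forming a three-oxygen cation-chelation cluster.
    - hydrophobic_pairs [(a, b)]: both become LEU and b's side chain is
      interdigitated with a's.
    """
    if n_residues < 1:
        raise FixtureError("n_residues must be >= 1")
    names = {}
    for i in range(1, n_residues + 1):
        names[i] = "GLY" if i % 2 else "SER"
    names.update({p: n.upper() for p, n in (residue_names or {}).items()})

    salt_bridges = salt_bridges or []
    chelation_plants = chelation_plants or []
    hydrophobic_pairs = hydrophobic_pairs or []
    planted_roles: dict[int, str] = {}
    for a, b, _ in salt_bridges:
        for pos, role in ((a, "ASP"), (b, "LYS")):
            if planted_roles.get(pos, role) != role:
                raise FixtureError(f"position {pos} planted with conflicting roles")
            planted_roles[pos] = role
    for g, _ in chelation_plants:
        if planted_roles.get(g, "GLU") != "GLU":
            raise FixtureError(f"position {g} planted with conflicting roles")
        planted_roles[g] = "GLU"
    for a, b in hydrophobic_pairs:
        for pos in (a, b):
            if planted_roles.get(pos, "LEU") != "LEU":
                raise FixtureError(f"position {pos} planted with conflicting roles")
            planted_roles[pos] = "LEU"
    names.update(planted_roles)

    residues = []
    x_axis = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_residues + 1):
        if geometry == "extended":
            ca = np.array([CA_SPACING * (i - 1), 0.0, 0.0])
        elif geometry == "helix-like":
            theta = np.deg2rad(100.0) * (i - 1)
            ca = np.array([1.5 * (i - 1), 2.3 * np.cos(theta), 2.3 * np.sin(theta)])
        else:
            raise FixtureError(f"unknown geometry {geometry!r}")
        res = Residue(chain_id=chain_id, number=i, insertion_code="", name=names[i])
        _backbone(res, ca, x_axis)
        _add_side_chain(res, names[i], ca)
        residues.append(res)
    structure = Structure(residues=residues)

    by_number = {r.number: r for r in structure.residues}
    for a, b, dist in salt_bridges:
        od1 = by_number[a].atom("OD1")
        od2 = by_number[a].atom("OD2")
        nz = by_number[b].atom("NZ")
        # along the OD2->OD1 axis so OD1 is the *minimum* O-N distance
        away = od1.coord - od2.coord
        away = away / np.linalg.norm(away)
        nz.coord = od1.coord + dist * away
    for g, c in chelation_plants:
        # carboxylate oxygens sit beyond the target carbonyl, away from the
        # chain (+x), so planting on the LAST residue yields one isolated
        # three-oxygen cluster with no neighbouring backbone carbonyl in reach
        carbonyl = by_number[c].atom("O")
        oe1, oe2 = by_number[g].atom("OE1"), by_number[g].atom("OE2")
        oe1.coord = carbonyl.coord + np.array([2.2, 0.6, 0.0])
        oe2.coord = carbonyl.coord + np.array([2.2, -0.6, 0.0])
    for a, b in hydrophobic_pairs:
        shift = by_number[a].atom("CG").coord + np.array([0.0, 1.0, 0.9])
        anchor = by_number[b].atom("CG").coord
        for atom in by_number[b].atoms:
            if atom.name not in ("N", "CA", "C", "O"):
                atom.coord = atom.coord - anchor + shift
    return structure


def make_buried_cluster(n_shell: int = 40, shell_radius: float = 4.0) -> Structure:
    """A central GLY fully caged by a shell of occluding pseudo-residues.

    The central residue's relative SASA lands near zero — the buried-core
    test case for surface classification.
    """
    center = Residue(chain_id="A", number=1, insertion_code="", name="GLY")
    _backbone(center, np.zeros(3), np.array([1.0, 0.0, 0.0]))
    residues = [center]
    from .structure import golden_spiral_points

    for i, point in enumerate(golden_spiral_points(n_shell), start=2):
        res = Residue(chain_id="A", number=i, insertion_code="", name="ALA")
        res.atoms.append(Atom("CB", "C", shell_radius * point))
        residues.append(res)
    return Structure(residues=residues)


def write_pdb(structure: Structure, path) -> None:
    """Minimal single-model PDB writer for fixtures."""
    with open(path, "w") as fh:
        serial = 1
        for res in structure.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:>5d} {name}{'':1s}{res.name:<3s} {res.chain_id}"
                    f"{res.number:>4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Alignments


def make_alignment(
    n_rows: int,
    length: int,
    variable_columns: dict[int, dict[str, float]] | None = None,
    gap_columns: dict[int, float] | None = None,
    seed: int = 0,
    query_id: str = "query",
    base_residue: str = "A",
) -> Alignment:
    """Sampled alignment with planted column compositions.

    ``variable_columns`` maps 0-based column -> residue frequency dict
    (must sum to 1); other columns are invariant ``base_residue``.
    ``gap_columns`` maps column -> fraction of non-query rows gapped.
    Row 0 is the query and is never gapped. Expected column entropy equals
    the planted frequency entropy.
    """
    rng = np.random.default_rng(seed)
    variable_columns = variable_columns or {}
    gap_columns = gap_columns or {}
    for col, freqs in variable_columns.items():
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise FixtureError(f"column {col}: frequencies sum to {sum(freqs.values())}")
        bad = set(freqs) - set(AMINO_ACIDS)
        if bad:
            raise FixtureError(f"column {col}: invalid residues {sorted(bad)}")

    rows = [[base_residue] * length for _ in range(n_rows)]
    for col, freqs in variable_columns.items():
        letters = sorted(freqs)
        probs = [freqs[l] for l in letters]
        draws = rng.choice(letters, size=n_rows, p=probs)
        for r in range(n_rows):
            rows[r][col] = str(draws[r])
    for col, frac in gap_columns.items():
        n_gap = int(round(frac * (n_rows - 1)))
        gap_rows = rng.choice(np.arange(1, n_rows), size=n_gap, replace=False)
        for r in gap_rows:
            rows[r][col] = "-"
    records = [(query_id if r == 0 else f"homolog_{r}", "".join(rows[r])) for r in range(n_rows)]
    return Alignment(records=records)


# ---------------------------------------------------------------------------
# Trajectories


def make_ion_trajectory(
    protein_coords: np.ndarray,
    n_ions: int,
    n_frames: int,
    shells: list[tuple[float, float]] | None = None,
    uniform_weight: float = 0.0,
    box_size: float = 40.0,
    seed: int = 0,
    ion_name: str = "NA",
) -> Trajectory:
    """Ions sampled per frame from a mixture of distance shells and a uniform
    background, around a fixed protein point set centred in a cubic box.

    ``shells`` is [(radius Å, weight)]; weights plus ``uniform_weight`` are
    normalised. Shell ions sit at exactly the stated minimum distance from a
    randomly chosen protein atom (use a single-atom "protein" when exact
    peak radii must be recovered). Groups: "protein", "ions".
    """
    protein_coords = np.atleast_2d(np.asarray(protein_coords, dtype=float))
    shells = shells or []
    weights = np.array([w for _, w in shells] + [uniform_weight], dtype=float)
    if weights.sum() <= 0:
        raise FixtureError("shell weights and uniform_weight are all zero")
    weights = weights / weights.sum()
    radius_of = [r for r, _ in shells]
    protein_extent = np.linalg.norm(
        protein_coords - protein_coords.mean(axis=0), axis=1
    ).max()
    for r in radius_of:
        if r <= 0:
            raise FixtureError(f"shell radius {r} must be positive")
    if radius_of and max(radius_of) + protein_extent > box_size / 2:
        raise FixtureError("shells do not fit inside the box around the protein")

    rng = np.random.default_rng(seed)
    center = np.full(3, box_size / 2.0)
    prot = protein_coords - protein_coords.mean(axis=0) + center
    n_prot = len(prot)

    frames = np.empty((n_frames, n_prot + n_ions, 3))
    frames[:, :n_prot] = prot
    for f in range(n_frames):
        for i in range(n_ions):
            mode = rng.choice(len(weights), p=weights)
            if mode < len(shells):
                r = radius_of[mode]
                anchor = prot[rng.integers(n_prot)]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                frames[f, n_prot + i] = anchor + r * direction
            else:
                frames[f, n_prot + i] = rng.uniform(0.0, box_size, size=3)
    return Trajectory(
        frames=frames,
        groups={
            "protein": np.arange(n_prot),
            "ions": np.arange(n_prot, n_prot + n_ions),
        },
        box=np.full(3, box_size),
        frame_spacing_ps=10.0,
    )


def trajectory_atom_names(traj: Trajectory, protein_name: str = "C", ion_name: str = "NA") -> list[str]:
    names = [protein_name] * len(traj.group("protein")) + [ion_name] * len(traj.group("ions"))
    if len(names) != traj.n_atoms:
        raise FixtureError("groups do not partition the trajectory atoms")
    return names
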