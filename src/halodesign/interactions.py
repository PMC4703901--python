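"""Interaction detection: salt bridges, hydrophobic contacts, cation-chelation sites.

Positions already engaged in stabilising contacts are excluded from the
acidification design; chelation microenvironments (three or more
coordinating oxygens from Asp/Glu carboxylates and backbone carbonyls
around a common point) are where long-lived Na+ association is expected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Residue, Structure

ACIDIC = {"ASP", "GLU"}
BASIC = {"LYS", "ARG", "HIS"}
APOLAR = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}

CARBOXYLATE_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_N = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # Å, carboxylate O to basic N
DEFAULT_HYDROPHOBIC_CUTOFF = 4.5  # Å, side-chain C to side-chain C
DEFAULT_MIN_ATOM_PAIRS = 3
DEFAULT_CHELATION_RADIUS = 3.0  # Å around the candidate site centre
DEFAULT_MIN_OXYGENS = 3
CENTROID_MERGE_DISTANCE = 1.5  # Å


@dataclass(frozen=True)
class SaltBridge:
    acidic: str  # residue key "chain:number"
    basic: str
    distance: float  # minimum O-N distance, Å


@dataclass(frozen=True)
class HydrophobicContact:
    residue_a: str
    residue_b: str
    atom_pairs: int  # carbon pairs within cutoff


@dataclass(frozen=True)
class ChelationSite:
    centroid: tuple[float, float, float]
    oxygen_atoms: tuple[str, ...]  # "chain:number/ATOM"
    count: int
    residues: tuple[str, ...]


@dataclass
class InteractionSet:
    salt_bridges: list[SaltBridge] = field(default_factory=list)
    hydrophobic_contacts: list[HydrophobicContact] = field(default_factory=list)
    chelation_sites: list[ChelationSite] = field(default_factory=list)

    def involved_positions(self) -> set[str]:
        """Residue keys engaged in a salt bridge or hydrophobic contact."""
        keys: set[str] = set()
        for sb in self.salt_bridges:
            keys.update((sb.acidic, sb.basic))
        for hc in self.hydrophobic_contacts:
            keys.update((hc.residue_a, hc.residue_b))
        return keys


def _side_chain_atoms(residue: Residue, names: tuple[str, ...]) -> list:
    atoms = [residue.atom(n) for n in names]
    return [a for a in atoms if a is not None]


def find_salt_bridges(
    structure: Structure,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    include_histidine: bool = True,
) -> list[SaltBridge]:
    """Acidic-basic pairs with any carboxylate O within ``cutoff`` of a basic N.

    His is counted as a basic partner by default (protonation-agnostic);
    pass include_histidine=False to restrict to Lys/Arg. Residues missing
    their charged side-chain atoms are skipped with a warning.
    """
    acidic, basic = [], []
    for res in structure.residues:
        if res.name in ACIDIC:
            atoms = _side_chain_atoms(res, CARBOXYLATE_O[res.name])
            if not atoms:
                warnings.warn(f"{res.key} ({res.name}): carboxylate oxygens missing, skipped")
                continue
            acidic.append((res, atoms))
        elif res.name in BASIC:
            if res.name == "HIS" and not include_histidine:
                continue
            atoms = _side_chain_atoms(res, BASIC_N[res.name])
            if not atoms:
                warnings.warn(f"{res.key} ({res.name}): basic nitrogens missing, skipped")
                continue
            basic.append((res, atoms))

    bridges = []
    for (ares, aatoms), (bres, batoms) in itertools.product(acidic, basic):
        dmin = min(
            float(np.linalg.norm(a.coord - b.coord))
            for a in aatoms
            for b in batoms
        )
        if dmin <= cutoff:
            bridges.append(SaltBridge(acidic=ares.key, basic=bres.key, distance=dmin))
    bridges.sort(key=lambda b: (b.acidic, b.basic))
    return bridges


def find_hydrophobic_contacts(
    structure: Structure,
    cutoff: float = DEFAULT_HYDROPHOBIC_CUTOFF,
    min_atom_pairs: int = DEFAULT_MIN_ATOM_PAIRS,
) -> list[HydrophobicContact]:
    """Apolar residue pairs with >= ``min_atom_pairs`` side-chain C pairs in contact."""
    candidates = []
    for res in structure.residues:
        if res.name not in APOLAR:
            continue
        carbons = [
            a
            for a in res.atoms
            if a.element == "C" and a.name not in ("C", "CA")  # side chain only
        ]
        if carbons:
            candidates.append((res, np.array([a.coord for a in carbons])))

    contacts = []
    for (ra, ca), (rb, cb) in itertools.combinations(candidates, 2):
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
        pairs = int((d <= cutoff).sum())
        if pairs >= min_atom_pairs:
            contacts.append(
                HydrophobicContact(residue_a=ra.key, residue_b=rb.key, atom_pairs=pairs)
            )
    contacts.sort(key=lambda c: (c.residue_a, c.residue_b))
    return contacts


def _candidate_oxygens(structure: Structure) -> list[tuple[str, str, np.ndarray]]:
    """Coordinating oxygens: Asp/Glu carboxylate O and backbone carbonyl O."""
    out = []
    for res in structure.residues:
        names = set(CARBOXYLATE_O.get(res.name, ())) | {"O"}
        for atom in res.atoms:
            if atom.name in names and atom.element == "O":
                out.append((res.key, f"{res.key}/{atom.name}", atom.coord))
    return out


def find_chelation_sites(
    structure: Structure,
    min_oxygens: int = DEFAULT_MIN_OXYGENS,
    radius: float = DEFAULT_CHELATION_RADIUS,
) -> list[ChelationSite]:
    """Clusters of >= ``min_oxygens`` coordinating oxygens around a common point.

    Candidate probe points are centroids of oxygen triples whose members all
    lie within ``radius`` of the centroid; overlapping candidates (centroids
    closer than 1.5 Å) are merged greedily, keeping the highest-count site.
    Deterministic and brute-force checkable.
    """
    oxygens = _candidate_oxygens(structure)
    if len(oxygens) < min_oxygens:
        return []
    coords = np.array([o[2] for o in oxygens])
    tree = cKDTree(coords)

    candidates = []  # (count, centroid, member indices)
    for triple in itertools.combinations(range(len(oxygens)), 3):
        centroid = coords[list(triple)].mean(axis=0)
        members = sorted(tree.query_ball_point(centroid, radius))
        if len(members) >= min_oxygens:
            candidates.append((len(members), centroid, tuple(members)))
    # highest-count candidates first; suppress near-duplicate centroids and
    # candidates whose oxygens are already covered by a kept site
    candidates.sort(key=lambda c: (-c[0], tuple(np.round(c[1], 6))))
    sites: list[ChelationSite] = []
    kept_centroids: list[np.ndarray] = []
    kept_members: list[set[int]] = []
    for count, centroid, members in candidates:
        if any(np.linalg.norm(centroid - kc) < CENTROID_MERGE_DISTANCE for kc in kept_centroids):
            continue
        if any(set(members) <= km for km in kept_members):
            continue
        kept_centroids.append(centroid)
        kept_members.append(set(members))
        sites.append(
            ChelationSite(
                centroid=tuple(float(x) for x in centroid),
                oxygen_atoms=tuple(oxygens[m][1] for m in members),
                count=count,
                residues=tuple(sorted({oxygens[m][0] for m in members})),
            )
        )
    sites.sort(key=lambda s: s.centroid)
    return sites


def find_interactions(
    structure: Structure,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    hydrophobic_cutoff: float = DEFAULT_HYDROPHOBIC_CUTOFF,
    min_atom_pairs: int = DEFAULT_MIN_ATOM_PAIRS,
    min_oxygens: int = DEFAULT_MIN_OXYGENS,
    chelation_radius: float = DEFAULT_CHELATION_RADIUS,
    include_histidine: bool = True,
) -> InteractionSet:
    return InteractionSet(
        salt_bridges=find_salt_bridges(structure, salt_bridge_cutoff, include_histidine),
        hydrophobic_contacts=find_hydrophobic_contacts(
            structure, hydrophobic_cutoff, min_atom_pairs
        ),
        chelation_sites=find_chelation_sites(structure, min_oxygens, chelation_radius),
    )


def interactions_report_tsv(iset: InteractionSet) -> str:
    lines = ["class\ta\tb\tvalue"]
    for sb in iset.salt_bridges:
        lines.append(f"salt_bridge\t{sb.acidic}\t{sb.basic}\t{sb.distance:.3f}")
    for hc in iset.hydrophobic_contacts:
        lines.append(f"hydrophobic\t{hc.residue_a}\t{hc.residue_b}\t{hc.atom_pairs}")
    for cs in iset.chelation_sites:
        lines.append(
            "chelation\t"
            + ",".join(cs.residues)
            + "\t"
            + ",".join(cs.oxygen_atoms)
            + f"\t{cs.count}"
        )
    return "\n".join(lines) + "\n"
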