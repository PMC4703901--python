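"""Staged surface-acidification design.

Combines three evidence streams — evolutionary variability, solvent
exposure, and freedom from existing stabilising interactions — into a
ranked candidate list; chooses Asp vs Glu per position by steric match with
a salt-bridge-opportunity override; and partitions the selected positions
into spatially dispersed stages (two parallel sets, their union, and an
extension), mirroring how halotolerance was introduced into carbonic
anhydrase II in increments so each increment's stability cost could be
measured.

Everything here is deterministic: ranking is lexicographic, dispersion is
greedy max-min with low-position tie-breaks, and no RNG is involved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .interactions import InteractionSet
from .msa import MsaProfile
from .mutations import Mutation, MutationSet
from .structure import ResidueRecord
from .tables import ONE_TO_THREE, RESIDUE_VOLUME

# Carboxylate reach window from Cβ of the mutated position to a basic
# nitrogen: close enough that the longer Glu side chain could complete a
# salt bridge, far enough that Asp could not.
SALT_BRIDGE_REACH = (3.0, 5.5)  # Å


class DesignError(ValueError):
    pass


@dataclass(eq=False)
class CandidateScore:
    position: int
    original: str  # one-letter
    variability: float
    relative_sasa: float
    surface: bool
    excluded_salt_bridge: bool = False
    excluded_hydrophobic: bool = False
    excluded_active_site: bool = False
    excluded_user: bool = False
    ca_coord: np.ndarray | None = None

    @property
    def eligible(self) -> bool:
        return self.surface and not (
            self.excluded_salt_bridge
            or self.excluded_hydrophobic
            or self.excluded_active_site
            or self.excluded_user
        )

    def flags(self) -> dict[str, bool]:
        return {
            "surface": self.surface,
            "salt_bridge": self.excluded_salt_bridge,
            "hydrophobic": self.excluded_hydrophobic,
            "active_site": self.excluded_active_site,
            "user": self.excluded_user,
        }


@dataclass
class DesignStage:
    label: str
    mutation_set: MutationSet
    provenance: str  # parallel | union | extension

    def positions(self) -> set[int]:
        return self.mutation_set.positions()


def _residue_key_to_position(key: str) -> int:
    # "A:57" -> 57; insertion codes are not produced by the fixtures
    return int("".join(ch for ch in key.split(":", 1)[1] if ch.isdigit()))


def candidate_positions(
    profile: MsaProfile,
    surface_records: list[ResidueRecord],
    interactions: InteractionSet,
    exclusions: set[int] | None = None,
    active_site: set[int] | None = None,
    ca_coords: dict[int, np.ndarray] | None = None,
) -> list[CandidateScore]:
    """Rank every profiled position, flagging why ineligible ones are out.

    Eligible candidates sort by variability (desc), then relative SASA
    (desc), then position (asc); ineligible positions trail in the same
    order so reports show the full picture. All inputs must share the
    query's native numbering.
    """
    exclusions = exclusions or set()
    active_site = active_site or set()
    by_position = {r.number: r for r in surface_records}
    bridged = {_residue_key_to_position(k) for b in interactions.salt_bridges for k in (b.acidic, b.basic)}
    hydrophobic = {
        _residue_key_to_position(k)
        for c in interactions.hydrophobic_contacts
        for k in (c.residue_a, c.residue_b)
    }

    scores = []
    for row in profile.table.itertuples():
        if row.low_coverage or math.isnan(getattr(row, profile.metric)):
            continue
        record = by_position.get(row.position)
        rel = record.relative_sasa if record and record.relative_sasa is not None else 0.0
        scores.append(
            CandidateScore(
                position=row.position,
                original=row.residue,
                variability=float(getattr(row, profile.metric)),
                relative_sasa=float(rel),
                surface=bool(record.is_surface) if record else False,
                excluded_salt_bridge=row.position in bridged,
                excluded_hydrophobic=row.position in hydrophobic,
                excluded_active_site=row.position in active_site,
                excluded_user=row.position in exclusions,
                ca_coord=None if ca_coords is None else ca_coords.get(row.position),
            )
        )
    scores.sort(key=lambda s: (-s.eligible, -s.variability, -s.relative_sasa, s.position))
    return scores


def choose_target_residue(
    original: str,
    neighbor_basic_distances: list[float] | None = None,
    volumes: dict[str, float] | None = None,
    reach: tuple[float, float] = SALT_BRIDGE_REACH,
) -> tuple[str, str]:
    """Pick Asp or Glu for a position; returns (one-letter choice, rationale).

    Default: the acidic residue whose volume is nearest the original's
    (steric conservatism; ties favour the smaller Asp). Override: if a basic
    side-chain nitrogen sits in the Glu-but-not-Asp reach window measured
    from the position's Cβ, Glu is chosen to create the salt bridge.
    ``neighbor_basic_distances`` are Cβ-to-basic-N distances in Å.
    """
    original = original.upper()
    if original in ("D", "E"):
        raise DesignError(f"position is already acidic ({original}); nothing to design")
    table = {**RESIDUE_VOLUME, **(volumes or {})}
    try:
        vol = table[ONE_TO_THREE[original]]
    except KeyError:
        raise DesignError(f"{original!r} is not a standard amino acid")
    d_diff = abs(vol - table["ASP"])
    e_diff = abs(vol - table["GLU"])
    choice = "D" if d_diff <= e_diff else "E"
    rationale = (
        f"volume match: {original} {vol:.1f} Å³ vs D {table['ASP']:.1f} / E {table['GLU']:.1f}"
        f" -> {choice}"
    )
    if choice == "D" and neighbor_basic_distances:
        lo, hi = reach
        reachable = [d for d in neighbor_basic_distances if lo <= d <= hi]
        if reachable:
            choice = "E"
            rationale = (
                f"salt-bridge opportunity: basic N at {min(reachable):.1f} Å from Cβ "
                f"within Glu reach window [{lo}, {hi}] -> E (overrides volume match D)"
            )
    return choice, rationale


def select_dispersed_set(
    candidates: list[CandidateScore],
    k: int,
    exclude: set[int] | None = None,
    seed_positions: set[int] | None = None,
) -> list[CandidateScore]:
    """Greedy max-min dispersion over Cα coordinates.

    Seeds with the farthest pair (or with ``seed_positions``, when spreading
    an extension away from already-chosen sites), then repeatedly adds the
    candidate whose minimum distance to the chosen set is largest. Ties
    break toward the lower residue number.
    """
    exclude = exclude or set()
    pool = [c for c in candidates if c.eligible and c.position not in exclude]
    if k > len(pool):
        raise DesignError(f"requested {k} positions but only {len(pool)} eligible")
    if k == 0:
        return []
    for c in pool:
        if c.ca_coord is None:
            raise DesignError(f"candidate {c.position} has no Cα coordinate")
    pool = sorted(pool, key=lambda c: c.position)
    coords = {c.position: np.asarray(c.ca_coord, dtype=float) for c in pool}

    chosen: list[CandidateScore] = []
    anchor_coords: list[np.ndarray] = [
        np.asarray(c.ca_coord, dtype=float)
        for c in candidates
        if seed_positions and c.position in seed_positions and c.ca_coord is not None
    ]

    if not anchor_coords:
        # farthest pair seed (ties -> lexicographically lowest position pair)
        best = None
        for i, a in enumerate(pool):
            for b in pool[i + 1 :]:
                d = float(np.linalg.norm(coords[a.position] - coords[b.position]))
                if best is None or d > best[0] + 1e-12:
                    best = (d, a, b)
        if k == 1:
            chosen = [pool[0]]
        else:
            chosen = [best[1], best[2]]

    def min_dist(c: CandidateScore) -> float:
        pts = anchor_coords + [coords[x.position] for x in chosen]
        return min(float(np.linalg.norm(coords[c.position] - p)) for p in pts)

    while len(chosen) < k:
        chosen_positions = {c.position for c in chosen}
        remaining = [c for c in pool if c.position not in chosen_positions]
        remaining.sort(key=lambda c: (-min_dist(c), c.position))
        chosen.append(remaining[0])
    chosen.sort(key=lambda c: c.position)
    return chosen[:k] if not anchor_coords else chosen


def min_pairwise_distance(candidates: list[CandidateScore]) -> float:
    pts = [np.asarray(c.ca_coord, dtype=float) for c in candidates]
    return min(
        float(np.linalg.norm(a - b))
        for i, a in enumerate(pts)
        for b in pts[i + 1 :]
    )


def _to_mutation_set(label: str, members: list[CandidateScore], choices: dict[int, str]) -> MutationSet:
    return MutationSet(
        label=label,
        mutations=[
            Mutation(c.original, c.position, choices[c.position])
            for c in sorted(members, key=lambda c: c.position)
        ],
    )


def stage_design(
    candidates: list[CandidateScore],
    stage_sizes: tuple[int, int, int] = (6, 6, 6),
    labels: tuple[str, str, str, str] = ("M1", "M2", "M3", "M4"),
    target_choices: dict[int, str] | None = None,
) -> list[DesignStage]:
    """Build the four-stage design: two disjoint dispersed sets, their union,
    and a dispersed extension.

    ``target_choices`` maps position -> 'D'/'E'; positions not listed fall
    back to the volume rule with no neighbour information.
    """
    s1, s2, s3 = stage_sizes
    eligible = [c for c in candidates if c.eligible]
    need = s1 + s2 + s3
    if len(eligible) < need:
        raise DesignError(
            f"need {need} eligible candidates for stages {stage_sizes}, have {len(eligible)}"
        )
    choices = dict(target_choices or {})
    for c in eligible:
        if c.position not in choices:
            choices[c.position] = choose_target_residue(c.original)[0]

    set_a = select_dispersed_set(candidates, s1)
    taken = {c.position for c in set_a}
    set_b = select_dispersed_set(candidates, s2, exclude=taken)
    taken |= {c.position for c in set_b}
    union = sorted(set_a + set_b, key=lambda c: c.position)
    ext = (
        select_dispersed_set(candidates, s3, exclude=taken, seed_positions=taken)
        if s3
        else []
    )

    la, lb, lc, ld = labels
    return [
        DesignStage(la, _to_mutation_set(la, set_a, choices), "parallel"),
        DesignStage(lb, _to_mutation_set(lb, set_b, choices), "parallel"),
        DesignStage(lc, _to_mutation_set(lc, union, choices), "union"),
        DesignStage(ld, _to_mutation_set(ld, union + ext, choices), "extension"),
    ]


def design_report_tsv(stages: list[DesignStage]) -> str:
    lines = ["stage\tprovenance\tsubstitutions"]
    for st in stages:
        subs = ", ".join(str(m) for m in st.mutation_set.mutations)
        lines.append(f"{st.label}\t{st.provenance}\t{subs}")
    return "\n".join(lines) + "\n"


def design_provenance_json(
    candidates: list[CandidateScore],
    stages: list[DesignStage],
    rationales: dict[int, str] | None = None,
) -> str:
    staged = {p: st.label for st in stages[:2] for p in st.positions()}
    for st in stages[2:]:
        for p in st.positions():
            staged.setdefault(p, st.label)
    payload = {
        "candidates": [
            {
                "position": c.position,
                "original": c.original,
                "variability": c.variability,
                "relative_sasa": c.relative_sasa,
                "eligible": c.eligible,
                "flags": c.flags(),
                "first_stage": staged.get(c.position),
                "rationale": (rationales or {}).get(c.position),
            }
            for c in candidates
        ]
    }
    return json.dumps(payload, indent=2)
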