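"""Point-mutation bookkeeping: parsing, application, composition and charge deltas.

Mutation sets use the standard one-letter notation ("G8D") in the protein's
native numbering. A staged design is a family of labelled sets related by
disjointness (parallel stages), union (combination stage) and strict
extension; `stage_algebra` verifies those relations exactly on
position-keyed sets. The packaged `staged_design_sets()` fixture is the
M1/M2/M3/M4 carbonic anhydrase II series used throughout the docs and tests.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .tables import AMINO_ACIDS, FORMAL_CHARGE

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class Mutation:
    original: str
    position: int
    replacement: str

    def __post_init__(self) -> None:
        for aa in (self.original, self.replacement):
            if aa not in AMINO_ACIDS:
                raise MutationError(f"{aa!r} is not a standard amino acid")
        if self.original == self.replacement:
            raise MutationError(
                f"identity substitution {self.original}{self.position}{self.replacement}"
            )
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.original}{self.position}{self.replacement}"


@dataclass
class MutationSet:
    label: str
    mutations: list[Mutation]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        dupes = [p for p, c in Counter(positions).items() if c > 1]
        if dupes:
            raise MutationError(f"{self.label}: duplicate positions {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.mutations)

    def positions(self) -> set[int]:
        return {m.position for m in self.mutations}

    def keyed(self) -> dict[int, Mutation]:
        return {m.position: m for m in self.mutations}

    def __str__(self) -> str:
        return f"{self.label}: " + ", ".join(str(m) for m in self.mutations)


def parse_mutation(text: str) -> Mutation:
    """Parse "G8D"-style notation; rejects malformed or identity substitutions."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise MutationError(f"cannot parse mutation {text!r} (expected e.g. 'G8D')")
    return Mutation(m.group(1).upper(), int(m.group(2)), m.group(3).upper())


def parse_mutation_set(label: str, text: str) -> MutationSet:
    parts = [p for p in re.split(r"[,\s]+", text.replace(" and ", ",")) if p]
    return MutationSet(label=label, mutations=[parse_mutation(p) for p in parts])


def read_mutation_tsv(path) -> dict[str, MutationSet]:
    """Read a TSV of (label, comma-separated substitutions) rows."""
    sets: dict[str, MutationSet] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or (i == 0 and line.lower().startswith("label")):
                continue
            label, _, rest = line.partition("\t")
            if not rest:
                raise MutationError(f"line {i + 1}: expected 'label<TAB>substitutions'")
            sets[label] = parse_mutation_set(label, rest)
    return sets


def staged_design_sets() -> dict[str, MutationSet]:
    """The packaged M1-M4 staged substitution sets (carbonic anhydrase II)."""
    ref = resources.files("halodesign").joinpath("data/table3.tsv")
    with resources.as_file(ref) as path:
        return read_mutation_tsv(path)


def apply_mutations(sequence: str, mset: MutationSet, numbering_offset: int = 0) -> str:
    """Apply a set to a sequence; ``numbering_offset`` shifts native numbering
    to the sequence index (e.g. offset 2 for an expressed construct carrying
    a two-residue N-terminal tag while native numbering is retained).
    """
    seq = list(sequence)
    for mut in mset.mutations:
        idx = mut.position - 1 + numbering_offset
        if idx < 0 or idx >= len(seq):
            raise MutationError(
                f"{mut}: position out of range for sequence of length {len(seq)}"
                f" (offset {numbering_offset})"
            )
        if seq[idx].upper() != mut.original:
            raise MutationError(
                f"{mut}: sequence mismatch at position {mut.position}: "
                f"expected {mut.original}, found {seq[idx].upper()}"
            )
        seq[idx] = mut.replacement
    return "".join(seq)


def diff_sequences(before: str, after: str, numbering_offset: int = 0, label: str = "diff") -> MutationSet:
    """Recover the mutation set separating two equal-length sequences."""
    if len(before) != len(after):
        raise MutationError("sequences differ in length")
    muts = [
        Mutation(b.upper(), i + 1 - numbering_offset, a.upper())
        for i, (b, a) in enumerate(zip(before, after))
        if b.upper() != a.upper()
    ]
    return MutationSet(label=label, mutations=muts)


@dataclass
class CompositionDelta:
    """Signed per-amino-acid count changes produced by a mutation set."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {aa: int(self.counts.get(aa, 0)) for aa in AMINO_ACIDS}

    def __getitem__(self, aa: str) -> int:
        return self.counts[aa]

    def nonzero(self) -> dict[str, int]:
        return {aa: c for aa, c in self.counts.items() if c != 0}

    def to_json(self) -> str:
        return json.dumps(self.nonzero(), sort_keys=True)


def composition_delta(mset: MutationSet) -> CompositionDelta:
    counts: Counter[str] = Counter()
    for mut in mset.mutations:
        counts[mut.original] -= 1
        counts[mut.replacement] += 1
    return CompositionDelta(counts=dict(counts))


def formal_charge_delta(mset: MutationSet) -> tuple[int, list[str]]:
    """Net formal-charge change and a list of His-involving mutations.

    Asp/Glu count -1, Lys/Arg +1, His 0 (pH-ambiguous; such mutations are
    returned in the flag list so the caller can see the assumption).
    """
    delta = 0
    his_flagged = []
    for mut in mset.mutations:
        delta += FORMAL_CHARGE[mut.replacement] - FORMAL_CHARGE[mut.original]
        if "H" in (mut.original, mut.replacement):
            his_flagged.append(str(mut))
    return delta, his_flagged


@dataclass
class RelationResult:
    relation: str
    labels: tuple[str, ...]
    holds: bool
    witness: str  # empty when the relation holds


def stage_algebra(
    sets: dict[str, MutationSet],
    relations: list[tuple[str, ...]],
) -> list[RelationResult]:
    """Check (relation, labels...) assertions on position-keyed sets.

    Supported relations: ("disjoint", a, b), ("union", child, parent_a,
    parent_b), ("subset", small, big). Comparison is exact on the full
    (original, position, replacement) triples, keyed by position.
    """
    results = []
    for rel in relations:
        name, *labels = rel
        for lab in labels:
            if lab not in sets:
                raise KeyError(f"unknown mutation-set label {lab!r}")
        keyed = [sets[lab].keyed() for lab in labels]
        if name == "disjoint":
            common = set(keyed[0]) & set(keyed[1])
            holds = not common
            witness = "" if holds else f"shared positions {sorted(common)}"
        elif name == "union":
            child, pa, pb = keyed
            merged = {**pa, **pb}
            holds = child == merged and set(pa) | set(pb) == set(child)
            mismatch = set(child) ^ (set(pa) | set(pb))
            witness = "" if holds else f"position mismatch {sorted(mismatch)}"
        elif name == "subset":
            small, big = keyed
            holds = all(p in big and big[p] == m for p, m in small.items()) and len(
                small
            ) < len(big)
            missing = [p for p in small if p not in big or big[p] != small[p]]
            witness = "" if holds else f"missing/mismatched positions {sorted(missing)}"
        else:
            raise ValueError(f"unknown relation {name!r}")
        results.append(
            RelationResult(relation=name, labels=tuple(labels), holds=holds, witness=witness)
        )
    return results
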