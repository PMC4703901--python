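# Methods

## The design model

The pipeline operationalises one mechanism of halophilic adaptation —
increased density of acidic residues on the solvent-exposed surface — as a
sequence of deterministic filters and selections over a query enzyme:

1. **Evolutionary tolerance.** Positions are scored by variability across a
   homolog alignment supplied by the user (building the alignment itself is
   out of scope). The default score is per-column Shannon entropy in bits
   with gaps excluded; a distinct-residue count is offered because
   "variability" is not uniquely defined and both orderings agree on
   uniform-frequency columns. Columns whose non-gap coverage falls below
   `min_coverage` (default 0.5) are flagged and left unscored rather than
   given a misleading 0 — alignment ends are gap-dominated and unreliable.
   Scores are reported in the query's own residue numbering via a
   column→position map; `start_number` lets constructs with N-terminal
   expression tags keep native numbering.

2. **Surface exposure.** Solvent-accessible surface area is computed by the
   Shrake–Rupley method: each atom's sphere is expanded by the probe radius
   (default 1.4 Å, water) and sampled at `n_points` quadrature points; the
   unoccluded fraction times the expanded-sphere area is the atom's SASA.
   The point set is a golden-spiral lattice, so results are bit-reproducible
   with no RNG; fewer than 32 points is refused as meaningless quadrature.
   At the default 960 points the error against the closed-form area of an
   isolated sphere and against the two-sphere spherical-cap formula is
   well under 0.1 % (the test suite asserts 1 %). Element radii are
   Bondi-style values; per-residue SASA is the exact sum of its atoms'.
   Relative SASA divides by a Tien-style theoretical maximum per residue
   type; residues at or above 0.25 are classified "surface". The 0.25
   threshold is a common convention standing in for what was originally a
   visual-inspection judgement, and is configurable. Relative values
   slightly above 1 occur for distorted or terminal geometries and are
   legitimate.

3. **Interaction exclusion.** Positions already stabilising the fold are
   removed: salt bridges (any Asp/Glu carboxylate O within 4.0 Å of Lys NZ,
   Arg NH1/NH2/NE or His ND1/NE2 — His counted protonation-agnostically,
   with a flag to exclude it) and hydrophobic contacts (two apolar residues
   with ≥ 3 side-chain carbon pairs within 4.5 Å). The cutoffs are standard
   structural-biology conventions; all are parameters and are echoed into
   report metadata.

4. **Target residue.** Asp vs Glu is decided by nearest side-chain volume
   (Zamyatnin residue volumes; ties to the smaller Asp), overridden to Glu
   when a basic nitrogen lies 3.0–5.5 Å from the position's Cβ — close
   enough for the longer Glu carboxylate to complete a salt bridge, too far
   for Asp. This formalises a judgement call ("steric bulk, with some
   consideration of new salt bridges") into a deterministic, logged rule;
   the rationale string records which rule fired. Historical designs include
   choices this rule cannot derive (e.g. a Lys→Asp where volume favours
   Glu); such cases are supplied as explicit overrides, not inferred.

5. **Staging and dispersion.** Candidates are ranked lexicographically —
   variability desc, relative SASA desc, position asc — with no learned
   weights, for transparency. Stages are chosen by greedy max–min dispersion
   on Cα coordinates: seed with the farthest pair, repeatedly add the
   candidate maximising its minimum distance to the chosen set, ties to the
   lower residue number. The extension stage disperses *away from* the
   already-chosen union by seeding with it. Greedy max–min is within 0.8×
   of the exhaustive optimum on every ≤ 12-candidate fixture tested (the
   classical 2-approximation bound guarantees ≥ 0.5). Stage algebra —
   parallel sets disjoint, union exact, extension a strict superset — is
   asserted on every output. Reproducing any specific historical design
   exactly is *not* claimed: human judgement entered those choices; what is
   asserted is cardinality and constraint satisfaction.

## Mutation bookkeeping

Mutations use one-letter "G8D" notation in native numbering; an expressed
construct with an N-terminal tag is handled by `numbering_offset` rather
than renumbering. Composition deltas are exact counts (−1 original, +1
replacement per mutation); the conservation identity (gains = losses = set
size, total zero) is a type invariant. Formal charge uses D/E = −1,
K/R = +1, H = 0 near pH 8 — His mutations are returned in a flag list so the
assumption is visible. The packaged staged design (M1/M2/M3/M4,
6/6/12/18 substitutions) ships as `data/table3.tsv` and is the fixture for
the bookkeeping tests.

## Ion association analyses

A pair g(r) against a whole, irregular protein is ill-defined without a
reference, so the whole-surface curve is defined as the distribution of each
ion's **minimum distance to any protein atom**, normalised by the same
statistic for pseudo-ions placed uniformly in the box (a seeded Monte-Carlo
ideal reference; 20× the real ion count per frame by default). The ratio
reads like a g(r): ≈ 1 at chance, > 1 where ions accumulate. The choice is
recorded in the curve metadata. No periodic imaging is applied in this mode
(solute-centred trajectories assumed).

Per-site curves use the textbook pair g(r): shell counts divided by bulk
density × shell volume × frames × site atoms, minimum-image convention,
orthorhombic boxes only; a missing box is an error rather than a silent
approximation.

Defaults: bin 0.05 Å, r_max 10 Å — fine enough to separate association
distances a few tenths of an Å apart (directly coordinated ~2.2 Å through
hydration-shell-mediated ~4.4–5.1 Å). Peak detection is a local-maximum
scan (scipy) with a height floor and a minimum separation, invariant to
uniform rescaling above the floor.

Residence events are contiguous runs of frames with ion–site minimum
distance ≤ 3.0 Å (direct coordination), merging runs separated by ≤ 2
frames — brief excursions to the first hydration shell shouldn't split one
visit into two. Merging is idempotent and durations are bounded by the
window; both are property-tested against a brute-force oracle.

## Synthetic fixtures

The fixture generators produce the study conditions for every test:
idealised extended or helix-like peptides with pseudo side chains carrying
only the atom names the detectors key on; alignments with planted per-column
residue frequencies (expected entropy equals the frequency entropy);
trajectories with ions drawn per frame from a mixture of exact
minimum-distance shells and a uniform background (alignment defaults: 50
rows, mirroring a typical homolog search; trajectories: tens of ions over
tens of frames, which resolves the planted structure while keeping the
suite in seconds). They are geometric idealisations, not physical models:
no excluded volume, no solvent, no correlated ion motion, no force field.
Tests passing on them demonstrate that the *detectors and estimators* are
correct — recovery of planted bridges, chelation clusters, shell radii
within one bin, enrichment ratios — not that the designed proteins are
stable; that remains an experimental question. Every generator is
deterministic given (arguments, seed). Chelation plants are placed on the
terminal residue's carbonyl with the carboxylate oxygens on the far side of
the chain; planting mid-chain legitimately creates additional
backbone-carbonyl clusters, which is the detector working as specified.

## Numerical and degenerate-input choices

- Alternate locations resolve to highest occupancy, ties to altloc 'A';
  waters/heteroatoms dropped by default; unknown elements are a typing
  error naming the atoms (SASA needs a radius for every atom).
- An empty effective alignment column yields NaN, never 0 — "no data" must
  not masquerade as "perfectly conserved".
- Chelation candidate sites are centroids of oxygen triples; near-duplicate
  centroids (< 1.5 Å) and sites whose oxygens are subsets of an
  already-kept site are suppressed, highest-count first — deterministic and
  brute-force checkable.
- Zero-ion site curves return all-zero g(r); empty-window or
  mismatched-binning comparisons raise.
- All stochastic components (fixture sampling, Monte-Carlo reference) take
  explicit seeds; the design path itself uses no RNG.

## Known limitations

- SASA is heavy-atom based; structures with explicit hydrogens will score
  slightly differently than with united-atom radii.
- The surface threshold, interaction cutoffs and the Glu reach window are
  conventions, not fitted values; sensitivity to them should be explored
  per target (they are all parameters).
- The whole-surface association curve depends on the sampling box through
  the Monte-Carlo reference; compare curves only between systems analysed
  with identical binning and boxes (`compare_association` enforces the
  binning half).
- mmCIF input, nucleic acids, hydrogen-bond networks, π-stacking, ΔΔG
  prediction and running molecular dynamics are out of scope.
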