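"""Run the full staged acidification design on synthetic inputs.

Variability profile + surface records + interaction map -> ranked
candidates -> Asp/Glu choice per position -> four spatially dispersed
stages: two parallel sets, their union, and an extension.
"""

import numpy as np

from halodesign import (
    candidate_positions,
    choose_target_residue,
    stage_design,
    variability_profile,
)
from halodesign import fixtures as fx
from halodesign.interactions import InteractionSet
from halodesign.structure import ResidueRecord

rng = np.random.default_rng(0)
aln = fx.make_alignment(
    50, 30,
    variable_columns={c: {"N": 0.4, "Q": 0.3, "S": 0.3} for c in range(0, 30, 1)},
    seed=1,
)
profile = variability_profile(aln, "query")
records = [
    ResidueRecord("A", i, "", "ASN", sasa=100.0, relative_sasa=0.6, is_surface=True)
    for i in range(1, 31)
]
ca = {i: rng.uniform(0, 30, 3) for i in range(1, 31)}

candidates = candidate_positions(profile, records, InteractionSet(), ca_coords=ca)
stages = stage_design(candidates, stage_sizes=(6, 6, 6))
for st in stages:
    subs = ", ".join(str(m) for m in st.mutation_set.mutations)
    print(f"{st.label} ({st.provenance}): {subs}")

choice, rationale = choose_target_residue("N")
print(f"\nwhy Asn -> {choice}: {rationale}")
# The two parallel stages are disjoint and internally spread out; the union
# stage combines them; the final stage extends the union by six more
# positions placed away from those already mutated.
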