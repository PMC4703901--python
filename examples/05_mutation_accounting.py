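"""Bookkeeping on the packaged staged carbonic anhydrase II design.

Prints each stage's size, amino-acid composition delta and net formal-charge
change, and verifies the stage algebra (disjointness, union, extension).
"""

from halodesign import composition_delta, formal_charge_delta, stage_algebra, staged_design_sets

sets = staged_design_sets()
for label, mset in sets.items():
    delta = composition_delta(mset)
    charge, _ = formal_charge_delta(mset)
    print(f"{label}: {len(mset)} substitutions, net charge {charge:+d}, "
          f"composition {delta.nonzero()}")

results = stage_algebra(
    sets,
    [("disjoint", "M1", "M2"), ("union", "M3", "M1", "M2"), ("subset", "M3", "M4")],
)
for r in results:
    print(f"{r.relation}{r.labels}: {'holds' if r.holds else 'FAILS ' + r.witness}")
# The final 18-substitution stage gains 10 Asp and 8 Glu while losing 5 Asn,
# 4 Gln, 3 Lys and 2 Val (one each of Gly/Leu/Arg/Thr), a net -22 formal
# charge: the acidified surface that confers halotolerance.
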