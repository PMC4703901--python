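"""Solvent accessibility and the surface/buried call.

Computes Shrake-Rupley SASA for a toy extended peptide and for a buried-core
cluster, printing each residue's relative accessibility and surface flag.
"""

from halodesign import classify_surface
from halodesign import fixtures as fx

peptide = fx.make_peptide(6)
print("extended peptide (everything exposed):")
for rec in classify_surface(peptide):
    print(f"  {rec.key:>5s} {rec.name}  SASA {rec.sasa:7.1f} A^2"
          f"  relative {rec.relative_sasa:.2f}  surface={rec.is_surface}")

cluster = fx.make_buried_cluster()
center = next(r for r in classify_surface(cluster) if r.number == 1)
print(f"\nburied center of an occluding cage: relative SASA "
      f"{center.relative_sasa:.3f} -> surface={center.is_surface}")
# A relative SASA at or above 0.25 marks a residue as surface; the caged
# residue falls far below that and is excluded from design.
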