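"""Detect the interactions a design must not disrupt.

Plants a salt bridge, a hydrophobic pair and a cation-chelation oxygen
cluster in toy peptides, then runs each detector.
"""

from halodesign import find_chelation_sites, find_hydrophobic_contacts, find_salt_bridges
from halodesign import fixtures as fx

bridged = fx.make_peptide(10, salt_bridges=[(2, 9, 3.5)])
for b in find_salt_bridges(bridged):
    print(f"salt bridge {b.acidic} - {b.basic} at {b.distance:.2f} A")

packed = fx.make_peptide(10, hydrophobic_pairs=[(2, 8)])
for c in find_hydrophobic_contacts(packed):
    print(f"hydrophobic contact {c.residue_a} - {c.residue_b}: {c.atom_pairs} C-C pairs")

chelating = fx.make_peptide(10, chelation_plants=[(3, 10)])
for s in find_chelation_sites(chelating):
    print(f"chelation site: {s.count} oxygens from {', '.join(s.residues)}"
          f" ({', '.join(s.oxygen_atoms)})")
# Salt-bridged or hydrophobically packed positions are flagged ineligible for
# acidification; three-or-more-oxygen sites are where long-lived Na+ binding
# is expected.
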