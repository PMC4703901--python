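"""Reference tables: element radii, maximum accessible surface areas, residue volumes.

All values in Å or Å²/Å³. Each consumer accepts an override mapping so a
caller can substitute their preferred parameter set without editing these.
"""

from __future__ import annotations

# Bondi-style van der Waals radii (Å) by element symbol.
ELEMENT_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "FE": 1.40,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
}

# Theoretical maximum accessible surface area per residue type (Å²),
# Tien et al. 2013 ("theoretical" column). Used to normalise residue SASA
# into a relative accessibility in [0, ~1.2].
MAX_ASA: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

# Mean residue volumes (Å³), Zamyatnin. Drive the Asp-vs-Glu steric choice:
# the replacement whose volume is nearer the original's wins by default.
RESIDUE_VOLUME: dict[str, float] = {
    "GLY": 60.1,
    "ALA": 88.6,
    "SER": 89.0,
    "CYS": 108.5,
    "ASP": 111.1,
    "PRO": 112.7,
    "ASN": 114.1,
    "THR": 116.1,
    "GLU": 138.4,
    "VAL": 140.0,
    "GLN": 143.8,
    "HIS": 153.2,
    "MET": 162.9,
    "ILE": 166.7,
    "LEU": 166.7,
    "LYS": 168.6,
    "ARG": 173.4,
    "PHE": 189.9,
    "TYR": 193.6,
    "TRP": 227.8,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

# Formal side-chain charge near pH 8. His is pH-ambiguous and scored 0;
# charge bookkeeping flags it so callers can see the assumption.
FORMAL_CHARGE: dict[str, int] = {
    **{aa: 0 for aa in AMINO_ACIDS},
    "D": -1,
    "E": -1,
    "K": +1,
    "R": +1,
}
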