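"""Amino-acid alphabets, 3-letter/1-letter translation and reference maximum ASA.

The 20 standard residues are indexed alphabetically by one-letter code; this
order is part of every versioned feature-vector layout and must never change
silently.
"""

from __future__ import annotations

# Fixed alphabetical order; index positions are baked into feature layouts.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AA)}

# Ambiguity codes tolerated in sequences but never counted as residues.
AMBIGUOUS_AA: frozenset[str] = frozenset("XBZU")

VALID_SEQUENCE_CHARS: frozenset[str] = frozenset(STANDARD_AA) | AMBIGUOUS_AA

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Theoretical maximum accessible surface area (Gly-X-Gly extended tripeptide),
# in A^2, used to normalize absolute accessibility into RSA.  Values follow the
# widely used theoretical Gly-X-Gly maxima; the table is swappable by config.
MAX_ASA_GXG: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
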