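"""Amino-acid tables shared across the package."""

from __future__ import annotations

# 20 standard residues, three-letter -> one-letter
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"  # sorted one-letter alphabet

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

UNIFORM_AA_FREQS = {aa: 1.0 / 20.0 for aa in STANDARD_AA}


def one_letter(resname: str) -> str:
    """Map a residue name to its one-letter code; non-standard residues -> 'X'."""
    return THREE_TO_ONE.get(resname.upper(), "X")
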