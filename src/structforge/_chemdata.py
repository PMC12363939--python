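"""Element tables used across sanitization and metrics.

Values are standard published constants: Cordero et al. single-bond covalent
radii, Bondi/Rowland van-der-Waals radii, and the Tien et al. (2013)
theoretical maximum accessible surface areas for extended Gly-X-Gly
tripeptides.
"""

from __future__ import annotations

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CO": 27, "NI": 28, "CU": 29, "ZN": 30, "BR": 35, "I": 53,
}

# Allowed bonded-electron-pair counts per element (neutral valence states).
STANDARD_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,),
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "P": (5, 3),
    "S": (2, 4, 6),
    "CL": (1,),
    "BR": (1,),
    "I": (1,),
}

# Elements whose over-valence reads as a positive formal charge (pnictogens);
# under-valence on these reads negative as well, mirroring amide anions.
POSITIVE_WHEN_HYPERVALENT = {"N", "P"}
# Elements whose under-valence reads as a negative formal charge.
NEGATIVE_WHEN_HYPOVALENT = {"O", "S", "F", "CL", "BR", "I", "N", "P", "C"}

# Single-bond covalent radii in Angstrom (Cordero 2008).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "NA": 1.66, "MG": 1.41, "P": 1.07, "S": 1.05, "CL": 1.02, "K": 2.03,
    "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24,
    "CU": 1.32, "ZN": 1.22, "BR": 1.20, "I": 1.39,
}

# Van-der-Waals radii in Angstrom for SASA (Bondi 1964 / Rowland 1996).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92,
    "NA": 2.27, "MG": 1.73, "K": 2.75, "CA": 2.31, "MN": 2.05,
    "FE": 2.05, "CO": 2.00, "NI": 1.97, "CU": 1.96, "ZN": 2.01,
}
VDW_DEFAULT = 1.70

# Theoretical max ASA (A^2) of residue X in an extended Gly-X-Gly tripeptide
# (Tien et al. 2013), used to normalize relative accessible surface area.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

BOND_ORDER_VALUES: dict[str, float] = {
    "single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5,
}


def atomic_number(element: str) -> int:
    """Atomic number for an element symbol (case-insensitive)."""
    try:
        return ATOMIC_NUMBERS[element.upper()]
    except KeyError:
        raise KeyError(f"unknown element symbol: {element!r}") from None
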