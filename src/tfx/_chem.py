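"""Per-element and per-atom-type chemistry tables.

Bondi van der Waals radii, atomic numbers, a coarse Ghose/Crippen-style
atomic hydrophobicity-constant table, and the residue-level role tables
(H-bond donors/acceptors, charged groups, aromatic rings) used by the
contact classifier and the MHP surface code.
"""

from __future__ import annotations

import warnings

# Bondi (1964) radii, Angstrom.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "CA": 2.31,
    "FE": 2.00, "SE": 1.90,
}
DEFAULT_RADIUS = 1.7

ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "F": 9,
    "CL": 17, "BR": 35, "I": 53, "NA": 11, "K": 19, "MG": 12,
    "ZN": 30, "CA": 20, "FE": 26, "SE": 34,
}
DEFAULT_ATOMIC_NUMBER = 6

_warned_elements: set[str] = set()


def vdw_radius(element: str) -> float:
    """Bondi radius for an element symbol; 1.7 A with a warning if unknown."""
    key = element.strip().upper()
    if key in BONDI_RADII:
        return BONDI_RADII[key]
    if key and key not in _warned_elements:
        _warned_elements.add(key)
        warnings.warn(f"unknown element {element!r}: using default vdW radius {DEFAULT_RADIUS} A")
    return DEFAULT_RADIUS


def atomic_number(element: str) -> int:
    return ATOMIC_NUMBERS.get(element.strip().upper(), DEFAULT_ATOMIC_NUMBER)


# ---------------------------------------------------------------------------
# Atomic hydrophobicity constants (unitless, signed).  Positive = lipophilic,
# negative = hydrophilic, in the spirit of Ghose-Crippen fragmental constants.
# Carbons attached to heteroatom-rich functional groups are treated as polar.
# ---------------------------------------------------------------------------

# carbons of carbonyl/carboxylate/amide/guanidinium groups, per residue
_POLAR_CARBONS = {
    ("*", "C"),        # backbone carbonyl carbon
    ("ASP", "CG"), ("GLU", "CD"),
    ("ASN", "CG"), ("GLN", "CD"),
    ("ARG", "CZ"),
}

_MHP_BY_ELEMENT = {
    "H": 0.0,
    "C": 0.36,
    "N": -0.60,
    "O": -0.45,
    "S": 0.40,
    "P": -0.50,
}

_warned_mhp: set[str] = set()


def mhp_constant(res_name: str, atom_name: str, element: str) -> float:
    """Atomic hydrophobicity constant for an atom type.

    Unknown elements get 0 with a warning.
    """
    el = element.strip().upper()
    res = res_name.strip().upper()
    name = atom_name.strip().upper()
    if el == "C":
        if ("*", name) in _POLAR_CARBONS or (res, name) in _POLAR_CARBONS:
            return -0.24
        return _MHP_BY_ELEMENT["C"]
    if el in _MHP_BY_ELEMENT:
        return _MHP_BY_ELEMENT[el]
    if el and el not in _warned_mhp:
        _warned_mhp.add(el)
        warnings.warn(f"no hydrophobicity constant for element {element!r}: using 0")
    return 0.0


# ---------------------------------------------------------------------------
# Residue role tables (heavy atoms only; hydrogens are not required).
# ---------------------------------------------------------------------------

# side-chain H-bond donors per residue; backbone N is a donor for everything
HBOND_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

# side-chain acceptors; backbone O (and OXT) accepts for everything
HBOND_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}

# positively charged (cationic) nitrogen atoms; His treated as protonated
CATION_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}

# negatively charged (anionic) oxygen atoms
ANION_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

# aromatic ring definitions: residue -> list of atom-name tuples (one per ring)
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}


def is_hbond_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N":
        return True
    return atom_name in HBOND_DONORS.get(res_name, ())


def is_hbond_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return atom_name in HBOND_ACCEPTORS.get(res_name, ())


def is_cation(res_name: str, atom_name: str) -> bool:
    return atom_name in CATION_ATOMS.get(res_name, ())


def is_anion(res_name: str, atom_name: str) -> bool:
    if atom_name == "OXT":
        return True
    return atom_name in ANION_ATOMS.get(res_name, ())


def is_polar_uncharged(res_name: str, atom_name: str, element: str) -> bool:
    """Uncharged polar O/N (ion-dipole partners)."""
    if element.strip().upper() not in ("N", "O"):
        return False
    if is_cation(res_name, atom_name) or is_anion(res_name, atom_name):
        return False
    return is_hbond_donor(res_name, atom_name) or is_hbond_acceptor(res_name, atom_name)


def is_apolar_carbon(res_name: str, atom_name: str, element: str) -> bool:
    return element.strip().upper() == "C" and mhp_constant(res_name, atom_name, element) > 0


def guess_element(atom_name: str) -> str:
    """Infer an element symbol from an atom name (PDB/GRO conventions)."""
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "SE") and len(stripped) <= 2:
        return two.capitalize()
    return stripped[0].upper()
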