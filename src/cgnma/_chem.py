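"""Amino-acid chemistry tables: residue codes, side-chain heavy-atom censuses,
van der Waals radii and the atom-type classification used by the interaction
matrix.

The atom-type classes (1..8) coarsely encode element, polarity and
aromaticity; the assignment table and the pairwise interaction matrix are
shipped as editable CSV files in ``cgnma/data`` so users can supply their own
parameterization without touching code.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA1 = set(AA1_TO_3)

# heavy side-chain atoms beyond CA, in canonical PDB order
SIDECHAIN_ATOMS: dict[str, list[str]] = {
    "G": [],
    "A": ["CB"],
    "S": ["CB", "OG"],
    "C": ["CB", "SG"],
    "T": ["CB", "OG1", "CG2"],
    "V": ["CB", "CG1", "CG2"],
    "L": ["CB", "CG", "CD1", "CD2"],
    "I": ["CB", "CG1", "CG2", "CD1"],
    "M": ["CB", "CG", "SD", "CE"],
    "P": ["CB", "CG", "CD"],
    "F": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "Y": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "W": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "D": ["CB", "CG", "OD1", "OD2"],
    "E": ["CB", "CG", "CD", "OE1", "OE2"],
    "N": ["CB", "CG", "OD1", "ND2"],
    "Q": ["CB", "CG", "CD", "OE1", "NE2"],
    "H": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "K": ["CB", "CG", "CD", "CE", "NZ"],
    "R": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

N_ATOM_CLASSES = 8


def element_of(atom_name: str) -> str:
    """Infer the element of a heavy protein atom from its PDB atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


@lru_cache(maxsize=1)
def _class_table() -> dict[tuple[str, str], int]:
    path = resources.files("cgnma.data") / "atom_classes.csv"
    df = pd.read_csv(path, comment="#")
    return {
        (str(r.resname).upper(), str(r.atom_name).upper()): int(r.atom_class)
        for r in df.itertuples()
    }


# fallback classes by element when no (residue, atom) row matches
_ELEMENT_CLASS = {"C": 1, "N": 3, "O": 5, "S": 7}


def atom_class(resname3: str, atom_name: str) -> int:
    """Atom-type class (1..8) for a heavy atom, from the shipped table.

    Lookup order: exact (residue, atom) row, then wildcard row for the
    element, then class 8 (other).
    """
    table = _class_table()
    key = (resname3.upper(), atom_name.upper())
    if key in table:
        return table[key]
    elem = element_of(atom_name)
    if ("*", elem) in table:
        return table[("*", elem)]
    return _ELEMENT_CLASS.get(elem, N_ATOM_CLASSES)


@lru_cache(maxsize=1)
def default_interaction_matrix() -> np.ndarray:
    """The shipped interaction matrix over atom-type class pairs.

    The default is all-ones (pure surface weighting): the sequence awareness
    then comes entirely from the atom census and packing of each residue.
    """
    path = resources.files("cgnma.data") / "interaction_matrix.csv"
    m = pd.read_csv(path, comment="#", index_col=0).to_numpy(dtype=float)
    if m.shape != (N_ATOM_CLASSES, N_ATOM_CLASSES):
        raise ValueError(f"interaction matrix must be {N_ATOM_CLASSES}x{N_ATOM_CLASSES}")
    return m


def vdw_radius(atom_name: str) -> float:
    return VDW_RADII.get(element_of(atom_name), DEFAULT_VDW)
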