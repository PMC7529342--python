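"""Compact side-chain rotamer library and chi-angle manipulation.

The library is intentionally small (canonical staggered chi wells with
rough probabilities) -- sufficient for desk-scale co-packing; the
packer accepts externally supplied libraries with the same shape.
Chi angles follow the standard IUPAC atom quadruples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import dihedral_deg, rotation_about_axis, unit

# chi definitions: residue -> list of 4-atom tuples (chi1, chi2, ...)
CHI_DEFS = {
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

# atoms moved by each chi (heavy atoms; attached hydrogens are moved too
# when present, matched by prefix)
_DOWNSTREAM = {
    "SER": [["OG", "HG"]],
    "THR": [["OG1", "HG1", "CG2"]],
    "CYS": [["SG", "HG"]],
    "VAL": [["CG1", "CG2"]],
    "ASP": [["CG", "OD1", "OD2"], ["OD1", "OD2"]],
    "ASN": [["CG", "OD1", "ND2", "HD21", "HD22"], ["OD1", "ND2", "HD21", "HD22"]],
    "LEU": [["CG", "CD1", "CD2"], ["CD1", "CD2"]],
    "ILE": [["CG1", "CG2", "CD1"], ["CD1"]],
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
            ["CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH", "HH"],
            ["CD1", "CD2", "CE1", "CE2", "CZ", "OH", "HH"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2", "HE1"],
            ["CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2", "HE1"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2", "HE2"],
            ["ND1", "CD2", "CE1", "NE2", "HE2"]],
    "GLU": [["CG", "CD", "OE1", "OE2"], ["CD", "OE1", "OE2"], ["OE1", "OE2"]],
    "GLN": [["CG", "CD", "OE1", "NE2", "HE21", "HE22"],
            ["CD", "OE1", "NE2", "HE21", "HE22"],
            ["OE1", "NE2", "HE21", "HE22"]],
    "MET": [["CG", "SD", "CE"], ["SD", "CE"], ["CE"]],
    "LYS": [["CG", "CD", "CE", "NZ", "HZ1", "HZ2", "HZ3"],
            ["CD", "CE", "NZ", "HZ1", "HZ2", "HZ3"],
            ["CE", "NZ", "HZ1", "HZ2", "HZ3"],
            ["NZ", "HZ1", "HZ2", "HZ3"]],
    "ARG": [["CG", "CD", "NE", "CZ", "NH1", "NH2", "HE", "HH11", "HH12", "HH21", "HH22"],
            ["CD", "NE", "CZ", "NH1", "NH2", "HE", "HH11", "HH12", "HH21", "HH22"],
            ["NE", "CZ", "NH1", "NH2", "HE", "HH11", "HH12", "HH21", "HH22"],
            ["CZ", "NH1", "NH2", "HH11", "HH12", "HH21", "HH22"]],
}

# last chi of these residues is 180-degree periodic (symmetric group)
SYMMETRIC_CHI = {"ASP": 2, "GLU": 3, "PHE": 2, "TYR": 2}

_G = (-60.0, 60.0, 180.0)

DEFAULT_LIBRARY = {
    "SER": [((c,), 1 / 3) for c in _G],
    "THR": [((c,), 1 / 3) for c in _G],
    "CYS": [((c,), 1 / 3) for c in _G],
    "VAL": [((175.0,), 0.7), ((-60.0,), 0.2), ((60.0,), 0.1)],
    "ASP": [((c1, c2), 1 / 6) for c1 in _G for c2 in (-15.0, 65.0)],
    "ASN": [((c1, c2), 1 / 6) for c1 in _G for c2 in (-20.0, 120.0)],
    "LEU": [((-60.0, 175.0), 0.6), ((180.0, 65.0), 0.3), ((-60.0, 65.0), 0.1)],
    "HIS": [((c1, c2), 1 / 6) for c1 in _G for c2 in (-75.0, 75.0)],
    "GLU": [((c1, 180.0, -10.0), 1 / 3) for c1 in _G],
    "GLN": [((c1, 180.0, 0.0), 1 / 3) for c1 in _G],
    "LYS": [((c1, 180.0, 180.0, 180.0), 1 / 3) for c1 in _G],
    "ARG": [((c1, 180.0, 180.0, 90.0), 1 / 3) for c1 in _G],
    "MET": [((c1, 180.0, 75.0), 1 / 3) for c1 in _G],
    "PHE": [((c1, 90.0), 1 / 3) for c1 in _G],
    "TYR": [((c1, 90.0), 1 / 3) for c1 in _G],
    "TRP": [((c1, 90.0), 1 / 3) for c1 in _G],
    "ILE": [((-60.0, 170.0), 0.6), ((60.0, 170.0), 0.2), ((180.0, 170.0), 0.2)],
}


@dataclass
class RotamerLibrary:
    """Per-residue-type chi-angle conformers with probabilities."""

    rotamers: dict  # resname -> list of (chi tuple, probability)

    def __post_init__(self):
        for rn, lst in self.rotamers.items():
            if not lst:
                raise ValueError(f"empty rotamer list for {rn}")
            for chis, _ in lst:
                for c in chis:
                    if not (-180.0 < c <= 180.0):
                        raise ValueError(f"chi out of (-180, 180] for {rn}: {c}")

    def get(self, resname):
        return self.rotamers.get(resname, [])


def default_library() -> RotamerLibrary:
    return RotamerLibrary(dict(DEFAULT_LIBRARY))


def get_chis(residue) -> tuple:
    """Current chi angles of a residue (empty tuple if none defined)."""
    defs = CHI_DEFS.get(residue.resname, [])
    out = []
    for quad in defs:
        atoms = [residue.get(n) for n in quad]
        if any(a is None for a in atoms):
            break
        out.append(dihedral_deg(*(a.coord for a in atoms)))
    return tuple(out)


def apply_chis(residue, chis) -> None:
    """Rotate the side chain of `residue` in place to the target chis."""
    defs = CHI_DEFS.get(residue.resname, [])
    moved = _DOWNSTREAM.get(residue.resname, [])
    for k, target in enumerate(chis):
        if k >= len(defs):
            break
        quad = defs[k]
        atoms = [residue.get(n) for n in quad]
        if any(a is None for a in atoms):
            continue
        current = dihedral_deg(*(a.coord for a in atoms))
        delta = target - current
        axis_b, axis_c = atoms[1].coord, atoms[2].coord
        R = rotation_about_axis(axis_c - axis_b, delta)
        for name in moved[k]:
            a = residue.get(name)
            if a is not None:
                a.coord = axis_b + R @ (a.coord - axis_b)


def chi_difference(a: float, b: float, period: float = 360.0) -> float:
    """Smallest absolute angular difference modulo `period`."""
    d = abs(a - b) % period
    return min(d, period - d)
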