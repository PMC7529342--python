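"""Construct small peptides and waters at ideal covalent geometry.

Fixtures and desk-scale tests need structures with exactly known
geometry; this module builds them from internal coordinates (NeRF
chaining) using standard bond lengths and angles.  Only a subset of
residue types is supported for *building* (reading arbitrary PDBs
supports all twenty); extending the template table is the intended
extension point.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom, rotation_about_axis, unit
from .structure import AtomRecord, Residue, Structure

# Ideal water internal geometry (gas-phase experimental values).
WATER_OH = 0.9572
WATER_HOH = 104.52

# backbone internal coordinates
_B = {
    "N-CA": 1.458, "CA-C": 1.523, "C-N": 1.329, "C-O": 1.231,
    "N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
}

# side-chain templates: atom -> (refs, bond, angle, dihedral spec)
# dihedral spec: number (fixed) or ("chi<k>", offset)
_SIDECHAINS = {
    "ALA": [("CB", ("N", "C", "CA"), 1.53, 110.1, -122.6)],
    "GLY": [],
    "SER": [
        ("CB", ("N", "C", "CA"), 1.53, 110.1, -122.6),
        ("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi1", 0.0)),
    ],
    "THR": [
        ("CB", ("N", "C", "CA"), 1.54, 110.1, -122.6),
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi1", 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", -120.0)),
    ],
    "ASN": [
        ("CB", ("N", "C", "CA"), 1.53, 110.1, -122.6),
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi1", 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi2", 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi2", 180.0)),
    ],
    "ASP": [
        ("CB", ("N", "C", "CA"), 1.53, 110.1, -122.6),
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi1", 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.250, 118.5, ("chi2", 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.250, 118.5, ("chi2", 180.0)),
    ],
    "LYS": [
        ("CB", ("N", "C", "CA"), 1.53, 110.1, -122.6),
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi2", 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi3", 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.7, ("chi4", 0.0)),
    ],
    "GLN": [
        ("CB", ("N", "C", "CA"), 1.53, 110.1, -122.6),
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi2", 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi3", 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi3", 180.0)),
    ],
    # proline ring is approximated (downstream code only needs N/CB context)
    "PRO": [
        ("CB", ("N", "C", "CA"), 1.53, 103.0, -115.0),
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, 28.0),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, -35.0),
    ],
}

_DEFAULT_CHI = {
    "SER": {"chi1": 180.0},
    "THR": {"chi1": 60.0},
    "ASN": {"chi1": -65.0, "chi2": -20.0},
    "ASP": {"chi1": -70.0, "chi2": -15.0},
    "LYS": {"chi1": -60.0, "chi2": 180.0, "chi3": 180.0, "chi4": 180.0},
    "GLN": {"chi1": -60.0, "chi2": 180.0, "chi3": 0.0},
}

BUILDABLE = set(_SIDECHAINS)


def build_peptide(sequence, phi=-120.0, psi=130.0, omega=180.0,
                  chain="A", start_seq=1, chis=None) -> Structure:
    """Build an extended peptide from one-letter-free residue names.

    `sequence` is a list of three-letter residue names drawn from
    :data:`BUILDABLE`.  `chis` optionally maps residue index (0-based)
    to a dict of chi angles in degrees.
    """
    sequence = list(sequence)
    for rn in sequence:
        if rn not in _SIDECHAINS:
            raise ValueError(f"residue type {rn} not in builder templates")
    n_res = len(sequence)
    phis = [phi] * n_res if np.isscalar(phi) else list(phi)
    psis = [psi] * n_res if np.isscalar(psi) else list(psi)

    bb = []  # per residue dict of N/CA/C coords
    for i in range(n_res):
        if i == 0:
            N = np.zeros(3)
            CA = np.array([_B["N-CA"], 0.0, 0.0])
            th = np.radians(180.0 - _B["N-CA-C"])
            C = CA + _B["CA-C"] * np.array([np.cos(th), np.sin(th), 0.0])
        else:
            p = bb[i - 1]
            N = place_atom(p["N"], p["CA"], p["C"], _B["C-N"], _B["CA-C-N"],
                           psis[i - 1])
            CA = place_atom(p["CA"], p["C"], N, _B["N-CA"], _B["C-N-CA"], omega)
            C = place_atom(p["C"], N, CA, _B["CA-C"], _B["N-CA-C"], phis[i])
        bb.append({"N": N, "CA": CA, "C": C})
    residues = []
    for i, rn in enumerate(sequence):
        res = Residue(chain, start_seq + i, " ", rn)
        coords = dict(bb[i])
        coords["O"] = place_atom(coords["N"], coords["CA"], coords["C"],
                                 _B["C-O"], _B["CA-C-O"], psis[i] + 180.0)
        chi = dict(_DEFAULT_CHI.get(rn, {}))
        if chis and i in chis:
            chi.update(chis[i])
        for (aname, refs, bond, angle, dspec) in _SIDECHAINS[rn]:
            if isinstance(dspec, tuple):
                dih = chi.get(dspec[0], 180.0) + dspec[1]
            else:
                dih = dspec
            coords[aname] = place_atom(coords[refs[0]], coords[refs[1]],
                                       coords[refs[2]], bond, angle, dih)
        for aname, xyz in coords.items():
            elem = aname[0] if aname[0] in "CNOS" else "C"
            res.add(AtomRecord(name=aname, element=elem, coord=xyz,
                               residue_id=res.residue_id, resname=rn))
        residues.append(res)
    return Structure(residues)


def water_hydrogen_offsets(R: np.ndarray | None = None) -> np.ndarray:
    """Offsets of the two hydrogens from the oxygen for orientation R.

    In the reference orientation the C2 (dipole) axis is +z and the
    molecule lies in the xz plane, hydrogens up.
    """
    half = np.radians(WATER_HOH / 2.0)
    h = np.array([
        [WATER_OH * np.sin(half), 0.0, WATER_OH * np.cos(half)],
        [-WATER_OH * np.sin(half), 0.0, WATER_OH * np.cos(half)],
    ])
    if R is not None:
        h = h @ np.asarray(R).T
    return h


def make_water(oxygen, R=None, chain="W", seqnum=1, occupancy=1.0) -> Residue:
    """Three-atom water residue at `oxygen` with orientation matrix R.

    With R=None only the oxygen is emitted (a point water)."""
    res = Residue(chain, seqnum, " ", "HOH")
    oxygen = np.asarray(oxygen, float)
    res.add(AtomRecord(name="O", element="O", coord=oxygen,
                       residue_id=res.residue_id, resname="HOH",
                       occupancy=occupancy, is_water=True))
    if R is not None:
        for name, off in zip(("H1", "H2"), water_hydrogen_offsets(R)):
            res.add(AtomRecord(name=name, element="H", coord=oxygen + off,
                               residue_id=res.residue_id, resname="HOH",
                               occupancy=occupancy, is_water=True))
    return res
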