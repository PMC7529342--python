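"""Structures, polar hydrogens, polar groups, and interfaces.

The in-memory model is deliberately light: an ordered list of residues,
each holding named :class:`AtomRecord` objects.  PDB parsing and writing
go through gemmi; everything downstream (hydrogen building, polar-group
typing, hydration-site construction) is hydrogen-explicit, so
:func:`build_polar_hydrogens` must run before any energetics.

Conventions
-----------
* Coordinates in Angstroms, PDB frame.
* Alternate locations: the highest-occupancy conformer wins, ties broken
  alphabetically by altloc identifier.
* Proline backbone N carries no amide hydrogen.
* Charged chain termini are treated as additional donor/acceptor groups
  (configurable via ``treat_termini``).
* Predicted waters are written as HOH in chain "W" with sequential
  numbering; occupancies may carry stage-1 dwell fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .geometry import place_atom, rotation_about_axis, unit

log = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SPC"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class StructureError(ValueError):
    pass


@dataclass
class AtomRecord:
    """One atom: name, element, coordinates and bookkeeping flags."""

    name: str
    element: str
    coord: np.ndarray
    residue_id: tuple  # (chain, seqnum, icode)
    resname: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_water: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinate for atom {self.name}")
        if not self.element:
            raise StructureError(f"empty element for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str
    resname: str
    atoms: dict = field(default_factory=dict)  # name -> AtomRecord

    @property
    def residue_id(self):
        return (self.chain, self.seqnum, self.icode)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_NAMES

    def get(self, name):
        return self.atoms.get(name)

    def add(self, atom: AtomRecord):
        self.atoms[atom.name] = atom

    def copy(self) -> "Residue":
        r = Residue(self.chain, self.seqnum, self.icode, self.resname)
        for a in self.atoms.values():
            r.add(replace(a, coord=a.coord.copy()))
        return r


class Structure:
    """An ordered collection of residues (protein, ligand, waters)."""

    def __init__(self, residues=None):
        self.residues: list[Residue] = list(residues) if residues else []
        self._check_unique_ids()

    def _check_unique_ids(self):
        seen = set()
        for r in self.residues:
            if r.residue_id in seen:
                raise StructureError(f"duplicate residue id {r.residue_id}")
            seen.add(r.residue_id)

    # -- views ---------------------------------------------------------
    @property
    def atoms(self) -> list:
        return [a for r in self.residues for a in r.atoms.values()]

    @property
    def waters(self) -> list:
        return [r for r in self.residues if r.is_water]

    @property
    def protein_residues(self) -> list:
        return [r for r in self.residues if not r.is_water]

    @property
    def chains(self) -> dict:
        out: dict[str, list] = {}
        for r in self.residues:
            out.setdefault(r.chain, []).append(r)
        return out

    def heavy_atoms(self, include_waters=True):
        return [
            a
            for r in self.residues
            if include_waters or not r.is_water
            for a in r.atoms.values()
            if not a.is_hydrogen
        ]

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues])

    def transform(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        s = self.copy()
        for a in s.atoms:
            a.coord = R @ a.coord + t
        return s

    def residue(self, chain, seqnum, icode=" "):
        for r in self.residues:
            if r.residue_id == (chain, seqnum, icode):
                return r
        raise KeyError((chain, seqnum, icode))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_structure(path, keep_waters: bool = True, clash_check: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Altlocs are resolved to the highest-occupancy conformer (ties:
    alphabetical).  Raises :class:`StructureError` when no protein
    residues are present or when non-bonded heavy atoms overlap.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise IOError(f"cannot read structure from {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model = st[0]
    residues = []
    for chain in model:
        for res in chain:
            is_wat = res.name in WATER_NAMES or res.is_water()
            if is_wat and not keep_waters:
                continue
            icode = res.seqid.icode if res.seqid.icode.strip() else " "
            out = Residue(chain.name, res.seqid.num, icode, res.name)
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                elif (at.occ, _altloc_rank(at.altloc)) > (
                    prev.occ, _altloc_rank(prev.altloc)
                ):
                    # higher occupancy wins; equal occupancy -> earlier
                    # altloc letter wins (rank is negated ordinal)
                    best[at.name] = at
            for name, at in best.items():
                elem = at.element.name if at.element.name else name[0]
                out.add(
                    AtomRecord(
                        name=name,
                        element=elem,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        residue_id=out.residue_id,
                        resname=res.name,
                        occupancy=at.occ,
                        bfactor=at.b_iso,
                        is_water=is_wat,
                    )
                )
            residues.append(out)
    s = Structure(residues)
    if not s.protein_residues:
        raise StructureError(f"no protein residues in {path}")
    if clash_check:
        _clash_guard(s)
    return s


def _altloc_rank(altloc: str) -> float:
    # ties on occupancy resolve alphabetically: 'A' beats 'B'
    if not altloc or altloc == "\x00":
        return 0.0
    return -ord(altloc)


def _clash_guard(s: Structure, cutoff: float = 1.0):
    heavy = s.heavy_atoms()
    if len(heavy) < 2:
        return
    coords = np.array([a.coord for a in heavy])
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        a, b = heavy[i], heavy[j]
        if a.residue_id != b.residue_id:
            raise StructureError(
                f"clash: {a.resname} {a.residue_id} {a.name} vs "
                f"{b.resname} {b.residue_id} {b.name} closer than {cutoff} A"
            )


def write_structure(s: Structure, path, occupancy_from_dwell: bool = False):
    """Write a Structure as PDB.  Waters go to chain 'W', renumbered."""
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    model = st[0]
    chains: dict[str, gemmi.Chain] = {}
    wat_num = 0
    for r in s.residues:
        chain_name = "W" if r.is_water else r.chain
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        gres = gemmi.Residue()
        if r.is_water:
            wat_num += 1
            gres.name = "HOH"
            gres.seqid = gemmi.SeqId(wat_num, " ")
            gres.het_flag = "H"
        else:
            gres.name = r.resname
            gres.seqid = gemmi.SeqId(r.seqnum, r.icode)
            gres.het_flag = "A" if r.resname in STANDARD_AA else "H"
        for a in r.atoms.values():
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = float(a.occupancy)
            ga.b_iso = float(a.bfactor)
            gres.add_atom(ga)
        chains[chain_name].add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Polar hydrogens
# ---------------------------------------------------------------------------

_ACCEPTOR_ELEMENTS = {"O", "N"}


def _acceptor_candidates(s: Structure, exclude_res):
    pts = []
    for r in s.residues:
        for a in r.atoms.values():
            if a.is_hydrogen:
                continue
            if a.element in _ACCEPTOR_ELEMENTS and (
                r.residue_id != exclude_res or a.name in ("O", "OXT")
            ):
                pts.append(a.coord)
    return np.array(pts) if pts else np.zeros((0, 3))


def _best_rotatable_h(heavy, ref_a, ref_b, acceptors, bond, angle=109.5, n_trial=12):
    """Place a rotatable hydrogen on `heavy`, scanning the torsion and
    picking the orientation whose H...acceptor distance is closest to the
    ideal 1.9 A.  Falls back to the anti conformer."""
    best_pos, best_score = None, np.inf
    for k in range(n_trial):
        pos = place_atom(ref_a, ref_b, heavy, bond, angle, k * 360.0 / n_trial)
        if len(acceptors):
            d = np.linalg.norm(acceptors - pos, axis=1)
            score = float(np.min(np.abs(d - 1.9)))
        else:
            score = abs(k * 360.0 / n_trial - 180.0) / 360.0
        if score < best_score:
            best_score, best_pos = score, pos
    return best_pos


def build_polar_hydrogens(s: Structure, treat_termini: bool = True) -> Structure:
    """Add missing polar hydrogens at ideal covalent geometry.

    Backbone amide H: 1.01 A along the bisector of N-CA and N-C(prev).
    Rotatable hydroxyl/thiol hydrogens are oriented toward the best
    available acceptor at build time (they are re-sampled during
    packing).  Unknown residues are skipped with a log warning.
    """
    s = s.copy()
    by_chain = s.chains
    acceptors_all = None  # built lazily per residue (cheap at desk scale)
    for chain_name, residues in by_chain.items():
        prot = [r for r in residues if not r.is_water]
        for idx, r in enumerate(prot):
            if r.resname not in STANDARD_AA:
                if not r.is_water:
                    log.warning("unknown residue %s %s: hydrogens skipped",
                                r.resname, r.residue_id)
                continue
            N, CA, C = r.get("N"), r.get("CA"), r.get("C")
            if N is None or CA is None or C is None:
                log.warning("incomplete backbone in %s %s", r.resname, r.residue_id)
                continue
            prev_C = None
            if idx > 0:
                pc = prot[idx - 1].get("C")
                if pc is not None and np.linalg.norm(pc.coord - N.coord) < 1.8:
                    prev_C = pc
            if r.resname != "PRO" and "H" not in r.atoms:
                if prev_C is not None:
                    d = unit(unit(N.coord - prev_C.coord) + unit(N.coord - CA.coord))
                    _add_h(r, "H", N.coord + 1.01 * d)
                elif treat_termini:
                    # charged N-terminus: three tetrahedral hydrogens
                    for i, name in enumerate(("H1", "H2", "H3")):
                        if name in r.atoms:
                            continue
                        pos = place_atom(C.coord, CA.coord, N.coord, 1.01,
                                         109.5, 60.0 + 120.0 * i)
                        _add_h(r, name, pos)
            _build_sidechain_h(s, r)
    return s


def _add_h(res: Residue, name: str, pos):
    res.add(AtomRecord(name=name, element="H", coord=pos,
                       residue_id=res.residue_id, resname=res.resname))


def _build_sidechain_h(s: Structure, r: Residue):
    g = r.get
    rn = r.resname
    try:
        if rn in ("SER", "THR"):
            o = g("OG") or g("OG1")
            cb = g("CB")
            ca = g("CA")
            hname = "HG" if rn == "SER" else "HG1"
            if o is not None and cb is not None and hname not in r.atoms:
                acc = _acceptor_candidates(s, r.residue_id)
                pos = _best_rotatable_h(o.coord, ca.coord, cb.coord, acc, 0.96)
                _add_h(r, hname, pos)
        elif rn == "TYR":
            oh, cz, ce1 = g("OH"), g("CZ"), g("CE1")
            if oh is not None and cz is not None and ce1 is not None and "HH" not in r.atoms:
                acc = _acceptor_candidates(s, r.residue_id)
                best, score = None, np.inf
                for dih in (0.0, 180.0):
                    pos = place_atom(ce1.coord, cz.coord, oh.coord, 0.96, 109.0, dih)
                    sc = (float(np.min(np.abs(np.linalg.norm(acc - pos, axis=1) - 1.9)))
                          if len(acc) else dih / 360.0)
                    if sc < score:
                        best, score = pos, sc
                _add_h(r, "HH", best)
        elif rn == "LYS":
            nz, ce, cd = g("NZ"), g("CE"), g("CD")
            if nz is not None and ce is not None and cd is not None:
                for i, name in enumerate(("HZ1", "HZ2", "HZ3")):
                    if name not in r.atoms:
                        _add_h(r, name, place_atom(cd.coord, ce.coord, nz.coord,
                                                   1.01, 109.5, 60.0 + 120.0 * i))
        elif rn == "ARG":
            ne, cz, cd = g("NE"), g("CZ"), g("CD")
            if ne is not None and cz is not None and cd is not None and "HE" not in r.atoms:
                d = unit(unit(ne.coord - cd.coord) + unit(ne.coord - cz.coord))
                _add_h(r, "HE", ne.coord + 1.01 * d)
            for nh, hs in (("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))):
                a = g(nh)
                if a is None or cz is None or ne is None:
                    continue
                for hname, dih in zip(hs, (0.0, 180.0)):
                    if hname not in r.atoms:
                        _add_h(r, hname, place_atom(ne.coord, cz.coord, a.coord,
                                                    1.01, 120.0, dih))
        elif rn in ("ASN", "GLN"):
            if rn == "ASN":
                n, c, cb = g("ND2"), g("CG"), g("CB")
                hs = ("HD21", "HD22")
            else:
                n, c, cb = g("NE2"), g("CD"), g("CG")
                hs = ("HE21", "HE22")
            if n is not None and c is not None and cb is not None:
                for hname, dih in zip(hs, (0.0, 180.0)):
                    if hname not in r.atoms:
                        _add_h(r, hname, place_atom(cb.coord, c.coord, n.coord,
                                                    1.01, 120.0, dih))
        elif rn == "HIS":
            # default epsilon tautomer: NE2 protonated, ND1 acceptor
            ne2, cd2, ce1 = g("NE2"), g("CD2"), g("CE1")
            if ne2 is not None and cd2 is not None and ce1 is not None and "HE2" not in r.atoms:
                d = unit(unit(ne2.coord - cd2.coord) + unit(ne2.coord - ce1.coord))
                _add_h(r, "HE2", ne2.coord + 1.01 * d)
        elif rn == "TRP":
            ne1, cd1, ce2 = g("NE1"), g("CD1"), g("CE2")
            if ne1 is not None and cd1 is not None and ce2 is not None and "HE1" not in r.atoms:
                d = unit(unit(ne1.coord - cd1.coord) + unit(ne1.coord - ce2.coord))
                _add_h(r, "HE1", ne1.coord + 1.01 * d)
    except ValueError as exc:  # degenerate geometry
        log.warning("hydrogen build failed for %s %s: %s", rn, r.residue_id, exc)


# ---------------------------------------------------------------------------
# Polar groups
# ---------------------------------------------------------------------------

@dataclass
class PolarGroup:
    """A donor/acceptor heavy atom with its covalent context.

    ``base_atoms`` hold the atoms bonded to the heavy atom that define
    hydrogen-bond geometry: one base for sp2 acceptors and donors, both
    bound atoms for sp3 acceptors (for serine OG these are CB and HG;
    for a water oxygen, its two hydrogens).  ``plane_atom`` supplies the
    in-plane reference needed to construct sp2 lone-pair directions.
    """

    heavy_atom: AtomRecord
    base_atoms: list
    hydrogens: list
    kind: str  # donor | acceptor | both
    hybridization: str  # sp2 | sp3 | ring
    atom_class: str
    plane_atom: AtomRecord | None = None
    is_backbone: bool = False
    residue_id: tuple = ()

    def __post_init__(self):
        if self.kind in ("donor", "both") and not self.hydrogens:
            raise StructureError(
                f"donor group {self.atom_class} at {self.heavy_atom.name} has no hydrogens"
            )
        if self.hybridization == "sp3" and self.kind in ("acceptor", "both"):
            if len(self.base_atoms) != 2:
                raise StructureError(
                    f"sp3 acceptor {self.atom_class} needs exactly 2 base atoms"
                )
        if not self.residue_id:
            self.residue_id = self.heavy_atom.residue_id


# side-chain polar atom table:
# resname -> list of (atom, kind, hybrid, bases, hydrogens, plane, class)
_SIDECHAIN_POLAR = {
    "SER": [("OG", "both", "sp3", ["CB", "HG"], ["HG"], None, "hydroxyl")],
    "THR": [("OG1", "both", "sp3", ["CB", "HG1"], ["HG1"], None, "hydroxyl")],
    "TYR": [("OH", "both", "sp2", ["CZ"], ["HH"], "CE1", "hydroxyl_aro")],
    "ASP": [
        ("OD1", "acceptor", "sp2", ["CG"], [], "OD2", "carboxyl_O"),
        ("OD2", "acceptor", "sp2", ["CG"], [], "OD1", "carboxyl_O"),
    ],
    "GLU": [
        ("OE1", "acceptor", "sp2", ["CD"], [], "OE2", "carboxyl_O"),
        ("OE2", "acceptor", "sp2", ["CD"], [], "OE1", "carboxyl_O"),
    ],
    "ASN": [
        ("OD1", "acceptor", "sp2", ["CG"], [], "ND2", "amide_O"),
        ("ND2", "donor", "sp2", ["CG"], ["HD21", "HD22"], "OD1", "amide_N"),
    ],
    "GLN": [
        ("OE1", "acceptor", "sp2", ["CD"], [], "NE2", "amide_O"),
        ("NE2", "donor", "sp2", ["CD"], ["HE21", "HE22"], "OE1", "amide_N"),
    ],
    "LYS": [("NZ", "donor", "sp3", ["CE"], ["HZ1", "HZ2", "HZ3"], None, "amine_N")],
    "ARG": [
        ("NE", "donor", "sp2", ["CZ"], ["HE"], "CD", "guanidinium_N"),
        ("NH1", "donor", "sp2", ["CZ"], ["HH11", "HH12"], "NE", "guanidinium_N"),
        ("NH2", "donor", "sp2", ["CZ"], ["HH21", "HH22"], "NE", "guanidinium_N"),
    ],
    "HIS": [
        ("ND1", "acceptor", "ring", ["CG", "CE1"], [], None, "imidazole_ND"),
        ("NE2", "donor", "ring", ["CD2", "CE1"], ["HE2"], None, "imidazole_NE"),
    ],
    "TRP": [("NE1", "donor", "sp2", ["CD1", "CE2"], ["HE1"], None, "indole_N")],
}


def extract_polar_groups(s: Structure, treat_termini: bool = True) -> list:
    """Enumerate all polar groups (backbone, side chains, waters, termini).

    Every backbone amide N-H, backbone C=O, and typed polar side-chain
    atom yields exactly one group.  Unknown residues are skipped with a
    log message.  Idempotent and independent of residue order.
    """
    groups: list[PolarGroup] = []
    by_chain = s.chains
    for chain_name, residues in by_chain.items():
        prot = [r for r in residues if not r.is_water]
        for idx, r in enumerate(prot):
            if r.resname not in STANDARD_AA:
                log.info("skipping polar typing for %s", r.resname)
                continue
            N, CA, C, O = r.get("N"), r.get("CA"), r.get("C"), r.get("O")
            is_nterm = True
            if idx > 0 and N is not None:
                pc = prot[idx - 1].get("C")
                if pc is not None and np.linalg.norm(pc.coord - N.coord) < 1.8:
                    is_nterm = False
            # backbone amide donor
            if N is not None and CA is not None and r.resname != "PRO":
                if is_nterm and treat_termini:
                    hs = [r.get(n) for n in ("H1", "H2", "H3", "H")]
                    hs = [h for h in hs if h is not None]
                    if len(hs) >= 2:
                        groups.append(PolarGroup(N, [CA, hs[0]], hs, "donor",
                                                 "sp3", "nterm_N",
                                                 is_backbone=True))
                    elif hs:
                        groups.append(PolarGroup(N, [CA], hs, "donor", "sp2",
                                                 "bb_N", plane_atom=C,
                                                 is_backbone=True))
                elif r.get("H") is not None:
                    groups.append(PolarGroup(N, [CA], [r.get("H")], "donor",
                                             "sp2", "bb_N", plane_atom=C,
                                             is_backbone=True))
            # backbone carbonyl acceptor
            if O is not None and C is not None and CA is not None:
                groups.append(PolarGroup(O, [C], [], "acceptor", "sp2",
                                         "bb_O", plane_atom=CA,
                                         is_backbone=True))
            oxt = r.get("OXT")
            if oxt is not None and C is not None and O is not None and treat_termini:
                groups.append(PolarGroup(oxt, [C], [], "acceptor", "sp2",
                                         "cterm_O", plane_atom=O,
                                         is_backbone=True))
            # side chain
            for (aname, kind, hyb, bases, hnames, plane, cls) in _SIDECHAIN_POLAR.get(
                r.resname, ()
            ):
                heavy = r.get(aname)
                if heavy is None:
                    continue
                base_atoms = [r.get(b) for b in bases]
                if any(b is None for b in base_atoms):
                    continue
                hs = [r.get(h) for h in hnames]
                hs = [h for h in hs if h is not None]
                if kind in ("donor", "both") and not hs:
                    log.warning("donor %s %s lacks hydrogens; skipped",
                                r.resname, aname)
                    continue
                groups.append(
                    PolarGroup(heavy, base_atoms, hs, kind, hyb, cls,
                               plane_atom=r.get(plane) if plane else None)
                )
    # waters: both donor and sp3 acceptor, symmetric about both hydrogens
    for w in s.waters:
        o = w.get("O") or w.get("OW")
        if o is None:
            continue
        hs = [a for a in w.atoms.values() if a.is_hydrogen]
        if len(hs) == 2:
            groups.append(PolarGroup(o, hs, hs, "both", "sp3", "water_O"))
        else:
            groups.append(PolarGroup(o, [], [], "acceptor", "sp3_bare", "water_O"))
    return groups


# ---------------------------------------------------------------------------
# SASA and interfaces
# ---------------------------------------------------------------------------

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
              "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}


def _sphere_points(n: int) -> np.ndarray:
    from .geometry import fibonacci_sphere

    return fibonacci_sphere(n)


def sasa(atoms, probe: float = 1.4, n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area over heavy atoms."""
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        return 0.0
    coords = np.array([a.coord for a in heavy])
    radii = np.array([_VDW_RADII.get(a.element.upper(), 1.7) + probe for a in heavy])
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    total = 0.0
    rmax = radii.max()
    for i in range(len(heavy)):
        sphere = coords[i] + radii[i] * pts
        nbr = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
               if j != i]
        if nbr:
            d = np.linalg.norm(sphere[:, None, :] - coords[nbr][None, :, :], axis=2)
            exposed = np.all(d >= radii[nbr][None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * radii[i] ** 2 * frac
    return float(total)


@dataclass
class InterfaceDefinition:
    partner_a: tuple
    partner_b: tuple
    interface_residues: list  # residue_id tuples
    buried_area: float

    def __post_init__(self):
        if self.buried_area < -1e-6:
            raise StructureError("negative buried area")
        self.buried_area = max(0.0, self.buried_area)


def _cb_or_ca(res: Residue):
    a = res.get("CB")
    if a is None or res.resname == "GLY":
        a = res.get("CA")
    return a


def define_interface(s: Structure, partner_a, partner_b,
                     cutoff: float = 8.0) -> InterfaceDefinition:
    """Interface residues (Cb within `cutoff` of the other partner) and
    buried area, (SASA_a + SASA_b - SASA_complex) / 2."""
    partner_a = tuple(partner_a)
    partner_b = tuple(partner_b)
    chains = s.chains
    for c in (*partner_a, *partner_b):
        if c not in chains:
            raise StructureError(f"partner chain {c!r} absent from structure")
    res_a = [r for c in partner_a for r in chains[c] if not r.is_water]
    res_b = [r for c in partner_b for r in chains[c] if not r.is_water]
    if not res_a or not res_b:
        raise StructureError("empty interface partner")
    atoms_a = [a for r in res_a for a in r.atoms.values() if not a.is_hydrogen]
    atoms_b = [a for r in res_b for a in r.atoms.values() if not a.is_hydrogen]
    ca = np.array([a.coord for a in atoms_a])
    cb = np.array([a.coord for a in atoms_b])
    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    iface = []
    for r in res_a:
        probe = _cb_or_ca(r)
        if probe is not None and tree_b.query(probe.coord)[0] <= cutoff:
            iface.append(r.residue_id)
    for r in res_b:
        probe = _cb_or_ca(r)
        if probe is not None and tree_a.query(probe.coord)[0] <= cutoff:
            iface.append(r.residue_id)
    area = 0.5 * (sasa(atoms_a) + sasa(atoms_b) - sasa(atoms_a + atoms_b))
    return InterfaceDefinition(partner_a, partner_b, iface, area)
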