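"""Binding energies, decoy discrimination, and water/rotamer recovery.

dG_bind follows a bound/unbound re-solvation protocol: solvate and
score the bound complex, separate the partners beyond interaction
range (each partner is scored as an isolated structure, equivalent to
infinite separation), duplicate the bound-state waters onto both
partners, let each unbound side re-pack (waters may retreat to bulk),
and take the energy difference.  Discrimination over a decoy ensemble is the Boltzmann
weight carried by near-native poses (1 = perfect).  Water recovery
uses a strict criterion: a predicted water counts as native if its
oxygen is within 0.5 A of a native water oxygen or if both waters are
coordinated by the identical set of protein polar atoms (within
3.2 A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .energy import EnergyBreakdown, EnergyModel
from .packer import AnnealSchedule, build_water_rotamers, stage2_pack
from .protocol import SolvateConfig, solvate
from .rotamers import (CHI_DEFS, SYMMETRIC_CHI, chi_difference, get_chis)
from .structure import (InterfaceDefinition, Structure, _cb_or_ca,
                        build_polar_hydrogens, extract_polar_groups)

log = logging.getLogger(__name__)

COORDINATION_CUTOFF = 3.2  # A, protein polar atom to water O
RECOVERY_DISTANCE = 0.5    # A, O-O match criterion
NEAR_NATIVE_PPI = 2.0      # A, ligand-chain CA RMSD
NEAR_NATIVE_LIGAND = 1.0   # A, heavy-atom RMSD
DEFAULT_KT = 1.0           # kcal/mol, discrimination temperature


@dataclass
class ScoreRecord:
    decoy_id: str
    rmsd_to_native: float
    delta_g_bind: float
    breakdown: EnergyBreakdown | None = None
    n_interface_waters: int = 0

    def __post_init__(self):
        if self.rmsd_to_native < 0:
            raise ValueError("negative RMSD")


@dataclass
class RecoveryReport:
    n_native: int
    n_predicted: int
    n_matched: int
    per_class: dict = field(default_factory=dict)
    matches: list = field(default_factory=list)

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.n_matched / self.n_native if self.n_native else 0.0

    @property
    def precision_pct(self) -> float:
        return (100.0 * self.n_matched / self.n_predicted
                if self.n_predicted else 0.0)


# ---------------------------------------------------------------------------
# ΔG_bind
# ---------------------------------------------------------------------------

def _repack_unbound(partner_struct: Structure, waters,
                    model: EnergyModel, sched: AnnealSchedule,
                    cfg: SolvateConfig):
    """Duplicate bound waters onto one unbound partner and let them
    re-anneal (or go virtual)."""
    if not waters:
        return partner_struct, 0
    rotamer_sets = [build_water_rotamers(np.asarray(w, float),
                                         cfg.angular_resolution,
                                         E_bulk=cfg.E_bulk)
                    for w in waters]
    solvated, report = stage2_pack(rotamer_sets, flexible_residues=[],
                                   model=model, sched=sched,
                                   structure=partner_struct)
    n_kept = sum(1 for e in report if e.get("kept"))
    return solvated, n_kept


def delta_g_bind(complex_struct: Structure, interface: InterfaceDefinition,
                 solvate_cfg: SolvateConfig | None = None,
                 model: EnergyModel | None = None,
                 decoy_id: str = "complex", rmsd: float = 0.0,
                 tables=None) -> ScoreRecord:
    """Bound/unbound re-solvation binding energy for a two-partner pose."""
    cfg = solvate_cfg or SolvateConfig()
    model = model or EnergyModel()
    if not interface.partner_a or not interface.partner_b:
        raise ValueError("both interface partners must be defined")
    bound, report = solvate(complex_struct, cfg, interface=interface,
                            model=model, tables=tables)
    bound_bd = model.score_total(bound)
    bound_waters = [ (r.get("O").coord.copy())
                    for r in bound.waters if r.get("O") is not None]
    report_n = report.get("n_waters", 0)

    # unbound state: each partner alone, re-solvated with duplicated waters
    unbound_total = 0.0
    prot = build_polar_hydrogens(complex_struct)
    for chains in (interface.partner_a, interface.partner_b):
        part = Structure([r.copy() for r in prot.residues
                          if r.chain in chains and not r.is_water])
        unb, _ = _repack_unbound(part, bound_waters, model, cfg.stage2, cfg)
        unbound_total += model.score_total(unb).total
    dg = bound_bd.total - unbound_total
    return ScoreRecord(decoy_id=decoy_id, rmsd_to_native=rmsd,
                       delta_g_bind=dg, breakdown=bound_bd,
                       n_interface_waters=report_n)


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def discrimination_score(records, near_native_rmsd: float = NEAR_NATIVE_PPI,
                         kT: float = DEFAULT_KT) -> float:
    """Boltzmann weight of near-native poses, in [0, 1].

    Energies are shifted by their minimum before exponentiation for
    numerical stability; the score is invariant to that shift."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records")
    energies = np.array([r.delta_g_bind for r in records], float)
    near = np.array([r.rmsd_to_native <= near_native_rmsd for r in records])
    if near.all() or not near.any():
        raise ValueError("discrimination undefined: all records on one side "
                         "of the near-native threshold")
    w = np.exp(-(energies - energies.min()) / kT)
    return float(w[near].sum() / w.sum())


def percent_correct(records, near_native_rmsd: float = NEAR_NATIVE_PPI) -> float:
    """100 if the lowest-energy record is near-native, else 0 (per case)."""
    records = list(records)
    best = min(records, key=lambda r: r.delta_g_bind)
    return 100.0 if best.rmsd_to_native <= near_native_rmsd else 0.0


# ---------------------------------------------------------------------------
# Water recovery and classification
# ---------------------------------------------------------------------------

def _water_oxygens(waters):
    out = []
    for w in waters:
        if hasattr(w, "atoms"):
            o = w.get("O") or w.get("OW")
            if o is not None:
                out.append(np.asarray(o.coord, float))
        else:
            out.append(np.asarray(w, float))
    return out


def coordinating_atoms(coord, s: Structure, cutoff: float = COORDINATION_CUTOFF):
    """Frozen set of protein polar atoms within `cutoff` of a water O."""
    out = set()
    for g in extract_polar_groups(s):
        if g.atom_class == "water_O":
            continue
        if np.linalg.norm(g.heavy_atom.coord - np.asarray(coord)) <= cutoff:
            out.add((g.residue_id, g.heavy_atom.name))
    return frozenset(out)


def water_recovery(predicted, native, s: Structure,
                   distance_cut: float = RECOVERY_DISTANCE,
                   coord_cut: float = COORDINATION_CUTOFF) -> RecoveryReport:
    """Greedy one-to-one matching of predicted to native waters.

    A match requires O-O distance <= 0.5 A, or an identical non-empty
    set of coordinating protein polar atoms.  Distance matches are
    assigned first, ascending; coordination matches fill in after.
    """
    pred = _water_oxygens(predicted)
    nat = _water_oxygens(native)
    if not nat:
        raise ValueError("no native waters to recover")
    used_p, used_n = set(), set()
    matches = []
    cand = sorted(
        ((float(np.linalg.norm(p - q)), i, j)
         for i, p in enumerate(pred) for j, q in enumerate(nat)),
        key=lambda t: t[0])
    for d, i, j in cand:
        if d > distance_cut:
            break
        if i in used_p or j in used_n:
            continue
        used_p.add(i)
        used_n.add(j)
        matches.append((i, j, d, "distance"))
    pred_coord = {i: coordinating_atoms(p, s, coord_cut)
                  for i, p in enumerate(pred) if i not in used_p}
    nat_coord = {j: coordinating_atoms(q, s, coord_cut)
                 for j, q in enumerate(nat) if j not in used_n}
    for d, i, j in cand:
        if i in used_p or j in used_n:
            continue
        ci = pred_coord.get(i)
        cj = nat_coord.get(j)
        if ci and cj and ci == cj:
            used_p.add(i)
            used_n.add(j)
            matches.append((i, j, d, "coordination"))
    rep = RecoveryReport(n_native=len(nat), n_predicted=len(pred),
                         n_matched=len(matches), matches=matches)
    classes = classify_waters(native, s)
    for j, cls in enumerate(classes):
        for label in (cls["buriedness"], f"{cls['coordination']} coord",
                      cls["contact_type"]):
            bucket = rep.per_class.setdefault(label, {"native": 0, "matched": 0})
            bucket["native"] += 1
            if any(m[1] == j for m in matches):
                bucket["matched"] += 1
    return rep


def classify_waters(waters, s: Structure) -> list:
    """Buriedness / coordination-count / contact-type classes per water.

    Buriedness counts Cb atoms (Ca for Gly) within 10 A of the water O:
    exposed <= 15, partially buried 16-25, buried > 25.  Coordination
    counts protein polar atoms within 3.2 A.  Contact type is
    backbone-only (>= 2 backbone coordinators and nothing else),
    side-chain-only, or mixed.
    """
    cb = []
    for r in s.protein_residues:
        a = _cb_or_ca(r)
        if a is not None:
            cb.append(a.coord)
    cb_tree = cKDTree(np.asarray(cb)) if cb else None
    groups = [g for g in extract_polar_groups(s) if g.atom_class != "water_O"]
    out = []
    for w in _water_oxygens(waters):
        n_cb = len(cb_tree.query_ball_point(w, 10.0)) if cb_tree else 0
        if n_cb <= 15:
            buried = "exposed"
        elif n_cb <= 25:
            buried = "partially_buried"
        else:
            buried = "buried"
        coords = [g for g in groups
                  if np.linalg.norm(g.heavy_atom.coord - w) <= COORDINATION_CUTOFF]
        n_coord = len(coords)
        n_bb = sum(1 for g in coords if g.is_backbone)
        n_sc = n_coord - n_bb
        if n_bb >= 2 and n_sc == 0:
            ctype = "BB_only"
        elif n_sc >= 1 and n_bb == 0:
            ctype = "SC_only"
        elif n_coord:
            ctype = "BB+SC"
        else:
            ctype = "uncoordinated"
        out.append({"n_cb": n_cb, "buriedness": buried,
                    "coordination": n_coord, "contact_type": ctype})
    return out


def interface_water_density(waters, interface: InterfaceDefinition) -> float:
    """Waters per 1000 A^2 of buried interface area."""
    if interface.buried_area <= 0:
        raise ValueError("zero interface area")
    n = len(_water_oxygens(waters))
    return 1000.0 * n / interface.buried_area


# ---------------------------------------------------------------------------
# Rotamer recovery
# ---------------------------------------------------------------------------

def rotamer_recovery(packed: Structure, reference: Structure,
                     tolerance: float = 20.0) -> float:
    """Fraction of side chains NOT recovered (all chis within tolerance).

    Symmetric terminal chis (Asp, Glu, Phe, Tyr) are compared modulo
    180 degrees.  Residues without chi angles are excluded."""
    n_eval = n_err = 0
    ref_by_id = {r.residue_id: r for r in reference.protein_residues}
    for r in packed.protein_residues:
        if r.resname not in CHI_DEFS:
            continue
        ref = ref_by_id.get(r.residue_id)
        if ref is None or ref.resname != r.resname:
            raise ValueError(f"sequence mismatch at {r.residue_id}")
        chis_p = get_chis(r)
        chis_r = get_chis(ref)
        if not chis_p or len(chis_p) != len(chis_r):
            continue
        n_eval += 1
        sym_k = SYMMETRIC_CHI.get(r.resname)
        ok = True
        for k, (a, b) in enumerate(zip(chis_p, chis_r), start=1):
            period = 180.0 if sym_k == k else 360.0
            if chi_difference(a, b, period) > tolerance:
                ok = False
                break
        if not ok:
            n_err += 1
    if n_eval == 0:
        return 0.0
    return n_err / n_eval
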