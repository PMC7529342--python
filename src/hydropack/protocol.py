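"""End-to-end solvation: candidate sites -> stage 1 -> stage 2.

`solvate` is the high-level entry point used by the CLI and by the
binding-energy protocol: enumerate backbone and side-chain-overlap
candidate sites, optionally restrict them to an interface region,
cluster, run dwell-time point-water packing, convert survivors to
explicit water rotamer sets and anneal orientations together with the
surrounding side chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .energy import EnergyModel
from .packer import (AnnealSchedule, build_water_rotamers, stage1_pack,
                     stage2_pack)
from .point_water import PointWaterParams, default_tables
from .rotamers import CHI_DEFS, default_library
from .sites import (backbone_sites, cluster_sites, filter_clashing_sites,
                    sidechain_overlap_sites)
from .structure import (InterfaceDefinition, Structure, _cb_or_ca,
                        build_polar_hydrogens)

log = logging.getLogger(__name__)

INTERFACE_WATER_TRIM = 6.0  # A from interface-residue CB (CA for Gly)


@dataclass
class SolvateConfig:
    angular_resolution: float = 30.0
    E_bulk: float = 1.22
    point_water: PointWaterParams = field(default_factory=PointWaterParams)
    stage1: AnnealSchedule = field(default_factory=AnnealSchedule)
    stage2: AnnealSchedule = field(default_factory=AnnealSchedule)
    flexible: bool = True          # co-sample side chains near waters
    include_overlap_sites: bool = True
    seed: int = 0

    def seeded(self, seed: int) -> "SolvateConfig":
        from dataclasses import replace

        return replace(self, seed=seed,
                       stage1=replace(self.stage1, seed=seed),
                       stage2=replace(self.stage2, seed=seed + 1))


def restrict_sites_to_interface(sites, s: Structure,
                                interface: InterfaceDefinition,
                                trim: float = INTERFACE_WATER_TRIM):
    """Keep sites within `trim` of an interface-residue Cb (Ca for Gly)."""
    probes = []
    iface = set(interface.interface_residues)
    for r in s.protein_residues:
        if r.residue_id in iface:
            a = _cb_or_ca(r)
            if a is not None:
                probes.append(a.coord)
    if not probes:
        return []
    tree = cKDTree(np.asarray(probes))
    return [st for st in sites if tree.query(st.coord)[0] <= trim]


def generate_candidate_sites(s: Structure, cfg: SolvateConfig | None = None,
                             interface: InterfaceDefinition | None = None):
    cfg = cfg or SolvateConfig()
    sites = backbone_sites(s)
    if cfg.include_overlap_sites:
        sites = sites + sidechain_overlap_sites(s)
    sites = filter_clashing_sites(sites, s)
    if interface is not None:
        sites = restrict_sites_to_interface(sites, s, interface)
    return cluster_sites(sites)


def _flexible_near_sites(s: Structure, sites, reach: float = 5.0):
    if not sites:
        return []
    pts = np.array([st.coord for st in sites])
    tree = cKDTree(pts)
    flex = []
    for r in s.protein_residues:
        if r.resname not in CHI_DEFS:
            continue
        sc = [a for a in r.atoms.values()
              if not a.is_hydrogen and a.name not in ("N", "CA", "C", "O")]
        if any(len(tree.query_ball_point(a.coord, reach)) for a in sc):
            flex.append(r)
    return flex


def solvate(s: Structure, cfg: SolvateConfig | None = None,
            interface: InterfaceDefinition | None = None,
            model: EnergyModel | None = None, tables=None):
    """Place explicit waters on a structure (optionally interface-only).

    Returns (solvated structure, report dict).  Input waters are
    ignored as candidates; hydrogens are built if missing.
    """
    cfg = cfg or SolvateConfig()
    model = model or EnergyModel()
    s = build_polar_hydrogens(s)
    tables = tables if tables is not None else default_tables()
    sites = generate_candidate_sites(s, cfg, interface)
    flex = _flexible_near_sites(s, sites) if cfg.flexible else []
    lib = default_library()
    retained, _stage1 = stage1_pack(
        sites, flexible_residues=flex, lib=lib, tables=tables,
        p=cfg.point_water, sched=cfg.stage1, structure=s)
    report = {"n_candidate_sites": len(sites),
              "n_retained_sites": len(retained)}
    if not retained:
        report["n_waters"] = 0
        return s.copy(), report
    rotamer_sets = [build_water_rotamers(st, cfg.angular_resolution,
                                         E_bulk=cfg.E_bulk)
                    for st in retained]
    solvated, pack_report = stage2_pack(
        rotamer_sets, flexible_residues=flex, lib=lib, model=model,
        sched=cfg.stage2, structure=s)
    # carry stage-1 occupancies onto the emitted waters
    kept = [e for e in pack_report if e.get("kept")]
    n_prior = len(s.waters)
    new_waters = solvated.waters[n_prior:]
    for w, entry in zip(new_waters, kept):
        occ = retained[entry["position"][1]].occupancy
        for a in w.atoms.values():
            a.occupancy = occ
    report["n_waters"] = len(kept)
    report["sites"] = retained
    report["pack_report"] = pack_report
    return solvated, report
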