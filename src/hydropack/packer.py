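"""Two-stage Monte Carlo water placement with side-chain co-sampling.

Stage 1 ("point water" packing).  Candidate oxygen positions, clustered
into mutually exclusive sets, are sampled together with side-chain
rotamers in one Metropolis chain.  Instead of annealing to a single
minimum, the chain runs long at low temperature (RT = 0.3 kcal/mol)
with periodic high-temperature spikes (RT = 100) that scramble the
state; the fraction of low-temperature steps a site spends occupied
(its "dwell time", counted after discarding the first 1/6 of each
low-temperature phase) is its occupancy, and sites above a 2% dwell
cutoff survive to stage 2.

Stage 2 (explicit rotamer packing).  Surviving sites become rigid
three-atom waters with a uniform SO(3) orientation grid (30 degree
spacing after quotienting the water C2 symmetry: 270 conformers) plus
one "virtual" bulk state.  Standard simulated annealing co-optimizes
water orientations and side chains; water moves propose the virtual
state half the time, and waters ending virtual are deleted.  Coming out
of bulk costs E_bulk = 1.22 kcal/mol.

Both stages are expressed as a discrete pairwise ("Potts") problem so
tiny instances can be checked against exhaustive enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .builder import make_water, water_hydrogen_offsets
from .energy import EnergyModel, Entity, assign_charges
from .geometry import fibonacci_sphere, rotation_about_axis, rotation_align
from .point_water import PointWaterParams, polar_term, water_water_term
from .rotamers import RotamerLibrary, apply_chis, default_library
from .structure import PolarGroup, Structure, extract_polar_groups

log = logging.getLogger(__name__)

STERIC_WW_CUT = 2.15  # A, hard point-water / point-water repulsion onset
STERIC_PENALTY = 6.0  # kcal/mol
ROTAMER_PROB_WEIGHT = 0.59  # kcal/mol per -log(prob)


@dataclass
class AnnealSchedule:
    """Monte Carlo schedule shared by both packing stages."""

    RT_low: float = 0.3    # kcal/mol
    RT_high: float = 100.0
    n_cycles: int = 6
    steps_per_cycle: int | None = None  # default: 200 * n_positions
    spike_fraction: float = 0.1
    burn_in_fraction: float = 1.0 / 6.0
    dwell_threshold: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.RT_low < self.RT_high):
            raise ValueError("need 0 < RT_low < RT_high")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass
class Position:
    """One packing degree of freedom with its discrete states."""

    label: object
    n_states: int
    kind: str  # "water_cluster" | "water_rotamer" | "sidechain"
    virtual_state: int | None = None  # off/bulk state index

    @property
    def is_water(self) -> bool:
        return self.kind in ("water_cluster", "water_rotamer")


class PackingProblem:
    """Pairwise decomposable discrete optimization problem."""

    def __init__(self, positions):
        self.positions: list[Position] = list(positions)
        self.one_body = [np.zeros(p.n_states) for p in self.positions]
        self.two_body: dict[tuple, np.ndarray] = {}

    def set_two_body(self, p: int, q: int, mat: np.ndarray):
        if p > q:
            p, q, mat = q, p, np.asarray(mat).T
        self.two_body[(p, q)] = np.asarray(mat, float)

    def neighbors(self, p: int):
        for (a, b), mat in self.two_body.items():
            if a == p:
                yield b, mat, False
            elif b == p:
                yield a, mat, True

    def energy(self, assignment) -> float:
        e = sum(self.one_body[p][s] for p, s in enumerate(assignment))
        for (a, b), mat in self.two_body.items():
            e += mat[assignment[a], assignment[b]]
        return float(e)

    def delta_energy(self, assignment, p: int, new_state: int) -> float:
        old = assignment[p]
        if new_state == old:
            return 0.0
        d = self.one_body[p][new_state] - self.one_body[p][old]
        for q, mat, transposed in self.neighbors(p):
            sq = assignment[q]
            if transposed:
                d += mat[sq, new_state] - mat[sq, old]
            else:
                d += mat[new_state, sq] - mat[old, sq]
        return float(d)


@dataclass
class AnnealResult:
    best_assignment: list
    best_energy: float
    dwell: list            # per position: state visit counts (low T, post burn-in)
    n_counted: int
    final_assignment: list


def anneal(problem: PackingProblem, sched: AnnealSchedule,
           rng: np.random.Generator | None = None,
           virtual_bias: float = 0.0,
           initial=None) -> AnnealResult:
    """Metropolis chain alternating high-T spikes and long low-T phases.

    Dwell counters accumulate only during low-temperature steps after
    the burn-in fraction of each cycle.  `virtual_bias` is the
    probability that a move at a water position proposes the virtual
    state instead of a uniformly drawn one.  Deterministic given the
    generator state.
    """
    rng = rng or np.random.default_rng(sched.seed)
    n_pos = len(problem.positions)
    if n_pos == 0:
        return AnnealResult([], 0.0, [], 0, [])
    steps = sched.steps_per_cycle or 200 * n_pos
    n_spike = max(1, int(round(sched.spike_fraction * steps)))
    if initial is None:
        assignment = [p.virtual_state if p.virtual_state is not None else 0
                      for p in problem.positions]
    else:
        assignment = list(initial)
    energy = problem.energy(assignment)
    best_e, best_a = energy, list(assignment)
    dwell = [np.zeros(p.n_states, dtype=np.int64) for p in problem.positions]
    n_counted = 0

    def do_step(rt: float):
        nonlocal energy, best_e, best_a
        p = int(rng.integers(n_pos))
        pos = problem.positions[p]
        if (pos.is_water and pos.virtual_state is not None
                and virtual_bias > 0.0 and rng.random() < virtual_bias):
            new = pos.virtual_state
        else:
            new = int(rng.integers(pos.n_states))
        d = problem.delta_energy(assignment, p, new)
        if d <= 0.0 or rng.random() < np.exp(-d / rt):
            assignment[p] = new
            energy += d
            if energy < best_e - 1e-12:
                best_e, best_a = energy, list(assignment)

    for _cycle in range(sched.n_cycles):
        for _ in range(n_spike):
            do_step(sched.RT_high)
        burn = int(sched.burn_in_fraction * steps)
        for i in range(steps):
            do_step(sched.RT_low)
            if i >= burn:
                for p, s in enumerate(assignment):
                    dwell[p][s] += 1
                n_counted += 1
    return AnnealResult(best_a, best_e, dwell, n_counted, list(assignment))


# ---------------------------------------------------------------------------
# Stage 1: point-water packing
# ---------------------------------------------------------------------------

def _sidechain_entity(residue, key) -> Entity:
    sub = Structure([residue])
    groups = [g for g in extract_polar_groups(sub) if not g.is_backbone]
    sc_atoms = [a for a in residue.atoms.values()
                if a.name not in ("N", "CA", "C", "O", "H")]
    return Entity(key=key, atoms=sc_atoms, groups=groups,
                  chain=residue.chain, seqnum=residue.seqnum)


def _rotamer_variants(residue, lib: RotamerLibrary):
    """Residue copies for each library rotamer (current conformation
    first), with -log probability one-body preferences."""
    variants = [(residue.copy(), 0.0)]
    for chis, prob in lib.get(residue.resname):
        work = residue.copy()
        apply_chis(work, chis)
        variants.append((work, -ROTAMER_PROB_WEIGHT * np.log(max(prob, 1e-6))))
    return variants


def _clash_count(atoms_a, atoms_b, cut=2.5):
    n = 0
    for a in atoms_a:
        if a.is_hydrogen:
            continue
        for b in atoms_b:
            if b.is_hydrogen:
                continue
            if np.linalg.norm(a.coord - b.coord) < cut:
                n += 1
    return n


def build_stage1_problem(sites, structure: Structure, flexible_residues=(),
                         lib: RotamerLibrary | None = None, tables=None,
                         p: PointWaterParams | None = None):
    """Potts encoding of the stage-1 problem.

    Water positions are the site clusters (state 0 = off); flexible
    residues contribute rotamer positions whose polar atoms re-enter
    the statistical term of every nearby site.
    """
    from .point_water import default_tables

    p = p or PointWaterParams()
    lib = lib or default_library()
    tables = tables if tables is not None else default_tables()
    flexible_residues = list(flexible_residues)
    flex_ids = {r.residue_id for r in flexible_residues}
    fixed_groups = [g for g in extract_polar_groups(structure)
                    if g.residue_id not in flex_ids or g.is_backbone]
    _BB = ("N", "CA", "C", "O", "H")
    fixed_heavy = [a for r in structure.protein_residues
                   for a in r.atoms.values()
                   if not a.is_hydrogen
                   and (r.residue_id not in flex_ids or a.name in _BB)]

    clusters: dict[int, list] = {}
    for s in sites:
        clusters.setdefault(s.cluster_id, []).append(s)
    cluster_ids = sorted(clusters)
    positions = []
    payload = []  # per position: ("cluster", [sites]) or ("res", [variants])
    for cid in cluster_ids:
        members = clusters[cid]
        positions.append(Position(("cluster", cid), 1 + len(members),
                                  "water_cluster", virtual_state=0))
        payload.append(("cluster", members))
    for r in flexible_residues:
        variants = _rotamer_variants(r, lib)
        positions.append(Position(("res", r.residue_id), len(variants),
                                  "sidechain"))
        payload.append(("res", variants))
    prob = PackingProblem(positions)

    # one-body
    for i, (kind, data) in enumerate(payload):
        if kind == "cluster":
            for s_idx, site in enumerate(data, start=1):
                e = polar_term(site.coord, fixed_groups, tables) + p.E_pwat_bulk
                prob.one_body[i][s_idx] = e
        else:
            for v_idx, (res, pref) in enumerate(data):
                ent = _sidechain_entity(res, ("res", res.residue_id))
                e = pref + 4.0 * _clash_count(
                    ent.atoms,
                    [a for a in fixed_heavy if a.residue_id != res.residue_id])
                prob.one_body[i][v_idx] = e

    # two-body
    n = len(positions)
    for i in range(n):
        ki, di = payload[i]
        for j in range(i + 1, n):
            kj, dj = payload[j]
            if ki == "cluster" and kj == "cluster":
                mat = np.zeros((len(di) + 1, len(dj) + 1))
                for a, sa in enumerate(di, start=1):
                    for b, sb in enumerate(dj, start=1):
                        d = float(np.linalg.norm(sa.coord - sb.coord))
                        e = 2.0 * water_water_term(d, p)
                        if d < STERIC_WW_CUT:
                            e += STERIC_PENALTY
                        mat[a, b] = e
                if np.any(mat):
                    prob.set_two_body(i, j, mat)
            elif ki == "cluster" and kj == "res":
                mat = np.zeros((len(di) + 1, len(dj)))
                for a, sa in enumerate(di, start=1):
                    for b, (res, _pref) in enumerate(dj):
                        ent = _sidechain_entity(res, ("res", res.residue_id))
                        e = polar_term(sa.coord, ent.groups, tables)
                        if any(np.linalg.norm(x.coord - sa.coord) < 2.0
                               for x in ent.atoms if not x.is_hydrogen):
                            e += STERIC_PENALTY
                        mat[a, b] = e
                if np.any(mat):
                    prob.set_two_body(i, j, mat)
            elif ki == "res" and kj == "res":
                mat = np.zeros((len(di), len(dj)))
                for a, (ra, _) in enumerate(di):
                    for b, (rb, _) in enumerate(dj):
                        ea = _sidechain_entity(ra, None)
                        eb = _sidechain_entity(rb, None)
                        mat[a, b] = 4.0 * _clash_count(ea.atoms, eb.atoms)
                if np.any(mat):
                    prob.set_two_body(i, j, mat)
    return prob, payload


def stage1_pack(sites, flexible_residues=(), lib=None, tables=None,
                p: PointWaterParams | None = None,
                sched: AnnealSchedule | None = None,
                structure: Structure | None = None,
                dwell_mode: str = "member"):
    """Dwell-time occupancy packing of point waters (+ side chains).

    Returns (retained_sites, result): sites with occupancy >= the dwell
    threshold, occupancies filled in, and the raw annealing result.
    """
    sched = sched or AnnealSchedule()
    p = p or PointWaterParams()
    sites = list(sites)
    if not sites:
        return [], None
    if structure is None:
        raise ValueError("stage1_pack requires the parent structure")
    prob, payload = build_stage1_problem(sites, structure, flexible_residues,
                                         lib, tables, p)
    rng = np.random.default_rng(sched.seed)
    res = anneal(prob, sched, rng, virtual_bias=0.0)
    retained = []
    for i, (kind, data) in enumerate(payload):
        if kind != "cluster":
            continue
        counts = res.dwell[i]
        total = max(1, res.n_counted)
        cluster_occ = float(counts[1:].sum()) / total
        for s_idx, site in enumerate(data, start=1):
            occ = float(counts[s_idx]) / total
            site.dwell_count = int(counts[s_idx])
            site.occupancy = min(1.0, cluster_occ if dwell_mode == "cluster"
                                 else occ)
            keep = (cluster_occ if dwell_mode == "cluster" else occ)
            if keep >= sched.dwell_threshold:
                retained.append(site)
    return retained, res


# ---------------------------------------------------------------------------
# Water rotamers (SO(3) grid)
# ---------------------------------------------------------------------------

@dataclass
class WaterRotamerSet:
    oxygen: np.ndarray
    rotamers: list  # rotation matrices, O fixed
    includes_virtual: bool = True
    E_bulk: float = 1.22  # kcal/mol out-of-bulk cost

    def __post_init__(self):
        self.oxygen = np.asarray(self.oxygen, float)


_FULL_SPHERE_SQDEG = 4.0 * np.pi * (180.0 / np.pi) ** 2  # 41252.96...


def supported_resolutions():
    return tuple(r for r in (10, 12, 15, 18, 20, 30, 36, 45, 60, 90)
                 if 180 % r == 0)


def build_water_rotamers(site, angular_resolution: float = 30.0,
                         E_bulk: float = 1.22) -> WaterRotamerSet:
    """Uniform SO(3) orientation grid reduced by the water C2 symmetry.

    Orientations factor through the Hopf-style product of a sphere grid
    for the C2 (dipole) axis direction with an in-plane spin about that
    axis.  The spin only covers [0, 180) because rotating a water half
    a turn about its C2 axis maps it onto itself.  Direction count is
    floor(41253 deg^2 / resolution^2); at 30 degrees this gives
    45 directions x 6 spins = 270 rotamers.
    """
    res = float(angular_resolution)
    if int(res) != res or int(res) not in supported_resolutions():
        raise ValueError(
            f"unsupported angular resolution {angular_resolution}; "
            f"supported: {supported_resolutions()}")
    res = int(res)
    n_dirs = int(np.floor(_FULL_SPHERE_SQDEG / (res * res)))
    n_spin = 180 // res
    dirs = fibonacci_sphere(n_dirs)
    rotamers = []
    z = np.array([0.0, 0.0, 1.0])
    for d in dirs:
        R_align = rotation_align(z, d)
        for k in range(n_spin):
            R_spin = rotation_about_axis(z, k * res)
            rotamers.append(R_align @ R_spin)
    coord = site.coord if hasattr(site, "coord") else np.asarray(site, float)
    return WaterRotamerSet(coord, rotamers, includes_virtual=True,
                           E_bulk=E_bulk)


def water_entity(oxygen, R, key=("water", 0)) -> Entity:
    res = make_water(oxygen, R, chain="W", seqnum=key[1] if len(key) > 1 else 1)
    o = res.get("O")
    h1, h2 = res.get("H1"), res.get("H2")
    group = PolarGroup(o, [h1, h2], [h1, h2], "both", "sp3", "water_O")
    return Entity(key=key, atoms=[o, h1, h2], groups=[group], is_water=True,
                  chain="W", seqnum=key[1] if len(key) > 1 else 1)


# ---------------------------------------------------------------------------
# Vectorized water-water pair energies
# ---------------------------------------------------------------------------

def _g_kernel_vec(x, S0):
    u = (x * x) / (S0 * S0)
    return np.where(np.abs(x) >= S0, 0.0, (1.0 - u * u) ** 2)


def _lj_vec(r, ri, rj):
    from .energy import LJ_CAP, LJ_EPS, PAIR_CUTOFF

    with np.errstate(divide="ignore"):
        sr6 = ((ri + rj) * 0.89 / np.maximum(r, 1e-9)) ** 6
    e = np.minimum(LJ_CAP, LJ_EPS * (sr6 * sr6 - 2.0 * sr6))
    return np.where((r > PAIR_CUTOFF) | (r < 1e-9), 0.0, e)


def _elec_vec(r, qi, qj):
    from .energy import COULOMB, PAIR_CUTOFF

    e = COULOMB * qi * qj / (4.0 * np.maximum(r, 1e-9) ** 2)
    return np.where((r > PAIR_CUTOFF) | (r < 1e-9), 0.0, e)


def water_pair_matrix(rs_a: "WaterRotamerSet", rs_b: "WaterRotamerSet",
                      model: EnergyModel | None = None) -> np.ndarray:
    """(n_a, n_b) weighted pair energies between two explicit waters.

    Numerically identical to :meth:`EnergyModel.pair_energy` over
    :func:`water_entity` pairs (waters carry no LK terms), but computed
    with array broadcasting over both rotamer grids.
    """
    from .energy import _CLASS_CHARGE

    model = model or EnergyModel()
    hb = model.hbond
    bah = hb.bah_water
    q_o = _CLASS_CHARGE["water_O"]
    q_h = 0.34
    h_loc = water_hydrogen_offsets()  # (2, 3)
    ra = np.stack(rs_a.rotamers)      # (na, 3, 3)
    rb = np.stack(rs_b.rotamers)
    oa, ob = np.asarray(rs_a.oxygen), np.asarray(rs_b.oxygen)
    ha = oa + np.einsum("nij,kj->nki", ra, h_loc)  # (na, 2, 3)
    hbb = ob + np.einsum("nij,kj->nki", rb, h_loc)
    na, nb = len(ra), len(rb)
    from .energy import LJ_RADII

    r_o, r_h = LJ_RADII["O"], LJ_RADII["H"]
    total = np.zeros((na, nb))

    # O-O (constant over rotamers)
    r_oo = float(np.linalg.norm(oa - ob))
    total += model.weights["lj"] * _lj_vec(np.array(r_oo), r_o, r_o)
    total += model.weights["elec"] * _elec_vec(np.array(r_oo), q_o, q_o)
    # O_a - H_b  (varies along b)
    d = np.linalg.norm(hbb - oa, axis=2)  # (nb, 2)
    eb_ = (model.weights["lj"] * _lj_vec(d, r_o, r_h)
           + model.weights["elec"] * _elec_vec(d, q_o, q_h)).sum(axis=1)
    total += eb_[None, :]
    # H_a - O_b  (varies along a)
    d = np.linalg.norm(ha - ob, axis=2)  # (na, 2)
    ea_ = (model.weights["lj"] * _lj_vec(d, r_h, r_o)
           + model.weights["elec"] * _elec_vec(d, q_h, q_o)).sum(axis=1)
    total += ea_[:, None]
    # H_a - H_b
    d = np.linalg.norm(ha[:, :, None, None, :] - hbb[None, None, :, :, :],
                       axis=4)  # (na, 2, nb, 2)
    e_hh = (model.weights["lj"] * _lj_vec(d, r_h, r_h)
            + model.weights["elec"] * _elec_vec(d, q_h, q_h))
    total += e_hh.sum(axis=(1, 3))

    def donor_to_acceptor(h_don, o_don, o_acc, h_acc):
        """Summed hbond of donor hydrogens (n_d, 2, 3) into acceptor
        (o_acc fixed, h_acc (n_a2, 2, 3)); returns (n_d, n_a2)."""
        d_ha = np.linalg.norm(h_don - o_acc, axis=2)          # (nd, 2)
        fd = _g_kernel_vec(d_ha - hb.ideal_ha, hb.dist_width)
        u = o_don - h_don                                      # (nd, 2, 3)
        v = o_acc - h_don
        cos_ahd = (np.einsum("nkd,nkd->nk", u, v)
                   / np.maximum(np.linalg.norm(u, axis=2)
                                * np.linalg.norm(v, axis=2), 1e-12))
        fa = np.maximum(0.0, -cos_ahd) ** 2                    # (nd, 2)
        # BAH angles at the acceptor O for both acceptor hydrogens
        bvec = h_acc - o_acc                                   # (na2, 2, 3)
        hvec = h_don - o_acc                                   # (nd, 2, 3)
        num = np.einsum("nkd,mjd->nkmj", hvec, bvec)
        den = (np.linalg.norm(hvec, axis=2)[:, :, None, None]
               * np.linalg.norm(bvec, axis=2)[None, None, :, :])
        th = np.degrees(np.arccos(np.clip(num / np.maximum(den, 1e-12),
                                          -1.0, 1.0)))        # (nd,2,na2,2)
        dev = np.abs(th - bah.theta0)
        e_bah = np.where(dev >= bah.width, 0.0,
                         -bah.depth * np.cos(np.pi / 2.0 * dev / bah.width) ** 2)
        m = hb.M
        e_ang = m * logsumexp(e_bah / m, axis=3)               # (nd, 2, na2)
        return np.einsum("nk,nkm->nm", fd * fa, e_ang)

    hb_term = donor_to_acceptor(ha, oa, ob, hbb)               # A donates
    hb_term += donor_to_acceptor(hbb, ob, oa, ha).T            # B donates
    total += model.weights["hbond"] * hb_term
    return total


# ---------------------------------------------------------------------------
# Stage 2: explicit rotamer packing
# ---------------------------------------------------------------------------

def build_stage2_problem(rotamer_sets, structure: Structure,
                         flexible_residues=(), lib=None,
                         model: EnergyModel | None = None,
                         reach: float = 8.0):
    model = model or EnergyModel()
    lib = lib or default_library()
    flexible_residues = list(flexible_residues)
    flex_ids = {r.residue_id for r in flexible_residues}
    fixed_entities = [e for e in model.entities(structure)
                      if e.key not in flex_ids and not e.is_water]
    charges = assign_charges([g for e in fixed_entities for g in e.groups]
                             + extract_polar_groups(structure))

    positions, payload = [], []
    for w_idx, rs in enumerate(rotamer_sets):
        ents = [water_entity(rs.oxygen, R, key=("water", w_idx))
                for R in rs.rotamers]
        positions.append(Position(("water", w_idx), 1 + len(ents),
                                  "water_rotamer", virtual_state=0))
        payload.append(("water", rs, ents))
    for r in flexible_residues:
        variants = _rotamer_variants(r, lib)
        ents = [(_sidechain_entity(res, ("res", r.residue_id)), pref)
                for res, pref in variants]
        positions.append(Position(("res", r.residue_id), len(ents), "sidechain"))
        payload.append(("res", r, ents))
    prob = PackingProblem(positions)

    def entity_charges(ent):
        q = dict(charges)
        q.update(assign_charges(ent.groups))
        return q

    # one-body vs fixed environment
    for i, entry in enumerate(payload):
        if entry[0] == "water":
            _, rs, ents = entry
            near = [fe for fe in fixed_entities
                    if np.linalg.norm(fe.centroid - rs.oxygen) < reach + 5.0]
            for s_idx, ent in enumerate(ents, start=1):
                q = entity_charges(ent)
                e = rs.E_bulk
                for fe in near:
                    e += model.pair_energy(ent, fe, charges=q, adjacent=False)
                prob.one_body[i][s_idx] = e
        else:
            _, r, ents = entry
            for v_idx, (ent, pref) in enumerate(ents):
                q = entity_charges(ent)
                e = pref
                for fe in fixed_entities:
                    if fe.key == r.residue_id:
                        continue
                    if np.linalg.norm(fe.centroid - ent.centroid) < reach + 6.0:
                        e += model.pair_energy(ent, fe, charges=q,
                                               adjacent=False)
                prob.one_body[i][v_idx] = e

    # two-body
    n = len(payload)
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = payload[i], payload[j]
            if pi[0] == "water" and pj[0] == "water":
                if np.linalg.norm(pi[1].oxygen - pj[1].oxygen) > reach:
                    continue
                mat = np.zeros((1 + len(pi[2]), 1 + len(pj[2])))
                mat[1:, 1:] = water_pair_matrix(pi[1], pj[1], model)
                prob.set_two_body(i, j, mat)
            elif pi[0] == "water" or pj[0] == "water":
                (wi, ri) = (i, j) if pi[0] == "water" else (j, i)
                wp, rp = payload[wi], payload[ri]
                if min(np.linalg.norm(wp[1].oxygen - ent.centroid)
                       for ent, _ in rp[2]) > reach + 4.0:
                    continue
                mat = np.zeros((1 + len(wp[2]), len(rp[2])))
                for a, ea in enumerate(wp[2], start=1):
                    qa = entity_charges(ea)
                    for b, (eb, _) in enumerate(rp[2]):
                        mat[a, b] = model.pair_energy(ea, eb, charges=qa,
                                                      adjacent=False)
                prob.set_two_body(wi, ri, mat)
            else:
                mat = np.zeros((len(pi[2]), len(pj[2])))
                for a, (ea, _) in enumerate(pi[2]):
                    qa = entity_charges(ea)
                    for b, (eb, _) in enumerate(pj[2]):
                        mat[a, b] = model.pair_energy(ea, eb, charges=qa,
                                                      adjacent=False)
                prob.set_two_body(i, j, mat)
    return prob, payload


def stage2_pack(rotamer_sets, flexible_residues=(), lib=None,
                model: EnergyModel | None = None,
                sched: AnnealSchedule | None = None,
                virtual_bias: float = 0.5,
                structure: Structure | None = None):
    """Explicit water-rotamer + side-chain simulated annealing.

    Returns (solvated_structure, report).  Waters that end in the
    virtual (bulk) state are removed from the output; survivors carry
    full three-atom geometry.
    """
    sched = sched or AnnealSchedule()
    if structure is None:
        raise ValueError("stage2_pack requires the parent structure")
    prob, payload = build_stage2_problem(rotamer_sets, structure,
                                         flexible_residues, lib, model)
    rng = np.random.default_rng(sched.seed)
    res = anneal(prob, sched, rng, virtual_bias=virtual_bias)
    out = structure.copy()
    report = []
    wat_num = len(out.waters)
    for i, entry in enumerate(payload):
        state = res.best_assignment[i]
        if entry[0] == "water":
            _, rs, ents = entry
            if state == 0:
                report.append({"position": prob.positions[i].label,
                               "kept": False, "energy": None})
                continue
            wat_num += 1
            R = rs.rotamers[state - 1]
            out.residues.append(make_water(rs.oxygen, R, chain="W",
                                           seqnum=wat_num))
            report.append({"position": prob.positions[i].label, "kept": True,
                           "energy": float(prob.one_body[i][state]),
                           "rotamer": state - 1})
        else:
            _, r, ents = entry
            target = out.residue(*r.residue_id)
            chosen = ents[state][0]
            for a in chosen.atoms:
                if a.name in target.atoms:
                    target.atoms[a.name].coord = a.coord.copy()
            report.append({"position": prob.positions[i].label,
                           "state": state})
    return out, report
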