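"""Implicit-solvation energetics with bridging-water awareness.

Terms
-----
lk_iso
    Isotropic Lazaridis-Karplus pair desolvation (Gaussian exclusion
    model): each atom j occludes part of the solvation shell of atom i.
lk_ball
    Anisotropic attenuation of the isotropic term: occluding an *ideal
    water site* of a polar atom costs more than occluding bulk-facing
    shell.  Implemented here as a distance-to-nearest-virtual-site
    weighting; an approximation, not a port of any particular code base.
lk_bridge
    A bonus for pairs of polar groups whose ideal hydration sites
    overlap such that one water could bridge them.  Product of the pair
    desolvation magnitude with two quartic kernels: one over the minimum
    water-site/water-site distance and one over the distance between the
    two polar heavy atoms.  Default parameters
    (D0_len, D0_angle, S0_len, S0_angle) = (0.5, 4.33, 1.61, 2.69) A.
hbond
    Minimal distance x angular hydrogen-bond potential.  sp3 acceptors
    (hydroxyls, waters) use a softmax over both atoms bound to the
    acceptor, which makes the water potential symmetric under swapping
    its two hydrogens.
lj / elec
    A plain 12-6 Lennard-Jones clash/attraction term and a
    distance-dependent-dielectric Coulomb term over a small set of
    polar partial charges.  These are deliberately simple: they make
    toy systems rank correctly and are not fitted to any force field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .geometry import angle_deg, rotation_about_axis, unit
from .structure import PolarGroup, Structure, extract_polar_groups

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class BridgeParams:
    """Bridging-water kernel parameters (lengths in Angstroms)."""

    D0_len: float = 0.5
    D0_angle: float = 4.33
    S0_len: float = 1.61
    S0_angle: float = 2.69
    weight: float = 1.0

    def __post_init__(self):
        if self.S0_len <= 0 or self.S0_angle <= 0:
            raise ValueError("kernel widths must be positive")


class CosineBAH:
    """Smooth cosine-well base-acceptor-hydrogen angular potential.

    Minimum -depth at the ideal angle, zero-clamped outside +-width.
    A stand-in with the right shape, swappable via HBondParams."""

    def __init__(self, theta0: float = 109.5, depth: float = 1.0,
                 width: float = 60.0):
        self.theta0 = theta0
        self.depth = depth
        self.width = width

    def __call__(self, base, acceptor, hydrogen) -> float:
        th = angle_deg(base, acceptor, hydrogen)
        dev = abs(th - self.theta0)
        if dev >= self.width:
            return 0.0
        return -self.depth * float(np.cos(np.pi / 2.0 * dev / self.width)) ** 2


@dataclass
class HBondParams:
    M: float = 0.4  # kcal/mol softmax softness
    bah_potential: object = field(default_factory=CosineBAH)
    bah_water: object = field(default_factory=lambda: CosineBAH(theta0=120.0))
    ideal_ha: float = 1.9  # A, H...acceptor optimum
    dist_width: float = 0.8

    def __post_init__(self):
        if self.M <= 0:
            raise ValueError("softmax softness M must be positive")


# Lazaridis-Karplus style per-element solvation parameters:
# element -> (dG_free kcal/mol, correlation length A, volume A^3, radius A)
LK_PARAMS = {
    "C": (0.52, 3.5, 14.7, 2.0),
    "N": (-9.0, 3.5, 11.2, 1.75),
    "O": (-6.8, 3.5, 11.2, 1.55),
    "S": (-2.2, 3.5, 14.7, 1.9),
    "P": (-4.0, 3.5, 14.7, 1.9),
}

LJ_RADII = {"C": 2.0, "N": 1.75, "O": 1.55, "S": 1.9, "P": 1.9, "H": 1.0}
LJ_EPS = 0.10  # kcal/mol, uniform well depth
LJ_CAP = 10.0  # kcal/mol clamp on the repulsive branch
COULOMB = 332.0637
PAIR_CUTOFF = 6.0

DEFAULT_WEIGHTS = {
    "lj": 1.0,
    "elec": 0.25,
    "lk_iso": 1.0,
    "lk_ball": 0.5,
    "lk_bridge": -1.0,  # the bridge kernel refunds spurious pair desolvation
    "hbond": 2.0,
}


# ---------------------------------------------------------------------------
# Kernels and pair terms
# ---------------------------------------------------------------------------

def g_kernel(x: float, S0: float) -> float:
    """Quartic bump kernel: (1 - (x^2/S0^2)^2)^2 on [-S0, S0], else 0.

    Even, continuous, equal to 1 at x = 0 and 0 at |x| >= S0."""
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    x = float(x)
    if abs(x) >= S0:
        return 0.0
    u = (x * x) / (S0 * S0)
    return (1.0 - u * u) ** 2


def lk_pair(elem_i: str, elem_j: str, r: float, params=None) -> float:
    """Symmetric LK pair desolvation energy at separation r (A).

    Positive for polar atoms (occlusion removes favorable solvation)."""
    params = params or LK_PARAMS
    if r > PAIR_CUTOFF or r < 1e-6:
        return 0.0
    out = 0.0
    for ei, ej in ((elem_i, elem_j), (elem_j, elem_i)):
        if ei not in params:
            raise KeyError(f"no LK parameters for atom class {ei!r}")
        dg_i, lam_i, _, rad_i = params[ei]
        _, _, vol_j, rad_j = params[ej]
        sigma = rad_i + rad_j
        x = (r - sigma) / lam_i
        out += -(dg_i / (2.0 * np.pi ** 1.5 * lam_i * r * r)) * np.exp(-x * x) * vol_j
    return float(out)


def lk_iso(group_i: PolarGroup, group_j: PolarGroup, params=None) -> float:
    """Isotropic desolvation between the heavy atoms of two polar groups."""
    r = float(np.linalg.norm(group_i.heavy_atom.coord - group_j.heavy_atom.coord))
    return lk_pair(group_i.heavy_atom.element, group_j.heavy_atom.element, r,
                   params)


# ---------------------------------------------------------------------------
# Virtual water sites
# ---------------------------------------------------------------------------

@dataclass
class VirtualWaterSite:
    coord: np.ndarray
    parent: PolarGroup
    geometry_label: str

    def __post_init__(self):
        d = float(np.linalg.norm(self.coord - self.parent.heavy_atom.coord))
        if not (1.5 < d < 4.0):
            raise ValueError(f"virtual site at {d:.2f} A from parent atom")


_DONOR_SITE_EXT = 1.9   # A beyond the hydrogen
_ACCEPTOR_SITE_D = 2.8  # A from the acceptor heavy atom


def ideal_water_sites(group: PolarGroup) -> list:
    """Ideal hydration sites for one polar group.

    Donors get one site collinear with each X-H bond, 1.9 A past the
    hydrogen.  sp2 acceptors get two in-plane lone-pair sites at +-120
    degrees from the base bond; sp3 acceptors get the two tetrahedral
    lone-pair directions; ring acceptors get the single in-plane
    external-bisector site.  Results are cached on the group.
    """
    cached = getattr(group, "_sites", None)
    if cached is not None:
        return cached
    sites: list[VirtualWaterSite] = []
    a = group.heavy_atom.coord
    if group.kind in ("donor", "both"):
        for h in group.hydrogens:
            d = unit(h.coord - a)
            sites.append(VirtualWaterSite(h.coord + _DONOR_SITE_EXT * d,
                                          group, f"donor_{h.name}"))
    if group.kind in ("acceptor", "both"):
        if group.hybridization == "sp2":
            base = group.base_atoms[0].coord
            e1 = unit(a - base)
            ref = group.plane_atom.coord if group.plane_atom is not None else None
            if ref is None:
                # arbitrary in-plane reference
                ref = base + np.array([1.0, 0.0, 0.0])
            v = ref - a
            e2 = v - np.dot(v, e1) * e1
            if np.linalg.norm(e2) < 1e-6:
                e2 = np.cross(e1, [0.0, 0.0, 1.0])
            e2 = unit(e2)
            for sign, lab in ((1.0, "sp2_plus"), (-1.0, "sp2_minus")):
                d = np.cos(np.radians(60.0)) * e1 + sign * np.sin(np.radians(60.0)) * e2
                sites.append(VirtualWaterSite(a + _ACCEPTOR_SITE_D * d, group, lab))
        elif group.hybridization == "sp3":
            u1 = unit(group.base_atoms[0].coord - a)
            u2 = unit(group.base_atoms[1].coord - a)
            n = unit(u1 + u2)
            m = np.cross(u1, u2)
            if np.linalg.norm(m) < 1e-6:
                m = np.cross(u1, [0.0, 0.0, 1.0])
            m = unit(m)
            cosb = np.clip(np.dot(n, u1), -1.0, 1.0)
            alpha = np.arccos(np.clip(-np.cos(np.radians(109.47)) / max(cosb, 1e-6),
                                      -1.0, 1.0))
            for sign, lab in ((1.0, "lp_plus"), (-1.0, "lp_minus")):
                d = unit(-np.cos(alpha) * n + sign * np.sin(alpha) * m)
                sites.append(VirtualWaterSite(a + _ACCEPTOR_SITE_D * d, group, lab))
        elif group.hybridization == "ring":
            b1, b2 = group.base_atoms[0].coord, group.base_atoms[1].coord
            d = -unit(unit(b1 - a) + unit(b2 - a))
            sites.append(VirtualWaterSite(a + _ACCEPTOR_SITE_D * d, group, "ring_lp"))
    group._sites = sites
    return sites


# ---------------------------------------------------------------------------
# Bridging-water and hydrogen-bond terms
# ---------------------------------------------------------------------------

def lk_bridge(group_i: PolarGroup, group_j: PolarGroup,
              p: BridgeParams | None = None, e_lk: float | None = None) -> float:
    """Bridging-water kernel energy between two polar groups.

    E = E_lk * G(max(min_site_pair_distance - D0_len, 0); S0_len)
      + E_lk * G(|b_i - b_j| - D0_angle; S0_angle)

    where the site-pair minimum runs over all ideal hydration sites of
    the two groups and b are the polar heavy atoms.  Symmetric in its
    arguments; zero when both kernels vanish.  `e_lk` may be supplied to
    decouple the kernel from the desolvation model (used in tests).
    """
    p = p or BridgeParams()
    si = ideal_water_sites(group_i)
    sj = ideal_water_sites(group_j)
    if not si or not sj:
        return 0.0
    if e_lk is None:
        e_lk = lk_iso(group_i, group_j)
    ci = np.array([s.coord for s in si])
    cj = np.array([s.coord for s in sj])
    dmin = float(np.min(np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)))
    term1 = g_kernel(max(dmin - p.D0_len, 0.0), p.S0_len)
    dbase = float(np.linalg.norm(group_i.heavy_atom.coord - group_j.heavy_atom.coord))
    term2 = g_kernel(dbase - p.D0_angle, p.S0_angle)
    return p.weight * e_lk * (term1 + term2)


def hbond_sp3_softmax(acceptor: PolarGroup, h_coord,
                      p: HBondParams | None = None) -> float:
    """Softmax angular potential for sp3 acceptors.

    E = M log sum_k exp(E_BAH(b_k, a, h)/M) over both atoms bound to the
    acceptor (for water: both hydrogens), giving a score close to the
    worse of the two angular wells and symmetric under base swap.
    """
    p = p or HBondParams()
    if acceptor.hybridization != "sp3":
        raise ValueError(f"softmax acceptor must be sp3, got {acceptor.hybridization}")
    if len(acceptor.base_atoms) != 2:
        raise ValueError("sp3 acceptor requires exactly 2 base atoms")
    bah = p.bah_water if acceptor.atom_class == "water_O" else p.bah_potential
    h_coord = np.asarray(h_coord, float)
    es = [bah(b.coord, acceptor.heavy_atom.coord, h_coord)
          for b in acceptor.base_atoms]
    return float(p.M * logsumexp(np.asarray(es) / p.M))


def _hbond_energy(donor: PolarGroup, acceptor: PolarGroup,
                  p: HBondParams) -> float:
    """Distance x AHD x BAH hydrogen-bond energy between two groups."""
    if not donor.hydrogens or acceptor.kind == "donor":
        return 0.0
    a = acceptor.heavy_atom.coord
    total = 0.0
    for h in donor.hydrogens:
        d_ha = float(np.linalg.norm(h.coord - a))
        if d_ha > p.ideal_ha + p.dist_width:
            continue
        fd = g_kernel(d_ha - p.ideal_ha, p.dist_width)
        if fd == 0.0:
            continue
        ahd = angle_deg(donor.heavy_atom.coord, h.coord, a)
        fa = max(0.0, -np.cos(np.radians(ahd))) ** 2
        if fa == 0.0:
            continue
        if acceptor.hybridization == "sp3" and len(acceptor.base_atoms) == 2:
            e_ang = hbond_sp3_softmax(acceptor, h.coord, p)
        elif acceptor.hybridization in ("sp2", "ring") and acceptor.base_atoms:
            bah = CosineBAH(theta0=120.0)
            es = [bah(b.coord, a, h.coord) for b in acceptor.base_atoms]
            e_ang = min(es)
        else:
            e_ang = -0.25  # bare acceptor fallback
        total += fd * fa * e_ang
    return total


# ---------------------------------------------------------------------------
# Partial charges (minimal polar set)
# ---------------------------------------------------------------------------

_CLASS_CHARGE = {
    "bb_N": -0.47, "bb_O": -0.51, "hydroxyl": -0.55, "hydroxyl_aro": -0.54,
    "carboxyl_O": -0.60, "cterm_O": -0.60, "amide_O": -0.55, "amide_N": -0.62,
    "amine_N": -0.30, "nterm_N": -0.30, "guanidinium_N": -0.60,
    "imidazole_ND": -0.55, "imidazole_NE": -0.45, "indole_N": -0.50,
    "water_O": -0.68,
}
_POLAR_H_CHARGE = 0.35
_CARBONYL_C_CHARGE = 0.51


def assign_charges(groups) -> dict:
    """Map id(atom) -> partial charge for polar atoms and their hydrogens."""
    q: dict[int, float] = {}
    for g in groups:
        q[id(g.heavy_atom)] = _CLASS_CHARGE.get(g.atom_class, -0.4)
        for h in g.hydrogens:
            q[id(h)] = 0.34 if g.atom_class == "water_O" else _POLAR_H_CHARGE
        if g.atom_class in ("bb_O", "amide_O", "carboxyl_O", "cterm_O"):
            for b in g.base_atoms:
                q.setdefault(id(b), _CARBONYL_C_CHARGE)
    return q


# ---------------------------------------------------------------------------
# Composite scoring
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    terms: dict = field(default_factory=dict)
    per_residue: dict = field(default_factory=dict)
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    @property
    def total(self) -> float:
        return float(sum(self.weights.get(t, 0.0) * v for t, v in self.terms.items()))

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        out = EnergyBreakdown(weights=dict(self.weights))
        for src in (self, other):
            for t, v in src.terms.items():
                out.terms[t] = out.terms.get(t, 0.0) + v
            for r, v in src.per_residue.items():
                out.per_residue[r] = out.per_residue.get(r, 0.0) + v
        return out


@dataclass
class Entity:
    """A rigid scored unit: the atoms and polar groups of one residue
    (or one water, or one side-chain rotamer)."""

    key: tuple
    atoms: list
    groups: list
    is_water: bool = False
    chain: str = ""
    seqnum: int = 0

    @property
    def centroid(self):
        return np.mean([a.coord for a in self.atoms], axis=0)


# adjacent-residue atom pairs excluded from nonbonded terms (1-2 / 1-3)
_ADJ_EXCLUDE = {("C", "N"), ("C", "CA"), ("C", "H"), ("C", "CD"),
                ("O", "N"), ("CA", "N")}


class EnergyModel:
    """Pairwise energy model over residue-level entities."""

    def __init__(self, weights=None, bridge: BridgeParams | None = None,
                 hbond: HBondParams | None = None, lk_params=None):
        self.weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
        self.bridge = bridge or BridgeParams()
        self.hbond = hbond or HBondParams()
        self.lk_params = lk_params or LK_PARAMS

    # -- entity construction ------------------------------------------
    def entities(self, s: Structure) -> list:
        groups = extract_polar_groups(s)
        by_res: dict[tuple, list] = {}
        for g in groups:
            by_res.setdefault(g.residue_id, []).append(g)
        out = []
        for r in s.residues:
            out.append(Entity(key=r.residue_id, atoms=list(r.atoms.values()),
                              groups=by_res.get(r.residue_id, []),
                              is_water=r.is_water, chain=r.chain,
                              seqnum=r.seqnum))
        return out

    # -- pair terms ----------------------------------------------------
    def pair_terms(self, ea: Entity, eb: Entity, charges=None,
                   adjacent: bool | None = None) -> dict:
        if adjacent is None:
            adjacent = (not ea.is_water and not eb.is_water
                        and ea.chain == eb.chain
                        and abs(ea.seqnum - eb.seqnum) == 1)
        terms = {t: 0.0 for t in ("lj", "elec", "lk_iso", "lk_ball",
                                  "lk_bridge", "hbond")}
        # explicit waters are solvent: they do not desolvate anything,
        # so all LK-family terms are restricted to solute/solute pairs
        has_water = ea.is_water or eb.is_water
        first_later = ea.seqnum <= eb.seqnum
        for ai in ea.atoms:
            for aj in eb.atoms:
                if adjacent:
                    pair = (ai.name, aj.name) if first_later else (aj.name, ai.name)
                    if pair in _ADJ_EXCLUDE:
                        continue
                r = float(np.linalg.norm(ai.coord - aj.coord))
                if r > PAIR_CUTOFF or r < 1e-9:
                    continue
                ri = LJ_RADII.get(ai.element, 1.8)
                rj = LJ_RADII.get(aj.element, 1.8)
                sr6 = ((ri + rj) * 0.89 / r) ** 6
                terms["lj"] += min(LJ_CAP, LJ_EPS * (sr6 * sr6 - 2.0 * sr6))
                if charges is not None:
                    qi = charges.get(id(ai), 0.0)
                    qj = charges.get(id(aj), 0.0)
                    if qi and qj:
                        terms["elec"] += COULOMB * qi * qj / (4.0 * r * r)
                if not has_water and not ai.is_hydrogen and not aj.is_hydrogen:
                    try:
                        terms["lk_iso"] += lk_pair(ai.element, aj.element, r,
                                                   self.lk_params)
                    except KeyError:
                        pass
        # anisotropic attenuation: occluding an ideal water site of a
        # polar group costs extra
        for ga, other in (() if has_water else ((ea, eb), (eb, ea))):
            for g in ga.groups:
                sites = ideal_water_sites(g)
                if not sites:
                    continue
                sc = np.array([s.coord for s in sites])
                for aj in other.atoms:
                    if aj.is_hydrogen:
                        continue
                    r = float(np.linalg.norm(g.heavy_atom.coord - aj.coord))
                    if r > PAIR_CUTOFF or r < 1e-9:
                        continue
                    dsite = float(np.min(np.linalg.norm(sc - aj.coord, axis=1)))
                    w = g_kernel(dsite, 2.6)
                    if w > 0.0:
                        try:
                            terms["lk_ball"] += w * lk_pair(
                                g.heavy_atom.element, aj.element, r, self.lk_params)
                        except KeyError:
                            pass
        for gi in ea.groups:
            for gj in eb.groups:
                if not has_water:
                    d = float(np.linalg.norm(gi.heavy_atom.coord
                                             - gj.heavy_atom.coord))
                    if d < self.bridge.D0_angle + self.bridge.S0_angle + 2.0:
                        terms["lk_bridge"] += lk_bridge(gi, gj, self.bridge)
                terms["hbond"] += _hbond_energy(gi, gj, self.hbond)
                terms["hbond"] += _hbond_energy(gj, gi, self.hbond)
        return terms

    def pair_energy(self, ea: Entity, eb: Entity, charges=None,
                    adjacent: bool | None = None) -> float:
        t = self.pair_terms(ea, eb, charges=charges, adjacent=adjacent)
        return float(sum(self.weights.get(k, 0.0) * v for k, v in t.items()))

    # -- whole-structure scoring --------------------------------------
    def score_total(self, s: Structure) -> EnergyBreakdown:
        """Sum all pairwise terms within cutoffs; per-residue halves."""
        ents = self.entities(s)
        bd = EnergyBreakdown(weights=dict(self.weights))
        bd.terms = {t: 0.0 for t in ("lj", "elec", "lk_iso", "lk_ball",
                                     "lk_bridge", "hbond")}
        if not ents:
            return bd
        charges = assign_charges([g for e in ents for g in e.groups])
        cent = np.array([e.centroid for e in ents])
        tree = cKDTree(cent)
        reach = 14.0
        for i, j in sorted(tree.query_pairs(reach)):
            terms = self.pair_terms(ents[i], ents[j], charges=charges)
            w = sum(self.weights.get(k, 0.0) * v for k, v in terms.items())
            for k, v in terms.items():
                bd.terms[k] += v
            for e in (ents[i], ents[j]):
                bd.per_residue[e.key] = bd.per_residue.get(e.key, 0.0) + 0.5 * w
        return bd


def score_total(s: Structure, weights=None, model: EnergyModel | None = None):
    """Convenience wrapper: score a structure with default parameters."""
    model = model or EnergyModel(weights=weights)
    return model.score_total(s)
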