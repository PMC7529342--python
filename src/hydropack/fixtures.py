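"""Deterministic synthetic fixtures and exhaustive oracles.

Everything here is generated programmatically from seeds -- no binary
or checked-in coordinate data.  The fixtures serve two purposes: they
feed the default statistical tables (:func:`sample_water_observations`,
:func:`sample_reference_observations`), and they provide small systems
with exactly known answers for the test suite (an idealized
bridged-water dimer, rigid-body decoy sets with exact RMSD labels, and
a brute-force enumeration oracle for the discrete packing problems).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .builder import build_peptide
from .energy import ideal_water_sites
from .geometry import rotation_about_axis, rotation_align, unit
from .structure import Structure, build_polar_hydrogens, extract_polar_groups

log = logging.getLogger(__name__)

D_RANGE = (2.0, 3.6)     # A, sampled water/polar distance support
THETA_RANGE = (0.0, 180.0)


# ---------------------------------------------------------------------------
# Observation generators for statistical-table fitting
# ---------------------------------------------------------------------------

def sample_water_observations(mode, spread, n: int, seed: int,
                              shell_weighting: bool = True) -> np.ndarray:
    """Draw n (distance, theta) observations around an ideal geometry.

    `mode` = (d0, theta0), `spread` = (sd_d, sd_theta).  With
    `shell_weighting` the samples are reweighted by the geometric phase
    space d^2 sin(theta), so that after the shell normalization applied
    during table fitting the recovered density peaks at the mode.  With
    shell_weighting=False the samples are plain truncated Gaussians
    (sample mean -> mode as n grows).  Deterministic given the seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    d0, t0 = mode
    sd, st = spread
    if sd <= 0 or st <= 0:
        raise ValueError("spreads must be positive")
    rng = np.random.default_rng(seed)
    w_max = D_RANGE[1] ** 2
    out_d: list[np.ndarray] = []
    out_t: list[np.ndarray] = []
    have = 0
    while have < n:
        m = max(4 * (n - have), 1000)
        d = rng.normal(d0, sd, m)
        t = rng.normal(t0, st, m)
        ok = ((d >= D_RANGE[0]) & (d < D_RANGE[1])
              & (t >= THETA_RANGE[0]) & (t <= THETA_RANGE[1]))
        d, t = d[ok], t[ok]
        if shell_weighting and len(d):
            w = d * d * np.maximum(np.sin(np.radians(t)), 0.0) / w_max
            keep = rng.random(len(d)) < w
            d, t = d[keep], t[keep]
        out_d.append(d)
        out_t.append(t)
        have += len(d)
    d = np.concatenate(out_d)[:n]
    t = np.concatenate(out_t)[:n]
    return np.column_stack([d, t])


def sample_reference_observations(n: int, seed: int) -> np.ndarray:
    """Shell-uniform nonpolar reference: d ~ d^2 on [2.0, 3.6),
    theta ~ sin(theta) on [0, 180], via inverse-CDF sampling."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    lo3, hi3 = D_RANGE[0] ** 3, D_RANGE[1] ** 3
    d = np.cbrt(lo3 + (hi3 - lo3) * rng.random(n))
    theta = np.degrees(np.arccos(1.0 - 2.0 * rng.random(n)))
    return np.column_stack([d, theta])


# ---------------------------------------------------------------------------
# Bridged-water dimer
# ---------------------------------------------------------------------------

@dataclass
class BridgedDimerFixture:
    """Two peptides whose ideal hydration sites coincide at one point.

    `water_site` is the shared ideal-water position; `acceptor_id` and
    `donor_id` are (residue_id, atom_name) of the bridged polar atoms.
    """

    structure: Structure
    water_site: np.ndarray
    acceptor_id: tuple
    donor_id: tuple


_WATER_APPROACH = 104.52  # deg, angle at the bridging water


def make_bridged_dimer(jitter: float = 0.0, seed: int = 0,
                       min_clearance: float = 2.4) -> BridgedDimerFixture:
    """Build an idealized bridged-water dimer.

    Peptide A donates a backbone carbonyl sp2 acceptor site; peptide B
    is rigidly placed so that the site of its central amide N-H donor
    coincides with that acceptor site, with the two approach directions
    at the water angle (104.5 deg).  At jitter=0 both bridging kernels
    of the implicit term evaluate above 0.9.  `jitter` (A) adds a
    Gaussian rigid displacement to peptide B.  Raises ValueError when
    no clash-free placement exists.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    pep_a = build_polar_hydrogens(build_peptide(["ALA", "ALA", "ALA"],
                                                chain="A"))
    acc = next(g for g in extract_polar_groups(pep_a)
               if g.atom_class == "bb_O" and g.residue_id[1] == 2)
    w_star = ideal_water_sites(acc)[0].coord
    u_a = unit(acc.heavy_atom.coord - w_star)  # water -> acceptor O

    pep_b0 = build_polar_hydrogens(build_peptide(["ALA", "ALA", "ALA"],
                                                 chain="B"))
    don = next(g for g in extract_polar_groups(pep_b0)
               if g.atom_class == "bb_N" and g.residue_id[1] == 2)
    h = don.hydrogens[0]
    s_b = ideal_water_sites(don)[0].coord
    v_b = unit(don.heavy_atom.coord - s_b)  # donor site -> donor N

    heavy_a = np.array([a.coord for a in pep_a.heavy_atoms()])
    # any perpendicular completes the water-angle construction; the spin
    # about u_a and about the final approach axis are free -- search both
    # for the most clash-free placement
    perp = np.cross(u_a, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u_a, [0.0, 1.0, 0.0])
    perp = unit(perp)
    cosw = np.cos(np.radians(_WATER_APPROACH))
    sinw = np.sin(np.radians(_WATER_APPROACH))
    best, best_clear = None, -np.inf
    for az in range(0, 360, 30):
        e2 = rotation_about_axis(u_a, float(az)) @ perp
        u_b = cosw * u_a + sinw * e2  # water -> donor N direction
        R1 = rotation_align(v_b, u_b)
        for spin in range(0, 360, 30):
            R = rotation_about_axis(u_b, float(spin)) @ R1
            t = w_star - R @ s_b
            moved = pep_b0.transform(R, t)
            hb = np.array([a.coord for a in moved.heavy_atoms()])
            d = np.linalg.norm(heavy_a[:, None, :] - hb[None, :, :], axis=2)
            clear = float(d.min())
            if clear > best_clear:
                best_clear, best = clear, moved
    if best is None or best_clear < min_clearance:
        raise ValueError(
            f"no clash-free bridged placement (best clearance "
            f"{best_clear:.2f} A < {min_clearance} A)")
    if jitter > 0:
        best = best.transform(np.eye(3), rng.normal(0.0, jitter, 3))
    don_moved = next(g for g in extract_polar_groups(best)
                     if g.atom_class == "bb_N" and g.residue_id[1] == 2)
    base_d = float(np.linalg.norm(acc.heavy_atom.coord
                                  - don_moved.heavy_atom.coord))
    if base_d > 12.0:
        raise ValueError(f"bridged groups ended {base_d:.1f} A apart")
    residues = [r.copy() for r in pep_a.residues] + \
               [r.copy() for r in best.residues]
    return BridgedDimerFixture(
        structure=Structure(residues),
        water_site=np.asarray(w_star, float),
        acceptor_id=(acc.residue_id, acc.heavy_atom.name),
        donor_id=(don_moved.residue_id, don_moved.heavy_atom.name))


# ---------------------------------------------------------------------------
# Brute-force packing oracle
# ---------------------------------------------------------------------------

def brute_force_pack_oracle(problem, RT: float | None = None,
                            max_states: int = 1_000_000) -> dict:
    """Exhaustive enumeration of a :class:`~.packer.PackingProblem`.

    Returns the exact global minimum and, when `RT` is given, the exact
    Boltzmann marginal occupancy of every state of every position.
    Guards against state spaces above `max_states`.
    """
    n_states = [p.n_states for p in problem.positions]
    total = 1
    for k in n_states:
        total *= k
        if total > max_states:
            raise ValueError(f"state space exceeds {max_states}")
    if not n_states:
        return {"best_assignment": [], "best_energy": 0.0, "marginals": []}
    best_e, best_a = np.inf, None
    e_min = np.inf
    for assign in itertools.product(*(range(k) for k in n_states)):
        e = problem.energy(assign)
        if e < best_e:
            best_e, best_a = e, list(assign)
        e_min = min(e_min, e)
    out = {"best_assignment": best_a, "best_energy": float(best_e)}
    if RT is not None:
        if RT <= 0:
            raise ValueError("RT must be positive")
        marg = [np.zeros(k) for k in n_states]
        z = 0.0
        for assign in itertools.product(*(range(k) for k in n_states)):
            w = np.exp(-(problem.energy(assign) - e_min) / RT)
            z += w
            for p, s in enumerate(assign):
                marg[p][s] += w
        out["marginals"] = [m / z for m in marg]
    return out


# ---------------------------------------------------------------------------
# Decoy sets
# ---------------------------------------------------------------------------

def _moving_rmsd(ref: Structure, moved: Structure, chains) -> float:
    """Exact RMSD over the moved chains: CA atoms when present,
    otherwise all heavy atoms (ligand case)."""
    ra, ma = [], []
    for rr, mr in zip(ref.residues, moved.residues):
        if rr.chain not in chains:
            continue
        ca_r, ca_m = rr.get("CA"), mr.get("CA")
        if ca_r is not None and ca_m is not None:
            ra.append(ca_r.coord)
            ma.append(ca_m.coord)
    if not ra:  # no CA atoms: heavy-atom RMSD
        for rr, mr in zip(ref.residues, moved.residues):
            if rr.chain not in chains:
                continue
            for name, a in rr.atoms.items():
                b = mr.get(name)
                if b is not None and not a.is_hydrogen:
                    ra.append(a.coord)
                    ma.append(b.coord)
    if not ra:
        raise ValueError(f"no atoms found in moving chains {chains}")
    d = np.asarray(ra) - np.asarray(ma)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def make_decoy_set(s: Structure, moving_chains, n: int = 10, seed: int = 0,
                   max_rot: float = 10.0, max_trans: float = 5.0,
                   min_clearance: float = 1.8,
                   near_native_rmsd: float = 2.0) -> list:
    """Rigid-body decoys of the `moving_chains` partner with exact RMSD.

    Returns a list of (structure, rmsd) including at least one
    near-native pose (the first decoys use small perturbations).
    Perturbation magnitude ramps linearly across the set; candidates
    that drive the partners into steric overlap are re-drawn.
    """
    if n < 2:
        raise ValueError("need at least 2 decoys")
    moving_chains = tuple(moving_chains)
    rng = np.random.default_rng(seed)
    fixed_heavy = np.array([a.coord for r in s.residues
                            if r.chain not in moving_chains
                            for a in r.atoms.values() if not a.is_hydrogen])
    if fixed_heavy.size == 0:
        raise ValueError("no fixed partner atoms")
    mov_res = [r for r in s.residues if r.chain in moving_chains]
    if not mov_res:
        raise ValueError(f"no residues in moving chains {moving_chains}")
    center = np.mean([a.coord for r in mov_res
                      for a in r.atoms.values() if not a.is_hydrogen], axis=0)
    decoys = []
    for i in range(n):
        scale = (i / (n - 1)) if n > 1 else 0.0
        for _attempt in range(50):
            axis = rng.normal(size=3)
            R = rotation_about_axis(axis, scale * max_rot * rng.random())
            t_dir = rng.normal(size=3)
            t_dir = t_dir / max(np.linalg.norm(t_dir), 1e-9)
            t = scale * max_trans * rng.random() * t_dir
            moved = s.copy()
            for r in moved.residues:
                if r.chain in moving_chains:
                    for a in r.atoms.values():
                        a.coord = R @ (a.coord - center) + center + t
            mh = np.array([a.coord for r in moved.residues
                           if r.chain in moving_chains
                           for a in r.atoms.values() if not a.is_hydrogen])
            dmin = float(np.min(np.linalg.norm(
                fixed_heavy[:, None, :] - mh[None, :, :], axis=2)))
            if dmin >= min_clearance:
                decoys.append((moved, _moving_rmsd(s, moved, moving_chains)))
                break
        else:
            raise ValueError("could not generate a clash-free decoy")
    if not any(r <= near_native_rmsd for _, r in decoys):
        raise ValueError("decoy set contains no near-native pose")
    return decoys
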