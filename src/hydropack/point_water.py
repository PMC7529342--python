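"""The low-resolution statistical "point water" potential.

A candidate water is a bare oxygen position w.  Its energy is

    E_i = sum_j -log P(d_ij, theta_ij)
          - K * sum_{k != i} exp(-(|w_i - w_k| - d_ww)^2 / sigma^2)
          + E_pwat_bulk

where j runs over polar protein atoms in range, d is the water/polar
distance, theta the water-polaratom-base angle, and the Gaussian term
rewards water-water contacts at the crystallographic optimum
d_ww = 2.7 A.  Defaults: K = 0.52 kcal/mol, sigma = 0.24 A,
E_pwat_bulk = 2.71 kcal/mol (the cost of bringing a water out of bulk).

The -log P tables are probability-ratio statistics per polar atom
class against a nonpolar reference.  The package ships the fitting
machinery plus a compact default table set fit from synthetic idealized
hydrogen-bond geometry (the published tables were derived from a large
crystallographic survey and are not restated anywhere reusable); users
can load their own tables from TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import angle_deg

log = logging.getLogger(__name__)


@dataclass
class PointWaterParams:
    K: float = 0.52          # kcal/mol, water-water Gaussian height
    sigma: float = 0.24      # A, water-water Gaussian width
    d_ww: float = 2.7        # A, water-water optimum separation
    E_pwat_bulk: float = 2.71  # kcal/mol, out-of-bulk cost per water

    def __post_init__(self):
        if self.K < 0 or self.sigma <= 0:
            raise ValueError("K must be >= 0 and sigma > 0")


@dataclass
class StatTable:
    """Binned -log(P_class / P_reference) over (distance, angle)."""

    atom_class: str
    d_bins: np.ndarray      # edges, strictly increasing, A
    theta_bins: np.ndarray  # edges, strictly increasing, degrees
    neg_log_ratio: np.ndarray  # (n_d, n_theta)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.d_bins = np.asarray(self.d_bins, float)
        self.theta_bins = np.asarray(self.theta_bins, float)
        self.neg_log_ratio = np.asarray(self.neg_log_ratio, float)
        if not (np.all(np.diff(self.d_bins) > 0)
                and np.all(np.diff(self.theta_bins) > 0)):
            raise ValueError("bin edges must be strictly increasing")
        if not np.all(np.isfinite(self.neg_log_ratio)):
            raise ValueError("table values must be finite")

    def lookup(self, d: float, theta: float) -> float:
        """Table value at (d, theta); 0 outside the distance range
        (beyond the second-solvation-shell ceiling the statistical term
        does not apply)."""
        if d < self.d_bins[0] or d >= self.d_bins[-1]:
            return 0.0
        i = int(np.searchsorted(self.d_bins, d, side="right")) - 1
        theta = float(np.clip(theta, self.theta_bins[0],
                              self.theta_bins[-1] - 1e-9))
        j = int(np.searchsorted(self.theta_bins, theta, side="right")) - 1
        return float(self.neg_log_ratio[i, j])

    def argmin_bin(self):
        i, j = np.unravel_index(int(np.argmin(self.neg_log_ratio)),
                                self.neg_log_ratio.shape)
        d_mid = 0.5 * (self.d_bins[i] + self.d_bins[i + 1])
        t_mid = 0.5 * (self.theta_bins[j] + self.theta_bins[j + 1])
        return (i, j), (float(d_mid), float(t_mid))


DEFAULT_D_BINS = np.arange(2.0, 3.6001, 0.1)
DEFAULT_THETA_BINS = np.arange(0.0, 180.0001, 5.0)
DEFAULT_CLAMP = 3.0


def _shell_weights(d_bins, theta_bins):
    """Geometric phase-space weight of each (d, theta) bin: shell volume
    element d^2 sin(theta)."""
    d_mid = 0.5 * (d_bins[:-1] + d_bins[1:])
    t_mid = np.radians(0.5 * (theta_bins[:-1] + theta_bins[1:]))
    w = np.outer(d_mid ** 2, np.sin(t_mid))
    return np.maximum(w, 1e-9)


def fit_stat_tables(observations, reference_observations,
                    d_bins=DEFAULT_D_BINS, theta_bins=DEFAULT_THETA_BINS,
                    pseudocount: float = 1.0, clamp: float = DEFAULT_CLAMP,
                    min_observations: int = 500) -> dict:
    """Fit -log probability-ratio tables from observations.

    observations: iterable of (atom_class, d, theta); the reference is a
    list of (d, theta) around a nonpolar probe.  Counts get additive
    pseudocounts and a distance-shell (d^2 sin theta) normalization;
    values are clamped to +-`clamp`.  Classes below `min_observations`
    are skipped with a warning.  Deterministic given its inputs.

    Because the nonpolar reference probe is isotropic, its distance and
    angle are independent; the reference density is therefore estimated
    as the product of its two marginal histograms, which has far lower
    per-bin variance than a joint 2-D histogram of the same sample.
    """
    d_bins = np.asarray(d_bins, float)
    theta_bins = np.asarray(theta_bins, float)
    shell = _shell_weights(d_bins, theta_bins)

    ref = np.asarray(list(reference_observations), float)
    if len(ref) < min_observations:
        raise ValueError("reference observation set below the minimum floor")
    h_d, _ = np.histogram(ref[:, 0], bins=d_bins)
    h_t, _ = np.histogram(ref[:, 1], bins=theta_bins)
    p_ref = np.outer(h_d + pseudocount, h_t + pseudocount) / shell
    p_ref = p_ref / p_ref.sum()

    by_class: dict[str, list] = {}
    for cls, d, th in observations:
        by_class.setdefault(cls, []).append((d, th))
    out = {}
    for cls, obs in sorted(by_class.items()):
        if len(obs) < min_observations:
            log.warning("class %s has %d observations (< %d); skipped",
                        cls, len(obs), min_observations)
            continue
        arr = np.asarray(obs, float)
        h, _, _ = np.histogram2d(arr[:, 0], arr[:, 1], bins=(d_bins, theta_bins))
        p = (h + pseudocount) / shell
        p = p / p.sum()
        nlr = np.clip(-(np.log(p) - np.log(p_ref)), -clamp, clamp)
        out[cls] = StatTable(cls, d_bins, theta_bins, nlr,
                             meta={"n_obs": len(obs), "clamp": clamp,
                                   "pseudocount": pseudocount})
    return out


# ---------------------------------------------------------------------------
# Energy evaluation
# ---------------------------------------------------------------------------

def water_water_term(d: float, p: PointWaterParams) -> float:
    """Per-site Gaussian water-water reward, minimized at d_ww."""
    return -p.K * float(np.exp(-((d - p.d_ww) ** 2) / (p.sigma ** 2)))


def polar_term(coord, groups, tables) -> float:
    """Sum of -log P(d, theta) over polar groups within table range."""
    coord = np.asarray(coord, float)
    total = 0.0
    for g in groups:
        tab = tables.get(g.atom_class)
        if tab is None:
            continue
        x = g.heavy_atom.coord
        d = float(np.linalg.norm(coord - x))
        if d < tab.d_bins[0] or d >= tab.d_bins[-1]:
            continue
        if not g.base_atoms:
            continue
        theta = angle_deg(coord, x, g.base_atoms[0].coord)
        total += tab.lookup(d, theta)
    return total


def point_water_energy(site_index: int, W, groups, tables,
                       p: PointWaterParams | None = None) -> float:
    """Energy of active point water `site_index` within the active set W.

    W is a sequence of oxygen coordinates; `groups` the polar groups of
    the biomolecule; `tables` maps atom_class -> StatTable.  An isolated
    site with nothing in range scores exactly E_pwat_bulk.
    """
    p = p or PointWaterParams()
    W = [np.asarray(w, float) for w in W]
    w = W[site_index]
    e = polar_term(w, groups, tables) + p.E_pwat_bulk
    for k, wk in enumerate(W):
        if k == site_index:
            continue
        e += water_water_term(float(np.linalg.norm(w - wk)), p)
    return float(e)


# ---------------------------------------------------------------------------
# Default synthetic tables
# ---------------------------------------------------------------------------

# per-class idealized hydration geometry: (d*, theta*) of the mode.
# theta is measured water-polaratom-base; sp2/ring lone pairs sit near
# 120 degrees, tetrahedral geometry near 109.5, amide donors near 119.
_CLASS_MODES = {
    "bb_N": (2.9, 119.0), "bb_O": (2.8, 120.0),
    "hydroxyl": (2.8, 109.5), "hydroxyl_aro": (2.8, 120.0),
    "carboxyl_O": (2.8, 120.0), "cterm_O": (2.8, 120.0),
    "amide_O": (2.8, 120.0), "amide_N": (2.9, 119.0),
    "amine_N": (2.9, 109.5), "nterm_N": (2.9, 109.5),
    "guanidinium_N": (2.9, 119.0), "imidazole_ND": (2.8, 126.0),
    "imidazole_NE": (2.9, 126.0), "indole_N": (2.9, 126.0),
    "water_O": (2.8, 109.5),
}

_DEFAULT_TABLES_CACHE: dict | None = None


def default_tables(seed: int = 20240901, n_per_class: int = 20000) -> dict:
    """Compact default table set fit from synthetic idealized geometry.

    Each polar class gets observations drawn around its ideal
    hydrogen-bond mode; the nonpolar reference is shell-uniform.
    Deterministic (fixed seed) and cached per process.
    """
    global _DEFAULT_TABLES_CACHE
    if _DEFAULT_TABLES_CACHE is not None and seed == 20240901:
        return _DEFAULT_TABLES_CACHE
    from .fixtures import sample_water_observations, sample_reference_observations

    obs = []
    for i, (cls, (d0, t0)) in enumerate(sorted(_CLASS_MODES.items())):
        samples = sample_water_observations(
            mode=(d0, t0), spread=(0.18, 14.0), n=n_per_class,
            seed=seed + i, shell_weighting=True)
        obs.extend((cls, d, th) for d, th in samples)
    ref = sample_reference_observations(n=200000, seed=seed + 999)
    tables = fit_stat_tables(obs, ref)
    if seed == 20240901:
        _DEFAULT_TABLES_CACHE = tables
    return tables


# ---------------------------------------------------------------------------
# Serialization: TSV body with a JSON header line
# ---------------------------------------------------------------------------

def save_tables(tables: dict, path):
    with open(path, "w") as fh:
        meta = {cls: {"d_bins": t.d_bins.tolist(),
                      "theta_bins": t.theta_bins.tolist(),
                      "meta": t.meta}
                for cls, t in tables.items()}
        fh.write("#" + json.dumps(meta) + "\n")
        fh.write("class\td_lo\td_hi\ttheta_lo\ttheta_hi\tvalue\n")
        for cls, t in sorted(tables.items()):
            for i in range(len(t.d_bins) - 1):
                for j in range(len(t.theta_bins) - 1):
                    fh.write(f"{cls}\t{t.d_bins[i]:.4f}\t{t.d_bins[i+1]:.4f}\t"
                             f"{t.theta_bins[j]:.4f}\t{t.theta_bins[j+1]:.4f}\t"
                             f"{t.neg_log_ratio[i, j]:.6f}\n")


def load_tables(path) -> dict:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing JSON header line")
        meta = json.loads(header[1:])
        fh.readline()  # column names
        values: dict[str, dict] = {c: {} for c in meta}
        for line in fh:
            cls, dlo, dhi, tlo, thi, val = line.rstrip("\n").split("\t")
            values[cls][(float(dlo), float(tlo))] = float(val)
    out = {}
    for cls, m in meta.items():
        d_bins = np.asarray(m["d_bins"])
        t_bins = np.asarray(m["theta_bins"])
        mat = np.zeros((len(d_bins) - 1, len(t_bins) - 1))
        for i in range(mat.shape[0]):
            for j in range(mat.shape[1]):
                mat[i, j] = values[cls][(round(float(d_bins[i]), 4),
                                         round(float(t_bins[j]), 4))]
        out[cls] = StatTable(cls, d_bins, t_bins, mat, meta=m.get("meta", {}))
    return out
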