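import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydropack.builder import build_peptide, make_water
from hydropack.energy import (DEFAULT_WEIGHTS, BridgeParams, EnergyModel,
                              HBondParams, assign_charges, g_kernel,
                              hbond_sp3_softmax, ideal_water_sites, lk_bridge,
                              lk_iso, lk_pair, score_total)
from hydropack.geometry import angle_deg
from hydropack.structure import (Structure, build_polar_hydrogens,
                                 extract_polar_groups)


# ---------------------------------------------------------------------------
# g kernel
# ---------------------------------------------------------------------------

def test_g_kernel_shape():
    assert g_kernel(0.0, 1.61) == 1.0
    assert g_kernel(1.61, 1.61) == 0.0
    assert g_kernel(-5.0, 1.61) == 0.0
    # continuous at the support boundary
    assert g_kernel(1.61 - 1e-7, 1.61) < 1e-10
    with pytest.raises(ValueError):
        g_kernel(0.5, 0.0)


@settings(max_examples=50, derandomize=True)
@given(x=st.floats(-10, 10), s0=st.floats(0.1, 5.0))
def test_g_kernel_properties(x, s0):
    v = g_kernel(x, s0)
    assert 0.0 <= v <= 1.0
    assert v == g_kernel(-x, s0)          # even
    if abs(x) >= s0:
        assert v == 0.0


# ---------------------------------------------------------------------------
# LK pair desolvation
# ---------------------------------------------------------------------------

def test_lk_pair_basics():
    e = lk_pair("O", "N", 3.0)
    assert e == lk_pair("N", "O", 3.0)            # symmetric
    assert e > 0.0                                # polar pair: desolvation
    assert lk_pair("O", "O", 7.0) == 0.0          # beyond cutoff
    with pytest.raises(KeyError):
        lk_pair("O", "Xx", 3.0)


def test_lk_pair_decays():
    es = [lk_pair("O", "O", r) for r in (3.2, 4.0, 5.0, 5.9)]
    assert all(a > b for a, b in zip(es, es[1:]))


# ---------------------------------------------------------------------------
# Ideal hydration sites
# ---------------------------------------------------------------------------

def test_ideal_sites_geometry(tripeptide):
    groups = {g.atom_class: g for g in extract_polar_groups(tripeptide)}
    # donor: collinear with N-H, 1.9 A beyond the hydrogen
    bbn = groups["bb_N"]
    site = ideal_water_sites(bbn)[0]
    h = bbn.hydrogens[0]
    assert np.linalg.norm(site.coord - h.coord) == pytest.approx(1.9, abs=1e-9)
    assert angle_deg(bbn.heavy_atom.coord, h.coord,
                     site.coord) == pytest.approx(180.0, abs=1e-6)
    # sp2 acceptor: two in-plane lone pairs, base-acceptor-site at 120 deg
    bbo = groups["bb_O"]
    sites = [s for s in ideal_water_sites(bbo) if s.geometry_label.startswith("sp2")]
    assert len(sites) == 2
    for s in sites:
        assert np.linalg.norm(s.coord - bbo.heavy_atom.coord) == \
            pytest.approx(2.8, abs=1e-9)
        assert angle_deg(bbo.base_atoms[0].coord, bbo.heavy_atom.coord,
                         s.coord) == pytest.approx(120.0, abs=1e-6)


def test_water_sp3_sites_tetrahedral():
    w = make_water(np.zeros(3), np.eye(3))
    s = Structure([build_peptide(["ALA"]).residues[0], w])
    wg = next(g for g in extract_polar_groups(s) if g.atom_class == "water_O")
    lps = [x for x in ideal_water_sites(wg) if x.geometry_label.startswith("lp")]
    assert len(lps) == 2
    for lp in lps:
        for h in wg.hydrogens:
            ang = angle_deg(h.coord, wg.heavy_atom.coord, lp.coord)
            assert ang == pytest.approx(109.47, abs=1.0)


# ---------------------------------------------------------------------------
# Bridging term
# ---------------------------------------------------------------------------

def _dimer_groups(fx):
    groups = extract_polar_groups(fx.structure)
    acc = next(g for g in groups
               if (g.residue_id, g.heavy_atom.name) == fx.acceptor_id)
    don = next(g for g in groups
               if (g.residue_id, g.heavy_atom.name) == fx.donor_id)
    return acc, don


def test_lk_bridge_ideal_dimer(bridged_dimer):
    """On the planted geometry both kernels are ~1 so the bridge term
    approaches 2 x E_lk; with E_lk = -1 it is about -2."""
    acc, don = _dimer_groups(bridged_dimer)
    e = lk_bridge(acc, don, BridgeParams(), e_lk=-1.0)
    assert e == pytest.approx(-2.0, abs=0.01)
    assert e == lk_bridge(don, acc, BridgeParams(), e_lk=-1.0)  # symmetric


def test_lk_bridge_vanishes_far_apart():
    a = build_polar_hydrogens(build_peptide(["ALA", "ALA"], chain="A"))
    b = build_polar_hydrogens(build_peptide(["ALA", "ALA"], chain="B"))
    b = b.transform(np.eye(3), np.array([25.0, 0.0, 0.0]))
    ga = next(g for g in extract_polar_groups(a) if g.atom_class == "bb_O")
    gb = next(g for g in extract_polar_groups(b) if g.atom_class == "bb_N")
    assert lk_bridge(ga, gb) == 0.0


def test_lk_bridge_contribution_is_negative(bridged_dimer):
    """The weighted bridge contribution refunds pair desolvation: the
    raw term is positive (like lk_iso) and its score weight flips it."""
    acc, don = _dimer_groups(bridged_dimer)
    raw = lk_bridge(acc, don)
    assert raw > 0.0
    assert lk_iso(acc, don) > 0.0
    assert DEFAULT_WEIGHTS["lk_bridge"] * raw < 0.0


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def test_sp3_softmax_requires_sp3(tripeptide):
    bbo = next(g for g in extract_polar_groups(tripeptide)
               if g.atom_class == "bb_O")
    with pytest.raises(ValueError, match="sp3"):
        hbond_sp3_softmax(bbo, np.zeros(3))


def test_sp3_softmax_water_swap_symmetry():
    w = make_water(np.array([1.0, 2.0, -0.5]),
                   np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], float))
    s = Structure([build_peptide(["ALA"]).residues[0], w])
    wg = next(g for g in extract_polar_groups(s) if g.atom_class == "water_O")
    h_probe = wg.heavy_atom.coord + np.array([0.0, 0.0, 1.9])
    e1 = hbond_sp3_softmax(wg, h_probe)
    wg.base_atoms = wg.base_atoms[::-1]
    assert hbond_sp3_softmax(wg, h_probe) == e1
    assert np.isfinite(e1)


def test_hbond_softmax_near_worse_well():
    """The softmax with small M tracks the worse (higher) of the wells."""
    w = make_water(np.zeros(3), np.eye(3))
    s = Structure([build_peptide(["ALA"]).residues[0], w])
    wg = next(g for g in extract_polar_groups(s) if g.atom_class == "water_O")
    h_probe = np.array([0.0, 0.0, -1.9])
    p = HBondParams()
    es = [p.bah_water(b.coord, wg.heavy_atom.coord, h_probe)
          for b in wg.base_atoms]
    soft = hbond_sp3_softmax(wg, h_probe, p)
    assert max(es) <= soft <= max(es) + p.M * np.log(2) + 1e-12


# ---------------------------------------------------------------------------
# Composite model
# ---------------------------------------------------------------------------

def test_assign_charges(tripeptide):
    groups = extract_polar_groups(tripeptide)
    q = assign_charges(groups)
    for g in groups:
        assert q[id(g.heavy_atom)] < 0.0
        for h in g.hydrogens:
            assert q[id(h)] > 0.0


def test_score_breakdown_addition(bridged_dimer):
    bd = score_total(bridged_dimer.structure)
    both = bd + bd
    for k, v in bd.terms.items():
        assert both.terms[k] == pytest.approx(2 * v)
    assert both.total == pytest.approx(2 * bd.total)


def test_waters_carry_no_lk_terms(bridged_dimer):
    """Explicit waters are solvent: LK desolvation applies only between
    solute groups."""
    model = EnergyModel()
    s = Structure([r.copy() for r in bridged_dimer.structure.residues])
    s.residues.append(make_water(bridged_dimer.water_site, np.eye(3)))
    ents = model.entities(s)
    wat = next(e for e in ents if e.is_water)
    prot = next(e for e in ents if not e.is_water)
    terms = model.pair_terms(wat, prot)
    assert terms["lk_iso"] == 0.0
    assert terms["lk_ball"] == 0.0
    assert terms["lk_bridge"] == 0.0


def test_adjacent_backbone_exclusion(tripeptide):
    model = EnergyModel()
    ents = model.entities(tripeptide)
    t_adj = model.pair_terms(ents[0], ents[1])
    t_all = model.pair_terms(ents[0], ents[1], adjacent=False)
    # the excluded 1-2/1-3 contacts are deep in LJ repulsion
    assert t_all["lj"] > t_adj["lj"] + 1.0
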