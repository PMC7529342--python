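import numpy as np
import pytest

from hydropack.energy import BridgeParams, g_kernel, ideal_water_sites
from hydropack.fixtures import (brute_force_pack_oracle, make_bridged_dimer,
                                make_decoy_set, sample_water_observations)
from hydropack.packer import PackingProblem, Position
from hydropack.structure import extract_polar_groups


def test_bridged_dimer_geometry(bridged_dimer):
    """At zero jitter the planted pair sits exactly on the bridge optimum:
    coincident hydration sites and a base distance inside both kernels."""
    fx = bridged_dimer
    groups = extract_polar_groups(fx.structure)
    acc = next(g for g in groups
               if (g.residue_id, g.heavy_atom.name) == fx.acceptor_id)
    don = next(g for g in groups
               if (g.residue_id, g.heavy_atom.name) == fx.donor_id)
    p = BridgeParams()
    ci = np.array([s.coord for s in ideal_water_sites(acc)])
    cj = np.array([s.coord for s in ideal_water_sites(don)])
    dmin = float(np.min(np.linalg.norm(ci[:, None] - cj[None, :], axis=2)))
    dbase = float(np.linalg.norm(acc.heavy_atom.coord - don.heavy_atom.coord))
    assert g_kernel(max(dmin - p.D0_len, 0.0), p.S0_len) > 0.9
    assert g_kernel(dbase - p.D0_angle, p.S0_angle) > 0.9
    # the shared site is the acceptor's first hydration site
    np.testing.assert_allclose(fx.water_site, ci[0], atol=1e-9)
    # chains do not clash
    ha = np.array([a.coord for r in fx.structure.residues if r.chain == "A"
                   for a in r.atoms.values() if not a.is_hydrogen])
    hb = np.array([a.coord for r in fx.structure.residues if r.chain == "B"
                   for a in r.atoms.values() if not a.is_hydrogen])
    assert np.min(np.linalg.norm(ha[:, None] - hb[None, :], axis=2)) >= 2.4


def test_bridged_dimer_jitter():
    fx0 = make_bridged_dimer(jitter=0.0, seed=1)
    fx1 = make_bridged_dimer(jitter=0.5, seed=1)
    # jitter moves chain B rigidly
    b0 = [a.coord for r in fx0.structure.residues if r.chain == "B"
          for a in r.atoms.values()]
    b1 = [a.coord for r in fx1.structure.residues if r.chain == "B"
          for a in r.atoms.values()]
    deltas = np.linalg.norm(np.asarray(b0) - np.asarray(b1), axis=1)
    assert deltas.std() < 1e-9 and deltas.mean() > 0.0
    with pytest.raises(ValueError):
        make_bridged_dimer(jitter=-0.1)


def test_brute_force_oracle_two_positions():
    prob = PackingProblem([Position("a", 2, "water_cluster", virtual_state=0),
                           Position("b", 2, "water_cluster", virtual_state=0)])
    prob.one_body[0][:] = [0.0, -1.0]
    prob.one_body[1][:] = [0.0, 0.5]
    prob.set_two_body(0, 1, np.array([[0.0, 0.0], [0.0, -2.0]]))
    out = brute_force_pack_oracle(prob, RT=1.0)
    assert out["best_assignment"] == [1, 1]
    assert out["best_energy"] == pytest.approx(-2.5)
    # exact Boltzmann marginals by hand: states (00,01,10,11) with
    # energies (0, .5, -1, -2.5)
    z = sum(np.exp(-e) for e in (0.0, 0.5, -1.0, -2.5))
    p_a1 = (np.exp(1.0) + np.exp(2.5)) / z
    assert out["marginals"][0][1] == pytest.approx(p_a1, abs=1e-12)


def test_brute_force_oracle_guard():
    prob = PackingProblem([Position(i, 100, "sidechain") for i in range(4)])
    with pytest.raises(ValueError, match="state space"):
        brute_force_pack_oracle(prob)


def test_decoy_set_exact_rmsd(bridged_dimer):
    s = bridged_dimer.structure
    decoys = make_decoy_set(s, ("B",), n=8, seed=3)
    assert len(decoys) == 8
    rmsds = [r for _, r in decoys]
    assert min(rmsds) <= 2.0                       # near-native present
    for moved, rmsd in decoys:
        ca_ref = [r.get("CA").coord for r in s.residues if r.chain == "B"]
        ca_mov = [r.get("CA").coord for r in moved.residues
                  if r.chain == "B"]
        d = np.asarray(ca_ref) - np.asarray(ca_mov)
        assert rmsd == pytest.approx(
            float(np.sqrt(np.mean(np.sum(d * d, axis=1)))), abs=1e-12)
        # fixed partner untouched
        for r_ref, r_mov in zip(s.residues, moved.residues):
            if r_ref.chain == "A":
                np.testing.assert_array_equal(r_ref.get("CA").coord,
                                              r_mov.get("CA").coord)
    again = make_decoy_set(s, ("B",), n=8, seed=3)
    np.testing.assert_allclose([r for _, r in again], rmsds)
    with pytest.raises(ValueError):
        make_decoy_set(s, ("B",), n=1, seed=0)


def test_sampler_validation():
    with pytest.raises(ValueError):
        sample_water_observations((2.8, 120.0), (0.1, 10.0), 0, seed=0)
    with pytest.raises(ValueError):
        sample_water_observations((2.8, 120.0), (0.0, 10.0), 10, seed=0)
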