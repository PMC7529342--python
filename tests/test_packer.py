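import numpy as np
import pytest

from hydropack.builder import water_hydrogen_offsets
from hydropack.energy import EnergyModel, assign_charges
from hydropack.fixtures import brute_force_pack_oracle
from hydropack.geometry import rotation_about_axis, rotation_angle_between
from hydropack.packer import (AnnealSchedule, PackingProblem, Position, anneal,
                              build_stage1_problem, build_water_rotamers,
                              stage1_pack, supported_resolutions, water_entity,
                              water_pair_matrix)
from hydropack.sites import backbone_sites, cluster_sites


# ---------------------------------------------------------------------------
# SO(3) water rotamer grid
# ---------------------------------------------------------------------------

def test_rotamer_count_at_30_degrees():
    rs = build_water_rotamers(np.zeros(3), 30.0)
    assert len(rs.rotamers) == 270
    assert rs.includes_virtual


def test_rotamer_grid_scaling():
    counts = {res: len(build_water_rotamers(np.zeros(3), res).rotamers)
              for res in (30, 45, 60)}
    assert counts[45] < counts[30]
    assert counts[60] < counts[45]
    with pytest.raises(ValueError, match="resolution"):
        build_water_rotamers(np.zeros(3), 17.0)
    assert 30 in supported_resolutions()


def test_rotamers_are_rotations_and_distinct():
    rs = build_water_rotamers(np.zeros(3), 45.0)
    mats = rs.rotamers
    for R in mats[:20]:
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0)
    # no two rotamers closer than a fraction of the grid resolution,
    # accounting for the water C2 symmetry (spin by 180 about local z)
    c2 = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 180.0)
    rng = np.random.default_rng(4)
    for _ in range(40):
        i, j = rng.choice(len(mats), 2, replace=False)
        sep = min(rotation_angle_between(mats[i], mats[j]),
                  rotation_angle_between(mats[i] @ c2, mats[j]))
        assert sep > 5.0


def test_c2_spin_maps_water_onto_itself():
    c2 = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 180.0)
    h = water_hydrogen_offsets()
    h_spun = water_hydrogen_offsets(c2)
    np.testing.assert_allclose(h_spun, h[::-1], atol=1e-12)


# ---------------------------------------------------------------------------
# Potts problem and annealer
# ---------------------------------------------------------------------------

def _random_problem(rng, n_pos=4, n_states=3):
    positions = [Position(("p", i), n_states, "water_rotamer",
                          virtual_state=0) for i in range(n_pos)]
    prob = PackingProblem(positions)
    for i in range(n_pos):
        prob.one_body[i] = rng.normal(size=n_states)
        prob.one_body[i][0] = 0.0
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            m = rng.normal(size=(n_states, n_states))
            m[0, :] = 0.0
            m[:, 0] = 0.0
            prob.set_two_body(i, j, m)
    return prob


def test_delta_energy_consistency(rng):
    prob = _random_problem(rng)
    assignment = [int(rng.integers(3)) for _ in range(4)]
    e0 = prob.energy(assignment)
    for p in range(4):
        for s in range(3):
            d = prob.delta_energy(assignment, p, s)
            trial = list(assignment)
            trial[p] = s
            assert d == pytest.approx(prob.energy(trial) - e0, abs=1e-10)


def test_anneal_deterministic(rng):
    prob = _random_problem(rng)
    sched = AnnealSchedule(n_cycles=2, steps_per_cycle=500, seed=42)
    r1 = anneal(prob, sched)
    r2 = anneal(prob, sched)
    assert r1.best_assignment == r2.best_assignment
    assert r1.final_assignment == r2.final_assignment
    assert r1.best_energy == r2.best_energy
    for d1, d2 in zip(r1.dwell, r2.dwell):
        np.testing.assert_array_equal(d1, d2)


def test_anneal_finds_global_minimum(rng):
    prob = _random_problem(rng, n_pos=5, n_states=3)
    oracle = brute_force_pack_oracle(prob)
    res = anneal(prob, AnnealSchedule(n_cycles=4, steps_per_cycle=2000,
                                      seed=9))
    assert res.best_energy == pytest.approx(oracle["best_energy"], abs=1e-9)


def test_schedule_validation():
    with pytest.raises(ValueError):
        AnnealSchedule(RT_low=5.0, RT_high=1.0)
    with pytest.raises(ValueError):
        AnnealSchedule(burn_in_fraction=1.0)


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

def test_stage1_retains_coordinated_sites(tetrapeptide):
    sites = cluster_sites(backbone_sites(tetrapeptide))
    prob, payload = build_stage1_problem(sites, tetrapeptide)
    # every cluster position has an off state at index 0 with zero energy
    for i, (kind, _) in enumerate(payload):
        if kind == "cluster":
            assert prob.one_body[i][0] == 0.0
    retained, res = stage1_pack(
        sites, structure=tetrapeptide,
        sched=AnnealSchedule(n_cycles=2, steps_per_cycle=2000, seed=5))
    assert res is not None
    assert 0 < len(retained) < len(sites)
    for s in retained:
        assert s.occupancy >= 0.02


# ---------------------------------------------------------------------------
# Vectorized water-water energies
# ---------------------------------------------------------------------------

def test_water_pair_matrix_matches_entity_path(rng):
    model = EnergyModel()
    rs_a = build_water_rotamers(np.zeros(3), 60.0)
    rs_b = build_water_rotamers(np.array([2.75, 0.4, -0.3]), 60.0)
    mat = water_pair_matrix(rs_a, rs_b, model)
    assert mat.shape == (len(rs_a.rotamers), len(rs_b.rotamers))
    for _ in range(15):
        a = int(rng.integers(len(rs_a.rotamers)))
        b = int(rng.integers(len(rs_b.rotamers)))
        ea = water_entity(rs_a.oxygen, rs_a.rotamers[a])
        eb = water_entity(rs_b.oxygen, rs_b.rotamers[b])
        q = assign_charges(ea.groups + eb.groups)
        slow = model.pair_energy(ea, eb, charges=q, adjacent=False)
        assert mat[a, b] == pytest.approx(slow, abs=1e-9)
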