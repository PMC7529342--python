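import numpy as np
import pytest

from hydropack.fixtures import (sample_reference_observations,
                                sample_water_observations)
from hydropack.point_water import (DEFAULT_D_BINS, DEFAULT_THETA_BINS,
                                   PointWaterParams, StatTable,
                                   default_tables, fit_stat_tables,
                                   load_tables, point_water_energy,
                                   polar_term, save_tables, water_water_term)
from hydropack.structure import extract_polar_groups


def test_params_validation():
    with pytest.raises(ValueError):
        PointWaterParams(sigma=0.0)
    with pytest.raises(ValueError):
        PointWaterParams(K=-1.0)


def test_stat_table_lookup():
    t = StatTable("x", [2.0, 3.0, 4.0], [0.0, 90.0, 180.0],
                  [[1.0, 2.0], [3.0, 4.0]])
    assert t.lookup(2.5, 45.0) == 1.0
    assert t.lookup(3.5, 100.0) == 4.0
    assert t.lookup(1.9, 45.0) == 0.0    # below range
    assert t.lookup(4.0, 45.0) == 0.0    # at/above ceiling
    assert t.lookup(2.5, 180.0) == 2.0   # angle clamped into last bin
    (i, j), (dm, tm) = t.argmin_bin()
    assert (i, j) == (0, 0) and (dm, tm) == (2.5, 45.0)
    with pytest.raises(ValueError):
        StatTable("x", [2.0, 2.0], [0.0, 90.0], [[1.0]])


def test_water_water_term_minimum():
    p = PointWaterParams()
    assert water_water_term(p.d_ww, p) == pytest.approx(-p.K)
    assert water_water_term(p.d_ww + 1.0, p) == pytest.approx(0.0, abs=1e-6)
    ds = np.linspace(2.0, 3.5, 301)
    es = [water_water_term(d, p) for d in ds]
    assert ds[int(np.argmin(es))] == pytest.approx(p.d_ww, abs=0.01)


def test_point_water_energy_composition(tripeptide):
    p = PointWaterParams()
    tables = default_tables()
    groups = extract_polar_groups(tripeptide)
    # isolated: exactly the out-of-bulk constant
    far = np.array([500.0, 0.0, 0.0])
    assert point_water_energy(0, [far], groups, tables, p) == p.E_pwat_bulk
    # two isolated waters at the optimum: bulk cost minus the full reward
    w2 = [far, far + np.array([p.d_ww, 0.0, 0.0])]
    assert point_water_energy(0, w2, groups, tables, p) == \
        pytest.approx(p.E_pwat_bulk - p.K)
    # a site at H-bond range of the backbone is rewarded by the tables
    bbo = next(g for g in groups if g.atom_class == "bb_O")
    site = bbo.heavy_atom.coord + 2.8 * np.array([0.0, 0.0, 1.0])
    assert polar_term(site, groups, tables) != 0.0


def test_fit_recovers_planted_mode(rng):
    """Parameter recovery: the fitted table's minimum sits in the bin of
    the planted (d*, theta*) mode."""
    mode = (2.8, 120.0)
    obs_xy = sample_water_observations(mode, (0.15, 12.0), 10000, seed=5)
    obs = [("probe", d, t) for d, t in obs_xy]
    ref = sample_reference_observations(50000, seed=6)
    tables = fit_stat_tables(obs, ref)
    (_, _), (d_mid, t_mid) = tables["probe"].argmin_bin()
    d_bin = DEFAULT_D_BINS[1] - DEFAULT_D_BINS[0]
    t_bin = DEFAULT_THETA_BINS[1] - DEFAULT_THETA_BINS[0]
    assert abs(d_mid - mode[0]) <= d_bin
    assert abs(t_mid - mode[1]) <= t_bin


def test_fit_skips_sparse_classes():
    obs_xy = sample_water_observations((2.8, 120.0), (0.15, 12.0), 600, seed=1)
    obs = [("dense", d, t) for d, t in obs_xy]
    obs += [("sparse", 2.8, 120.0)] * 10
    ref = sample_reference_observations(5000, seed=2)
    tables = fit_stat_tables(obs, ref)
    assert "dense" in tables and "sparse" not in tables
    with pytest.raises(ValueError, match="reference"):
        fit_stat_tables(obs, ref[:10])


def test_tables_clamped_and_finite():
    tables = default_tables()
    assert len(tables) >= 10
    for t in tables.values():
        assert np.all(np.isfinite(t.neg_log_ratio))
        assert np.all(np.abs(t.neg_log_ratio) <= 3.0 + 1e-9)


def test_table_serialization_round_trip(tmp_path):
    tables = default_tables()
    path = tmp_path / "tables.tsv"
    save_tables(tables, path)
    back = load_tables(path)
    assert set(back) == set(tables)
    for cls in tables:
        np.testing.assert_allclose(back[cls].neg_log_ratio,
                                   tables[cls].neg_log_ratio, atol=1e-6)
        np.testing.assert_allclose(back[cls].d_bins, tables[cls].d_bins)


def test_observation_sampler_statistics():
    """Without shell weighting the sampler is a truncated Gaussian whose
    sample mean converges on the requested mode."""
    mode = (2.8, 100.0)
    obs = sample_water_observations(mode, (0.1, 8.0), 20000, seed=11,
                                    shell_weighting=False)
    assert obs.shape == (20000, 2)
    assert obs[:, 0].mean() == pytest.approx(mode[0], abs=0.01)
    assert obs[:, 1].mean() == pytest.approx(mode[1], abs=0.5)
    # determinism
    again = sample_water_observations(mode, (0.1, 8.0), 20000, seed=11,
                                      shell_weighting=False)
    np.testing.assert_array_equal(obs, again)


def test_reference_sampler_distribution():
    ref = sample_reference_observations(50000, seed=3)
    d, th = ref[:, 0], ref[:, 1]
    assert d.min() >= 2.0 and d.max() < 3.6
    # d^3 uniform on [2^3, 3.6^3]
    assert (d ** 3).mean() == pytest.approx((2.0 ** 3 + 3.6 ** 3) / 2, rel=0.02)
    # cos(theta) uniform on [-1, 1]
    assert np.cos(np.radians(th)).mean() == pytest.approx(0.0, abs=0.02)
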