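import numpy as np
import pytest

from hydropack.builder import build_peptide, make_water
from hydropack.rotamers import apply_chis, get_chis
from hydropack.scoring import (ScoreRecord, classify_waters,
                               discrimination_score, interface_water_density,
                               percent_correct, rotamer_recovery,
                               water_recovery)
from hydropack.structure import (InterfaceDefinition, Structure,
                                 build_polar_hydrogens)


def _records(energies, rmsds):
    return [ScoreRecord(str(i), r, e)
            for i, (e, r) in enumerate(zip(energies, rmsds))]


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

def test_discrimination_bounds_and_shift_invariance(rng):
    for _ in range(10):
        energies = rng.normal(size=12)
        rmsds = rng.random(12) * 10.0
        rmsds[0] = 0.5  # ensure both sides populated
        rmsds[1] = 9.0
        d1 = discrimination_score(_records(energies, rmsds))
        assert 0.0 <= d1 <= 1.0
        shift = rng.normal() * 100.0
        d2 = discrimination_score(_records(energies + shift, rmsds))
        assert d2 == pytest.approx(d1, abs=1e-9)


def test_discrimination_perfect_and_degenerate():
    # near-natives far below everything else: score ~ 1
    energies = [-50.0, -49.0, 0.0, 1.0, 2.0]
    rmsds = [0.5, 1.0, 8.0, 9.0, 10.0]
    assert discrimination_score(_records(energies, rmsds)) > 0.99
    with pytest.raises(ValueError, match="one side"):
        discrimination_score(_records([0.0, 1.0], [0.5, 1.0]))
    with pytest.raises(ValueError):
        discrimination_score(_records([0.0], [0.5]))


def test_percent_correct():
    recs = _records([-5.0, 0.0, 1.0], [0.5, 8.0, 9.0])
    assert percent_correct(recs) == 100.0
    recs = _records([5.0, 0.0, -1.0], [0.5, 8.0, 9.0])
    assert percent_correct(recs) == 0.0


def test_score_record_validation():
    with pytest.raises(ValueError):
        ScoreRecord("x", -1.0, 0.0)


# ---------------------------------------------------------------------------
# Water recovery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def peptide_with_waters():
    s = build_polar_hydrogens(build_peptide(["ALA", "SER", "ASN", "ALA"]))
    o1 = s.residues[1].get("O").coord + np.array([0.0, 0.0, 2.9])
    o2 = s.residues[2].get("O").coord + np.array([0.0, 0.0, 2.9])
    return s, [o1, o2]


def test_water_recovery_distance_and_coordination(peptide_with_waters):
    s, native = peptide_with_waters
    # prediction 1: 0.3 A off (distance match); prediction 2: 0.9 A off
    # but still coordinated by the same polar atoms (coordination match)
    pred = [native[0] + np.array([0.3, 0.0, 0.0]),
            native[1] + np.array([0.0, 0.0, -0.9])]
    rep = water_recovery(pred, native, s)
    assert rep.n_matched == 2
    kinds = {m[3] for m in rep.matches}
    assert kinds == {"distance", "coordination"}
    assert rep.recovery_pct == 100.0


def test_water_recovery_one_to_one(peptide_with_waters):
    s, native = peptide_with_waters
    # two predictions near the same native water: only one may match
    pred = [native[0] + 0.1, native[0] + 0.2, np.array([50.0, 0.0, 0.0])]
    rep = water_recovery(pred, [native[0]], s)
    assert rep.n_matched == 1
    assert rep.precision_pct == pytest.approx(100.0 / 3.0)
    with pytest.raises(ValueError, match="native"):
        water_recovery(pred, [], s)


def test_water_recovery_accepts_residues(peptide_with_waters):
    s, native = peptide_with_waters
    nat_res = [make_water(o, np.eye(3), seqnum=i + 1)
               for i, o in enumerate(native)]
    rep = water_recovery(list(native), nat_res, s)
    assert rep.n_matched == 2


def test_classify_waters(peptide_with_waters):
    s, native = peptide_with_waters
    far = np.array([200.0, 0.0, 0.0])
    out = classify_waters([native[0], far], s)
    assert out[0]["coordination"] >= 1
    assert out[1] == {"n_cb": 0, "buriedness": "exposed",
                      "coordination": 0, "contact_type": "uncoordinated"}


def test_bb_only_classification():
    # a water between two backbone carbonyls and nothing else
    s = build_polar_hydrogens(build_peptide(["ALA"] * 6))
    o1 = s.residues[1].get("O").coord
    o2 = s.residues[2].get("O").coord
    w = 0.5 * (o1 + o2)
    if np.linalg.norm(o1 - o2) <= 6.4:  # both within 3.2
        cls = classify_waters([w], s)[0]
        assert cls["contact_type"] in ("BB_only", "BB+SC")
        assert cls["coordination"] >= 2


def test_interface_water_density():
    iface = InterfaceDefinition(("A",), ("B",), [], 500.0)
    assert interface_water_density([np.zeros(3)] * 3, iface) == \
        pytest.approx(6.0)
    empty = InterfaceDefinition(("A",), ("B",), [], 0.0)
    with pytest.raises(ValueError, match="area"):
        interface_water_density([np.zeros(3)], empty)


# ---------------------------------------------------------------------------
# Rotamer recovery
# ---------------------------------------------------------------------------

def test_rotamer_recovery():
    ref = build_peptide(["ALA", "SER", "ASN", "ALA"])
    same = Structure([r.copy() for r in ref.residues])
    assert rotamer_recovery(same, ref) == 0.0
    moved = Structure([r.copy() for r in ref.residues])
    chis = get_chis(moved.residues[1])
    apply_chis(moved.residues[1], (chis[0] + 60.0,))
    assert rotamer_recovery(moved, ref) == pytest.approx(0.5)  # 1 of 2 wrong
    small = Structure([r.copy() for r in ref.residues])
    chis = get_chis(small.residues[1])
    apply_chis(small.residues[1], (chis[0] + 10.0,))
    assert rotamer_recovery(small, ref) == 0.0  # within 20 degrees


def test_rotamer_recovery_symmetric_chi():
    ref = build_peptide(["ALA", "ASP", "ALA"])
    flipped = Structure([r.copy() for r in ref.residues])
    chis = get_chis(flipped.residues[1])
    # 180-degree flip of the carboxylate is the same physical state
    apply_chis(flipped.residues[1], (chis[0], chis[1] + 180.0))
    assert rotamer_recovery(flipped, ref) == 0.0


def test_rotamer_recovery_sequence_mismatch():
    ref = build_peptide(["ALA", "SER", "ALA"])
    other = build_peptide(["ALA", "THR", "ALA"])
    with pytest.raises(ValueError, match="mismatch"):
        rotamer_recovery(other, ref)
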