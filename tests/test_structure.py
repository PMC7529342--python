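import numpy as np
import pytest

from hydropack.builder import build_peptide, make_water
from hydropack.structure import (Structure, StructureError,
                                 build_polar_hydrogens, define_interface,
                                 extract_polar_groups, read_structure, sasa,
                                 write_structure)


def test_pdb_round_trip(tmp_path, tripeptide):
    path = tmp_path / "pep.pdb"
    write_structure(tripeptide, path)
    back = read_structure(path)
    assert len(back.residues) == 3
    assert not back.waters
    for r_orig, r_back in zip(tripeptide.residues, back.residues):
        for name, a in r_orig.atoms.items():
            assert np.allclose(r_back.get(name).coord, a.coord, atol=1.5e-3)


def test_waters_written_to_chain_w(tmp_path, tripeptide):
    s = tripeptide.copy()
    s.residues.append(make_water(np.array([30.0, 0.0, 0.0]), np.eye(3)))
    path = tmp_path / "wat.pdb"
    write_structure(s, path)
    back = read_structure(path)
    assert len(back.waters) == 1
    w = back.waters[0]
    assert w.chain == "W" and w.resname == "HOH"
    back2 = read_structure(path, keep_waters=False)
    assert not back2.waters


ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  {occ_a:4.2f}  0.00           C
ATOM      3  CA BALA A   1       1.458   1.000   0.000  {occ_b:4.2f}  0.00           C
ATOM      4  C   ALA A   1       2.004   1.420   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


@pytest.mark.parametrize("occ_a,occ_b,want_y", [
    (0.60, 0.40, 0.0),   # higher occupancy wins
    (0.40, 0.60, 1.0),
    (0.50, 0.50, 0.0),   # tie: alphabetically first altloc wins
])
def test_altloc_resolution(tmp_path, occ_a, occ_b, want_y):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB.format(occ_a=occ_a, occ_b=occ_b))
    s = read_structure(path)
    ca = s.residues[0].get("CA")
    assert ca.coord[1] == pytest.approx(want_y, abs=1e-3)


def test_clash_guard(tmp_path, tripeptide):
    s = tripeptide.copy()
    # drop a second residue right on top of the first CA
    clash = build_peptide(["ALA"], chain="B")
    shift = tripeptide.residues[0].get("CA").coord - \
        clash.residues[0].get("CA").coord
    clash = clash.transform(np.eye(3), shift + 0.3)
    s.residues.extend(clash.residues)
    path = tmp_path / "clash.pdb"
    write_structure(s, path)
    with pytest.raises(StructureError, match="clash"):
        read_structure(path)
    read_structure(path, clash_check=False)  # opt-out works


def test_unreadable_and_empty(tmp_path):
    with pytest.raises(IOError):
        read_structure(tmp_path / "missing.pdb")
    p = tmp_path / "hetonly.pdb"
    p.write_text("HETATM    1  O   HOH W   1       0.000   0.000   0.000"
                 "  1.00  0.00           O\nEND\n")
    with pytest.raises(StructureError, match="no protein"):
        read_structure(p)


def test_polar_hydrogens_backbone():
    s = build_polar_hydrogens(build_peptide(["ALA", "PRO", "ALA"]))
    r1, r2, r3 = s.residues
    # N-terminus: three hydrogens, no plain amide H
    assert all(r1.get(h) is not None for h in ("H1", "H2", "H3"))
    assert r2.get("H") is None          # proline
    h3 = r3.get("H")
    assert h3 is not None
    n3 = r3.get("N")
    assert np.linalg.norm(h3.coord - n3.coord) == pytest.approx(1.01, abs=1e-6)


def test_polar_hydrogens_serine(tripeptide):
    ser = tripeptide.residues[1]
    hg = ser.get("HG")
    assert hg is not None
    d = np.linalg.norm(hg.coord - ser.get("OG").coord)
    assert d == pytest.approx(0.96, abs=1e-6)


def test_polar_group_enumeration(tripeptide):
    groups = extract_polar_groups(tripeptide)
    classes = sorted(g.atom_class for g in groups)
    # 1 N-term + 2 amide N-H + 3 C=O + 1 Ser hydroxyl
    assert classes == ["bb_N", "bb_N", "bb_O", "bb_O", "bb_O",
                       "hydroxyl", "nterm_N"]
    for g in groups:
        if g.kind in ("donor", "both"):
            assert g.hydrogens
        if g.hybridization == "sp3" and g.kind in ("acceptor", "both"):
            assert len(g.base_atoms) == 2


def test_water_group_symmetric():
    w = make_water(np.zeros(3), np.eye(3))
    groups = extract_polar_groups(Structure(
        [build_peptide(["ALA"]).residues[0], w]))
    wg = [g for g in groups if g.atom_class == "water_O"]
    assert len(wg) == 1 and wg[0].kind == "both"
    assert len(wg[0].base_atoms) == 2


def test_sasa_against_biotite(tetrapeptide):
    """Our Shrake-Rupley agrees with an independent implementation."""
    import biotite.structure as struc

    heavy = [a for a in tetrapeptide.atoms if not a.is_hydrogen]
    arr = struc.AtomArray(len(heavy))
    for i, a in enumerate(heavy):
        arr.coord[i] = a.coord
        arr.element[i] = a.element
        arr.atom_name[i] = a.name
        arr.res_name[i] = a.resname
        arr.res_id[i] = a.residue_id[1]
        arr.chain_id[i] = a.residue_id[0]
    ref = float(np.nansum(struc.sasa(arr, probe_radius=1.4, point_number=960,
                                     vdw_radii="Single")))
    ours = sasa(heavy)
    assert ours == pytest.approx(ref, rel=0.05)


def test_interface_definition():
    a = build_peptide(["ALA", "ALA", "ALA"], chain="A")
    b = build_peptide(["ALA", "ALA", "ALA"], chain="B")
    far = b.transform(np.eye(3), np.array([60.0, 0.0, 0.0]))
    near = b.transform(np.eye(3), np.array([0.0, 7.0, 0.0]))
    s_far = Structure(a.residues + far.residues)
    s_near = Structure([r.copy() for r in a.residues]
                       + [r.copy() for r in near.residues])
    iface_far = define_interface(s_far, ("A",), ("B",))
    assert iface_far.buried_area == pytest.approx(0.0, abs=1.0)
    assert not iface_far.interface_residues
    iface_near = define_interface(s_near, ("A",), ("B",))
    assert iface_near.buried_area > 10.0
    assert iface_near.interface_residues
    with pytest.raises(StructureError, match="chain"):
        define_interface(s_near, ("A",), ("C",))
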