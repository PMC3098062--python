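"""Structure I/O, superposition, first-layer selection, Ala substitution."""

import numpy as np
import pytest

from pocketshape.config import load_vdw_radii
from pocketshape.geometry import bond_angle, dihedral
from pocketshape.structure import (
    AtomRecord,
    LigandEnsemble,
    ala_substitute,
    build_cb,
    build_ligand_ensemble,
    read_structure,
    select_flr,
    superpose_backbone,
    validate_flexible,
    write_structure,
)

PDB_ALTLOC = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       3.200   1.600   0.000  1.00  0.00           O
ATOM      5  CB ASER A   1       2.000  -1.000   1.000  0.30  0.00           C
ATOM      6  CB BSER A   1       2.000  -1.000  -1.000  0.70  0.00           C
ATOM      7  H   SER A   1       0.000   0.500   0.500  1.00  0.00           H
HETATM    8  O   HOH A 100       9.000   9.000   9.000  1.00  0.00           O
HETATM    9  C1  LIG A 200       5.000   5.000   5.000  1.00  0.00           C
HETATM   10  C2  LIG A 200       6.000   5.000   5.000  1.00  0.00           C
END
"""


def test_read_structure_resolves_altloc_skips_waters_and_splits_ligands(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(PDB_ALTLOC)
    st = read_structure(path)
    assert len(st.residues) == 1
    assert len(st.ligands) == 1 and len(st.ligands[0].atoms) == 2
    res = st.residues[0]
    assert not res.has_atom("H")
    cb = res.atom("CB")
    assert cb.coords[2] == pytest.approx(-1.0)  # highest occupancy kept
    assert cb.vdw_radius == pytest.approx(1.70)


def test_read_structure_rejects_unknown_element(tmp_path):
    bad = PDB_ALTLOC.replace(
        "HETATM    9  C1  LIG A 200       5.000   5.000   5.000  1.00  0.00           C",
        "HETATM    9 XX1  LIG A 200       5.000   5.000   5.000  1.00  0.00           Xx",
    )
    path = tmp_path / "bad.pdb"
    path.write_text(bad)
    with pytest.raises(ValueError, match="XX1"):
        read_structure(path)


def test_flexible_residue_without_backbone_is_rejected(tmp_path):
    ca_only = (
        "ATOM      1  CA  LEU A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "ca.pdb"
    path.write_text(ca_only)
    st = read_structure(path)
    with pytest.raises(ValueError, match="backbone"):
        validate_flexible(st, [("A", 1, "")])


def test_write_read_roundtrip_preserves_coordinates(tmp_path, toy):
    out = tmp_path / "toy.pdb"
    write_structure(toy.template, out)
    back = read_structure(out)
    assert len(back.residues) == len(toy.template.residues)
    for ra, rb in zip(toy.template.residues, back.residues):
        assert ra.key == rb.key and ra.name == rb.name
        assert np.allclose(ra.coords(), rb.coords(), atol=1e-3)


def test_superpose_identity_and_translation(toy):
    res = superpose_backbone(toy.template, toy.template)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(res.rotation, np.eye(3))
    shifted = toy.template.transformed(np.eye(3), np.array([5.0, 0.0, 0.0]))
    res2 = superpose_backbone(shifted, toy.template)
    assert res2.rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_rmsd_invariant_under_rigid_pretransform(toy):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(5)
    noisy = toy.template.transformed(np.eye(3), np.zeros(3))
    for res in noisy.residues:
        for a in res.atoms:
            a.coords = a.coords + rng.normal(scale=0.2, size=3)
    base = superpose_backbone(noisy, toy.template).rmsd
    R = Rotation.from_rotvec([0.5, -0.3, 1.1]).as_matrix()
    pre = noisy.transformed(R, np.array([-4.0, 2.0, 7.0]))
    assert superpose_backbone(pre, toy.template).rmsd == pytest.approx(base, abs=1e-6)


def test_superpose_requires_three_matched_calphas(toy):
    tiny = toy.template.transformed(np.eye(3), np.zeros(3))
    tiny.residues = tiny.residues[:2]
    with pytest.raises(ValueError, match=">= 3"):
        superpose_backbone(tiny, toy.template)


def test_ligand_ensemble_union_counts(toy):
    ens = build_ligand_ensemble(toy.superposed)
    expected = sum(len(lig.atoms) for h in toy.superposed for lig in h.ligands)
    assert len(ens.atoms) == expected
    with pytest.warns(UserWarning, match="apo"):
        empty = build_ligand_ensemble([toy.template])
    assert empty.apo_mode


def test_select_flr_boundary_and_monotonicity(radii):
    """A residue 4.9 A from the ensemble is in; 5.1 A is out."""
    def residue_at(x, seq):
        from pocketshape.structure import Residue

        return Residue(
            "A", seq, "", "GLY",
            [AtomRecord("CA", "C", np.array([x, 0.0, 0.0]), radii["C"], True)],
        )

    from pocketshape.structure import ProteinStructure

    st = ProteinStructure("t", [residue_at(4.9, 1), residue_at(5.1, 2)])
    ens = LigandEnsemble(
        atoms=[("h", AtomRecord("C1", "C", np.zeros(3), radii["C"]))]
    )
    assert select_flr(st, ens, cutoff=5.0) == [("A", 1, "")]
    wide = select_flr(st, ens, cutoff=6.0)
    assert set(select_flr(st, ens, cutoff=5.0)) <= set(wide)


def test_ala_substitute_trims_idempotently(toy):
    flex = [k for k in toy.flr if k[1] >= 100]
    sub = ala_substitute(toy.template, flex)
    for key in flex:
        res = sub.residue(key)
        assert res.name == "ALA"
        assert sorted(a.name for a in res.atoms) == ["C", "CA", "CB", "N", "O"]
        # source untouched
        assert len(toy.template.residue(key).atoms) > 5
    again = ala_substitute(sub, flex)
    for key in flex:
        assert sorted(a.name for a in again.residue(key).atoms) == [
            "C", "CA", "CB", "N", "O",
        ]


def test_ala_substitute_leaves_gly_alone(toy):
    gly_key = next(r.key for r in toy.template.residues if r.name == "GLY")
    sub = ala_substitute(toy.template, [gly_key])
    assert sub.residue(gly_key).name == "GLY"
    assert len(sub.residue(gly_key).atoms) == len(toy.template.residue(gly_key).atoms)


def test_missing_cbeta_rebuilt_at_ideal_tetrahedral_geometry(toy):
    key = next(k for k in toy.flr if k[1] >= 100)
    stripped = toy.template.transformed(np.eye(3), np.zeros(3))
    res = stripped.residue(key)
    res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
    sub = ala_substitute(stripped, [key])
    rebuilt = sub.residue(key)
    n, ca, c, cb = (rebuilt.atom(x).coords for x in ("N", "CA", "C", "CB"))
    assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=1e-6)
    assert bond_angle(n, ca, cb) == pytest.approx(110.5, abs=1e-6)
    assert dihedral(c, n, ca, cb) == pytest.approx(-122.6, abs=1e-6)
    assert np.allclose(cb, build_cb(rebuilt))
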