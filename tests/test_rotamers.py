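"""Rotamer library parsing, side-chain construction and clash tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketshape.config import ClashParams
from pocketshape.rotamers import (
    RotamerPlacement,
    apply_rotamer,
    clash,
    load_rotamer_library,
    measure_chi,
    normalize_angle,
    prefilter_rotamers,
    write_rotamer_library,
)
from pocketshape.sidechain_tables import CHI_COUNTS, SIDECHAIN_TOPOLOGY, bond_distances
from pocketshape.structure import AtomRecord


def test_library_roundtrip_and_row_count(tmp_path, toy):
    path = tmp_path / "lib.tsv"
    write_rotamer_library(toy.library, path)
    lib = load_rotamer_library(path)
    assert lib.n_rotamers == toy.library.n_rotamers
    for name, rots in toy.library.rotamers.items():
        assert [r.chi for r in lib[name]] == [r.chi for r in rots]
        assert all(len(r.chi) == CHI_COUNTS[name] for r in lib[name])


def test_library_chi_count_mismatch_reports_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "residue_name\trotamer_id\tchi1\tchi2\tchi3\tchi4\tprobability\n"
        "LEU\t0\t-60.0\t\t\t\t\n"
    )
    with pytest.raises(ValueError, match=":2"):
        load_rotamer_library(path)


def test_angle_normalization_range():
    assert normalize_angle(190.0) == pytest.approx(-170.0)
    assert normalize_angle(-180.0) == 180.0
    assert normalize_angle(360.0) == 0.0


@pytest.mark.parametrize(
    "resname,chi",
    [
        ("LEU", (-60.0, 160.0)),
        ("SER", (62.0,)),
        ("TYR", (-65.0, 95.0)),
        ("ARG", (-60.0, 180.0, 65.0, -90.0)),
        ("TRP", (-70.0, 100.0)),
        ("ILE", (-60.0, 170.0)),
    ],
)
def test_apply_rotamer_reproduces_requested_chi(resname, chi, radii):
    from pocketshape.structure import Residue, build_cb

    res = Residue(
        "A", 1, "", resname,
        [
            AtomRecord("N", "N", np.array([0.0, 0.0, 0.0]), radii["N"], True),
            AtomRecord("CA", "C", np.array([1.46, 0.0, 0.0]), radii["C"], True),
            AtomRecord("C", "C", np.array([2.0, 1.4, 0.0]), radii["C"], True),
        ],
    )
    placement = apply_rotamer(res, resname, chi, vdw_radii=radii)
    full = Residue("A", 1, "", resname, list(res.atoms) + placement.atoms)
    full.atoms.append(AtomRecord("CB", "C", build_cb(res), radii["C"], False))
    measured = measure_chi(full)
    assert np.allclose(measured, chi, atol=1e-3)
    # built bonds match the geometry table
    placed = {a.name: a.coords for a in full.atoms}
    for step in SIDECHAIN_TOPOLOGY[resname]:
        atom, _el, parent, _aref, _tref, bond = step[:6]
        assert np.linalg.norm(placed[atom] - placed[parent]) == pytest.approx(bond, abs=1e-6)


def test_chi_roundtrip_on_intact_fixture_residue(toy, radii):
    res = next(r for r in toy.template.residues if r.seqnum >= 100)
    chi = measure_chi(res)
    rebuilt = apply_rotamer(res, res.name, chi, vdw_radii=radii)
    for atom in rebuilt.atoms:
        original = res.atom(atom.name)
        assert np.linalg.norm(atom.coords - original.coords) < 0.3


def test_chi1_flip_moves_only_atoms_beyond_cbeta(toy, radii):
    res = next(r for r in toy.template.residues if r.seqnum >= 100)
    chi = measure_chi(res)
    flipped = (normalize_angle(chi[0] + 180.0),) + chi[1:]
    a = apply_rotamer(res, res.name, chi, vdw_radii=radii)
    b = apply_rotamer(res, res.name, flipped, vdw_radii=radii)
    for atom_a, atom_b in zip(a.atoms, b.atoms):
        assert np.linalg.norm(atom_a.coords - atom_b.coords) > 0.5
    # determinism: identical chi -> identical coordinates
    c = apply_rotamer(res, res.name, chi, vdw_radii=radii)
    assert all(
        np.array_equal(x.coords, y.coords) for x, y in zip(a.atoms, c.atoms)
    )


def _carbon(x, r=1.7):
    return AtomRecord("C", "C", np.array([x, 0.0, 0.0]), r)


@pytest.mark.parametrize(
    "d,ctd,expected",
    [
        (0.0, 0.5, True),     # coincident atoms always clash
        (3.4, 1.0, False),    # 3.4 >= 1.7 + 1.7 - 1.0
        (2.3, 1.0, True),     # 2.3 < 2.4
        (2.4, 1.0, False),    # boundary: strict inequality
    ],
)
def test_clash_soft_vdw_criterion(d, ctd, expected):
    assert clash(_carbon(0.0), _carbon(d), ClashParams(ctd=ctd)) is expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x=st.floats(0.0, 5.0),
    ctd=st.floats(0.0, 2.0),
)
def test_clash_is_symmetric(x, ctd):
    a, b = _carbon(0.0), _carbon(x)
    params = ClashParams(ctd=ctd)
    assert clash(a, b, params) == clash(b, a, params)


def test_prefilter_matches_direct_all_pairs_scan(toy, radii):
    """Oracle: O(n*m) direct clash scan with explicit bond exclusions."""
    params = toy.cfg.clash_params()
    slr_set = set(toy.slr)
    fixed = []
    for res in toy.template.residues:
        for a in res.atoms:
            if res.key in slr_set and not a.is_backbone and a.name != "CB":
                continue
            fixed.append((res.key, a))
    for key, survivors in toy.placements.items():
        res = toy.template.residue(key)
        dists = bond_distances(res.name)
        expected = []
        for i, rot in enumerate(toy.library[res.name]):
            pl = apply_rotamer(res, res.name, rot.chi, rotamer_index=i, vdw_radii=radii)
            ok = True
            for atom in pl.atoms:
                for fkey, fatom in fixed:
                    if fkey == key and dists[atom.name].get(fatom.name, 99) <= 3:
                        continue
                    if clash(atom, fatom, params):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                expected.append(i)
        assert [p.rotamer_index for p in survivors] == expected


def test_conformer_structure_swaps_side_chains(toy):
    from pocketshape.rotamers import conformer_structure

    conf = toy.conformers[0]
    chosen = {k: toy.placements[k][ri] for k, ri in conf.assignment.items()}
    st = conformer_structure(toy.template, chosen)
    for key, placement in chosen.items():
        res = st.residue(key)
        for atom in placement.atoms:
            assert np.array_equal(res.atom(atom.name).coords, atom.coords)
        # backbone untouched
        for name in ("N", "CA", "C"):
            assert np.array_equal(
                res.atom(name).coords, toy.template.residue(key).atom(name).coords
            )


def test_prefilter_monotone_in_ctd(toy):
    relaxed = prefilter_rotamers(
        toy.library, toy.template, toy.slr, ClashParams(ctd=2.5)
    )
    strict = toy.placements  # ctd = 1.0
    for key in toy.slr:
        strict_set = {p.rotamer_index for p in strict[key]}
        relaxed_set = {p.rotamer_index for p in relaxed[key]}
        assert strict_set <= relaxed_set
    huge = prefilter_rotamers(toy.library, toy.template, toy.slr, ClashParams(ctd=50.0))
    for key in toy.slr:
        assert len(huge[key]) == len(toy.library[toy.template.residue(key).name])
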