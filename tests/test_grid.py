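"""Lattice generation, point classification and second-layer selection."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from pocketshape.config import ContactParams
from pocketshape.grid import (
    Lattice,
    classify_points,
    generate_pocket_points,
    identify_ccrs,
    select_slr,
)


def test_lattice_matches_bruteforce_scan(toy):
    """Oracle: exhaustive triple loop applying the vdW, trim and
    buriedness tests point by point."""
    cfg = toy.cfg
    flr = set(toy.flr)
    ala = toy.ala
    site = np.array(
        [a.coords for r in ala.residues if r.key in flr for a in r.atoms]
    )
    anchors = np.vstack([site, toy.ensemble.coords()])
    protein = np.array([a.coords for r in ala.residues for a in r.atoms])
    radii = np.array([a.vdw_radius for r in ala.residues for a in r.atoms])
    spacing, trim = cfg.spacing, cfg.trim_cutoff
    lo = np.floor((anchors.min(0) - trim) / spacing).astype(int)
    hi = np.ceil((anchors.max(0) + trim) / spacing).astype(int)

    directions = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1]],
        float,
    )
    n_steps = int(np.ceil(cfg.psp_range / spacing))

    def hits_protein(p):
        d = np.linalg.norm(protein - p, axis=1)
        return np.any(d < radii)

    expected = set()
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                p = spacing * np.array([i, j, k], float)
                if np.min(np.linalg.norm(anchors - p, axis=1)) > trim:
                    continue
                if hits_protein(p):
                    continue
                blocked = 0
                for u in directions:
                    uu = u / np.linalg.norm(u)
                    both = True
                    for sign in (1.0, -1.0):
                        if not any(
                            hits_protein(p + sign * s * spacing * uu)
                            for s in range(1, n_steps + 1)
                        ):
                            both = False
                            break
                    if both:
                        blocked += 1
                if blocked >= cfg.psp_min_directions:
                    expected.add((i, j, k))
    got = {tuple(t) for t in toy.lattice.triples}
    assert got == expected


def test_points_inside_vdw_sphere_are_rejected(toy):
    protein = np.array([a.coords for r in toy.ala.residues for a in r.atoms])
    radii = np.array([a.vdw_radius for r in toy.ala.residues for a in r.atoms])
    tree = cKDTree(protein)
    coords = toy.lattice.coords()
    d, idx = tree.query(coords, k=1)
    assert np.all(d >= radii[idx])


def test_points_respect_trim_cutoff(toy):
    flr = set(toy.flr)
    site = np.array(
        [a.coords for r in toy.ala.residues if r.key in flr for a in r.atoms]
    )
    anchors = np.vstack([site, toy.ensemble.coords()])
    d, _ = cKDTree(anchors).query(toy.lattice.coords(), k=1)
    assert np.all(d <= toy.cfg.trim_cutoff + 1e-9)


def test_lattice_ordering_is_lexicographic_and_stable(toy):
    t = toy.lattice.triples
    as_tuples = [tuple(row) for row in t]
    assert as_tuples == sorted(as_tuples)


def test_shrinking_trim_never_adds_points(toy):
    smaller = generate_pocket_points(
        toy.ala, toy.ensemble, toy.flr, toy.cfg.spacing, trim_cutoff=4.5,
        psp_min=toy.cfg.psp_min_directions, psp_range=toy.cfg.psp_range,
    )
    big = {tuple(t) for t in toy.lattice.triples}
    small = {tuple(t) for t in smaller.triples}
    assert small <= big


def test_classify_points_set_algebra():
    lattice = Lattice(origin=np.zeros(3), spacing=1.0,
                      triples=np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0], [1, 0, 0]]))
    # points {a,b,c,d} = ids {0,1,2,3}; sets {a,b} and {b,c}
    pts = classify_points(lattice, [{0, 1}, {1, 2}])
    assert pts.always_contact.tolist() == [1]
    assert pts.always_free.tolist() == [3]
    assert pts.conditional.tolist() == [0, 2]


def test_single_conformer_has_no_conditional_points():
    lattice = Lattice(origin=np.zeros(3), spacing=1.0,
                      triples=np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]]))
    with pytest.warns(UserWarning, match="no conditional"):
        pts = classify_points(lattice, [{0}])
    assert len(pts.conditional) == 0
    assert pts.always_contact.tolist() == [0]
    assert pts.always_free.tolist() == [1, 2]


def test_classification_partition_exact_and_order_independent(toy):
    pts = toy.points
    n = toy.lattice.n_points
    assert len(pts.always_free) + len(pts.always_contact) + len(pts.conditional) == n
    reversed_pts = classify_points(toy.lattice, list(reversed(toy.contact_sets)))
    assert np.array_equal(reversed_pts.conditional, pts.conditional)
    assert np.array_equal(reversed_pts.always_contact, pts.always_contact)


def test_select_slr_boundary(toy, radii):
    """A residue 2.9 A from a contact point is in; 3.2 A is out."""
    from pocketshape.structure import AtomRecord, ProteinStructure, Residue

    lattice = Lattice(origin=np.zeros(3), spacing=1.0, triples=np.array([[0, 0, 0]]))
    params = ContactParams(cpd=0.5)

    def residue(name, seq, x, atoms=None):
        ats = atoms or [AtomRecord("CB", "C", np.array([x, 0.0, 0.0]), radii["C"])]
        return Residue("A", seq, "", name, ats)

    # the FLR residue touches the single point (|x| < 1.7 + 0.5)
    flr_res = residue("LEU", 1, 1.5)
    near = residue("SER", 2, 2.9)
    far = residue("VAL", 3, 3.2)
    gly = residue("GLY", 4, 2.0)
    st = ProteinStructure("t", [flr_res, near, far, gly])
    slr = select_slr(st, lattice, [flr_res.key], params, cutoff=3.0)
    assert near.key in slr
    assert far.key not in slr
    assert gly.key not in slr  # no chi angles


def test_identify_ccrs_requires_conditional_contact(toy):
    contacts = {
        toy.slr[0]: set(),             # touches only always-X points
        toy.slr[1]: {int(toy.points.conditional[0])},
    }
    assert identify_ccrs(toy.slr[:2], contacts) == [toy.slr[1]]
    # in the full toy system every flexible residue modulates the shape
    per_res = {}
    cond = set(toy.points.conditional.tolist())
    for (key, _idx), pts in toy.contact.items():
        per_res.setdefault(key, set()).update(pts & cond)
    assert identify_ccrs(toy.slr, per_res) == toy.slr
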