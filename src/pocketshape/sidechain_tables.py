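"""Ideal side-chain geometry tables.

Each residue type maps to an ordered list of build steps. A step places one
heavy atom by internal coordinates against three previously placed atoms:

    (atom, element, parent, angle_ref, torsion_ref, bond, angle, torsion)

``torsion`` is either ``("chi", i, offset)`` — the torsion equals chi_i plus
a fixed offset in degrees — or ``("fixed", value)``. Bond lengths and angles
are ideal (Engh/Huber-style) values; branch offsets use ideal tetrahedral
(120) or planar (180) geometry. CHI_DEFS lists the atom quadruples defining
each chi dihedral, used both for building and for measuring.

Backbone connectivity (N-CA, CA-C, C-O, CA-CB) plus the parent bonds below
define the intra-residue bond graph used for 1-2/1-3/1-4 clash exclusions.
"""

from __future__ import annotations

Chi = tuple[str, int, float]     # ("chi", index (1-based), offset degrees)
Fixed = tuple[str, float]        # ("fixed", degrees)


def _chi(i: int, offset: float = 0.0) -> Chi:
    return ("chi", i, offset)


def _fix(value: float) -> Fixed:
    return ("fixed", value)


# atom, element, parent, angle_ref, torsion_ref, bond(A), angle(deg), torsion
SIDECHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "SER": [("OG", "O", "CB", "CA", "N", 1.42, 111.1, _chi(1))],
    "CYS": [("SG", "S", "CB", "CA", "N", 1.81, 114.4, _chi(1))],
    "THR": [
        ("OG1", "O", "CB", "CA", "N", 1.43, 109.6, _chi(1)),
        ("CG2", "C", "CB", "CA", "N", 1.52, 111.5, _chi(1, -120.0)),
    ],
    "VAL": [
        ("CG1", "C", "CB", "CA", "N", 1.52, 110.5, _chi(1)),
        ("CG2", "C", "CB", "CA", "N", 1.52, 110.5, _chi(1, 120.0)),
    ],
    "LEU": [
        ("CG", "C", "CB", "CA", "N", 1.53, 116.3, _chi(1)),
        ("CD1", "C", "CG", "CB", "CA", 1.52, 110.7, _chi(2)),
        ("CD2", "C", "CG", "CB", "CA", 1.52, 110.7, _chi(2, 120.0)),
    ],
    "ILE": [
        ("CG1", "C", "CB", "CA", "N", 1.53, 110.4, _chi(1)),
        ("CG2", "C", "CB", "CA", "N", 1.52, 110.5, _chi(1, -120.0)),
        ("CD1", "C", "CG1", "CB", "CA", 1.51, 113.8, _chi(2)),
    ],
    "ASP": [
        ("CG", "C", "CB", "CA", "N", 1.52, 112.6, _chi(1)),
        ("OD1", "O", "CG", "CB", "CA", 1.25, 118.4, _chi(2)),
        ("OD2", "O", "CG", "CB", "CA", 1.25, 118.4, _chi(2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", "CB", "CA", "N", 1.52, 112.6, _chi(1)),
        ("OD1", "O", "CG", "CB", "CA", 1.23, 120.8, _chi(2)),
        ("ND2", "N", "CG", "CB", "CA", 1.33, 116.4, _chi(2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        ("CD", "C", "CG", "CB", "CA", 1.52, 112.6, _chi(2)),
        ("OE1", "O", "CD", "CG", "CB", 1.25, 118.4, _chi(3)),
        ("OE2", "O", "CD", "CG", "CB", 1.25, 118.4, _chi(3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        ("CD", "C", "CG", "CB", "CA", 1.52, 112.6, _chi(2)),
        ("OE1", "O", "CD", "CG", "CB", 1.23, 120.8, _chi(3)),
        ("NE2", "N", "CD", "CG", "CB", 1.33, 116.4, _chi(3, 180.0)),
    ],
    "MET": [
        ("CG", "C", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        ("SD", "S", "CG", "CB", "CA", 1.81, 112.7, _chi(2)),
        ("CE", "C", "SD", "CG", "CB", 1.79, 100.9, _chi(3)),
    ],
    "LYS": [
        ("CG", "C", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        ("CD", "C", "CG", "CB", "CA", 1.52, 111.3, _chi(2)),
        ("CE", "C", "CD", "CG", "CB", 1.52, 111.3, _chi(3)),
        ("NZ", "N", "CE", "CD", "CG", 1.49, 111.9, _chi(4)),
    ],
    "ARG": [
        ("CG", "C", "CB", "CA", "N", 1.52, 114.1, _chi(1)),
        ("CD", "C", "CG", "CB", "CA", 1.52, 111.3, _chi(2)),
        ("NE", "N", "CD", "CG", "CB", 1.46, 111.8, _chi(3)),
        ("CZ", "C", "NE", "CD", "CG", 1.33, 124.2, _chi(4)),
        ("NH1", "N", "CZ", "NE", "CD", 1.33, 120.0, _fix(0.0)),
        ("NH2", "N", "CZ", "NE", "CD", 1.33, 120.0, _fix(180.0)),
    ],
    "PHE": [
        ("CG", "C", "CB", "CA", "N", 1.50, 113.8, _chi(1)),
        ("CD1", "C", "CG", "CB", "CA", 1.39, 120.8, _chi(2)),
        ("CD2", "C", "CG", "CB", "CA", 1.39, 120.8, _chi(2, 180.0)),
        ("CE1", "C", "CD1", "CG", "CB", 1.39, 120.8, _fix(180.0)),
        ("CE2", "C", "CD2", "CG", "CB", 1.39, 120.8, _fix(180.0)),
        ("CZ", "C", "CE1", "CD1", "CG", 1.39, 120.0, _fix(0.0)),
    ],
    "TYR": [
        ("CG", "C", "CB", "CA", "N", 1.51, 113.9, _chi(1)),
        ("CD1", "C", "CG", "CB", "CA", 1.39, 120.8, _chi(2)),
        ("CD2", "C", "CG", "CB", "CA", 1.39, 120.8, _chi(2, 180.0)),
        ("CE1", "C", "CD1", "CG", "CB", 1.39, 121.2, _fix(180.0)),
        ("CE2", "C", "CD2", "CG", "CB", 1.39, 121.2, _fix(180.0)),
        ("CZ", "C", "CE1", "CD1", "CG", 1.38, 119.6, _fix(0.0)),
        ("OH", "O", "CZ", "CE1", "CD1", 1.38, 119.9, _fix(180.0)),
    ],
    "HIS": [
        ("CG", "C", "CB", "CA", "N", 1.49, 113.8, _chi(1)),
        ("ND1", "N", "CG", "CB", "CA", 1.38, 122.7, _chi(2)),
        ("CD2", "C", "CG", "CB", "CA", 1.36, 131.0, _chi(2, 180.0)),
        ("CE1", "C", "ND1", "CG", "CB", 1.32, 109.0, _fix(180.0)),
        ("NE2", "N", "CD2", "CG", "CB", 1.37, 107.2, _fix(180.0)),
    ],
    "TRP": [
        ("CG", "C", "CB", "CA", "N", 1.50, 113.6, _chi(1)),
        ("CD1", "C", "CG", "CB", "CA", 1.37, 126.9, _chi(2)),
        ("CD2", "C", "CG", "CB", "CA", 1.43, 126.6, _chi(2, 180.0)),
        ("NE1", "N", "CD1", "CG", "CB", 1.38, 110.2, _fix(180.0)),
        ("CE2", "C", "CD2", "CG", "CB", 1.41, 107.2, _fix(180.0)),
        ("CE3", "C", "CD2", "CG", "CD1", 1.40, 133.9, _fix(0.0)),
        ("CZ2", "C", "CE2", "CD2", "CG", 1.40, 122.4, _fix(180.0)),
        ("CZ3", "C", "CE3", "CD2", "CE2", 1.39, 118.6, _fix(180.0)),
        ("CH2", "C", "CZ2", "CE2", "CD2", 1.37, 117.5, _fix(180.0)),
    ],
}

# Atom-name quadruples defining each chi dihedral, in chi order.
CHI_DEFS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
}

CHI_COUNTS: dict[str, int] = {name: len(defs) for name, defs in CHI_DEFS.items()}

# Residue types with no chi angles: never flexible.
RIGID_TYPES = frozenset({"GLY", "ALA"})


def bond_graph(resname: str) -> dict[str, set[str]]:
    """Intra-residue heavy-atom bond graph (backbone + side chain)."""
    adj: dict[str, set[str]] = {}

    def add(a: str, b: str) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    add("N", "CA")
    add("CA", "C")
    add("C", "O")
    if resname != "GLY":
        add("CA", "CB")
    for step in SIDECHAIN_TOPOLOGY.get(resname, []):
        atom, _el, parent = step[0], step[1], step[2]
        add(atom, parent)
    # ring-closure bonds not produced by the build tree
    closures = {
        "PHE": [("CE2", "CZ")],
        "TYR": [("CE2", "CZ")],
        "HIS": [("CE1", "NE2")],
        "TRP": [("NE1", "CE2"), ("CE3", "CZ3"), ("CZ2", "CH2")],
    }
    for a, b in closures.get(resname, []):
        add(a, b)
    return adj


def bond_distances(resname: str) -> dict[str, dict[str, int]]:
    """All-pairs bond-path lengths within one residue (BFS per atom)."""
    adj = bond_graph(resname)
    out: dict[str, dict[str, int]] = {}
    for start in adj:
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[start] = dist
    return out
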