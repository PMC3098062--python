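"""Lattice mapping of the Ala-enlarged binding pocket.

A cubic lattice (default 1.0 A spacing) is laid over the bounding box of
the first-layer residues and the ligand ensemble. A point is retained iff

  (a) it lies outside every protein atom's van der Waals sphere,
  (b) it is buried in the pocket cavity — along at least ``psp_min`` of the
      7 lattice scan directions (3 axes + 4 body diagonals) the ray hits
      protein within ``psp_range`` in *both* senses (a protein-solvent-
      protein event, the classic grid-scan buriedness criterion), and
  (c) it is within ``trim_cutoff`` (default 6 A) of a binding-site-residue
      atom or a ligand-ensemble atom (atom centers).

Points are identified by integer index triples, ordered lexicographically,
so bit positions derived from them are reproducible across runs.

After the conformer ensemble has been scanned, points are partitioned into
always-contact (touched in every conformer), always-free (touched in none)
and conditional (the rest); only conditional points carry shape
information and define the fingerprint bit order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .config import ContactParams
from .structure import LigandEnsemble, ProteinStructure, ResidueKey

# 7 scan directions: 3 axes + 4 body diagonals (integer lattice steps).
SCAN_DIRECTIONS = np.array(
    [
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 1],
        [1, 1, -1],
        [1, -1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


@dataclass
class Lattice:
    origin: np.ndarray            # 3-vector, A
    spacing: float                # A
    triples: np.ndarray           # (n, 3) int array, lexicographically sorted

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        self.origin = np.asarray(self.origin, float)
        self.triples = np.asarray(self.triples, int)

    @property
    def n_points(self) -> int:
        return len(self.triples)

    def coords(self) -> np.ndarray:
        return self.origin[None, :] + self.spacing * self.triples


@dataclass
class PocketPoints:
    """Partition of the retained lattice points by contact behavior.

    Index arrays refer to positions in ``lattice.triples``. ``conditional``
    is kept in lattice order and defines the fingerprint bit order.
    """

    lattice: Lattice
    always_free: np.ndarray
    always_contact: np.ndarray
    conditional: np.ndarray
    ccr_keys: list[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.lattice.n_points
        union = np.concatenate([self.always_free, self.always_contact, self.conditional])
        if len(union) != n or len(np.unique(union)) != n:
            raise ValueError("point classes must partition the lattice exactly")

    def conditional_coords(self) -> np.ndarray:
        return self.lattice.coords()[self.conditional]


def _sort_triples(triples: np.ndarray) -> np.ndarray:
    order = np.lexsort((triples[:, 2], triples[:, 1], triples[:, 0]))
    return triples[order]


def generate_pocket_points(
    structure: ProteinStructure,
    ensemble: LigandEnsemble,
    flr_keys: list[ResidueKey],
    spacing: float = 1.0,
    trim_cutoff: float = 6.0,
    psp_min: int = 4,
    psp_range: float = 8.0,
) -> Lattice:
    """Lattice points mapping the (Ala-enlarged) pocket of ``structure``.

    ``structure`` should be the Ala-substituted template; ``flr_keys``
    identifies the binding-site residues used for the trim test (with the
    ligand ensemble). The origin is snapped to a multiple of ``spacing`` so
    the same inputs always yield the same integer triples.
    """
    flr = set(flr_keys)
    site_coords = [a.coords for r in structure.residues if r.key in flr for a in r.atoms]
    site = np.array(site_coords) if site_coords else np.zeros((0, 3))
    lig = ensemble.coords()
    anchors = np.vstack([c for c in (site, lig) if len(c)])
    if len(anchors) == 0:
        raise ValueError("no binding-site or ligand atoms to anchor the lattice")

    lo = np.floor((anchors.min(axis=0) - trim_cutoff) / spacing).astype(int)
    hi = np.ceil((anchors.max(axis=0) + trim_cutoff) / spacing).astype(int)
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    coords = grid * spacing

    protein_coords = np.array([a.coords for r in structure.residues for a in r.atoms])
    protein_radii = np.array([a.vdw_radius for r in structure.residues for a in r.atoms])
    ptree = cKDTree(protein_coords)
    max_r = float(protein_radii.max())

    # (c) trim: within trim_cutoff of a binding-site or ensemble atom
    atree = cKDTree(anchors)
    d_anchor, _ = atree.query(coords, k=1, distance_upper_bound=trim_cutoff + 1e-9)
    keep = np.isfinite(d_anchor)
    grid, coords = grid[keep], coords[keep]

    # (a) outside every protein atom's vdW sphere
    outside = np.ones(len(coords), dtype=bool)
    for i, neigh in enumerate(ptree.query_ball_point(coords, max_r)):
        for j in neigh:
            if np.linalg.norm(coords[i] - protein_coords[j]) < protein_radii[j]:
                outside[i] = False
                break
    grid, coords = grid[outside], coords[outside]

    # (b) buriedness: protein-solvent-protein count over 7 scan directions
    if len(coords):
        n_steps = int(np.ceil(psp_range / spacing))
        steps = np.arange(1, n_steps + 1)[:, None] * spacing
        blocked_count = np.zeros(len(coords), dtype=int)
        for direction in SCAN_DIRECTIONS:
            u = direction / np.linalg.norm(direction)
            hit = {}
            for sign in (1.0, -1.0):
                samples = coords[:, None, :] + sign * steps[None, :, :] * u[None, None, :]
                flat = samples.reshape(-1, 3)
                # several atoms of different radii can overlap a sample, so
                # check a generous set of near neighbors, not just the nearest
                kq = min(12, len(protein_coords))
                d, idx = ptree.query(flat, k=kq, distance_upper_bound=max_r + 1e-9)
                if kq == 1:
                    d, idx = d[:, None], idx[:, None]
                valid = np.isfinite(d)
                idx_safe = np.where(valid, idx, 0)
                inside = np.any(valid & (d < protein_radii[idx_safe]), axis=1)
                hit[sign] = inside.reshape(len(coords), n_steps).any(axis=1)
            blocked_count += (hit[1.0] & hit[-1.0]).astype(int)
        buried = blocked_count >= psp_min
        grid = grid[buried]

    if len(grid) == 0:
        raise ValueError("no lattice points retained; pocket not found")
    return Lattice(origin=np.zeros(3), spacing=spacing, triples=_sort_triples(grid))


def contact_point_indices(
    atom_coords: np.ndarray,
    atom_radii: np.ndarray,
    point_coords: np.ndarray,
    params: ContactParams,
    tree: cKDTree | None = None,
) -> np.ndarray:
    """Indices of points in contact (d < r_vdw + CPD) with any of the atoms."""
    if tree is None:
        tree = cKDTree(point_coords)
    hit: set[int] = set()
    for xyz, r in zip(np.atleast_2d(atom_coords), np.atleast_1d(atom_radii)):
        # strict inequality: shrink the ball radius by a hair
        hit.update(tree.query_ball_point(xyz, r + params.cpd - 1e-12))
    return np.array(sorted(hit), dtype=int)


def select_slr(
    structure: ProteinStructure,
    lattice: Lattice,
    flr_keys: list[ResidueKey],
    params: ContactParams,
    cutoff: float = 3.0,
) -> list[ResidueKey]:
    """Second-layer residues: within ``cutoff`` of lattice points that
    contact first-layer side chains.

    ``structure`` must be the original template (side chains restored), not
    the Ala form: contact of a point with a first-layer residue is tested
    against the full side chain with the same vdW + CPD rule used for
    fingerprint encoding. Gly and Ala are excluded (no chi angles).
    """
    flr = set(flr_keys)
    point_coords = lattice.coords()
    tree = cKDTree(point_coords)
    flr_atoms = [
        a for r in structure.residues if r.key in flr for a in r.atoms
    ]
    idx = contact_point_indices(
        np.array([a.coords for a in flr_atoms]),
        np.array([a.vdw_radius for a in flr_atoms]),
        point_coords,
        params,
        tree=tree,
    )
    if len(idx) == 0:
        raise ValueError("no lattice points contact the first-layer residues")
    contact_tree = cKDTree(point_coords[idx])
    selected: set[ResidueKey] = set()
    for res in structure.residues:
        if res.name in ("GLY", "ALA"):
            continue
        d, _ = contact_tree.query(res.coords(), k=1)
        if np.min(d) <= cutoff:
            selected.add(res.key)
    if not selected:
        raise ValueError("no second-layer residues found within cutoff")
    return sorted(selected)


def classify_points(lattice: Lattice, contact_sets) -> PocketPoints:
    """Partition lattice points by contact behavior over the conformers.

    ``contact_sets`` is an iterable of per-conformer contacted-point index
    collections. always_contact = intersection over conformers; always_free
    = points in no conformer's set; conditional = the remainder, in lattice
    order. The result is independent of iteration order.
    """
    n = lattice.n_points
    intersection = np.ones(n, dtype=bool)
    union = np.zeros(n, dtype=bool)
    count = 0
    for s in contact_sets:
        mask = np.zeros(n, dtype=bool)
        mask[np.asarray(list(s), dtype=int)] = True
        intersection &= mask
        union |= mask
        count += 1
    if count == 0:
        raise ValueError("at least one conformer contact set is required")
    always_contact = np.flatnonzero(intersection)
    always_free = np.flatnonzero(~union)
    conditional = np.flatnonzero(union & ~intersection)
    if len(conditional) == 0:
        warnings.warn("no conditional points: every conformer has the same shape")
    return PocketPoints(
        lattice=lattice,
        always_free=always_free,
        always_contact=always_contact,
        conditional=conditional,
    )


def identify_ccrs(
    slr_keys: list[ResidueKey],
    per_residue_conditional_contacts: dict[ResidueKey, set[int]],
) -> list[ResidueKey]:
    """Conditional-contact residues: flexible residues at least one of whose
    rotamers touches at least one conditional point."""
    return sorted(
        k for k in slr_keys if per_residue_conditional_contacts.get(k)
    )


def write_points_tsv(points: PocketPoints, path: str | Path) -> None:
    """TSV export: id, i, j, k, x, y, z, class (0 free / 1 conditional / 2 contact)."""
    cls = np.zeros(points.lattice.n_points, dtype=int)
    cls[points.conditional] = 1
    cls[points.always_contact] = 2
    coords = points.lattice.coords()
    lines = ["id\ti\tj\tk\tx\ty\tz\tclass"]
    for pid, (t, xyz) in enumerate(zip(points.lattice.triples, coords)):
        lines.append(
            f"{pid}\t{t[0]}\t{t[1]}\t{t[2]}\t{xyz[0]:.3f}\t{xyz[1]:.3f}\t{xyz[2]:.3f}\t{cls[pid]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_points_pdb(points: PocketPoints, path: str | Path) -> None:
    """Pseudo-atom export: one HETATM per point, B-factor encodes the class."""
    cls = np.zeros(points.lattice.n_points, dtype=int)
    cls[points.conditional] = 1
    cls[points.always_contact] = 2
    coords = points.lattice.coords()
    lines = []
    for pid, xyz in enumerate(coords):
        serial = (pid % 99999) + 1
        lines.append(
            f"HETATM{serial:>5}  O   PNT P{(pid % 9999) + 1:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{float(cls[pid]):6.2f}"
            f"           O"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lattice_tsv(path: str | Path) -> tuple[Lattice, np.ndarray]:
    """Read a points TSV back into a Lattice plus the class vector."""
    rows = Path(path).read_text().splitlines()[1:]
    triples, classes = [], []
    spacing = None
    for row in rows:
        if not row.strip():
            continue
        f = row.split("\t")
        triples.append([int(f[1]), int(f[2]), int(f[3])])
        classes.append(int(f[7]))
        if spacing is None and int(f[1]) != 0:
            spacing = float(f[4]) / int(f[1])
    triples_arr = np.array(triples, int)
    if spacing is None:
        spacing = 1.0
    return (
        Lattice(origin=np.zeros(3), spacing=spacing, triples=triples_arr),
        np.array(classes, int),
    )
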