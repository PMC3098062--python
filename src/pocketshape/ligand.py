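"""Ligand volumes on the pocket lattice and shape-incompatibility scoring.

A ligand's volume is the set of retained lattice points within
r_vdw + CPD of any of its heavy atoms — the same contact rule used for
pocket encoding, on the same lattice. The incompatibility between a ligand
L and a conformer's open pocket P is |L \\ P|: the number of ligand points
sticking out of the volume the pocket leaves open. The open pocket of a
conformer is the union of the always-free points and the conditional
points whose fingerprint bit is off; always-contact points are inside the
pocket wall in every conformer and always count as incompatible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .bitmap import ShapeBitString
from .config import ContactParams
from .grid import Lattice, PocketPoints, contact_point_indices
from .structure import AtomRecord


@dataclass
class LigandVolume:
    ligand_id: str
    point_ids: frozenset[int] = field(default_factory=frozenset)  # lattice point indices

    @property
    def n_points(self) -> int:
        return len(self.point_ids)


def encode_ligand_volume(
    ligand_id: str,
    atoms: list[AtomRecord],
    lattice: Lattice,
    params: ContactParams,
    tree: cKDTree | None = None,
) -> LigandVolume:
    """Mark the retained lattice points occupied by the ligand."""
    idx = contact_point_indices(
        np.array([a.coords for a in atoms]),
        np.array([a.vdw_radius for a in atoms]),
        lattice.coords(),
        params,
        tree=tree,
    )
    if len(idx) == 0:
        warnings.warn(f"ligand {ligand_id} occupies no lattice point (outside the pocket?)")
    return LigandVolume(ligand_id=ligand_id, point_ids=frozenset(int(i) for i in idx))


def open_pocket_ids(points: PocketPoints, string: ShapeBitString) -> frozenset[int]:
    """Lattice point indices left open by a conformer: always-free points
    plus conditional points with the bit off."""
    if string.n_bits != len(points.conditional):
        raise ValueError("bit-string length does not match the conditional point count")
    open_conditional = points.conditional[string.bits == 0]
    return frozenset(int(i) for i in points.always_free) | frozenset(
        int(i) for i in open_conditional
    )


def incompatibility(ligand: LigandVolume, pocket_open: frozenset[int] | set[int]) -> int:
    """|L \\ P|: ligand points outside the open pocket volume."""
    return len(ligand.point_ids - frozenset(pocket_open))


def incompatibility_profile(
    ligands: list[LigandVolume],
    strings: list[ShapeBitString],
    points: PocketPoints,
) -> np.ndarray:
    """Strings-by-ligands matrix of incompatibility counts.

    Computed with bit operations: for each string, the closed-point mask is
    the always-contact set plus the set conditional bits; each cell counts
    the ligand points falling on closed (or unretained) positions.
    """
    n = points.lattice.n_points
    lig_masks = []
    for lig in ligands:
        mask = np.zeros(n, dtype=bool)
        if lig.point_ids:
            mask[np.array(sorted(lig.point_ids), dtype=int)] = True
        lig_masks.append(mask)
    out = np.zeros((len(strings), len(ligands)), dtype=int)
    closed_base = np.zeros(n, dtype=bool)
    closed_base[points.always_contact] = True
    for si, s in enumerate(strings):
        closed = closed_base.copy()
        closed[points.conditional[s.bits == 1]] = True
        for li, lmask in enumerate(lig_masks):
            out[si, li] = int(np.sum(lmask & closed))
    return out
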