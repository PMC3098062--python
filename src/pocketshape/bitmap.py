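"""Bit-string fingerprints of pocket shapes.

Each conformer's pocket shape is a binary vector over the conditional
lattice points (1 = point in contact with a side-chain atom, tested as
d < r_vdw + CPD). Identical strings from different conformers are pruned by
hashing while keeping the conformer <-> string mapping; near-identical
strings can optionally be merged by Hamming distance. Similarity between
two shapes is the Tanimoto coefficient N_AB / (N_A + N_B - N_AB) over set
bits, and 1 - Tanimoto is the clustering dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial import cKDTree

from .config import ContactParams
from .grid import PocketPoints, contact_point_indices
from .rotamers import RotamerPlacement


@dataclass
class ShapeBitString:
    """An ordered bit vector over conditional points plus the conformer ids
    that map to it."""

    bits: np.ndarray                      # uint8 0/1 vector
    conformer_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, np.uint8)

    @property
    def n_bits(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def key(self) -> bytes:
        return np.packbits(self.bits).tobytes()

    def hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstr: str, n_bits: int, conformer_ids: list[int] | None = None) -> "ShapeBitString":
        packed = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
        bits = np.unpackbits(packed)[:n_bits]
        return cls(bits=bits, conformer_ids=conformer_ids or [])


def point_contact(point: np.ndarray, atom, params: ContactParams) -> bool:
    """Contact between a lattice point and an atom: d < r_vdw + CPD."""
    d = float(np.linalg.norm(np.asarray(point, float) - atom.coords))
    return d < atom.vdw_radius + params.cpd


def placement_contacts(
    placements: Iterable[RotamerPlacement],
    point_coords: np.ndarray,
    params: ContactParams,
    tree: cKDTree | None = None,
) -> np.ndarray:
    """Indices of points contacted by any side-chain atom of the placements."""
    atoms = [a for p in placements for a in p.atoms]
    if not atoms:
        return np.array([], dtype=int)
    return contact_point_indices(
        np.array([a.coords for a in atoms]),
        np.array([a.vdw_radius for a in atoms]),
        point_coords,
        params,
        tree=tree,
    )


def encode(
    placements: Iterable[RotamerPlacement],
    points: PocketPoints,
    params: ContactParams,
    tree: cKDTree | None = None,
) -> ShapeBitString:
    """Encode one conformer's shape over the conditional points.

    Bit i is set iff conditional point i is within r_vdw + CPD of at least
    one side-chain atom. A KD-tree over the conditional coordinates makes
    the cost near-linear in atoms; pass ``tree`` to reuse it across
    conformers. Independent of atom iteration order.
    """
    coords = points.conditional_coords()
    bits = np.zeros(len(coords), dtype=np.uint8)
    idx = placement_contacts(placements, coords, params, tree=tree)
    bits[idx] = 1
    return ShapeBitString(bits=bits)


def deduplicate(
    stream: Iterable[tuple[int, ShapeBitString]]
) -> list[ShapeBitString]:
    """Collapse identical bit patterns, merging conformer ids.

    The number of conformers is conserved: the group sizes sum to the
    number of input pairs. Output order is first-seen order.
    """
    table: dict[bytes, ShapeBitString] = {}
    n_bits: int | None = None
    for cid, s in stream:
        if n_bits is None:
            n_bits = s.n_bits
        elif s.n_bits != n_bits:
            raise ValueError(f"bit-string length mismatch: {s.n_bits} != {n_bits}")
        key = s.key()
        if key in table:
            table[key].conformer_ids.append(cid)
        else:
            table[key] = ShapeBitString(bits=s.bits.copy(), conformer_ids=[cid])
    return list(table.values())


def _canonical_order(strings: list[ShapeBitString]) -> list[int]:
    """Descending conformer count, ties by bit pattern (lexicographic)."""
    return sorted(
        range(len(strings)),
        key=lambda i: (-len(strings[i].conformer_ids), strings[i].key()),
    )


def merge_similar(
    strings: list[ShapeBitString],
    threshold_bits: int = 5,
    transitive: bool = False,
) -> list[ShapeBitString]:
    """Merge strings whose Hamming distance is strictly below the threshold.

    Greedy single pass in canonical order: each string joins the first
    existing group whose *representative* (founding string) is < threshold
    bits away, else founds a new group; conformer ids are unioned. With
    ``transitive=True``, single-linkage closure over all pairs < threshold
    is used instead.
    """
    if threshold_bits < 0:
        raise ValueError("threshold must be >= 0")
    if not strings:
        return []
    if threshold_bits == 0:
        return [
            ShapeBitString(bits=s.bits.copy(), conformer_ids=sorted(s.conformer_ids))
            for s in strings
        ]
    order = _canonical_order(strings)
    if transitive:
        mat = np.stack([strings[i].bits for i in order]).astype(np.int16)
        ham = np.abs(mat[:, None, :] - mat[None, :, :]).sum(axis=2)
        parent = list(range(len(order)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                if ham[i, j] < threshold_bits:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[int]] = {}
        for i in range(len(order)):
            groups.setdefault(find(i), []).append(i)
        out = []
        for root in sorted(groups):
            members = groups[root]
            ids = sorted(cid for m in members for cid in strings[order[m]].conformer_ids)
            out.append(ShapeBitString(bits=strings[order[root]].bits.copy(), conformer_ids=ids))
        return out

    reps: list[np.ndarray] = []
    merged: list[ShapeBitString] = []
    for i in order:
        s = strings[i]
        joined = False
        if reps:
            ham = np.abs(np.stack(reps).astype(np.int16) - s.bits.astype(np.int16)).sum(axis=1)
            hits = np.flatnonzero(ham < threshold_bits)
            if len(hits):
                merged[int(hits[0])].conformer_ids.extend(s.conformer_ids)
                joined = True
        if not joined:
            reps.append(s.bits)
            merged.append(ShapeBitString(bits=s.bits.copy(), conformer_ids=list(s.conformer_ids)))
    for g in merged:
        g.conformer_ids = sorted(g.conformer_ids)
    return merged


def tanimoto(a: ShapeBitString, b: ShapeBitString) -> float:
    """Shape-fingerprint Tanimoto: N_AB / (N_A + N_B - N_AB)."""
    if a.n_bits != b.n_bits:
        raise ValueError("bit-string lengths differ")
    na, nb = a.popcount, b.popcount
    if na == 0 and nb == 0:
        warnings.warn("both strings all-zero: identical empty shapes, similarity 1")
        return 1.0
    nab = int(np.sum((a.bits & b.bits)))
    return nab / (na + nb - nab)


def dissimilarity_matrix(strings: list[ShapeBitString]) -> np.ndarray:
    """Symmetric matrix of 1 - Tanimoto with a zero diagonal."""
    if len(strings) < 2:
        raise ValueError("need at least two strings")
    B = np.stack([s.bits for s in strings]).astype(np.int64)
    inter = B @ B.T
    pop = B.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return D


def bit_matrix(strings: list[ShapeBitString]) -> np.ndarray:
    """Strings-by-conditional-points 0/1 matrix."""
    return np.stack([s.bits for s in strings]).astype(np.uint8)


def write_strings_tsv(strings: list[ShapeBitString], path: str | Path) -> None:
    lines = [
        "string_id\thex_bits\tn_bits\tpopcount\tn_conformers\t"
        "representative_conformer\tconformer_ids"
    ]
    for sid, s in enumerate(strings):
        rep = min(s.conformer_ids) if s.conformer_ids else -1
        ids = ",".join(str(c) for c in sorted(s.conformer_ids))
        lines.append(
            f"{sid}\t{s.hex()}\t{s.n_bits}\t{s.popcount}\t{len(s.conformer_ids)}\t{rep}\t{ids}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_strings_tsv(path: str | Path) -> list[ShapeBitString]:
    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        _sid, hexbits, n_bits, _pop, _n, _rep, ids = line.split("\t")
        s = ShapeBitString.from_hex(hexbits, int(n_bits))
        s.conformer_ids = [int(c) for c in ids.split(",") if c]
        out.append(s)
    return out
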