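"""Shape clustering: classical MDS, k-medoids partitioning, two-way
hierarchical clustering of the bit matrix, and attribution of shape
variation to individual pocket residues.

Cluster counts are chosen either explicitly or by maximizing the average
silhouette over a configured range ("auto"); each cluster is represented by
its medoid — the member minimizing mean dissimilarity to the others. The
residue attribution replaces visual inspection of colored ordination plots
with two assertable statistics: the between-rotamer-group variance fraction
(eta squared) of each principal coordinate, and the normalized mutual
information between a residue's rotamer state and the cluster labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import normalized_mutual_info_score, silhouette_score

from .bitmap import ShapeBitString
from .structure import ResidueKey


@dataclass
class ClusterModel:
    labels: np.ndarray                 # cluster id (1..k) per string
    medoids: dict[int, int]            # cluster id -> string index
    embedding: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.medoids)


@dataclass
class KeyResidueReport:
    """Per-residue association scores, ranked by the strongest signal."""

    eta_squared: dict[ResidueKey, np.ndarray]   # residue -> score per PC axis
    nmi: dict[ResidueKey, float]                # residue -> NMI with labels
    ranking: list[ResidueKey] = field(default_factory=list)


def mds_embed(matrix: np.ndarray, dims: int = 3) -> np.ndarray:
    """Classical (metric) multidimensional scaling.

    Double-centers the squared dissimilarities, eigendecomposes, and
    returns the top-``dims`` principal coordinates scaled by the square
    root of the eigenvalue. Axes with non-positive eigenvalues contribute
    zero coordinates. Sign is fixed so each axis's largest-magnitude
    loading is positive, making the embedding fully deterministic.
    """
    D = np.asarray(matrix, float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.all(eigval <= 1e-12):
        warnings.warn("all dissimilarities are zero: embedding collapsed to origin")
        return np.zeros((n, dims))
    X = np.zeros((n, dims))
    for d in range(min(dims, n)):
        if eigval[d] > 1e-12:
            axis = eigvec[:, d] * np.sqrt(eigval[d])
            i = int(np.argmax(np.abs(axis)))
            if axis[i] < 0:
                axis = -axis
            X[:, d] = axis
    return X


def find_medoid(matrix: np.ndarray, members: list[int]) -> int:
    """Member minimizing mean dissimilarity to the other members.

    A singleton cluster returns its only member; ties break to the lowest
    index.
    """
    if not members:
        raise ValueError("empty member set")
    members = sorted(members)
    if len(members) == 1:
        return members[0]
    sub = matrix[np.ix_(members, members)]
    mean_to_others = sub.sum(axis=1) / (len(members) - 1)
    return members[int(np.argmin(mean_to_others))]


def _pam(matrix: np.ndarray, k: int) -> tuple[np.ndarray, list[int]]:
    """Deterministic PAM: greedy BUILD then best-improvement SWAP."""
    n = matrix.shape[0]
    # BUILD: first medoid minimizes total dissimilarity; then greedily add
    # the point giving the largest cost reduction (ties -> lowest index).
    medoids = [int(np.argmin(matrix.sum(axis=1)))]
    while len(medoids) < k:
        current = np.min(matrix[:, medoids], axis=1)
        best_gain, best_i = -np.inf, -1
        for i in range(n):
            if i in medoids:
                continue
            gain = np.sum(np.maximum(current - matrix[:, i], 0.0))
            if gain > best_gain + 1e-12:
                best_gain, best_i = gain, i
        medoids.append(best_i)
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(np.min(matrix[:, meds], axis=1).sum())

    improved = True
    current_cost = cost(medoids)
    while improved:
        improved = False
        best = (current_cost, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1 :])
                c = cost(trial)
                if c < best[0] - 1e-12:
                    best = (c, trial)
        if best[1] is not None:
            medoids = best[1]
            current_cost = best[0]
            improved = True

    # nearest-medoid assignment; a medoid belongs to its own cluster, other
    # ties -> lower medoid index
    d = matrix[:, medoids]
    nearest = np.argmin(d, axis=1)
    for ci, m in enumerate(medoids):
        nearest[m] = ci
    labels = nearest + 1  # cluster ids 1..k in sorted-medoid order
    return labels.astype(int), medoids


def assign_clusters(
    matrix: np.ndarray,
    k: int | str,
    k_range: tuple[int, int] = (2, 15),
) -> ClusterModel:
    """Partition strings by k-medoids on the dissimilarity matrix.

    ``k="auto"`` selects the cluster count maximizing the average
    silhouette over ``k_range`` (ties to the smaller k). Deterministic for
    a given matrix and k.
    """
    n = matrix.shape[0]
    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"k must be an integer or 'auto', got {k!r}")
        best = (-np.inf, None, None)
        for kk in range(max(2, k_range[0]), min(k_range[1], n - 1) + 1):
            labels, medoids = _pam(matrix, kk)
            if len(set(labels.tolist())) < 2:
                continue
            score = silhouette_score(matrix, labels, metric="precomputed")
            if score > best[0] + 1e-12:
                best = (score, labels, medoids)
        if best[1] is None:
            labels, medoids = _pam(matrix, 1)
        else:
            _, labels, medoids = best
    else:
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > n:
            raise ValueError(f"k={k} exceeds the number of strings ({n})")
        labels, medoids = _pam(matrix, k)
    model = ClusterModel(labels=labels, medoids={})
    # re-derive each cluster's medoid from its final membership
    for cid in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == cid).tolist()
        model.medoids[cid] = find_medoid(matrix, members)
    return model


def cluster_bits(bits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative complete-linkage clustering of the bit columns.

    Column-column dissimilarity is 1 - Tanimoto over the strings (a pair of
    all-zero columns counts as identical). Returns the leaf order for
    heat-map export and the scipy linkage matrix.
    """
    B = np.asarray(bits, np.int64)
    if B.shape[1] < 2:
        raise ValueError("need at least two bit columns")
    cols = B.T
    inter = cols @ cols.T
    pop = cols.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = linkage(squareform(D, checks=False), method="complete")
    return np.asarray(leaves_list(Z)), Z


def _eta_squared(values: np.ndarray, groups: np.ndarray) -> float:
    """Between-group variance fraction of a one-way decomposition."""
    total = np.sum((values - values.mean()) ** 2)
    if total <= 1e-300:
        return 0.0
    between = 0.0
    for g in np.unique(groups):
        sub = values[groups == g]
        between += len(sub) * (sub.mean() - values.mean()) ** 2
    return float(between / total)


def key_residue_association(
    strings: list[ShapeBitString],
    conformer_rotamers: dict[int, dict[ResidueKey, int]],
    embedding: np.ndarray,
    labels: np.ndarray,
    residues: list[ResidueKey],
) -> KeyResidueReport:
    """Score how strongly each residue's rotamer state drives shape variation.

    A string's rotamer state is taken from its representative conformer
    (lowest conformer id). For each residue: eta squared of each principal
    coordinate across rotamer-state groups, and normalized mutual
    information between state and cluster label. Residues observed in a
    single state score zero. Ranked by the maximum of all scores.
    """
    states = {}
    for r in residues:
        states[r] = np.array(
            [conformer_rotamers[min(s.conformer_ids)][r] for s in strings]
        )
    eta: dict[ResidueKey, np.ndarray] = {}
    nmi: dict[ResidueKey, float] = {}
    for r in residues:
        g = states[r]
        if len(np.unique(g)) < 2:
            eta[r] = np.zeros(embedding.shape[1])
            nmi[r] = 0.0
            continue
        eta[r] = np.array(
            [_eta_squared(embedding[:, d], g) for d in range(embedding.shape[1])]
        )
        if len(np.unique(labels)) < 2:
            nmi[r] = 0.0
        else:
            nmi[r] = float(normalized_mutual_info_score(g, labels))
    ranking = sorted(
        residues, key=lambda r: (-max(float(np.max(eta[r])), nmi[r]), r)
    )
    return KeyResidueReport(eta_squared=eta, nmi=nmi, ranking=ranking)


def conformer_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain coordinate rmsd between two matched atom sets (no refit —
    conformers share the fixed backbone frame)."""
    a, b = np.asarray(coords_a, float), np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("atom sets must match")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
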