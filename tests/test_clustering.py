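"""MDS closed forms, k-medoids behavior, bit clustering and key-residue
attribution."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pocketshape.bitmap import ShapeBitString, dissimilarity_matrix
from pocketshape.clustering import (
    assign_clusters,
    cluster_bits,
    conformer_rmsd,
    find_medoid,
    key_residue_association,
    mds_embed,
)
from pocketshape.fixtures import make_planted_clusters


def test_mds_two_point_closed_form():
    D = np.array([[0.0, 0.4], [0.4, 0.0]])
    X = mds_embed(D, dims=1)
    assert np.allclose(sorted(X[:, 0]), [-0.2, 0.2], atol=1e-9)


def test_mds_equilateral_three_points():
    d = 0.6
    D = np.full((3, 3), d)
    np.fill_diagonal(D, 0.0)
    X = mds_embed(D, dims=2)
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(X[i] - X[j]) == pytest.approx(d, abs=1e-9)


def test_mds_reconstructs_euclidean_configurations_exactly():
    rng = np.random.default_rng(4)
    Y = rng.normal(size=(8, 3))
    D = np.linalg.norm(Y[:, None, :] - Y[None, :, :], axis=2)
    X = mds_embed(D, dims=3)
    D2 = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    assert np.allclose(D, D2, atol=1e-9)


def test_mds_sign_convention_is_deterministic():
    D = np.array([[0.0, 0.4], [0.4, 0.0]])
    X1, X2 = mds_embed(D, dims=1), mds_embed(D, dims=1)
    assert np.array_equal(X1, X2)
    assert X1[np.argmax(np.abs(X1[:, 0])), 0] > 0


def test_mds_degenerate_all_identical_warns():
    with pytest.warns(UserWarning, match="collapsed"):
        X = mds_embed(np.zeros((4, 4)), dims=3)
    assert np.all(X == 0)


def test_find_medoid_matches_exhaustive_argmin():
    rng = np.random.default_rng(6)
    for _ in range(20):
        n = int(rng.integers(2, 50))
        A = rng.random((n, n))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        members = sorted(rng.choice(n, size=int(rng.integers(1, n + 1)), replace=False).tolist())
        got = find_medoid(D, members)
        best = min(
            members,
            key=lambda i: (sum(D[i, j] for j in members if j != i) / max(len(members) - 1, 1), i),
        )
        assert got == best


def test_find_medoid_singleton_and_tie_rule():
    D = np.array([[0.0, 0.3], [0.3, 0.0]])
    assert find_medoid(D, [1]) == 1
    assert find_medoid(D, [0, 1]) == 0  # symmetric pair: lower id


def test_assign_clusters_extremes():
    strings, _ = make_planted_clusters(12, 40, 3, 1, seed=5)
    D = dissimilarity_matrix(strings)
    one = assign_clusters(D, 1)
    assert set(one.labels.tolist()) == {1}
    each = assign_clusters(D, 12)
    assert len(set(each.labels.tolist())) == 12
    with pytest.raises(ValueError, match="exceeds"):
        assign_clusters(D, 13)
    # determinism
    a = assign_clusters(D, 3)
    b = assign_clusters(D, 3)
    assert np.array_equal(a.labels, b.labels) and a.medoids == b.medoids


def test_assign_clusters_recovers_two_tight_groups():
    strings, labels = make_planted_clusters(30, 60, 2, 2, seed=13)
    D = dissimilarity_matrix(strings)
    model = assign_clusters(D, 2)
    assert adjusted_rand_score(labels, model.labels) == 1.0
    for cid, medoid in model.medoids.items():
        assert model.labels[medoid] == cid


def test_cluster_bits_merges_identical_columns_first():
    bits = np.array(
        [
            [1, 1, 0, 1],
            [1, 1, 1, 0],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
        ],
        np.uint8,
    )
    order, Z = cluster_bits(bits)
    assert sorted(order.tolist()) == [0, 1, 2, 3]
    first_merge = Z[0]
    assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
    assert first_merge[2] == pytest.approx(0.0)


def test_cluster_bits_hand_traced_complete_linkage():
    """4 columns with hand-built distances; verify the merge heights against
    a manual complete-linkage trace."""
    # columns: c0=c1 (distance 0), c2 near them, c3 far from everything
    bits = np.array(
        [
            [1, 1, 1, 0],
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 0, 1],
        ],
        np.uint8,
    )
    cols = bits.T.astype(float)

    def tani(a, b):
        inter = np.sum((a > 0) & (b > 0))
        union = np.sum((a > 0) | (b > 0))
        return inter / union if union else 1.0

    d01 = 1 - tani(cols[0], cols[1])          # 0.0
    d02 = 1 - tani(cols[0], cols[2])          # 1 - 2/3
    d03 = 1 - tani(cols[0], cols[3])          # 1.0
    d23 = 1 - tani(cols[2], cols[3])          # 1.0
    order, Z = cluster_bits(bits)
    heights = Z[:, 2]
    assert heights[0] == pytest.approx(d01)
    assert heights[1] == pytest.approx(max(d02, d02))  # {0,1} joins {2}
    assert heights[2] == pytest.approx(max(d03, d23))  # {0,1,2} joins {3}
    assert len(order) == 4


def test_key_residue_eta_squared_detects_constructed_dependence():
    rng = np.random.default_rng(21)
    n = 60
    r1 = ("A", 1, "")
    r2 = ("A", 2, "")
    rot1 = rng.integers(0, 2, n)
    rot2 = rng.integers(0, 3, n)
    # axis 1 is a deterministic function of residue 1's rotamer; axis 2 of
    # residue 2's; axis 3 is pure noise
    emb = np.column_stack(
        [rot1 * 2.0 - 1.0, rot2 * 1.5, rng.normal(size=n)]
    )
    strings = [ShapeBitString(bits=np.zeros(4, np.uint8), conformer_ids=[i]) for i in range(n)]
    conf_rot = {i: {r1: int(rot1[i]), r2: int(rot2[i])} for i in range(n)}
    labels = rot1 + 1
    report = key_residue_association(strings, conf_rot, emb, labels, [r1, r2])
    assert report.eta_squared[r1][0] == pytest.approx(1.0)
    assert report.eta_squared[r2][1] == pytest.approx(1.0)
    assert report.eta_squared[r1][2] < 0.2
    # the top residue on axis 1 differs from the top on axis 2
    assert report.eta_squared[r1][0] > report.eta_squared[r2][0]
    assert report.eta_squared[r2][1] > report.eta_squared[r1][1]
    # residue 1 drives the labels exactly
    assert report.nmi[r1] == pytest.approx(1.0)


def test_key_residue_nmi_near_zero_for_independent_states():
    """Permutation baseline: states drawn independently of the labels."""
    rng = np.random.default_rng(31)
    n = 1000
    r = ("A", 9, "")
    states = rng.integers(0, 3, n)
    labels = rng.integers(1, 5, n)
    strings = [ShapeBitString(bits=np.zeros(2, np.uint8), conformer_ids=[i]) for i in range(n)]
    conf_rot = {i: {r: int(states[i])} for i in range(n)}
    emb = rng.normal(size=(n, 3))
    report = key_residue_association(strings, conf_rot, emb, labels, [r])
    assert report.nmi[r] < 0.05


def test_single_state_residue_scores_zero():
    r = ("A", 1, "")
    strings = [ShapeBitString(bits=np.zeros(2, np.uint8), conformer_ids=[i]) for i in range(5)]
    conf_rot = {i: {r: 0} for i in range(5)}
    emb = np.arange(15, dtype=float).reshape(5, 3)
    report = key_residue_association(strings, conf_rot, emb, np.array([1, 1, 2, 2, 2]), [r])
    assert np.all(report.eta_squared[r] == 0)
    assert report.nmi[r] == 0.0


def test_conformer_rmsd_basics():
    a = np.zeros((4, 3))
    b = np.zeros((4, 3))
    b[:, 0] = 2.0
    assert conformer_rmsd(a, b) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        conformer_rmsd(a, b[:3])
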