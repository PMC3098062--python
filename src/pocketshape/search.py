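"""Exhaustive enumeration of pairwise clash-free rotamer combinations.

Residue-residue steric interactions are mapped onto a graph: nodes are
flexible residues, an edge is present when at least one rotamer pair of the
two residues clashes, and each edge carries a boolean compatibility matrix
over rotamer indices. Enumeration decomposes the graph into connected
components, solves each by depth-first backtracking with forward checking
(pruning rotamers left without a compatible partner), and combines the
per-component solutions as a Cartesian product. Because there is no energy
model, pruning never discards a feasible assignment: the output is exactly
the set of clash-free conformers.

Ordering is deterministic: residues are visited sorted by key, rotamers by
library index, components by their smallest residue key — so conformer ids
are reproducible across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

from .config import ClashParams
from .rotamers import RotamerPlacement
from .structure import ResidueKey


@dataclass
class InteractionGraph:
    nodes: list[ResidueKey]                       # sorted residue keys
    n_rotamers: dict[ResidueKey, int]             # surviving rotamers per residue
    # (u, v) with u < v -> boolean matrix [rot_u, rot_v], True = compatible
    compat: dict[tuple[ResidueKey, ResidueKey], np.ndarray] = field(default_factory=dict)

    def edges(self) -> list[tuple[ResidueKey, ResidueKey]]:
        return sorted(self.compat)

    def components(self) -> list[list[ResidueKey]]:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.compat)
        comps = [sorted(c) for c in nx.connected_components(g)]
        return sorted(comps, key=lambda c: c[0])


@dataclass
class Conformer:
    """A complete, pairwise-compatible rotamer assignment over all
    flexible residues. ``assignment`` maps residue key -> index into that
    residue's surviving-rotamer list."""

    conformer_id: int
    assignment: dict[ResidueKey, int]


def _pair_compat_matrix(
    placements_u: list[RotamerPlacement],
    placements_v: list[RotamerPlacement],
    params: ClashParams,
) -> np.ndarray:
    """compat[i, j] is True iff rotamer i of u and rotamer j of v do not clash."""
    nu, nv = len(placements_u), len(placements_v)
    compat = np.ones((nu, nv), dtype=bool)
    for i, pu in enumerate(placements_u):
        cu = pu.coords()
        ru = np.array([a.vdw_radius for a in pu.atoms])
        for j, pv in enumerate(placements_v):
            cv = pv.coords()
            rv = np.array([a.vdw_radius for a in pv.atoms])
            d = np.linalg.norm(cu[:, None, :] - cv[None, :, :], axis=2)
            limit = ru[:, None] + rv[None, :] - params.ctd
            if np.any(d < limit):
                compat[i, j] = False
    return compat


def build_interaction_graph(
    placements: dict[ResidueKey, list[RotamerPlacement]], params: ClashParams
) -> InteractionGraph:
    """Pairwise rotamer-compatibility graph over the flexible residues.

    Residue pairs whose side-chain atom sets can never come within clash
    range (bounding-sphere test) are skipped without computing the matrix.
    """
    nodes = sorted(placements)
    graph = InteractionGraph(
        nodes=nodes, n_rotamers={k: len(v) for k, v in placements.items()}
    )
    max_r = 2.0  # conservative atom radius bound for the bounding-sphere skip
    for u, v in itertools.combinations(nodes, 2):
        all_u = np.concatenate([p.coords() for p in placements[u]])
        all_v = np.concatenate([p.coords() for p in placements[v]])
        cu, cv = all_u.mean(axis=0), all_v.mean(axis=0)
        span_u = np.max(np.linalg.norm(all_u - cu, axis=1))
        span_v = np.max(np.linalg.norm(all_v - cv, axis=1))
        if np.linalg.norm(cu - cv) - span_u - span_v > 2 * max_r:
            continue
        compat = _pair_compat_matrix(placements[u], placements[v], params)
        if not compat.all():
            graph.compat[(u, v)] = compat
    return graph


def _component_solutions(
    graph: InteractionGraph, component: list[ResidueKey]
) -> Iterator[dict[ResidueKey, int]]:
    """Backtracking with forward checking over one connected component."""
    order = sorted(component)
    n = len(order)
    # neighbor constraints as (position, matrix oriented [me, other])
    constraints: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n)]
    pos = {k: i for i, k in enumerate(order)}
    for (u, v), m in graph.compat.items():
        if u in pos and v in pos:
            constraints[pos[u]].append((pos[v], m))
            constraints[pos[v]].append((pos[u], m.T))

    domains = [np.ones(graph.n_rotamers[k], dtype=bool) for k in order]
    assignment = [0] * n

    def backtrack(i: int, doms: list[np.ndarray]) -> Iterator[dict[ResidueKey, int]]:
        if i == n:
            yield {order[j]: assignment[j] for j in range(n)}
            return
        for r in np.flatnonzero(doms[i]):
            new_doms = doms
            feasible = True
            updated: list[np.ndarray] | None = None
            for j, m in constraints[i]:
                if j <= i:
                    continue
                allowed = m[r]  # partners of rotamer r in residue j's index space
                narrowed = doms[j] & allowed
                if not narrowed.any():
                    feasible = False
                    break
                if updated is None:
                    updated = list(new_doms)
                updated[j] = narrowed
            if not feasible:
                continue
            assignment[i] = int(r)
            yield from backtrack(i + 1, updated if updated is not None else doms)

    yield from backtrack(0, domains)


def enumerate_conformers(graph: InteractionGraph) -> Iterator[Conformer]:
    """Yield every pairwise clash-free complete assignment, lazily.

    Components are solved independently and combined as a Cartesian
    product. A component admitting no solution is a hard error naming its
    residues. Conformer ids follow the deterministic enumeration order.
    """
    components = graph.components()
    solution_lists: list[list[dict[ResidueKey, int]]] = []
    for comp in components:
        sols = list(_component_solutions(graph, comp))
        if not sols:
            raise ValueError(
                f"no clash-free rotamer combination for residues {comp}; "
                "the pocket admits no conformer"
            )
        solution_lists.append(sols)
    for cid, parts in enumerate(itertools.product(*solution_lists)):
        assignment: dict[ResidueKey, int] = {}
        for part in parts:
            assignment.update(part)
        yield Conformer(conformer_id=cid, assignment=assignment)


def count_conformers(graph: InteractionGraph) -> int:
    """Number of clash-free conformers, by per-component counting.

    Equals ``len(list(enumerate_conformers(graph)))`` without materializing
    cross-component products.
    """
    total = 1
    for comp in graph.components():
        total *= sum(1 for _ in _component_solutions(graph, comp))
    return total
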