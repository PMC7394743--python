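"""Spanning-tree backbone of a functional connectivity matrix.

Following the brain-network MST literature, the "minimum spanning tree" is
formally a *maximum* spanning tree over the strictly positive correlations:
edges are ranked by correlation, the strongest is placed first, and edges
that would close a loop are skipped (Kruskal's algorithm with union-find)
until all regions are connected by n-1 edges.  Negative and zero
correlations are treated as absent edges; if the positive-correlation graph
is disconnected the subject is not analyzable under this rule and an error
lists the components.

Three global metrics are computed on the tree:

* strength — mean edge weight (mean correlation of the backbone);
* diameter — number of edges between the two most remote nodes (lower =
  more efficiently organized network);
* leaf fraction — proportion of nodes with degree one (higher = more
  integrated, star-like topology).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "SpanningTree",
    "DisconnectedGraphError",
    "kruskal_mst",
    "global_strength",
    "diameter",
    "leaf_fraction",
    "tree_outcomes",
]


class DisconnectedGraphError(ValueError):
    """The strictly-positive-correlation graph does not span all regions."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        super().__init__(
            f"positive-correlation graph is disconnected: "
            f"{len(self.components)} components "
            f"(sizes {[len(c) for c in self.components]})"
        )


@dataclass
class SpanningTree:
    """A maximum spanning tree: n-1 positive-weight edges, no cycles.

    ``edges`` is (n-1, 2) node indices (0-based positions into
    ``region_ids``); ``weights`` the matching correlations.
    """

    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray
    region_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.edges.shape[0] != self.n_nodes - 1:
            raise ValueError("a spanning tree on n nodes has exactly n-1 edges")
        if self.weights.shape != (self.n_nodes - 1,):
            raise ValueError("one weight per edge required")
        if np.any(self.weights <= 0):
            raise ValueError("all spanning-tree weights must be positive")

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(int(j))
            adj[j].append(int(i))
        return adj


def _find(parent: np.ndarray, x: int) -> int:
    # path halving
    while parent[x] != x:
        parent[x] = parent[parent[x]]
        x = parent[x]
    return x


def kruskal_mst(matrix: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Maximum spanning tree of the strictly positive correlations.

    Edges are considered in descending weight order (ties broken by
    lexicographic (i, j) order for reproducibility); an edge closing a loop
    is discarded.  Raises :class:`DisconnectedGraphError` when the positive
    graph does not connect all regions.
    """
    if isinstance(matrix, ConnectivityMatrix):
        W = matrix.values
        region_ids = matrix.region_ids
    else:
        W = np.asarray(matrix, dtype=float)
        region_ids = None
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")

    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    pos = w > 0.0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    ei = iu[order].tolist()
    ej = ju[order].tolist()
    ew = w[order].tolist()

    parent = list(range(n))
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    target = n - 1
    for a, b, wt in zip(ei, ej, ew):
        ra = a
        while parent[ra] != ra:  # find with path halving
            parent[ra] = parent[parent[ra]]
            ra = parent[ra]
        rb = b
        while parent[rb] != rb:
            parent[rb] = parent[parent[rb]]
            rb = parent[rb]
        if ra == rb:
            continue  # would close a loop
        parent[rb] = ra
        edges.append((a, b))
        weights.append(wt)
        if len(edges) == target:
            break
    if len(edges) < target:
        comps: dict[int, list[int]] = {}
        for x in range(n):
            comps.setdefault(_find(np.asarray(parent), x), []).append(x)
        raise DisconnectedGraphError(comps.values())
    return SpanningTree(n_nodes=n, edges=np.array(edges),
                        weights=np.array(weights), region_ids=region_ids)


def global_strength(tree: SpanningTree) -> float:
    """Mean edge weight of the tree (global connectivity strength)."""
    return float(tree.weights.mean())


def _bfs_farthest(adj: list[list[int]], start: int) -> tuple[int, int]:
    """(farthest node, distance in edges) from ``start`` by BFS."""
    dist = [-1] * len(adj)
    dist[start] = 0
    q = deque([start])
    far, fard = start, 0
    while q:
        u = q.popleft()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                if dist[v] > fard:
                    far, fard = v, dist[v]
                q.append(v)
    return far, fard


def diameter(tree: SpanningTree, normalized: bool = False) -> int | float:
    """Edge count between the two most remote nodes (double BFS).

    With ``normalized=True`` the count is divided by n - 1 (the path
    maximum); the unnormalized count is the default and the reported form.
    """
    adj = tree.adjacency_lists()
    u, _ = _bfs_farthest(adj, 0)
    _, d = _bfs_farthest(adj, u)
    return d / (tree.n_nodes - 1) if normalized else int(d)


def leaf_fraction(tree: SpanningTree) -> float:
    """Proportion of nodes with degree one."""
    if tree.n_nodes < 2:
        raise ValueError("leaf fraction needs at least 2 nodes")
    return float((tree.degrees == 1).sum() / tree.n_nodes)


def tree_outcomes(matrix: ConnectivityMatrix | np.ndarray) -> dict[str, float]:
    """Strength, diameter and leaf fraction of the tree of ``matrix``."""
    t = kruskal_mst(matrix)
    return {
        "strength": global_strength(t),
        "diameter": float(diameter(t)),
        "leaf_fraction": leaf_fraction(t),
    }
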