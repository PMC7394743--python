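"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: exhaustive
spanning-tree enumeration, greedy Prim growth, all-pairs BFS, and a literal
step-up FDR transcription.
"""

import itertools

import numpy as np


def enumerate_max_spanning_tree(W):
    """Exhaustive maximum-weight spanning tree over positive edges (n <= 7)."""
    n = W.shape[0]
    edges = [(i, j, W[i, j]) for i in range(n) for j in range(i + 1, n)
             if W[i, j] > 0]
    best, best_w = None, -np.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j, _ in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if not ok:
            continue
        total = sum(w for _, _, w in combo)
        if total > best_w:
            best_w, best = total, {frozenset((i, j)) for i, j, _ in combo}
    return best, best_w


def prim_max_spanning_tree(W):
    """Prim-style maximum spanning tree (greedy frontier growth)."""
    n = W.shape[0]
    Wp = np.where(W > 0, W, -np.inf)
    np.fill_diagonal(Wp, -np.inf)
    in_tree = {0}
    edges = set()
    while len(in_tree) < n:
        best, bw = None, -np.inf
        for u in in_tree:
            for v in range(n):
                if v not in in_tree and Wp[u, v] > bw:
                    best, bw = (u, v), Wp[u, v]
        if best is None:
            raise ValueError("disconnected")
        edges.add(frozenset(best))
        in_tree.add(best[1])
    return edges


def bfs_all_pairs_diameter(adj):
    """Longest shortest path (in edges) by BFS from every node."""
    best = 0
    for s in range(len(adj)):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        best = max(best, max(dist.values()))
    return best


def stepup_fdr_oracle(p):
    """Literal Benjamini-Hochberg step-up transcription (loop form)."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def random_connected_positive(rng, n):
    """Random symmetric matrix whose positive part spans all nodes."""
    while True:
        W = np.round(rng.uniform(-1, 1, (n, n)), 6)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        # connectivity of the positive graph via simple BFS
        adj = [[j for j in range(n)
                if j != i and W[i, j] > 0] for i in range(n)]
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) == n:
            return W
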