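"""Independent reference implementations used only as test oracles.

Each oracle is written as a different algorithmic formulation from the code
it checks: local alignment as best-global-over-all-substring-pairs (and a
plain three-matrix DP), cluster detection as connected components of an
adjacency graph, monophyly as edge-removal bipartition enumeration.
"""

from __future__ import annotations

from functools import lru_cache

import networkx as nx
from Bio.Align import substitution_matrices

B62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11  # gap of length k costs GAP_OPEN + k * GAP_EXTEND
GAP_EXTEND = 1


def sw_score_dp(a: str, b: str) -> float:
    """Plain three-matrix affine Smith–Waterman, floored at zero."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = float(B62[a[i - 1], b[j - 1]])
            M[i][j] = sub + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - GAP_OPEN - GAP_EXTEND, X[i - 1][j] - GAP_EXTEND
            )
            Y[i][j] = max(
                M[i][j - 1] - GAP_OPEN - GAP_EXTEND, Y[i][j - 1] - GAP_EXTEND
            )
            best = max(best, M[i][j])
    return best


def sw_score_exhaustive(a: str, b: str) -> float:
    """Local score as the best affine global score over every substring pair
    (including the empty pair, score 0). Exponential-free but exhaustive in
    the substring choice; for tiny inputs only."""

    def global_affine(x: str, y: str) -> float:
        @lru_cache(maxsize=None)
        def rec(i: int, j: int, state: int) -> float:
            if i == len(x) and j == len(y):
                return 0.0
            cands = []
            if i < len(x) and j < len(y):
                cands.append(float(B62[x[i], y[j]]) + rec(i + 1, j + 1, 0))
            if i < len(x):
                cost = GAP_EXTEND if state == 1 else GAP_OPEN + GAP_EXTEND
                cands.append(-cost + rec(i + 1, j, 1))
            if j < len(y):
                cost = GAP_EXTEND if state == 2 else GAP_OPEN + GAP_EXTEND
                cands.append(-cost + rec(i, j + 1, 2))
            return max(cands)

        return rec(0, 0, 0)

    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_affine(a[i1:i2], b[j1:j2]))
    return best


def clusters_by_components(
    assigned_indices: list[int], max_gap: int
) -> list[list[int]]:
    """Cluster membership as connected components of the graph joining
    consecutive assigned positions with <= max_gap intervening genes."""
    g = nx.Graph()
    g.add_nodes_from(assigned_indices)
    ordered = sorted(assigned_indices)
    for u, v in zip(ordered, ordered[1:]):
        if v - u - 1 <= max_gap:
            g.add_edge(u, v)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def monophyly_by_edge_removal(tree, subset: set[str]) -> bool:
    """Monophyly via explicit edge removal on the tree graph: the subset is
    monophyletic iff removing some edge leaves it exactly as the leaf set of
    one component."""
    g = nx.Graph()
    ids = {}

    def node_id(n):
        if id(n) not in ids:
            ids[id(n)] = len(ids)
        return ids[id(n)]

    leaves = {}
    for node in tree.traverse(include_self=True):
        nid = node_id(node)
        if node.is_tip():
            leaves[nid] = node.name
        for child in node.children:
            g.add_edge(nid, node_id(child))
    all_leaves = set(leaves.values())
    if subset in ({l} for l in all_leaves) or subset == all_leaves:
        return True
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        for comp in nx.connected_components(g):
            side = {leaves[n] for n in comp if n in leaves}
            if side == subset:
                g.add_edge(u, v)
                return True
        g.add_edge(u, v)
    return False


def random_additive_tree(rng, n_leaves: int):
    """Random binary topology with random branch lengths; returns (skbio
    TreeNode, labels, path-length matrix) built by successive leaf
    attachment on a networkx graph, with distances from shortest paths."""
    import numpy as np
    from skbio import TreeNode

    labels = [f"t{i}" for i in range(n_leaves)]
    # build newick by random coalescence
    nodes = [(lab, None) for lab in labels]
    subtrees = {lab: lab for lab in labels}
    active = list(labels)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        name = f"({subtrees[a]}:{la:.6f},{subtrees[b]}:{lb:.6f})"
        key = a + b
        subtrees[key] = name
        active = [x for x in active if x not in (a, b)] + [key]
    la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
    newick = f"({subtrees[active[0]]}:{la:.6f},{subtrees[active[1]]}:{lb:.6f});"
    tree = TreeNode.read([newick])
    D = np.zeros((n_leaves, n_leaves))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            D[i, j] = D[j, i] = tips[labels[i]].distance(tips[labels[j]])
    return tree, labels, D
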