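"""Independent reference implementations used to cross-check the package.

These are deliberately written in the most transparent style possible
(plain Python loops, no numpy, no shared code with the package) so they can
serve as oracles: a cell-by-cell Gotoh local-alignment DP, a regex
translation of degenerate motifs, and a random additive-tree generator for
the neighbor-joining consistency check.
"""

from __future__ import annotations

import re

NEG = float("-inf")


def brute_force_local_score(column_scores, gap_open, gap_extend, seq_codes) -> float:
    """Cell-by-cell affine-gap local alignment score.

    ``column_scores[j][c]`` is the score of residue code ``c`` at profile
    column ``j``; a gap of length L costs ``gap_open + (L-1)*gap_extend``.
    """
    n = len(seq_codes)
    m = len(column_scores)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = prev + column_scores[j - 1][seq_codes[i - 1]]
            X[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_extend)
            Y[i][j] = max(M[i - 1][j] - gap_open, Y[i - 1][j] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def pattern_to_regex(pattern) -> re.Pattern:
    """Translate a MotifPattern into a regex over residue windows.

    Wildcards become ``.`` (accepting anything including X); allowed sets
    become character classes, which naturally reject X.
    """
    parts = []
    for el in pattern.elements:
        if el is None:
            parts.append(".")
        else:
            parts.append("[" + "".join(sorted(el)) + "]")
    return re.compile("".join(parts))


# ---------------------------------------------------------------------------
# random additive trees for the NJ consistency check

def random_additive_instance(rng, n_leaves, min_len=0.05, max_len=1.0):
    """A random unrooted binary tree and its additive leaf distance matrix.

    Returns (taxa, distance dict, true splits) where splits are the
    non-trivial bipartitions as frozensets of frozensets of labels.
    """
    # adjacency: node -> {neighbor: branch length}
    adj: dict[int, dict[int, float]] = {}

    def add_edge(u, v, ln):
        adj.setdefault(u, {})[v] = ln
        adj.setdefault(v, {})[u] = ln

    def del_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    def rand_len():
        return float(min_len + (max_len - min_len) * rng.random())

    leaves = [0, 1, 2]
    center = 3
    next_id = 4
    for leaf in leaves:
        add_edge(leaf, center, rand_len())
    while len(leaves) < n_leaves:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        old = adj[u][v]
        mid = next_id
        next_id += 1
        del_edge(u, v)
        split = old * float(rng.random())
        add_edge(u, mid, split)
        add_edge(mid, v, old - split)
        leaf = next_id
        next_id += 1
        add_edge(leaf, mid, rand_len())
        leaves.append(leaf)
    taxa = [f"t{i:02d}" for i in range(len(leaves))]
    label = dict(zip(leaves, taxa))

    def distances_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        return dist

    dmat: dict[tuple[str, str], float] = {}
    for leaf in leaves:
        d = distances_from(leaf)
        for other in leaves:
            dmat[(label[leaf], label[other])] = d[other]

    # splits: remove each internal edge, collect leaf labels on one side
    all_labels = frozenset(taxa)
    splits = set()
    for u in adj:
        for v in adj[u]:
            if u < v and u not in leaves and v not in leaves:
                side = set()
                stack = [u]
                seen = {u, v}
                while stack:
                    w = stack.pop()
                    if w in leaves:
                        side.add(label[w])
                    for x in adj[w]:
                        if x not in seen:
                            seen.add(x)
                            stack.append(x)
                a = frozenset(side)
                splits.add(frozenset({a, all_labels - a}))
    return taxa, dmat, splits


def tree_splits(phylo_tree):
    """Non-trivial bipartitions of a PhyloTree (unrooted comparison form)."""
    all_labels = frozenset(phylo_tree.leaf_labels())
    splits = set()
    for node in phylo_tree.dtree.preorder_node_iter():
        if node is phylo_tree.dtree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 2 <= len(below) <= len(all_labels) - 2:
            splits.add(frozenset({below, all_labels - below}))
    return splits


def tree_leaf_distances(phylo_tree):
    """Pairwise leaf path-length distances of a PhyloTree."""
    adj: dict[object, dict[object, float]] = {}
    for node in phylo_tree.dtree.preorder_node_iter():
        for child in node.child_nodes():
            ln = child.edge.length or 0.0
            adj.setdefault(node, {})[child] = ln
            adj.setdefault(child, {})[node] = ln
    leaves = list(phylo_tree.dtree.leaf_node_iter())
    out: dict[tuple[str, str], float] = {}
    for src in leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj.get(u, {}).items():
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for dst in leaves:
            out[(src.taxon.label, dst.taxon.label)] = dist[dst]
    return out
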