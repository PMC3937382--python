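"""Distance-based trees and clade logic.

Neighbor joining over p- or Poisson-corrected distances serves as the
desk-scale surrogate for likelihood/Bayesian tree inference: the only
downstream consumers are clade questions (is the candidate lineage
monophyletic, what is its sister group?), which are agnostic to how the
tree was inferred.  NJ is exact on additive distance matrices, which is the
regime the tests certify.

Trees are dendropy ``Tree`` objects wrapped in :class:`PhyloTree`; newick
reading/writing goes through dendropy.  The NJ pair selection is
deterministic: lowest Q, ties broken by the lexicographically smallest
(label, label) pair, where a cluster is labelled by its smallest leaf.
Negative estimated branch lengths are clamped to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
import numpy as np

from .errors import ParseError, ValidationError
from .io_formats import GAP, Msa

DistanceModel = Literal["p-distance", "poisson"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered taxon list."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValidationError("taxa labels must be unique")
        if self.values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("distances must be finite and nonnegative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


class PhyloTree:
    """A tree over uniquely labelled leaves with nonnegative branch lengths."""

    def __init__(self, dtree: dendropy.Tree):
        self.dtree = dtree
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate leaf labels in tree")
        for edge in dtree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            elif edge.length < 0:
                raise ValidationError("branch lengths must be nonnegative")

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.dtree.leaf_node_iter()]

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.dtree.preorder_edge_iter())

    def newick(self) -> str:
        return self.dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree({self.newick()})"


def pairwise_distances(msa: Msa, model: DistanceModel = "p-distance") -> DistanceMatrix:
    """p-distance or Poisson-corrected distance between all row pairs.

    Shared columns are those where both rows carry a standard residue
    (gaps and ``X`` excluded).  Errors: no shared columns (pair named), or
    p = 1 under the Poisson model (advice: use p-distance).
    """
    if model not in ("p-distance", "poisson"):
        raise ValidationError(f"unknown distance model {model!r}")
    ids = msa.ids()
    n = len(ids)
    arr = np.array([[ch for ch in aligned] for _, aligned in msa.rows])
    usable = (arr != GAP) & (arr != "X")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = usable[i] & usable[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValidationError(f"no shared non-gap columns between {ids[i]!r} and {ids[j]!r}")
            p = float((arr[i, shared] != arr[j, shared]).sum()) / n_shared
            if model == "poisson":
                if p >= 1.0:
                    raise ValidationError(
                        f"p = 1 between {ids[i]!r} and {ids[j]!r}: Poisson correction "
                        "undefined, use p-distance"
                    )
                dist = -math.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=list(ids), values=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with the standard Q-criterion.

    Deterministic: the joined pair minimises Q, ties broken by sorted
    cluster labels; negative branch-length estimates are clamped to 0.
    Exact (topology and branch lengths) on additive matrices.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    ns = dendropy.TaxonNamespace(sorted(dm.taxa))
    nodes: dict[int, dendropy.Node] = {}
    labels: dict[int, str] = {}  # cluster key = smallest leaf label, for tie-breaks
    for k, taxon_label in enumerate(dm.taxa):
        node = dendropy.Node(taxon=ns.get_taxon(taxon_label))
        nodes[k] = node
        labels[k] = taxon_label
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.values[i, j])

    def dist(i: int, j: int) -> float:
        return D[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - row_sum[i] - row_sum[j]
                tie = tuple(sorted((labels[i], labels[j])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        assert best is not None
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (row_sum[i] - row_sum[j]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        child_i, child_j = nodes[i], nodes[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = li
        child_j.edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        labels[u] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            D[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree)


def _leafset_below(node: dendropy.Node) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root at the midpoint of the edge separating the outgroup.

    The outgroup must be a nonempty proper subset of the taxa, separable
    from the rest by a single edge (monophyletic in the unrooted sense).
    """
    og = frozenset(outgroup)
    all_taxa = frozenset(tree.leaf_labels())
    if not og:
        raise ValidationError("outgroup must be nonempty")
    if not og < all_taxa:
        raise ValidationError("outgroup must be a proper subset of the tree's taxa")
    clone = dendropy.Tree(tree.dtree)  # operate on a copy
    target = None
    for edge in clone.preorder_edge_iter():
        if edge.head_node is clone.seed_node:
            continue
        below = _leafset_below(edge.head_node)
        if below == og or (all_taxa - below) == og:
            target = edge
            break
    if target is None:
        raise ValidationError(f"outgroup {sorted(og)} is not separable by a single edge")
    half = (target.length or 0.0) / 2.0
    clone.reroot_at_edge(target, length1=half, length2=half, suppress_unifurcations=True)
    clone.is_rooted = True
    return PhyloTree(clone)


def is_monophyletic(tree: PhyloTree, taxa: Iterable[str]) -> bool:
    """True iff ``taxa`` is exactly the leaf set of some clade of the rooted tree."""
    target = frozenset(taxa)
    leaves = frozenset(tree.leaf_labels())
    if not target or not target <= leaves:
        raise ValidationError("taxa must be a nonempty subset of the tree's leaves")
    if len(target) == 1:
        return True
    mrca = tree.dtree.mrca(taxon_labels=list(target))
    return _leafset_below(mrca) == target


def sister_group(tree: PhyloTree, taxa: Iterable[str]) -> frozenset:
    """Leaves of the clade adjacent to the (monophyletic) ``taxa`` clade."""
    target = frozenset(taxa)
    if not is_monophyletic(tree, target):
        raise ValidationError(f"{sorted(target)} is not monophyletic; no sister group")
    if len(target) == 1:
        node = next(
            leaf for leaf in tree.dtree.leaf_node_iter() if leaf.taxon.label in target
        )
    else:
        node = tree.dtree.mrca(taxon_labels=list(target))
    parent = node.parent_node
    if parent is None:
        raise ValidationError("clade is the entire tree; no sister group")
    sisters: set[str] = set()
    for child in parent.child_nodes():
        if child is not node:
            sisters.update(_leafset_below(child))
    return frozenset(sisters)


def read_newick(path: str | Path) -> PhyloTree:
    """Read a newick tree; missing branch lengths default to 0."""
    text = Path(path).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: invalid newick: {exc}") from exc
    return PhyloTree(dtree)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write newick with branch lengths to 6 decimals."""
    text = tree.dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        preserve_spaces=True,
    )
    Path(path).write_text(text)


def benchmark_clade_report(
    tree: PhyloTree,
    candidate: Sequence[str],
    outgroup: Sequence[str],
    reference_groups: dict[str, Sequence[str]] | None = None,
) -> dict:
    """Root by the outgroup, test candidate monophyly and identify its sister.

    Returns a JSON-ready dict; ``sister_matches`` names the reference group
    whose leaf set equals the sister clade, if any.
    """
    rooted = root_with_outgroup(tree, outgroup)
    mono = is_monophyletic(rooted, candidate)
    report: dict = {
        "schema": "kinscan-clade/1",
        "candidate_monophyletic": mono,
        "sister_group": None,
        "sister_matches": None,
    }
    if mono:
        sisters = sister_group(rooted, candidate)
        report["sister_group"] = sorted(sisters)
        if reference_groups:
            for gname, members in reference_groups.items():
                if frozenset(members) == sisters:
                    report["sister_matches"] = gname
                    break
    return report
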