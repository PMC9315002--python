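"""Rooted phylogenies: Newick/Nexus I/O, consensus, depths, MRCA.

Wraps :mod:`dendropy` trees with the small query surface the comparative
analyses need (node depths from the root, MRCA lookup, phylogenetic
covariance), plus a majority-rule consensus over a tree sample with edge
lengths fitted by least squares to the mean patristic distances.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.optimize import nnls

__all__ = ["Phylogeny", "majority_consensus", "least_squares_edge_lengths",
           "split_frequencies"]


class Phylogeny:
    """A rooted tree with unique tip labels and nonnegative branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length: {edge.length}")
        tree.is_rooted = True
        self.tree = tree
        self.tip_labels: list[str] = sorted(labels)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, text: str,
                    taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> "Phylogeny":
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 taxon_namespace=taxon_namespace,
                                 preserve_underscores=True)
        return cls(tree)

    @classmethod
    def from_path(cls, path: str | Path, schema: str | None = None) -> "Phylogeny":
        path = Path(path)
        schema = schema or ("nexus" if path.suffix.lower() in
                            {".nex", ".nexus", ".trees"} else "newick")
        tree = dendropy.Tree.get(path=str(path), schema=schema,
                                 preserve_underscores=True)
        return cls(tree)

    @classmethod
    def read_sample(cls, path: str | Path, schema: str | None = None
                    ) -> list["Phylogeny"]:
        """Read a multi-tree file (Newick one-per-line, or a Nexus trees
        block) into a list of phylogenies on a shared taxon namespace."""
        path = Path(path)
        schema = schema or ("nexus" if path.suffix.lower() in
                            {".nex", ".nexus", ".trees"} else "newick")
        tl = dendropy.TreeList.get(path=str(path), schema=schema,
                                   preserve_underscores=True)
        return [cls(t) for t in tl]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    # -------------------------------------------------------------- queries
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Summed branch length from the root to every node (root depth 0)."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {leaf.taxon.label: depths[leaf]
                for leaf in self.tree.leaf_node_iter()}

    def max_depth(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    def mrca(self, tip_labels: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of the named tips."""
        labels = list(tip_labels)
        unknown = set(labels) - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tip name(s): {sorted(unknown)}")
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:
            raise ValueError("no common ancestor found")
        return node

    def vcv(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Phylogenetic covariance: shared root-to-MRCA path lengths.

        Entry (i, j) is the depth of the MRCA of tips i and j; the diagonal
        holds tip depths. Rows/columns follow ``order`` (default: sorted
        tip labels).
        """
        order = list(order) if order is not None else self.tip_labels
        idx = {lab: k for k, lab in enumerate(order)}
        unknown = set(order) - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tip name(s): {sorted(unknown)}")
        n = len(order)
        V = np.zeros((n, n))
        depths = self.node_depths()
        # postorder accumulation of tip sets; MRCA depth fills each block
        tipsets: dict[dendropy.Node, list[int]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                tipsets[node] = [idx[lab]] if lab in idx else []
                if lab in idx:
                    V[idx[lab], idx[lab]] = depths[node]
            else:
                kids = [tipsets.pop(c) for c in node.child_nodes()]
                d = depths[node]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            V[i, kids[b]] = d
                            V[kids[b], i] = d
                merged = [i for k in kids for i in k]
                tipsets[node] = merged
        return V

    def patristic_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Tip-to-tip path-length (patristic) distance matrix."""
        order = list(order) if order is not None else self.tip_labels
        V = self.vcv(order)
        d = np.diag(V)
        return d[:, None] + d[None, :] - 2 * V


# ---------------------------------------------------------------- consensus

def _clades(phylo: Phylogeny, idx: dict[str, int]) -> set[frozenset[int]]:
    """Nontrivial rooted clades (tip-index sets below internal edges)."""
    n = len(idx)
    out: set[frozenset[int]] = set()
    tipsets: dict[dendropy.Node, frozenset[int]] = {}
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([idx[node.taxon.label]])
        else:
            tipsets[node] = frozenset().union(*(tipsets[c]
                                                for c in node.child_nodes()))
            s = tipsets[node]
            if 1 < len(s) < n:
                out.add(s)
    return out


def majority_consensus(trees: Sequence[Phylogeny],
                       distances: str = "mean") -> Phylogeny:
    """Majority-rule consensus with least-squares edge lengths.

    Retains exactly the rooted clades present in strictly more than half of
    the trees (ties excluded), then assigns edge lengths by nonnegative
    least squares against the ``mean`` (or ``median``) patristic distance
    matrix of the sample.
    """
    if not trees:
        raise ValueError("empty tree sample")
    labels = trees[0].tip_labels
    for t in trees[1:]:
        if t.tip_labels != labels:
            raise ValueError("trees must share an identical tip set")
    idx = {lab: k for k, lab in enumerate(labels)}
    counts: dict[frozenset[int], int] = {}
    for t in trees:
        for s in _clades(t, idx):
            counts[s] = counts.get(s, 0) + 1
    half = len(trees) / 2.0
    majority = [s for s, c in counts.items() if c > half]
    topo = _tree_from_splits(labels, majority)
    dists = np.stack([t.patristic_matrix(labels) for t in trees])
    summary = (np.mean if distances == "mean" else np.median)(dists, axis=0)
    return least_squares_edge_lengths(topo, summary, order=labels)


def split_frequencies(trees: Sequence[Phylogeny]) -> dict[frozenset[str], float]:
    """Rooted-clade support frequencies (by tip-label set) in a tree sample."""
    labels = trees[0].tip_labels
    idx = {lab: k for k, lab in enumerate(labels)}
    counts: dict[frozenset[int], int] = {}
    for t in trees:
        for s in _clades(t, idx):
            counts[s] = counts.get(s, 0) + 1
    return {frozenset(labels[i] for i in s): c / len(trees)
            for s, c in counts.items()}


def _tree_from_splits(labels: Sequence[str],
                      splits: Sequence[frozenset[int]]) -> Phylogeny:
    """Assemble the rooted tree containing exactly the given (compatible)
    splits plus the trivial ones, zero branch lengths."""
    ns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    ordered = sorted(set(splits), key=len, reverse=True)
    all_tips = frozenset(range(len(labels)))
    nodes: dict[frozenset[int], dendropy.Node] = {all_tips: tree.seed_node}
    for s in ordered:
        parent_key = min((t for t in nodes if s < t), key=len)
        node = dendropy.Node()
        nodes[parent_key].add_child(node)
        nodes[s] = node
    for k, lab in enumerate(labels):
        parent_key = min((t for t in nodes if k in t), key=len)
        leaf = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes[parent_key].add_child(leaf)
    for edge in tree.preorder_edge_iter():
        edge.length = 0.0
    return Phylogeny(tree)


def least_squares_edge_lengths(topology: Phylogeny, distances: np.ndarray,
                               order: Sequence[str] | None = None) -> Phylogeny:
    """Fit nonnegative edge lengths minimising the squared mismatch between
    tree patristic distances and a target distance matrix.

    ``distances`` must be symmetric with zero diagonal, indexed by ``order``
    (default: sorted tip labels). Edges whose length the least-squares
    system cannot identify are driven to zero by the nonnegativity
    constraint.
    """
    order = list(order) if order is not None else topology.tip_labels
    D = np.asarray(distances, dtype=float)
    n = len(order)
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distances must be a symmetric zero-diagonal matrix "
                         "matching the tip order")
    idx = {lab: k for k, lab in enumerate(order)}
    tree = topology.tree.clone(depth=1)
    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    # membership[e][i]: does tip i sit below edge e?
    memb = np.zeros((len(edges), n), dtype=bool)
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [idx[node.taxon.label]]
        else:
            tipsets[node] = [i for c in node.child_nodes() for i in tipsets[c]]
    for k, e in enumerate(edges):
        memb[k, tipsets[e.head_node]] = True
    iu = np.triu_indices(n, 1)
    A = (memb[:, iu[0]] ^ memb[:, iu[1]]).T.astype(float)
    lengths, _ = nnls(A, D[iu])
    for e, ln in zip(edges, lengths):
        e.length = float(ln)
    _rebalance_root(tree)
    return Phylogeny(tree)


def _rebalance_root(tree: dendropy.Tree) -> None:
    """Resolve the one degeneracy patristic distances leave open.

    When the root has exactly two children, only the sum of the two root
    edges is identified by tip-to-tip distances. Shift length between them
    to equalise the mean tip depth on the two sides (keeping both edges
    nonnegative), which restores the original lengths whenever the target
    distances came from an ultrametric tree.
    """
    kids = tree.seed_node.child_nodes()
    if len(kids) != 2:
        return
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    sums = []
    for child in kids:
        acc, cnt = 0.0, 0
        stack = [(child, child.edge.length or 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf():
                acc += d
                cnt += 1
            for c in node.child_nodes():
                stack.append((c, d + (c.edge.length or 0.0)))
        sums.append(acc / cnt)
    l1, l2 = kids[0].edge.length or 0.0, kids[1].edge.length or 0.0
    delta = (sums[0] - sums[1]) / 2.0
    delta = max(-l2, min(l1, delta))
    kids[0].edge.length = l1 - delta
    kids[1].edge.length = l2 + delta
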