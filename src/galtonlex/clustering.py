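"""Rooted trees from distance matrices by agglomerative clustering.

UPGMA (unweighted average linkage) is the default: at each step the two
clusters with minimal average inter-cluster distance merge at height
distance/2, yielding an ultrametric rooted tree.  Ties are broken on the
lexicographically smallest pair of cluster representative labels so
results are identical across platforms.  Single and complete linkage are
available behind a flag.  Trees serialize to Newick with branch length =
parent height − child height.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from skbio.stats.distance import DistanceMatrix

from .lexical_io import ValidationError

logger = logging.getLogger("galtonlex")

LINKAGES = ("average", "single", "complete")

_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.\-|]+$")


@dataclass
class Node:
    """Tree node; ``height`` is the merge height (0 for leaves)."""

    height: float
    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    order: int = 0  # creation order of merges; used for deterministic cuts

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


class ClusterTree:
    """Rooted tree with merge heights; leaves labeled by matrix labels."""

    def __init__(self, root: Node):
        self.root = root

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.root.leaves()]

    def __len__(self) -> int:
        return len(self.root.leaves())

    # -- serialization -----------------------------------------------------

    def to_newick(self, with_lengths: bool = True) -> str:
        """Valid Newick; edge length = parent height − child height."""

        def quote(label: str) -> str:
            if _SAFE_LABEL.match(label):
                return label
            return "'" + label.replace("'", "''") + "'"

        def render(node: Node, parent_height: float | None) -> str:
            if node.is_leaf:
                s = quote(node.label)
            else:
                s = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
            if with_lengths and parent_height is not None:
                s += f":{parent_height - node.height!r}"
            return s

        return render(self.root, None) + ";"

    # -- derived quantities ------------------------------------------------

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Leaf-pair path distances (= 2 × MRCA height for ultrametric trees)."""
        labels = self.leaf_labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        data = np.zeros((n, n))

        def visit(node: Node) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [visit(ch) for ch in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for u in groups[gi]:
                        for v in groups[gj]:
                            d = 2.0 * node.height
                            data[index[u], index[v]] = d
                            data[index[v], index[u]] = d
            return [lab for g in groups for lab in g]

        visit(self.root)
        return DistanceMatrix(data, labels)

    def cut(self, k: int) -> list[frozenset[str]]:
        """Partition leaves into k clusters by undoing the k−1 highest merges."""
        n = len(self)
        if not 1 <= k <= n:
            raise ValidationError(f"k={k} out of range [1, {n}]")
        active = [self.root]
        for _ in range(k - 1):
            internal = [nd for nd in active if not nd.is_leaf]
            top = max(internal, key=lambda nd: (nd.height, nd.order))
            active.remove(top)
            active.extend(top.children)
        return [frozenset(lf.label for lf in nd.leaves()) for nd in active]


def upgma(d: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of a distance matrix into a rooted tree.

    Merge height is half the inter-cluster distance, so cophenetic
    distances on the output reproduce an ultrametric input exactly.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    labels = list(d.ids)
    n = len(labels)
    if n < 2:
        raise ValidationError("need at least 2 labels to cluster")
    # cluster state: representative label (lexicographic min), node, size
    nodes = {i: Node(0.0, label=labels[i]) for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {}
    data = np.asarray(d.data)
    active = list(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(data[i, j])

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_id = n
    order = 0
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                i, j = active[ii], active[jj]
                dij = get(i, j)
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (dij, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, _, i, j = best
        order += 1
        # children ordered by representative label for a canonical layout
        kids = [nodes[k] for k in sorted((i, j), key=lambda k: reps[k])]
        merged = Node(dij / 2.0, children=kids, order=order)
        nodes[next_id] = merged
        reps[next_id] = min(reps[i], reps[j])
        sizes[next_id] = sizes[i] + sizes[j]
        for m in active:
            if m in (i, j):
                continue
            dim, djm = get(i, m), get(j, m)
            if linkage == "average":
                dnew = (sizes[i] * dim + sizes[j] * djm) / (sizes[i] + sizes[j])
            elif linkage == "single":
                dnew = min(dim, djm)
            else:
                dnew = max(dim, djm)
            dist[(min(next_id, m), max(next_id, m))] = dnew
        active = [m for m in active if m not in (i, j)] + [next_id]
        next_id += 1
    return ClusterTree(nodes[active[0]])


def top_branches(t: ClusterTree, k: int) -> list[frozenset[str]]:
    """The k leaf sets obtained by cutting the tree at its k−1 highest merges."""
    return t.cut(k)


def to_newick(t: ClusterTree, with_lengths: bool = True) -> str:
    return t.to_newick(with_lengths=with_lengths)
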