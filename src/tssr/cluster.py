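"""Distance computation and agglomerative clustering of genome TSSR profiles.

City-block (L1) distance between the raw nine-scalar genome profiles,
complete-linkage agglomeration with a fully deterministic tie-break, and
tree queries (smallest containing cluster, monophyly) plus Newick export.

The agglomeration is written out explicitly rather than delegated so that
ties are broken by the lexicographically smallest pair of cluster creation
indices — leaves are numbered 0..n-1 in input order, each merge takes the
next index — making the dendrogram reproducible down to its topology.
SciPy's implementation serves as an independent cross-check in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import ProfileTable

Linkage = Literal["complete", "single", "average"]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass(frozen=True)
class Node:
    """A dendrogram node; leaves carry a label, internal nodes a merge height."""

    index: int
    height: float
    leaves: frozenset[str]
    label: str | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def __iter__(self):
        """Depth-first iteration over all nodes."""
        yield self
        if self.left is not None:
            yield from self.left
        if self.right is not None:
            yield from self.right


@dataclass(frozen=True)
class Dendrogram:
    root: Node
    labels: tuple[str, ...]  # leaf labels in input order

    @property
    def merge_heights(self) -> tuple[float, ...]:
        return tuple(
            sorted(n.height for n in self.root if not n.is_leaf)
        )


def cityblock_distances(table: ProfileTable) -> DistanceMatrix:
    """Pairwise L1 distances between the raw nine-scalar genome profiles."""
    if len(table) < 2:
        raise ValueError("need at least 2 genomes")
    X = np.array([v.ratios for v in table.vectors])
    return DistanceMatrix(tuple(table.genome_ids), cdist(X, X, metric="cityblock"))


def linkage_tree(d: DistanceMatrix, method: Linkage = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Inter-cluster distance is the maximum (complete), minimum (single) or
    size-weighted mean (average) of member-pair distances.  At every step the
    closest active pair merges; exact ties go to the pair whose sorted
    creation indices are lexicographically smallest.
    """
    n = len(d.labels)
    nodes: dict[int, Node] = {
        i: Node(index=i, height=0.0, leaves=frozenset([d.labels[i]]), label=d.labels[i])
        for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])
    active = set(range(n))
    next_index = n
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        merged = Node(
            index=next_index,
            height=h,
            leaves=nodes[a].leaves | nodes[b].leaves,
            left=nodes[a],
            right=nodes[b],
        )
        active -= {a, b}
        for k in active:
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            if method == "complete":
                dk = max(da, db)
            elif method == "single":
                dk = min(da, db)
            elif method == "average":
                dk = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            else:
                raise ValueError(f"unknown linkage {method!r}")
            dist[(k, next_index)] = dk
        del dist[(a, b)]
        nodes[next_index] = merged
        sizes[next_index] = sizes.pop(a) + sizes.pop(b)
        active.add(next_index)
        next_index += 1
    root = nodes[next_index - 1] if n > 1 else nodes[0]
    return Dendrogram(root=root, labels=d.labels)


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomeration (the published clustering)."""
    return linkage_tree(d, method="complete")


def smallest_containing_cluster(t: Dendrogram, leaves: Sequence[str]) -> Node:
    """The lowest node whose leaf set contains every query label."""
    query = frozenset(leaves)
    unknown = query - t.root.leaves
    if unknown:
        raise KeyError(f"unknown leaf label(s): {sorted(unknown)}")
    node = t.root
    while not node.is_leaf:
        if query <= node.left.leaves:
            node = node.left
        elif query <= node.right.leaves:
            node = node.right
        else:
            break
    return node


def is_monophyletic(t: Dendrogram, group: Sequence[str]) -> bool:
    """True iff some cluster of the tree contains exactly this label set."""
    return smallest_containing_cluster(t, group).leaves == frozenset(group)


def newick_safe(label: str) -> str:
    """Replace characters that are structural in Newick with underscores."""
    for ch in " :;,()[]'":
        label = label.replace(ch, "_")
    return label


def to_newick(t: Dendrogram, scale: Literal["raw", "unit"] = "raw") -> str:
    """Serialise the dendrogram as Newick with branch lengths.

    Heights are split at the midpoint (an ultrametric tree: every leaf sits
    at depth root_height/2).  ``unit`` rescales all merge heights by the
    root height so the tree spans 0-1.  Labels are sanitised with
    `newick_safe`.
    """
    root_h = t.root.height
    factor = 1.0 / root_h if (scale == "unit" and root_h > 0) else 1.0

    def render(node: Node, parent_height: float) -> str:
        branch = (parent_height - node.height) * factor / 2
        if node.is_leaf:
            return f"{newick_safe(node.label)}:{branch:.10g}"
        inner = f"({render(node.left, node.height)},{render(node.right, node.height)})"
        return f"{inner}:{branch:.10g}"

    if t.root.is_leaf:
        return f"{t.root.label}:0;"
    body = f"({render(t.root.left, t.root.height)},{render(t.root.right, t.root.height)})"
    return body + ";"


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    """TSV export: labelled square matrix, deterministic formatting."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(d.labels) + "\n")
        for i, lab in enumerate(d.labels):
            cells = "\t".join(f"{x:.10g}" for x in d.values[i])
            fh.write(f"{lab}\t{cells}\n")
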