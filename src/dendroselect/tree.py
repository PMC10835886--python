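"""Navigable dendrogram built from a condensed linkage matrix.

Everything here is iterative (explicit stacks, no recursion) so trees with
tens of thousands of leaves — the scale at which interactive dendrogram
tools are expected to operate — are handled without touching the
interpreter's recursion limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .linkage import DendroJSON, LinkageMatrix

__all__ = ["DendroNode", "Dendrogram", "build_tree", "from_dendro_json"]


@dataclass
class DendroNode:
    """One node of a dendrogram: a leaf or a binary merge."""

    id: int
    height: float
    leaf_count: int
    name: str | None = None
    label: str | None = None
    children: tuple["DendroNode", "DendroNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def __repr__(self) -> str:  # keep huge trees printable
        kind = f"leaf {self.label!r}" if self.is_leaf else f"{self.leaf_count} leaves"
        return f"DendroNode(id={self.id}, height={self.height}, {kind})"


@dataclass
class Dendrogram:
    """Rooted binary tree with an id index and a fixed leaf display order."""

    root: DendroNode
    n_leaves: int
    leaf_order: tuple[str, ...]
    index: dict[int, DendroNode]
    linkage: LinkageMatrix
    labels: tuple[str, ...]
    node_names: dict[int, str] = field(default_factory=dict)
    has_duplicate_labels: bool = False

    def node(self, id: int) -> DendroNode:
        try:
            return self.index[id]
        except KeyError:
            raise KeyError(f"no node with id {id} in this dendrogram") from None

    def is_internal(self, id: int) -> bool:
        return not self.node(id).is_leaf

    def internal_ids(self) -> range:
        return range(self.n_leaves, 2 * self.n_leaves - 1)

    def node_info(self, id: int) -> tuple[int, str | None, int, float]:
        """(id, name, leaf_count, height) — what a tool shows on hover."""
        nd = self.node(id)
        return (nd.id, nd.name, nd.leaf_count, nd.height)

    def leaves_under(self, id: int) -> list[str]:
        """Leaf labels below ``id``, in display (in-order) order."""
        return [nd.label for nd in self.leaf_nodes_under(id)]  # type: ignore[misc]

    def leaf_nodes_under(self, id: int) -> list[DendroNode]:
        out: list[DendroNode] = []
        stack = [self.node(id)]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                a, b = nd.children  # type: ignore[misc]
                stack.append(b)
                stack.append(a)
        return out

    def find_by_label(self, label: str) -> list[DendroNode]:
        """All leaves carrying ``label`` (duplicates allowed, hence a list)."""
        return [
            self.index[i] for i in range(self.n_leaves)
            if self.index[i].label == label
        ]

    def to_newick(self, from_id: int | None = None) -> str:
        """Serialize (a subtree of) the dendrogram as a Newick string.

        A child's branch length is ``parent height - child height``; leaves
        sit at height 0, so for ultrametric trees the cophenetic distance
        between two leaves is twice the height of their lowest common
        ancestor. Negative branch lengths arising from height inversions are
        clamped to 0 with a warning.
        """
        start = self.node(self.root.id if from_id is None else from_id)
        clamped = False

        def fmt(x: float) -> str:
            return repr(round(x, 12))

        # post-order assembly with an explicit stack
        pieces: dict[int, str] = {}
        stack: list[tuple[DendroNode, bool]] = [(start, False)]
        while stack:
            nd, expanded = stack.pop()
            if nd.is_leaf:
                pieces[nd.id] = _escape_newick(nd.label or str(nd.id))
            elif not expanded:
                stack.append((nd, True))
                a, b = nd.children  # type: ignore[misc]
                stack.append((b, False))
                stack.append((a, False))
            else:
                a, b = nd.children  # type: ignore[misc]
                parts = []
                for ch in (a, b):
                    bl = nd.height - ch.height
                    if bl < 0:
                        clamped = True
                        bl = 0.0
                    parts.append(f"{pieces.pop(ch.id)}:{fmt(bl)}")
                pieces[nd.id] = "(" + ",".join(parts) + ")"
        if clamped:
            warnings.warn(
                "height inversion: negative Newick branch lengths clamped to 0"
            )
        if start.is_leaf:
            return pieces[start.id] + ";"
        return pieces[start.id] + ";"


def _escape_newick(label: str) -> str:
    if any(c in label for c in "():;, '\t\n[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def build_tree(
    m: LinkageMatrix,
    labels: Sequence[str],
    node_names: dict[int, str] | None = None,
) -> Dendrogram:
    """Build a :class:`Dendrogram` from a condensed linkage matrix.

    Leaf display order is the depth-first in-order traversal with
    ``child_a`` visited first. Duplicate leaf labels are permitted but
    flagged (``has_duplicate_labels``) with a warning, since real gene and
    compound tables contain them.
    """
    n = m.n_leaves
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels supplied for {n} leaves")
    node_names = dict(node_names or {})

    index: dict[int, DendroNode] = {
        i: DendroNode(id=i, height=0.0, leaf_count=1, label=labels[i])
        for i in range(n)
    }
    inversion = False
    for i, (a, b, h, c) in enumerate(m.rows):
        nid = n + i
        ca, cb = index[a], index[b]
        if h < max(ca.height, cb.height):
            inversion = True
        index[nid] = DendroNode(
            id=nid,
            height=float(h),
            leaf_count=int(c),
            name=node_names.get(nid),
            children=(ca, cb),
        )
    if inversion:
        warnings.warn("linkage contains height inversions; tree built anyway")

    root = index[2 * n - 2]
    dup = len(set(labels)) != len(labels)
    if dup:
        warnings.warn("duplicate leaf labels; label lookups may return several")

    d = Dendrogram(
        root=root,
        n_leaves=n,
        leaf_order=(),  # filled below, needs the tree
        index=index,
        linkage=m,
        labels=labels,
        node_names=node_names,
        has_duplicate_labels=dup,
    )
    d.leaf_order = tuple(d.leaves_under(root.id))
    return d


def cut(d: Dendrogram, k: int) -> list[int]:
    """Node ids of the ``k`` clusters obtained by undoing the last merges.

    Removing the final ``k - 1`` linkage rows leaves a forest of exactly
    ``k`` subtrees; their root ids are returned in ascending order. For a
    monotone linkage this equals cutting the tree just below the height of
    the ``(k-1)``-th highest merge. The returned ids can be selected
    directly to color and export the clusters.
    """
    n = d.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    kept = n - k  # number of merge rows retained
    used = set()
    for a, b, _, _ in d.linkage.rows[:kept]:
        used.add(a)
        used.add(b)
    roots = [i for i in range(n + kept) if i not in used]
    assert len(roots) == k
    return roots


def from_dendro_json(dj: DendroJSON) -> Dendrogram:
    """Build the tree a JSON interchange file describes."""
    return build_tree(dj.linkage, dj.labels, dj.node_names)


def to_dendro_json(d: Dendrogram, orientation: str = "horizontal") -> DendroJSON:
    """Interchange form of a dendrogram (inverse of :func:`from_dendro_json`)."""
    return DendroJSON(
        labels=d.labels,
        linkage=d.linkage,
        node_names=dict(d.node_names),
        orientation=orientation,
    )


def node_info(d: Dendrogram, id: int) -> tuple[int, str | None, int, float]:
    return d.node_info(id)


def leaves_under(d: Dendrogram, id: int) -> list[str]:
    return d.leaves_under(id)


def to_newick(d: Dendrogram, from_id: int | None = None) -> str:
    return d.to_newick(from_id)
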