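"""Linkage-matrix interchange: condensed tables, signed merge tables, JSON.

Three encodings of the same agglomeration record circulate in the
hierarchical-clustering ecosystem:

* the **condensed four-column table** used by :mod:`scipy.cluster.hierarchy`
  (row *i* merges two node ids at a height, creating node ``n_leaves + i``;
  leaves are ids ``0 .. n_leaves-1``),
* the **signed merge table** carried by R ``hclust`` objects (negative
  entries are 1-based leaves, positive entries reference earlier merge
  rows), and
* a versioned **JSON interchange schema** for moving dendrograms between
  tools, defined here as ``{"schema_version", "labels", "linkage",
  "node_names", "orientation"}``.

This module validates each encoding and converts losslessly between them.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

SCHEMA_VERSION = "1.0"

__all__ = [
    "LinkageMatrix",
    "SignedMergeTable",
    "DendroJSON",
    "LinkageValidationError",
    "read_linkage_json",
    "write_linkage_json",
    "signed_to_condensed",
    "condensed_to_signed",
]


class LinkageValidationError(ValueError):
    """A linkage structure violates a structural invariant."""


@dataclass(frozen=True)
class LinkageMatrix:
    """Condensed (n-1) x 4 agglomeration record.

    ``rows[i] = (child_a, child_b, height, count)`` merges the clusters with
    node ids ``child_a`` and ``child_b`` at the given height, creating the
    internal node with id ``n_leaves + i``. Leaves are ids
    ``0 .. n_leaves - 1`` and have count 1.
    """

    rows: tuple[tuple[int, int, float, int], ...]
    n_leaves: int

    def __post_init__(self) -> None:
        validate_linkage(self.rows, self.n_leaves)

    @classmethod
    def from_array(cls, arr: np.ndarray | Sequence[Sequence[float]]) -> "LinkageMatrix":
        """Build from an (n-1) x 4 array in the scipy convention."""
        a = np.asarray(arr, dtype=float)
        if a.ndim != 2 or a.shape[1] != 4:
            raise LinkageValidationError(
                f"linkage array must be (n-1) x 4, got shape {a.shape}"
            )
        n_leaves = a.shape[0] + 1
        rows = tuple(
            (int(r[0]), int(r[1]), float(r[2]), int(r[3])) for r in a
        )
        return cls(rows=rows, n_leaves=n_leaves)

    def to_array(self) -> np.ndarray:
        """Return the scipy-convention (n-1) x 4 float array."""
        return np.array(self.rows, dtype=float).reshape(len(self.rows), 4)

    def canonicalized(self) -> "LinkageMatrix":
        """Return a copy with ``child_a < child_b`` in every row."""
        rows = tuple(
            (b, a, h, c) if a > b else (a, b, h, c) for a, b, h, c in self.rows
        )
        return LinkageMatrix(rows=rows, n_leaves=self.n_leaves)


def validate_linkage(
    rows: Sequence[tuple[int, int, float, int]], n_leaves: int
) -> None:
    """Check every structural invariant of a condensed linkage table.

    Raises :class:`LinkageValidationError` naming the offending row. Height
    inversions along root-ward paths (a parent merging lower than a child)
    are reported as a warning, not an error: several linkage methods
    legitimately produce them.
    """
    if n_leaves < 2:
        raise LinkageValidationError("a dendrogram needs at least 2 leaves")
    if len(rows) != n_leaves - 1:
        raise LinkageValidationError(
            f"expected {n_leaves - 1} merge rows for {n_leaves} leaves, "
            f"got {len(rows)}"
        )
    n_nodes = 2 * n_leaves - 1
    counts = np.zeros(n_nodes, dtype=np.int64)
    counts[:n_leaves] = 1
    heights = np.zeros(n_nodes, dtype=float)
    used_as_child = np.zeros(n_nodes, dtype=bool)
    for i, (a, b, h, c) in enumerate(rows):
        node = n_leaves + i
        for child in (a, b):
            if not (0 <= child < node):
                raise LinkageValidationError(
                    f"row {i}: child id {child} out of range [0, {node})"
                )
            if used_as_child[child]:
                raise LinkageValidationError(
                    f"row {i}: node {child} already merged in an earlier row"
                )
            used_as_child[child] = True
        if a == b:
            raise LinkageValidationError(f"row {i}: merges node {a} with itself")
        if not np.isfinite(h) or h < 0:
            raise LinkageValidationError(
                f"row {i}: height {h!r} is not a nonnegative finite real"
            )
        if c != counts[a] + counts[b]:
            raise LinkageValidationError(
                f"row {i}: count {c} != count({a}) + count({b}) = "
                f"{counts[a] + counts[b]}"
            )
        if h < max(heights[a], heights[b]):
            warnings.warn(
                f"row {i}: height inversion ({h} below a child's merge height)",
                stacklevel=3,
            )
        counts[node] = c
        heights[node] = h
    if counts[n_nodes - 1] != n_leaves:
        raise LinkageValidationError(
            f"root count {counts[n_nodes - 1]} != n_leaves {n_leaves}"
        )
    # every non-root node must have been consumed exactly once
    if not used_as_child[: n_nodes - 1].all():
        missing = int(np.flatnonzero(~used_as_child[: n_nodes - 1])[0])
        raise LinkageValidationError(
            f"node {missing} is never merged; the tree is not connected"
        )


@dataclass(frozen=True)
class SignedMergeTable:
    """R-ecosystem merge encoding (as carried by ``hclust`` objects).

    ``merge[j] = (x, y)`` with negative ``-k`` denoting leaf ``k`` (1-based)
    and positive ``j`` denoting the cluster created at merge row ``j``
    (1-based). ``order`` is the leaf display permutation (1-based) and
    ``labels`` the leaf labels.
    """

    merge: tuple[tuple[int, int], ...]
    heights: tuple[float, ...]
    order: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merge) != n - 1:
            raise LinkageValidationError(
                f"merge table has {len(self.merge)} rows, expected {n - 1}"
            )
        if len(self.heights) != len(self.merge):
            raise LinkageValidationError("heights length != merge rows")
        if sorted(self.order) != list(range(1, n + 1)):
            raise LinkageValidationError("order is not a permutation of 1..n")
        leaf_seen = set()
        row_seen = set()
        for j, (x, y) in enumerate(self.merge, start=1):
            for v in (x, y):
                if v < 0:
                    if -v > n:
                        raise LinkageValidationError(
                            f"merge row {j}: leaf {-v} out of range 1..{n}"
                        )
                    if v in leaf_seen:
                        raise LinkageValidationError(
                            f"merge row {j}: leaf {-v} appears twice"
                        )
                    leaf_seen.add(v)
                elif v == 0 or v >= j:
                    raise LinkageValidationError(
                        f"merge row {j}: reference {v} is not an earlier row"
                    )
                else:
                    if v in row_seen:
                        raise LinkageValidationError(
                            f"merge row {j}: row {v} referenced twice"
                        )
                    row_seen.add(v)
        if len(leaf_seen) != n:
            raise LinkageValidationError(
                "not every leaf appears in the merge table"
            )


@dataclass
class DendroJSON:
    """The JSON interchange bundle: labels + linkage + optional node names.

    ``node_names`` maps internal node ids (as produced by the condensed
    convention) to display names. ``orientation`` records the preferred
    layout and carries no structural meaning.
    """

    labels: tuple[str, ...]
    linkage: LinkageMatrix
    node_names: dict[int, str] = field(default_factory=dict)
    orientation: str = "horizontal"
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        # child order within a row is not meaningful; canonicalize on entry
        # so equality, display order and written bytes all agree
        self.linkage = self.linkage.canonicalized()
        if len(self.labels) != self.linkage.n_leaves:
            raise LinkageValidationError(
                f"{len(self.labels)} labels for {self.linkage.n_leaves} leaves"
            )
        n_nodes = 2 * self.linkage.n_leaves - 1
        for k in self.node_names:
            if not (self.linkage.n_leaves <= int(k) < n_nodes):
                raise LinkageValidationError(
                    f"node_names key {k} is not a valid internal node id"
                )
        self.node_names = {int(k): str(v) for k, v in self.node_names.items()}
        if self.orientation not in ("horizontal", "vertical"):
            raise LinkageValidationError(
                f"orientation must be horizontal|vertical, got {self.orientation!r}"
            )

    @property
    def n_leaves(self) -> int:
        return self.linkage.n_leaves

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DendroJSON):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.linkage == other.linkage
            and self.node_names == other.node_names
            and self.orientation == other.orientation
            and self.schema_version == other.schema_version
        )


def _open_text(path: Path, mode: str):
    if path.name.endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_linkage_json(path: str | Path) -> DendroJSON:
    """Read and fully validate an interchange JSON file.

    Transparently decompresses ``*.json.gz``. Raises ``json.JSONDecodeError``
    on malformed JSON and :class:`LinkageValidationError` on any structural
    violation, naming the offending row.
    """
    path = Path(path)
    with _open_text(path, "r") as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise LinkageValidationError("top-level JSON value must be an object")
    for key in ("labels", "linkage"):
        if key not in obj:
            raise LinkageValidationError(f"missing required key {key!r}")
    linkage = LinkageMatrix.from_array(obj["linkage"])
    return DendroJSON(
        labels=tuple(obj["labels"]),
        linkage=linkage,
        node_names={int(k): v for k, v in (obj.get("node_names") or {}).items()},
        orientation=obj.get("orientation", "horizontal"),
        schema_version=str(obj.get("schema_version", SCHEMA_VERSION)),
    )


def dendro_json_to_dict(d: DendroJSON) -> dict:
    """Canonical plain-dict form (child_a < child_b in every linkage row)."""
    link = d.linkage.canonicalized()
    return {
        "schema_version": d.schema_version,
        "labels": list(d.labels),
        "linkage": [[a, b, h, c] for a, b, h, c in link.rows],
        "node_names": {str(k): v for k, v in sorted(d.node_names.items())},
        "orientation": d.orientation,
    }


def write_linkage_json(d: DendroJSON, path: str | Path) -> Path:
    """Write canonical, byte-stable interchange JSON.

    Keys are sorted, child ids canonicalized to ``child_a < child_b``, and
    floats serialized with Python's shortest round-trip representation, so
    the same dendrogram always produces identical bytes and file diffs are
    meaningful.
    """
    path = Path(path)
    payload = json.dumps(
        dendro_json_to_dict(d), sort_keys=True, indent=1, ensure_ascii=False
    )
    with _open_text(path, "w") as fh:
        fh.write(payload)
        fh.write("\n")
    return path


def signed_to_condensed(
    t: SignedMergeTable,
) -> tuple[LinkageMatrix, tuple[str, ...]]:
    """Convert a signed merge table to the condensed encoding.

    Leaf ``-k`` maps to node id ``k - 1``; merge row ``j`` (1-based) maps to
    internal node id ``n_leaves + j - 1``. Heights carry over unchanged and
    counts are recomputed.
    """
    n = len(t.labels)
    counts = {i: 1 for i in range(n)}
    rows = []
    for j, ((x, y), h) in enumerate(zip(t.merge, t.heights)):
        ids = tuple((-v - 1) if v < 0 else (n + v - 1) for v in (x, y))
        a, b = sorted(ids)
        c = counts[a] + counts[b]
        counts[n + j] = c
        rows.append((a, b, float(h), c))
    return LinkageMatrix(rows=tuple(rows), n_leaves=n), t.labels


def condensed_to_signed(
    m: LinkageMatrix, labels: Sequence[str]
) -> SignedMergeTable:
    """Exact inverse of :func:`signed_to_condensed` (up to within-row order).

    The ``order`` vector is derived from an in-order depth-first traversal
    with ``child_a`` visited first, matching the display order the tree
    module computes.
    """
    n = m.n_leaves
    if len(labels) != n:
        raise LinkageValidationError(f"{len(labels)} labels for {n} leaves")
    merge = tuple(
        tuple((v + 1 - n) if v >= n else -(v + 1) for v in (a, b))
        for a, b, _, _ in m.rows
    )
    heights = tuple(h for _, _, h, _ in m.rows)
    order = tuple(i + 1 for i in leaf_order_ids(m))
    return SignedMergeTable(
        merge=merge, heights=heights, order=order, labels=tuple(labels)
    )


def leaf_order_ids(m: LinkageMatrix) -> list[int]:
    """Leaf ids in in-order (depth-first, child_a first) display order."""
    n = m.n_leaves
    children = {n + i: (a, b) for i, (a, b, _, _) in enumerate(m.rows)}
    out: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            out.append(node)
        else:
            a, b = children[node]
            stack.append(b)
            stack.append(a)
    return out
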