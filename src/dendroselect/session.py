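"""Multi-level multi-cluster selection, child dendrograms, and sessions.

The selection model mirrors how an analyst works with an interactive
dendrogram: click an internal node to select the cluster beneath it (it
receives the next color from a fixed categorical palette), click again to
unselect, override colors explicitly, and cut a selected cluster out as a
standalone child dendrogram. Nested and overlapping selections are allowed;
the membership export is long-format, so a leaf under two nested selections
appears once per selection.

A :class:`Session` bundles the dendrogram, the selection state and any
extracted child dendrograms (fully materialized, so the file alone
reconstructs the session anywhere) into a versioned JSON file.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import warnings
from dataclasses import dataclass, field, replace

from .linkage import (
    SCHEMA_VERSION,
    DendroJSON,
    LinkageMatrix,
    dendro_json_to_dict,
    read_linkage_json,
)
from .tree import Dendrogram, build_tree, from_dendro_json, to_dendro_json

__all__ = [
    "DEFAULT_PALETTE",
    "SelectionState",
    "Session",
    "SelectionError",
    "select",
    "unselect",
    "set_color",
    "extract_child",
    "membership_table",
    "save_session",
    "load_session",
]

# Fixed 12-color categorical palette (hex), cycled modulo 12 in selection
# order. Chosen for pairwise distinguishability on a white background.
DEFAULT_PALETTE: tuple[str, ...] = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728",
    "#9467bd", "#8c564b", "#e377c2", "#7f7f7f",
    "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)

_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


class SelectionError(ValueError):
    """An operation on the selection state is invalid."""


@dataclass(frozen=True)
class Selection:
    node_id: int
    color: str
    name: str | None = None


@dataclass(frozen=True)
class SelectionState:
    """Ordered set of selected internal nodes with deterministic colors.

    Immutable: every operation returns a new state, so selection histories
    can be kept and replayed.
    """

    selections: tuple[Selection, ...] = ()
    palette: tuple[str, ...] = DEFAULT_PALETTE
    # total number of selections ever made; drives palette cycling so that
    # unselecting never recolors the survivors
    n_assigned: int = 0

    def selected_ids(self) -> tuple[int, ...]:
        return tuple(s.node_id for s in self.selections)

    def get(self, node_id: int) -> Selection:
        for s in self.selections:
            if s.node_id == node_id:
                return s
        raise SelectionError(f"node {node_id} is not selected")


def select(
    s: SelectionState, d: Dendrogram, node_id: int, name: str | None = None
) -> SelectionState:
    """Select the cluster rooted at an internal node.

    Leaves cannot be selected (a single label is not a cluster), and
    selecting an already-selected node is an error — unselection is an
    explicit, separate operation.
    """
    node = d.node(node_id)
    if node.is_leaf:
        raise SelectionError(
            f"node {node_id} is a leaf; only non-leaf nodes can be selected"
        )
    if node_id in s.selected_ids():
        raise SelectionError(f"node {node_id} is already selected")
    color = s.palette[s.n_assigned % len(s.palette)]
    sel = Selection(node_id=node_id, color=color, name=name)
    return replace(
        s, selections=s.selections + (sel,), n_assigned=s.n_assigned + 1
    )


def unselect(s: SelectionState, node_id: int) -> SelectionState:
    """Remove a selection; remaining selections keep their colors."""
    if node_id not in s.selected_ids():
        raise SelectionError(f"node {node_id} is not selected")
    return replace(
        s,
        selections=tuple(x for x in s.selections if x.node_id != node_id),
    )


def set_color(s: SelectionState, node_id: int, color: str) -> SelectionState:
    """Override the assigned color of a selection (stored verbatim)."""
    if not _HEX_RE.match(color):
        raise SelectionError(f"{color!r} is not a #rrggbb hex color")
    sel = s.get(node_id)
    new = tuple(
        replace(x, color=color) if x.node_id == node_id else x
        for x in s.selections
    )
    return replace(s, selections=new)


def rename(s: SelectionState, node_id: int, name: str) -> SelectionState:
    s.get(node_id)
    return replace(
        s,
        selections=tuple(
            replace(x, name=name) if x.node_id == node_id else x
            for x in s.selections
        ),
    )


def extract_child(d: Dendrogram, node_id: int) -> Dendrogram:
    """Cut the subtree at an internal node out as a standalone dendrogram.

    The child's m leaves are renumbered 0..m-1 preserving the parent's
    in-order leaf order; its merge rows are exactly the parent's rows
    internal to the subtree, in original row order, with heights unchanged
    and counts recomputed. Node display names inside the subtree carry over
    to the re-indexed ids.
    """
    node = d.node(node_id)
    if node.is_leaf:
        raise SelectionError(
            f"node {node_id} is a leaf; a child dendrogram needs a cluster"
        )
    leaves = d.leaf_nodes_under(node_id)
    m = len(leaves)
    new_id = {nd.id: i for i, nd in enumerate(leaves)}

    # collect internal nodes of the subtree, then renumber them in original
    # (parent) row order so merge rows stay sorted by creation order
    internal: list[int] = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf:
            internal.append(nd.id)
            a, b = nd.children  # type: ignore[misc]
            stack.append(a)
            stack.append(b)
    internal.sort()
    for j, old in enumerate(internal):
        new_id[old] = m + j

    n_parent = d.n_leaves
    rows = []
    for old in internal:
        a_old, b_old, h, _ = d.linkage.rows[old - n_parent]
        a, b = new_id[a_old], new_id[b_old]
        ca = 1 if a < m else rows[a - m][3]
        cb = 1 if b < m else rows[b - m][3]
        rows.append((a, b, h, ca + cb))
    child_linkage = LinkageMatrix(rows=tuple(rows), n_leaves=m)
    labels = tuple(nd.label for nd in leaves)
    names = {
        new_id[k]: v for k, v in d.node_names.items() if k in new_id and k >= n_parent
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # parent already warned about dups/inversions
        return build_tree(child_linkage, labels, names)


def membership_table(
    d: Dendrogram, s: SelectionState
) -> list[tuple[str, str, str]]:
    """Long-format (label, cluster, color) rows, one per leaf per selection.

    ``cluster`` is the selection's explicit name if set, else the node's
    display name, else the node id as a string. Leaves under nested
    selections appear once per covering selection.
    """
    rows: list[tuple[str, str, str]] = []
    for sel in s.selections:
        cluster = sel.name or d.node_names.get(sel.node_id) or str(sel.node_id)
        for label in d.leaves_under(sel.node_id):
            rows.append((label, cluster, sel.color))
    return rows


def write_membership_tsv(d: Dendrogram, s: SelectionState, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\tcluster\tcolor\n")
        for label, cluster, color in membership_table(d, s):
            fh.write(f"{label}\t{cluster}\t{color}\n")


@dataclass
class ChildEntry:
    parent_node_id: int
    dendrogram: DendroJSON
    selection: SelectionState = field(default_factory=SelectionState)


@dataclass
class Session:
    """Serializable bundle: dendrogram + selections + child dendrograms."""

    dendrogram: DendroJSON
    selection: SelectionState = field(default_factory=SelectionState)
    children: list[ChildEntry] = field(default_factory=list)
    session_name: str = "session"
    saved_at: str | None = None
    heatmap_ref: str | None = None
    schema_version: str = SCHEMA_VERSION

    def tree(self) -> Dendrogram:
        return from_dendro_json(self.dendrogram)

    def add_child(self, node_id: int) -> Dendrogram:
        """Extract and register a child dendrogram for a selected-able node."""
        t = self.tree()
        child = extract_child(t, node_id)
        self.children.append(
            ChildEntry(parent_node_id=node_id, dendrogram=to_dendro_json(child))
        )
        return child


def _selection_to_dict(s: SelectionState) -> dict:
    return {
        "selections": [
            {"node_id": x.node_id, "color": x.color, "name": x.name}
            for x in s.selections
        ],
        "palette": list(s.palette),
        "n_assigned": s.n_assigned,
    }


def _selection_from_dict(obj: dict) -> SelectionState:
    return SelectionState(
        selections=tuple(
            Selection(
                node_id=int(x["node_id"]),
                color=str(x["color"]),
                name=x.get("name"),
            )
            for x in obj.get("selections", [])
        ),
        palette=tuple(obj.get("palette", DEFAULT_PALETTE)),
        n_assigned=int(obj.get("n_assigned", len(obj.get("selections", [])))),
    )


_KNOWN_SESSION_KEYS = {
    "schema_version", "session_name", "saved_at", "dendrogram",
    "selection", "children", "heatmap_ref",
}


def save_session(sess: Session, path) -> str:
    """Write the session as versioned JSON; refreshes ``saved_at``."""
    sess.saved_at = (
        _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    )
    payload = {
        "schema_version": sess.schema_version,
        "session_name": sess.session_name,
        "saved_at": sess.saved_at,
        "dendrogram": dendro_json_to_dict(sess.dendrogram),
        "selection": _selection_to_dict(sess.selection),
        "children": [
            {
                "parent_node_id": c.parent_node_id,
                "dendrogram": dendro_json_to_dict(c.dendrogram),
                "selection": _selection_to_dict(c.selection),
            }
            for c in sess.children
        ],
        "heatmap_ref": sess.heatmap_ref,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1, ensure_ascii=False)
        fh.write("\n")
    return sess.saved_at


def _dendro_from_dict(obj: dict) -> DendroJSON:
    return DendroJSON(
        labels=tuple(obj["labels"]),
        linkage=LinkageMatrix.from_array(obj["linkage"]),
        node_names={int(k): v for k, v in (obj.get("node_names") or {}).items()},
        orientation=obj.get("orientation", "horizontal"),
        schema_version=str(obj.get("schema_version", SCHEMA_VERSION)),
    )


def load_session(path) -> Session:
    """Load and validate a session file.

    The file is parsed and validated in full before any state is returned,
    so a truncated file raises rather than yielding partial state. A
    schema-version mismatch is an explicit error; unknown optional keys are
    ignored with a warning (forward readability).
    """
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    version = str(obj.get("schema_version", ""))
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"session schema_version {version!r} is not supported "
            f"(this build reads {SCHEMA_VERSION!r})"
        )
    unknown = set(obj) - _KNOWN_SESSION_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown session keys: {sorted(unknown)}")
    dendro = _dendro_from_dict(obj["dendrogram"])
    children = []
    parent_tree = from_dendro_json(dendro)
    for c in obj.get("children", []):
        entry = ChildEntry(
            parent_node_id=int(c["parent_node_id"]),
            dendrogram=_dendro_from_dict(c["dendrogram"]),
            selection=_selection_from_dict(c.get("selection", {})),
        )
        expected = tuple(parent_tree.leaves_under(entry.parent_node_id))
        if tuple(entry.dendrogram.labels) != expected:
            raise ValueError(
                f"child of node {entry.parent_node_id}: leaf labels do not "
                "match the parent subtree"
            )
        children.append(entry)
    return Session(
        dendrogram=dendro,
        selection=_selection_from_dict(obj.get("selection", {})),
        children=children,
        session_name=str(obj.get("session_name", "session")),
        saved_at=obj.get("saved_at"),
        heatmap_ref=obj.get("heatmap_ref"),
        schema_version=version,
    )
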