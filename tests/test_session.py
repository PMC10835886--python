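"""Selection semantics, child extraction, membership export, session files."""

import json

import pytest

from dendroselect import (
    DEFAULT_PALETTE,
    DendroJSON,
    LinkageMatrix,
    SelectionError,
    SelectionState,
    Session,
    build_tree,
    extract_child,
    load_session,
    membership_table,
    random_linkage,
    save_session,
    select,
    set_color,
    unselect,
)
from dendroselect.tree import to_dendro_json


class TestSelect:
    def test_first_selection_gets_first_palette_color(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        assert s.selections[0].color == DEFAULT_PALETTE[0]

    def test_successive_colors_cycle_in_order(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        s = select(s, three_leaf, 3)
        assert [x.color for x in s.selections] == list(DEFAULT_PALETTE[:2])

    def test_leaf_cannot_be_selected(self, three_leaf):
        with pytest.raises(SelectionError, match="non-leaf"):
            select(SelectionState(), three_leaf, 0)

    def test_double_selection_is_error(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        with pytest.raises(SelectionError, match="already"):
            select(s, three_leaf, 4)

    def test_select_unselect_is_identity(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        s = unselect(s, 4)
        assert s.selections == ()

    def test_unselect_keeps_other_colors(self, three_leaf):
        m, labels = random_linkage(8, seed=0)
        d = build_tree(m, labels)
        ids = list(d.internal_ids())[:3]
        s = SelectionState()
        for i in ids:
            s = select(s, d, i)
        s = unselect(s, ids[1])
        colors = {x.node_id: x.color for x in s.selections}
        assert colors[ids[0]] == DEFAULT_PALETTE[0]
        assert colors[ids[2]] == DEFAULT_PALETTE[2]

    def test_unselect_unknown_is_error(self, three_leaf):
        with pytest.raises(SelectionError, match="not selected"):
            unselect(SelectionState(), 4)

    def test_color_override_stored_verbatim(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        s = set_color(s, 4, "#ff0000")
        assert s.get(4).color == "#ff0000"

    def test_invalid_hex_rejected(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        with pytest.raises(SelectionError, match="hex"):
            set_color(s, 4, "red")

    def test_palette_cycles_modulo_12(self):
        m, labels = random_linkage(20, seed=1)
        d = build_tree(m, labels)
        s = SelectionState()
        ids = list(d.internal_ids())[:13]
        for i in ids:
            s = select(s, d, i)
        assert s.selections[12].color == DEFAULT_PALETTE[0]


class TestExtractChild:
    def test_three_leaf_subcluster(self, three_leaf):
        child = extract_child(three_leaf, 3)
        assert child.linkage.rows == ((0, 1, 0.2, 2),)
        assert child.leaf_order == ("A", "B")

    def test_extract_root_is_reindexed_identity(self, three_leaf):
        child = extract_child(three_leaf, 4)
        assert child.n_leaves == 3
        assert sorted(child.leaf_order) == ["A", "B", "C"]
        assert sorted(h for _, _, h, _ in child.linkage.rows) == [0.2, 0.7]

    def test_leaf_rejected(self, three_leaf):
        with pytest.raises(SelectionError):
            extract_child(three_leaf, 1)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_every_internal_node_extracts_consistently(self, seed):
        """Leaf sets and height multisets must match the parent subtree."""
        m, labels = random_linkage(40, seed=seed)
        d = build_tree(m, labels)
        for nid in d.internal_ids():
            child = extract_child(d, nid)
            assert list(child.leaf_order) == d.leaves_under(nid)
            parent_heights = sorted(
                d.node(x).height
                for x in range(d.n_leaves, 2 * d.n_leaves - 1)
                if set(d.leaves_under(x)) <= set(d.leaves_under(nid))
            )
            child_heights = sorted(h for _, _, h, _ in child.linkage.rows)
            assert child_heights == pytest.approx(parent_heights)

    def test_grandchild_composition(self):
        """extract(extract(d, a), b') == extract(d, b) for every nested b."""
        m, labels = random_linkage(16, seed=4)
        d = build_tree(m, labels)
        for a in d.internal_ids():
            child = extract_child(d, a)
            for b in child.internal_ids():
                grand = extract_child(child, b)
                # locate the original node with the same leaf set
                target = set(grand.leaf_order)
                matches = [
                    x for x in d.internal_ids()
                    if set(d.leaves_under(x)) == target
                ]
                assert matches, "grandchild leaf set missing from original"
                direct = extract_child(d, matches[0])
                assert direct.linkage == grand.linkage
                assert direct.leaf_order == grand.leaf_order


class TestMembership:
    def test_single_selection_covers_all_leaves(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        rows = membership_table(three_leaf, s)
        assert len(rows) == 3
        assert {r[2] for r in rows} == {DEFAULT_PALETTE[0]}

    def test_nested_selections_long_format(self, three_leaf):
        s = select(SelectionState(), three_leaf, 4)
        s = select(s, three_leaf, 3)
        rows = membership_table(three_leaf, s)
        labels = [r[0] for r in rows]
        assert labels.count("A") == 2
        assert labels.count("B") == 2
        assert labels.count("C") == 1

    def test_disjoint_selections_partition(self):
        m, labels = random_linkage(30, seed=6)
        d = build_tree(m, labels)
        a, b = (c.id for c in d.root.children)
        s = SelectionState()
        for nid in (a, b):
            if not d.node(nid).is_leaf:
                s = select(s, d, nid)
        rows = membership_table(d, s)
        expected = sum(d.node(x.node_id).leaf_count for x in s.selections)
        assert len(rows) == expected

    def test_order_independence(self, three_leaf):
        s1 = select(select(SelectionState(), three_leaf, 4), three_leaf, 3)
        # same selected set reached by a different history, colors forced equal
        s2 = select(SelectionState(), three_leaf, 3)
        s2 = unselect(s2, 3)
        s2 = select(select(s2, three_leaf, 4), three_leaf, 3)
        s2 = set_color(s2, 4, DEFAULT_PALETTE[0])
        s2 = set_color(s2, 3, DEFAULT_PALETTE[1])
        assert membership_table(three_leaf, s1) == membership_table(three_leaf, s2)


class TestSessionIO:
    def test_minimal_round_trip(self, tmp_path):
        m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
        sess = Session(dendrogram=DendroJSON(labels=("A", "B"), linkage=m))
        p = tmp_path / "s.json"
        save_session(sess, p)
        back = load_session(p)
        assert back.dendrogram == sess.dendrogram
        assert back.selection.selections == ()

    def test_rich_session_round_trip(self, tmp_path):
        m, labels = random_linkage(24, seed=7)
        d = build_tree(m, labels)
        sess = Session(
            dendrogram=to_dendro_json(d), session_name="demo", heatmap_ref="h.png"
        )
        s = SelectionState()
        internal = list(d.internal_ids())
        for nid in internal[:5]:
            s = select(s, d, nid)
        s = set_color(s, internal[2], "#123abc")
        sess.selection = s
        sess.add_child(internal[0])
        sess.add_child(internal[3])
        p = tmp_path / "s.json"
        save_session(sess, p)
        back = load_session(p)
        assert back.session_name == "demo"
        assert back.heatmap_ref == "h.png"
        assert back.selection == sess.selection
        assert [c.parent_node_id for c in back.children] == [
            internal[0], internal[3],
        ]
        for got, want in zip(back.children, sess.children):
            assert got.dendrogram == want.dendrogram

    def test_saved_at_refreshed(self, tmp_path):
        m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
        sess = Session(dendrogram=DendroJSON(labels=("A", "B"), linkage=m))
        stamp = save_session(sess, tmp_path / "s.json")
        assert sess.saved_at == stamp is not None

    def test_truncated_file_is_clean_error(self, tmp_path):
        p = tmp_path / "s.json"
        m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
        save_session(
            Session(dendrogram=DendroJSON(labels=("A", "B"), linkage=m)), p
        )
        p.write_text(p.read_text()[: len(p.read_text()) // 2])
        with pytest.raises(json.JSONDecodeError):
            load_session(p)

    def test_schema_version_mismatch(self, tmp_path):
        p = tmp_path / "s.json"
        m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
        save_session(
            Session(dendrogram=DendroJSON(labels=("A", "B"), linkage=m)), p
        )
        obj = json.loads(p.read_text())
        obj["schema_version"] = "99.0"
        p.write_text(json.dumps(obj))
        with pytest.raises(ValueError, match="schema_version"):
            load_session(p)

    def test_unknown_keys_ignored_with_warning(self, tmp_path):
        p = tmp_path / "s.json"
        m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
        save_session(
            Session(dendrogram=DendroJSON(labels=("A", "B"), linkage=m)), p
        )
        obj = json.loads(p.read_text())
        obj["future_feature"] = {"x": 1}
        p.write_text(json.dumps(obj))
        with pytest.warns(UserWarning, match="future_feature"):
            load_session(p)

    def test_child_labels_must_match_parent(self, tmp_path):
        m, labels = random_linkage(8, seed=2)
        d = build_tree(m, labels)
        sess = Session(dendrogram=to_dendro_json(d))
        nid = list(d.internal_ids())[0]
        sess.add_child(nid)
        p = tmp_path / "s.json"
        save_session(sess, p)
        obj = json.loads(p.read_text())
        obj["children"][0]["dendrogram"]["labels"][0] = "INTRUDER"
        p.write_text(json.dumps(obj))
        with pytest.raises(ValueError, match="leaf labels"):
            load_session(p)
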