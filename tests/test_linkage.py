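"""Linkage encodings: validation, conversion round trips, JSON stability."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendroselect import (
    DendroJSON,
    LinkageMatrix,
    LinkageValidationError,
    SignedMergeTable,
    condensed_to_signed,
    random_linkage,
    read_linkage_json,
    signed_to_condensed,
    write_linkage_json,
)


class TestValidation:
    def test_smallest_tree_accepted(self):
        m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
        assert m.n_leaves == 2
        assert m.rows == ((0, 1, 0.5, 2),)

    def test_count_must_telescope(self):
        with pytest.raises(LinkageValidationError, match="row 0"):
            LinkageMatrix.from_array([[0, 1, 0.5, 3]])

    def test_child_used_twice_rejected(self):
        with pytest.raises(LinkageValidationError, match="already merged"):
            LinkageMatrix.from_array(
                [[0, 1, 0.1, 2], [0, 2, 0.2, 2], [3, 4, 0.3, 4]]
            )

    def test_forward_reference_rejected(self):
        with pytest.raises(LinkageValidationError, match="out of range"):
            LinkageMatrix.from_array([[0, 4, 0.1, 2], [1, 2, 0.2, 2]])

    def test_negative_height_rejected(self):
        with pytest.raises(LinkageValidationError, match="height"):
            LinkageMatrix.from_array([[0, 1, -0.5, 2]])

    def test_inversion_is_warning_not_error(self):
        with pytest.warns(UserWarning, match="inversion"):
            LinkageMatrix.from_array([[0, 1, 0.9, 2], [2, 3, 0.4, 3]])

    @pytest.mark.parametrize("seed", range(30))
    def test_fuzz_single_field_corruption_rejected(self, seed):
        """Every single-field mutation of a valid instance must be rejected."""
        rng = np.random.default_rng(seed)
        m, _ = random_linkage(int(rng.integers(3, 12)), seed=seed)
        arr = m.to_array()
        i = int(rng.integers(arr.shape[0]))
        j = int(rng.integers(3))  # corrupt a child id or the count
        col = [0, 1, 3][j]
        arr[i, col] = arr[i, col] + int(rng.integers(1, 5)) * (
            1 if col == 3 else 2 * m.n_leaves
        )
        with pytest.raises(LinkageValidationError):
            LinkageMatrix.from_array(arr)


class TestSignedConversion:
    def test_two_leaf_mapping(self):
        t = SignedMergeTable(
            merge=((-1, -2),), heights=(0.5,), order=(1, 2), labels=("A", "B")
        )
        m, labels = signed_to_condensed(t)
        assert m.rows == ((0, 1, 0.5, 2),)
        assert labels == ("A", "B")

    def test_three_leaf_mapping_with_row_reference(self):
        t = SignedMergeTable(
            merge=((-1, -2), (-3, 1)),
            heights=(0.2, 0.7),
            order=(1, 2, 3),
            labels=("A", "B", "C"),
        )
        m, _ = signed_to_condensed(t)
        assert m.rows == ((0, 1, 0.2, 2), (2, 3, 0.7, 3))

    def test_two_leaf_inverse(self):
        m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
        t = condensed_to_signed(m, ["A", "B"])
        assert t.merge == ((-1, -2),)
        assert t.heights == (0.5,)

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(LinkageValidationError, match="twice"):
            SignedMergeTable(
                merge=((-1, -1),), heights=(0.5,), order=(1, 2), labels=("A", "B")
            )

    def test_dangling_row_reference_rejected(self):
        with pytest.raises(LinkageValidationError, match="earlier row"):
            SignedMergeTable(
                merge=((-1, -2), (-3, 2)),
                heights=(0.2, 0.7),
                order=(1, 2, 3),
                labels=("A", "B", "C"),
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_double_round_trip_is_identity(self, seed):
        """condensed -> signed -> condensed preserves topology/heights/counts."""
        n = 2 + seed % 39  # spans 2..40
        m, labels = random_linkage(n, seed=seed)
        t = condensed_to_signed(m, labels)
        m2, labels2 = signed_to_condensed(t)
        assert m2 == m
        assert labels2 == labels

    def test_round_trip_order_vector_is_traversal(self):
        m, labels = random_linkage(10, seed=3)
        t = condensed_to_signed(m, labels)
        from dendroselect.linkage import leaf_order_ids

        assert t.order == tuple(i + 1 for i in leaf_order_ids(m))


class TestJsonIO:
    def test_minimal_file_reads(self, tmp_path):
        p = tmp_path / "t.json"
        p.write_text(json.dumps({"labels": ["A", "B"], "linkage": [[0, 1, 0.5, 2]]}))
        dj = read_linkage_json(p)
        assert dj.n_leaves == 2
        assert dj.linkage.rows == ((0, 1, 0.5, 2),)

    def test_invalid_rows_named_in_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"labels": ["A", "B"], "linkage": [[0, 1, 0.5, 3]]}))
        with pytest.raises(LinkageValidationError, match="row 0"):
            read_linkage_json(p)

    def test_malformed_json_raises_parse_error(self, tmp_path):
        p = tmp_path / "trunc.json"
        p.write_text('{"labels": ["A", "B"], "link')
        with pytest.raises(json.JSONDecodeError):
            read_linkage_json(p)

    def test_write_read_round_trip(self, tmp_path, three_leaf_json):
        p = tmp_path / "t.json"
        write_linkage_json(three_leaf_json, p)
        assert read_linkage_json(p) == three_leaf_json

    def test_write_is_byte_stable(self, tmp_path, three_leaf_json):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_linkage_json(three_leaf_json, p1)
        write_linkage_json(three_leaf_json, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_child_order_canonicalized(self, tmp_path):
        dj = DendroJSON(
            labels=("A", "B", "C"),
            linkage=LinkageMatrix.from_array([[1, 0, 0.2, 2], [3, 2, 0.7, 3]]),
        )
        assert dj.linkage.rows[0][:2] == (0, 1)

    def test_gzip_transparent(self, tmp_path, three_leaf_json):
        p = tmp_path / "t.json.gz"
        write_linkage_json(three_leaf_json, p)
        assert read_linkage_json(p) == three_leaf_json

    def test_node_names_round_trip(self, tmp_path):
        dj = DendroJSON(
            labels=("A", "B", "C"),
            linkage=LinkageMatrix.from_array([[0, 1, 0.2, 2], [2, 3, 0.7, 3]]),
            node_names={3: "pair", 4: "root"},
        )
        p = tmp_path / "t.json"
        write_linkage_json(dj, p)
        assert read_linkage_json(p).node_names == {3: "pair", 4: "root"}

    def test_invalid_node_name_key_rejected(self):
        with pytest.raises(LinkageValidationError, match="node_names"):
            DendroJSON(
                labels=("A", "B"),
                linkage=LinkageMatrix.from_array([[0, 1, 0.5, 2]]),
                node_names={0: "leaf"},
            )

    def test_large_instance_round_trips(self, tmp_path):
        m, labels = random_linkage(2000, seed=11)
        dj = DendroJSON(labels=labels, linkage=m)
        p = tmp_path / "big.json"
        write_linkage_json(dj, p)
        assert read_linkage_json(p) == dj


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 64))
def test_property_json_round_trip_any_instance(seed, n, tmp_path_factory):
    m, labels = random_linkage(n, seed=seed)
    dj = DendroJSON(labels=labels, linkage=m)
    p = tmp_path_factory.mktemp("rt") / "x.json"
    write_linkage_json(dj, p)
    assert read_linkage_json(p) == dj
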