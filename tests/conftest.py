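import numpy as np
import pytest

from dendroselect import DendroJSON, LinkageMatrix, build_tree


@pytest.fixture
def two_leaf():
    """Smallest dendrogram: (A, B) merged at 0.5."""
    m = LinkageMatrix.from_array([[0, 1, 0.5, 2]])
    return build_tree(m, ["A", "B"])


@pytest.fixture
def three_leaf():
    """A and B merge at 0.2; C joins at 0.7."""
    m = LinkageMatrix.from_array([[0, 1, 0.2, 2], [2, 3, 0.7, 3]])
    return build_tree(m, ["A", "B", "C"])


@pytest.fixture
def three_leaf_json():
    m = LinkageMatrix.from_array([[0, 1, 0.2, 2], [2, 3, 0.7, 3]])
    return DendroJSON(labels=("A", "B", "C"), linkage=m)


def brute_force_agglomerate(D, method="average"):
    """Independent oracle: recompute all inter-cluster distances each step.

    Clusters are explicit leaf-member lists; average linkage is the plain
    mean over all member pairs of the original distance matrix. Ties on the
    minimal distance are broken toward the smallest (id_a, id_b) pair, the
    same rule the implementation states.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    members = {i: [i] for i in range(n)}
    rows = []
    for step in range(n - 1):
        best = None
        ids = sorted(members)
        for ai, a in enumerate(ids):
            for b in ids[ai + 1:]:
                pair = D[np.ix_(members[a], members[b])]
                if method == "average":
                    d = float(pair.mean())
                elif method == "single":
                    d = float(pair.min())
                elif method == "complete":
                    d = float(pair.max())
                else:
                    raise ValueError(method)
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        rows.append((a, b, d, len(members[a]) + len(members[b])))
        members[n + step] = members.pop(a) + members.pop(b)
    return rows


@pytest.fixture
def brute_agglomerator():
    return brute_force_agglomerate
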