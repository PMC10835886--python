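"""Delimited matrix in -> standardization -> distances -> linkage -> files out.

The pipeline reproduces the headless core of a cluster-heatmap run: read a
labeled matrix from a delimited text file (delimiter inferred), optionally
z-score standardize one axis, compute pairwise distances on rows and columns
with independent metrics, agglomerate both axes, and write two interchange
JSON dendrograms plus a PNG of the matrix reordered by both leaf orders.

The agglomerator is written here rather than delegated so that its
tie-breaking is fully specified: when several cluster pairs share the
minimal inter-cluster distance, the pair with the lexicographically smallest
(id_a, id_b) node-id pair is merged. This makes outputs bit-reproducible
across platforms, which matters when the JSON files are diffed or shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .linkage import DendroJSON, LinkageMatrix, write_linkage_json
from .tree import build_tree

__all__ = [
    "LabeledMatrix",
    "ClusterParams",
    "PipelineError",
    "infer_delimiter",
    "read_labeled_matrix",
    "zscore",
    "pairwise_distance",
    "agglomerate",
    "run_pipeline",
]

Metric = Literal["euclidean", "cosine", "correlation", "cityblock"]
Method = Literal["average", "single", "complete", "ward"]

_DELIM_CANDIDATES = ("\t", ",", ";")  # tie order: tab, comma, semicolon


class PipelineError(ValueError):
    pass


@dataclass
class LabeledMatrix:
    """A dense real matrix with row and column labels."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    source_delimiter: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_labels = tuple(str(x) for x in self.row_labels)
        self.col_labels = tuple(str(x) for x in self.col_labels)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise PipelineError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_labels)} row / {len(self.col_labels)} column labels"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class ClusterParams:
    """Clustering parameters; defaults mirror a typical signature analysis:
    z-score along columns, cosine distance on rows, correlation distance on
    columns, average (UPGMA) linkage."""

    z_axis: Literal["none", "rows", "columns"] = "columns"
    row_metric: Metric = "cosine"
    col_metric: Metric = "correlation"
    method: Method = "average"

    def __post_init__(self) -> None:
        if self.method == "ward" and not (
            self.row_metric == "euclidean" and self.col_metric == "euclidean"
        ):
            raise PipelineError("ward linkage requires euclidean distances")


def infer_delimiter(text: str, max_lines: int = 20) -> str:
    """Infer the field delimiter of a delimited text head.

    The candidates tab, comma and semicolon are tried in that order; the
    first one producing a constant field count of at least 2 across the
    first ``max_lines`` non-empty lines wins.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() != ""][:max_lines]
    if len(lines) < 2:
        raise PipelineError("need at least 2 lines to infer a delimiter")
    for cand in _DELIM_CANDIDATES:
        counts = {ln.count(cand) + 1 for ln in lines}
        if len(counts) == 1 and counts.pop() >= 2:
            return cand
    raise PipelineError(
        "cannot infer the delimiter (no candidate among tab/comma/semicolon "
        "gives a constant field count >= 2); pass sep explicitly (--sep)"
    )


def read_labeled_matrix(
    path: str | Path,
    sep: str = "auto",
    impute: Literal[None, "row-mean"] = None,
) -> LabeledMatrix:
    """Read a labeled matrix from a delimited text file.

    Missing values are rejected by default, naming the first offending cell;
    pass ``impute="row-mean"`` to replace them by their row means instead.
    """
    import pandas as pd

    path = Path(path)
    if sep == "auto":
        with open(path, encoding="utf-8") as fh:
            head = "".join(fh.readline() for _ in range(21))
        sep = infer_delimiter(head)
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        if impute == "row-mean":
            row_means = np.nanmean(values, axis=1, keepdims=True)
            idx = np.where(np.isnan(values))
            values[idx] = np.broadcast_to(row_means, values.shape)[idx]
        else:
            i, j = (int(x[0]) for x in np.where(np.isnan(values)))
            raise PipelineError(
                f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}; "
                "use impute='row-mean' to impute"
            )
    return LabeledMatrix(
        values=values,
        row_labels=tuple(map(str, df.index)),
        col_labels=tuple(map(str, df.columns)),
        source_delimiter=sep,
    )


def zscore(
    m: LabeledMatrix, axis: Literal["rows", "columns"]
) -> LabeledMatrix:
    """Standardize each row or column to mean 0 and sample sd 1 (ddof=1).

    Constant vectors map to all zeros with a warning instead of dividing by
    zero; downstream metrics will still refuse them where they are
    genuinely degenerate (correlation distance).
    """
    x = m.values
    ax = 0 if axis == "columns" else 1
    if x.shape[ax] < 2:
        raise PipelineError(f"z-score along {axis} needs >= 2 entries per vector")
    mean = x.mean(axis=ax, keepdims=True)
    sd = x.std(axis=ax, ddof=1, keepdims=True)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant vector(s) along {axis} mapped to zeros"
        )
    sd = np.where(const, 1.0, sd)
    out = (x - mean) / sd
    out[np.broadcast_to(const, out.shape)] = 0.0
    return LabeledMatrix(
        values=out,
        row_labels=m.row_labels,
        col_labels=m.col_labels,
        source_delimiter=m.source_delimiter,
    )


def pairwise_distance(
    m: LabeledMatrix, metric: Metric, axis: Literal["rows", "columns"]
) -> np.ndarray:
    """Square symmetric distance matrix between rows or columns.

    cosine = 1 - u.v/(|u||v|); correlation = 1 - Pearson r. Degenerate
    vectors (zero norm under cosine, constant under correlation) raise an
    error naming the offending row/column label.
    """
    x = m.values if axis == "rows" else m.values.T
    labels = m.row_labels if axis == "rows" else m.col_labels
    if metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise PipelineError(
                f"cosine distance undefined for zero-norm {axis[:-1]} "
                f"{labels[bad[0]]!r}"
            )
    if metric == "correlation":
        sds = x.std(axis=1)
        bad = np.flatnonzero(sds == 0)
        if bad.size:
            raise PipelineError(
                f"correlation distance undefined for constant {axis[:-1]} "
                f"{labels[bad[0]]!r}"
            )
    d = squareform(pdist(x, metric=metric))
    np.fill_diagonal(d, 0.0)
    return d


def agglomerate(dist: np.ndarray, method: Method = "average") -> LinkageMatrix:
    """Agglomerative clustering of a square distance matrix.

    Average linkage is UPGMA: the distance between two clusters is the
    unweighted mean of all member-pair distances. Cluster distances are
    updated with the Lance-Williams recurrences; ties on the minimal
    distance are broken toward the lexicographically smallest (id_a, id_b)
    node-id pair, where ids follow the condensed-linkage convention.
    """
    D = np.array(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise PipelineError("distance matrix must be square")
    n = D.shape[0]
    if n < 2:
        raise PipelineError("need at least 2 observations to cluster")
    if not np.allclose(D, D.T):
        raise PipelineError("distance matrix must be symmetric")

    W = D.copy()
    np.fill_diagonal(W, np.inf)
    active = np.ones(n, dtype=bool)
    ids = np.arange(n)          # condensed node id living in each slot
    sizes = np.ones(n, dtype=np.int64)
    rows: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        h = float(W.min())  # retired slots and the diagonal hold inf
        # candidate slot pairs at the minimum; break ties on node ids
        pi, pj = np.where(W == h)
        best = None
        for si, sj in zip(pi, pj):
            if si >= sj:
                continue
            key = tuple(sorted((int(ids[si]), int(ids[sj]))))
            if best is None or key < best[0]:
                best = (key, int(si), int(sj))
        assert best is not None
        (id_a, id_b), si, sj = best
        na, nb = int(sizes[si]), int(sizes[sj])
        new_id = n + step
        rows.append((id_a, id_b, h, na + nb))

        # Lance-Williams update into slot si; retire slot sj
        other = active.copy()
        other[si] = other[sj] = False
        d_a = W[si, other]
        d_b = W[sj, other]
        if method == "average":
            upd = (na * d_a + nb * d_b) / (na + nb)
        elif method == "single":
            upd = np.minimum(d_a, d_b)
        elif method == "complete":
            upd = np.maximum(d_a, d_b)
        elif method == "ward":
            nk = sizes[other]
            upd = np.sqrt(
                ((na + nk) * d_a**2 + (nb + nk) * d_b**2 - nk * h**2)
                / (na + nb + nk)
            )
        else:
            raise PipelineError(f"unknown linkage method {method!r}")
        W[si, other] = upd
        W[other, si] = upd
        W[si, si] = np.inf
        active[sj] = False
        W[sj, :] = np.inf
        W[:, sj] = np.inf
        ids[si] = new_id
        sizes[si] = na + nb

    return LinkageMatrix(rows=tuple(rows), n_leaves=n)


def run_pipeline(
    path: str | Path,
    params: ClusterParams | None = None,
    out_dir: str | Path | None = None,
    sep: str = "auto",
    impute: Literal[None, "row-mean"] = None,
) -> tuple[DendroJSON, DendroJSON, Path]:
    """Full run: matrix file -> ``<stem>_rows.json``, ``<stem>_cols.json``,
    ``<stem>_heatmap.png`` in ``out_dir`` (default: the input's folder).

    Returns the two dendrogram bundles and the heatmap path. Errors from
    individual stages are re-raised with the stage named.
    """
    params = params or ClusterParams()
    path = Path(path)
    out_dir = Path(out_dir) if out_dir is not None else path.parent
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise PipelineError(f"[{name}] {e}") from e

    m = stage("read", read_labeled_matrix, path, sep=sep, impute=impute)
    if params.z_axis != "none":
        m = stage("zscore", zscore, m, params.z_axis)
    row_d = stage("row-distance", pairwise_distance, m, params.row_metric, "rows")
    col_d = stage("col-distance", pairwise_distance, m, params.col_metric, "columns")
    row_link = stage("row-linkage", agglomerate, row_d, params.method)
    col_link = stage("col-linkage", agglomerate, col_d, params.method)

    rows_dj = DendroJSON(labels=m.row_labels, linkage=row_link)
    cols_dj = DendroJSON(
        labels=m.col_labels, linkage=col_link, orientation="vertical"
    )
    stem = path.name
    for suffix in (".csv", ".tsv", ".txt"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    write_linkage_json(rows_dj, out_dir / f"{stem}_rows.json")
    write_linkage_json(cols_dj, out_dir / f"{stem}_cols.json")

    heatmap = out_dir / f"{stem}_heatmap.png"
    stage("heatmap", _render_heatmap, m, row_link, col_link, heatmap)
    return rows_dj, cols_dj, heatmap


def _render_heatmap(
    m: LabeledMatrix, row_link: LinkageMatrix, col_link: LinkageMatrix, path: Path
) -> None:
    """Plain image of the matrix reordered by both dendrograms' leaf orders
    (no embedded tree drawing — a viewer overlays its own dendrogram)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .linkage import leaf_order_ids

    ri = leaf_order_ids(row_link)
    ci = leaf_order_ids(col_link)
    data = m.values[np.ix_(ri, ci)]
    fig, ax = plt.subplots(
        figsize=(max(2.0, min(12.0, data.shape[1] / 8)),
                 max(2.0, min(12.0, data.shape[0] / 8))),
        dpi=120,
    )
    ax.imshow(data, aspect="auto", interpolation="nearest", cmap="RdBu_r")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
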