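# Methods

## Data model

Everything reduces to the condensed linkage matrix: `(n−1)` rows
`(child_a, child_b, height, count)` over node ids `0..2n−2`, leaves first.
Validation enforces the structural invariants (each non-root node consumed
exactly once as a child, counts telescoping to `n` at the root, finite
nonnegative heights). Two deliberate relaxations:

* **Height monotonicity is not an error.** Some linkage methods (centroid,
  median) legitimately produce inversions, and files from other tools may
  carry them. A parent merging below a child triggers a warning; Newick
  export clamps the resulting negative branch lengths to 0, again with a
  warning. Strictness here would reject real-world inputs for no analytical
  gain.
* **Within-row child order is not meaningful.** Rows are canonicalized to
  `child_a < child_b` when they enter the interchange bundle, so equality,
  display order and written bytes agree. Display (leaf) order is the
  depth-first traversal visiting `child_a` first — recomputed from the
  canonicalized linkage rather than trusted from an upstream `order` vector,
  which can therefore differ from the ordering another tool displayed for
  the same clustering.

The signed merge encoding maps leaf `−k` ↔ id `k−1` and merge row `j`
(1-based) ↔ id `n+j−1`; conversions recompute counts and are exact inverses
up to the canonical child order. JSON files carry
`{schema_version, labels, linkage, node_names, orientation}`; this schema is
original to this package and not claimed byte-compatible with any deployed
viewer's internal files. Output is byte-stable (sorted keys, shortest
round-trip float representation) so files can be diffed; `.json.gz` is
handled transparently by extension.

## Selection and sessions

Selections are immutable values: selecting appends the next color of a fixed
12-color categorical palette, cycling modulo 12 by the number of colors
*ever assigned*, so unselecting never recolors survivors and exports stay
stable across edits. Leaves cannot be selected; re-selecting a selected node
is an error rather than a toggle, keeping histories explicit. Overlapping
and nested selections are allowed — the membership export is long-format
(one row per leaf per covering selection) precisely so nesting loses
nothing. Ancestor-of-selected selection is not blocked.

Child extraction renumbers the subtree's `m` leaves `0..m−1` in the parent's
display order and keeps the parent's internal rows in original order with
heights unchanged; counts are recomputed. Extraction composes: cutting a
grandchild out of a child equals cutting it out of the original.

Sessions serialize the dendrogram, selection state, and children *fully
materialized* (not as node references), so one file reconstructs the state
anywhere. Loading validates everything before returning (no partial state
from truncated files), errors on a schema-version mismatch, checks each
child's labels against the parent subtree, and ignores unknown keys with a
warning so files from future minor versions stay readable.

## Clustering pipeline

Delimiter inference tries tab, comma, semicolon in that order and accepts
the first candidate giving a constant field count ≥ 2 over the first 20
lines; ambiguity resolves by that fixed order, and failure instructs the
caller to pass the separator explicitly. Missing values are rejected naming
the cell — silent imputation corrupts distances — with opt-in row-mean
imputation.

Z-scoring uses the sample standard deviation (ddof = 1); constant vectors
become zeros with a warning rather than NaN. Distances come from
`scipy.spatial.distance.pdist` after explicit degeneracy checks that name
the offending row/column (zero norm under cosine, constant under
correlation).

The agglomerator is implemented here, not delegated, because its tie rule is
part of the contract: at each step the minimal inter-cluster distance is
found and, among exactly-equal minima, the pair with the lexicographically
smallest `(id_a, id_b)` merges. Updates use the Lance–Williams recurrences
(UPGMA, single, complete, Ward; Ward restricted to euclidean input). This
makes outputs deterministic across platforms and lets a brute-force oracle
(recomputing every inter-cluster mean from the original matrix each step)
check it exactly; the test suite also cross-checks cophenetic matrices
against `scipy.cluster.hierarchy.linkage` on tie-free inputs. Complexity is
O(n³) time / O(n²) memory — fine for the hundreds-to-low-thousands of
observations a heatmap axis carries; the synthetic-linkage generator, which
needs 10⁴ leaves, delegates to scipy's O(n²) nearest-neighbor-chain
implementation instead.

Pipeline defaults mirror a typical signature analysis: z-score along
columns, cosine distance on rows, correlation distance on columns, average
linkage. The heatmap output is a plain reordered-matrix image without an
embedded tree drawing; consumers overlay their own dendrogram.

## Replicate QC

ACD of a `k×g` replicate block is the mean of the `k(k−1)/2` pairwise
cosine distances; it is scale-invariant per row, 0 for identical replicates,
and concentrates near 1 for independent directions as `g` grows (at
`g = 978` the spread is a few percent). It is undefined for `k < 2` and for
zero-norm rows, both hard errors.

Filtering keeps compounds with at least `min_experiments = 10` experiments
and unweighted mean per-experiment ACD strictly below `max_acd = 0.9`; the
boundary semantics (≥ 10, < 0.9) are exercised explicitly in tests. "Mean of
per-experiment ACDs" was chosen over pooling all replicate pairs because it
weights experiments equally regardless of replicate count. Unnamed
compounds — blank, missing, or matching a configurable bare-identifier
pattern (default: Broad `BRD-…` ids) — are dropped before counting.
Compound signatures are per-gene means of experiment signatures (experiment
signature = mean of its replicate rows), not renormalized: cosine distances
downstream are scale-invariant, and renormalizing would discard magnitude
without buying anything.

One ambiguity is resolved conservatively: whether a separate significance
score beyond the ACD criterion gates compounds is not specified by the
analyses this mirrors; only the ACD criterion is implemented. Likewise ACD
accepts any `k×g` replicate block and leaves the provenance of those rows
(raw profiles vs per-replicate signatures) to the caller.

## Synthetic data

All generators take an explicit seed and use one local
`numpy.random.Generator`; same spec + seed ⇒ identical bytes.

* `random_linkage(n, seed)`: average-linkage agglomeration of i.i.d.
  uniform(0,1) dissimilarities — valid linkage structure with realistic
  height/count patterns.
* `planted_matrix`: cluster centers are a random *orthonormal frame* scaled
  so every between-center distance is `separation · noise_sd`, plus
  isotropic Gaussian noise. The frame is dense in all columns on purpose:
  axis-aligned centers would be erased by column-wise z-scoring (the one
  signal column gets divided by its large sd), whereas a dense frame is
  rescaled roughly uniformly and the planted geometry survives the
  pipeline's default standardization. Default `separation = 10` is far
  above the recovery threshold; `separation = 0` is the null.
* `replicate_signatures`: per compound a latent unit direction `u`;
  replicates are `u + σ·ε` with `σ² = (1−t)/(t·g)` so the expected
  within-experiment cosine similarity is `t` (`t = 1` ⇒ exact copies,
  `t = 0` ⇒ pure noise, ACD ≈ 1 at `g = 978`). Defaults (20 compounds ×
  10 experiments × 3 replicates, 978 genes) give every compound exactly the
  filter's minimum experiment count, so the QC defaults keep all of them
  when concordance is high.

What passing on these fixtures does *not* show: real signature matrices have
gene–gene covariance, heavy-tailed effects, batch structure and unequal
replicate counts; the generators emulate only the separation and concordance
structure the methods consume. Results on real data depend on those unmodeled
features.

## Problem sizes and budgets

The shipped verification uses: capacity workflow at 10,000 leaves (runs in
well under a minute), 500 brute-force-oracle comparisons at n ≤ 8, 200
round-trip instances at n ∈ 2..64, planted recovery at 60×50 with k = 3, and
a 30-leaf R-side clustering for the cross-language check. These sizes make
the whole suite fast while still exercising every code path at its intended
scale; the capacity case is the one deliberately large instance.

## Known limitations

* No graphical tree rendering or interactive view; exports (Newick,
  membership TSV, session JSON, PNG) are the interface.
* The agglomerator's O(n³) loop is not meant for axes beyond a few thousand
  observations.
* Serialized clustering objects from other ecosystems (RDS, pickle) are not
  parsed; the R helper exports plain tables/JSON instead.
* Optimal leaf ordering is not implemented; display order is the canonical
  traversal.
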