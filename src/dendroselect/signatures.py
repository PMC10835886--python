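"""Replicate-signature quality control and per-compound aggregation.

In perturbation-transcriptomics screens (L1000-style), each experiment
(one compound, cell line, dose, time) yields several replicate
differential-expression signatures — by convention vectors over 978
landmark genes, though any length is accepted. The *average cosine
distance* (ACD) among an experiment's replicate signatures measures the
experiment's strength: concordant replicates (small ACD) indicate a real,
reproducible transcriptional response, while ACD near 1 is what random
directions in high dimension produce.

The standard aggregation path implemented here:

1. score every experiment by its replicate ACD;
2. keep only named compounds tested in at least ``min_experiments``
   experiments with a mean ACD below ``max_acd`` (defaults 10 and 0.9);
3. average each surviving compound's experiment signatures into a single
   per-compound signature;
4. assemble the compounds x genes matrix, ready for the clustering
   pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .pipeline import LabeledMatrix

__all__ = [
    "SignatureSet",
    "acd",
    "acd_per_experiment",
    "filter_compounds",
    "average_signature",
    "build_compound_matrix",
    "qc_report",
]

# LINCS-style bare Broad identifiers do not count as compound names
DEFAULT_UNNAMED_PATTERN = r"^BRD-[A-Z0-9-]+$"


@dataclass
class SignatureSet:
    """Replicate-level signatures with compound and experiment grouping.

    ``signatures`` holds one row per replicate signature; ``replicate_group``
    keys rows into experiments (replicates share a key) and ``compound``
    names the perturbagen of each row. An experiment's signature is the mean
    of its replicate rows, so a set whose rows are already experiment-level
    signatures (one row per group) works unchanged.
    """

    signatures: pd.DataFrame  # rows: replicates, columns: gene ids
    compound: pd.Series
    replicate_group: pd.Series

    def __post_init__(self) -> None:
        n = len(self.signatures)
        self.compound = pd.Series(
            np.asarray(self.compound, dtype=object), index=self.signatures.index
        )
        self.replicate_group = pd.Series(
            np.asarray(self.replicate_group, dtype=object),
            index=self.signatures.index,
        )
        if len(self.compound) != n or len(self.replicate_group) != n:
            raise ValueError("grouping columns must match the signature rows")
        if n == 0:
            raise ValueError("empty signature set")
        if any(str(g) == "" for g in self.replicate_group):
            raise ValueError("replicate_group keys must be non-empty")

    @property
    def experiment_ids(self) -> list:
        return list(dict.fromkeys(self.replicate_group))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(map(str, self.signatures.columns))

    def experiment_signatures(self) -> pd.DataFrame:
        """Experiments x genes: mean over each experiment's replicates."""
        return self.signatures.groupby(self.replicate_group, sort=False).mean()

    def experiment_compound(self) -> pd.Series:
        """Compound of each experiment (must be unique within experiment)."""
        mapping = {}
        for g, c in zip(self.replicate_group, self.compound):
            if g in mapping and mapping[g] != c:
                raise ValueError(
                    f"experiment {g!r} spans two compounds ({mapping[g]!r}, {c!r})"
                )
            mapping[g] = c
        return pd.Series(mapping)


def acd(replicates: np.ndarray | pd.DataFrame) -> float:
    """Average cosine distance over all unordered replicate pairs.

    For k replicate signatures this is the mean of the k(k-1)/2 pairwise
    cosine distances ``1 - u.v/(|u||v|)``; the result lies in [0, 2], with 0
    for perfectly concordant replicates. Undefined for a single replicate
    and for zero-norm rows.
    """
    x = np.asarray(replicates, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("ACD is undefined for singletons (need >= 2 replicates)")
    norms = np.linalg.norm(x, axis=1)
    if (norms == 0).any():
        raise ValueError("ACD undefined: zero-norm replicate signature")
    return float(pdist(x, metric="cosine").mean())


def acd_per_experiment(s: SignatureSet) -> dict:
    """ACD of every experiment with >= 2 replicates, keyed by group."""
    out = {}
    for g, idx in s.signatures.groupby(s.replicate_group, sort=False).groups.items():
        block = s.signatures.loc[idx]
        if len(block) >= 2:
            out[g] = acd(block.to_numpy())
    return out


def _is_named(compound: object, unnamed_pattern: str) -> bool:
    name = str(compound).strip()
    if name == "" or name.lower() in ("nan", "none", "-666"):
        return False
    return re.match(unnamed_pattern, name) is None


def filter_compounds(
    s: SignatureSet,
    per_experiment_acd: Mapping,
    min_experiments: int = 10,
    max_acd: float = 0.9,
    unnamed_pattern: str = DEFAULT_UNNAMED_PATTERN,
) -> list:
    """Compounds tested in enough strong experiments.

    A compound is kept when it has at least ``min_experiments`` experiments
    with an ACD value and the unweighted mean of those per-experiment ACDs
    is strictly below ``max_acd``. Unnamed compounds (blank, missing, or
    matching the bare-identifier pattern) are dropped first. The filter is
    monotone: tightening either threshold never adds a compound.
    """
    exp_compound = s.experiment_compound()
    per_compound: dict = {}
    for g, c in exp_compound.items():
        if g not in per_experiment_acd:
            raise ValueError(f"experiment {g!r} has no ACD value")
        per_compound.setdefault(c, []).append(float(per_experiment_acd[g]))
    kept = []
    for c in dict.fromkeys(exp_compound):  # first-appearance order
        if not _is_named(c, unnamed_pattern):
            continue
        acds = per_compound[c]
        if len(acds) >= min_experiments and float(np.mean(acds)) < max_acd:
            kept.append(c)
    return kept


def average_signature(s: SignatureSet, compound) -> np.ndarray:
    """Per-gene arithmetic mean over a compound's experiment signatures.

    The average is not re-normalized to unit length: downstream cosine
    distances are scale-invariant, so renormalization would change nothing
    they see while discarding the magnitude information other consumers may
    want.
    """
    exp_sig = s.experiment_signatures()
    exp_compound = s.experiment_compound()
    rows = exp_sig.loc[exp_compound[exp_compound == compound].index]
    if rows.empty:
        raise KeyError(f"unknown compound {compound!r}")
    return rows.to_numpy().mean(axis=0)


def build_compound_matrix(
    s: SignatureSet,
    min_experiments: int = 10,
    max_acd: float = 0.9,
    unnamed_pattern: str = DEFAULT_UNNAMED_PATTERN,
) -> LabeledMatrix:
    """Compounds x genes matrix of filtered, averaged signatures.

    Feeds the clustering pipeline directly. Raises if the filter leaves no
    compound.
    """
    acds = acd_per_experiment(s)
    kept = filter_compounds(
        s, acds, min_experiments=min_experiments, max_acd=max_acd,
        unnamed_pattern=unnamed_pattern,
    )
    if not kept:
        raise ValueError("no compound survives the filters")
    mat = np.vstack([average_signature(s, c) for c in kept])
    return LabeledMatrix(
        values=mat,
        row_labels=tuple(str(c) for c in kept),
        col_labels=s.gene_ids,
    )


def qc_report(
    s: SignatureSet,
    min_experiments: int = 10,
    max_acd: float = 0.9,
    unnamed_pattern: str = DEFAULT_UNNAMED_PATTERN,
) -> pd.DataFrame:
    """Per-compound QC table: n_experiments, mean ACD, kept flag."""
    acds = acd_per_experiment(s)
    exp_compound = s.experiment_compound()
    kept = set(
        filter_compounds(
            s, acds, min_experiments=min_experiments, max_acd=max_acd,
            unnamed_pattern=unnamed_pattern,
        )
    )
    rows = []
    for c in dict.fromkeys(exp_compound):
        groups = exp_compound[exp_compound == c].index
        vals = [acds[g] for g in groups if g in acds]
        rows.append(
            {
                "compound": c,
                "n_experiments": len(vals),
                "mean_acd": float(np.mean(vals)) if vals else np.nan,
                "kept": c in kept,
            }
        )
    return pd.DataFrame(rows)
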