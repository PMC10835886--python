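"""Deterministic generators for every input the package consumes.

Three generators cover the test surface: random valid linkage structures
(agglomerated from uniform random dissimilarities), planted-cluster
matrices with a controllable separation-to-noise ratio, and replicate
signature sets whose within-experiment cosine similarity is calibrated to a
target. Each is a pure function of its parameters and an explicit seed — a
single local ``numpy.random.Generator`` per call, never global RNG state —
so fixtures are byte-reproducible across platforms.

The replicate generator emulates only the statistical structure the
downstream analysis relies on (a shared latent direction per compound,
isotropic replicate noise); it does not attempt real gene-gene covariance.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .linkage import LinkageMatrix
from .pipeline import LabeledMatrix
from .signatures import SignatureSet

__all__ = [
    "PlantedClusterSpec",
    "ReplicateSpec",
    "random_linkage",
    "planted_matrix",
    "replicate_signatures",
]


def _labels(n: int, prefix: str = "L") -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def random_linkage(
    n: int, seed: int, method: str = "average"
) -> tuple[LinkageMatrix, tuple[str, ...]]:
    """A valid random linkage: agglomeration of uniform random distances.

    Dissimilarities are drawn i.i.d. uniform on (0, 1) and agglomerated
    (average linkage by default), yielding a linkage with the height and
    count structure of a real clustering rather than an arbitrary tree.
    """
    if n < 2:
        raise ValueError("need n >= 2 leaves")
    rng = np.random.default_rng(seed)
    condensed = rng.uniform(size=n * (n - 1) // 2)
    z = sch.linkage(condensed, method=method)
    return LinkageMatrix.from_array(z).canonicalized(), _labels(n)


@dataclass(frozen=True)
class PlantedClusterSpec:
    """k Gaussian blobs at simplex vertices, ``separation`` noise-sds apart."""

    n_rows: int = 60
    n_cols: int = 50
    k_clusters: int = 3
    separation: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k_clusters <= self.n_rows):
            raise ValueError("need 1 <= k_clusters <= n_rows")
        if self.separation < 0 or self.noise_sd <= 0:
            raise ValueError("separation >= 0 and noise_sd > 0 required")
        if self.k_clusters > self.n_cols:
            raise ValueError("need k_clusters <= n_cols for simplex centers")


def planted_matrix(spec: PlantedClusterSpec) -> tuple[LabeledMatrix, np.ndarray]:
    """Matrix with planted row clusters, plus the ground-truth assignment.

    Cluster centers are the vertices of a regular simplex: k mutually
    orthogonal equal-norm directions (a random orthonormal frame from a QR
    decomposition) scaled so every between-center distance equals
    ``separation * noise_sd``. Rows are centers plus isotropic Gaussian
    noise of sd ``noise_sd``. The frame is dense in all columns, so
    column-wise standardization rescales the geometry roughly uniformly
    instead of erasing it. With separation 0 all rows share one center and
    the partition is unrecoverable beyond chance.
    """
    rng = np.random.default_rng(spec.seed)
    assign = np.arange(spec.n_rows) % spec.k_clusters
    rng.shuffle(assign)
    frame, _ = np.linalg.qr(rng.normal(size=(spec.n_cols, spec.k_clusters)))
    # orthogonal centers with |c_i - c_j| = sqrt(2) |c| = separation * sd
    centers = frame.T * (spec.separation * spec.noise_sd / np.sqrt(2.0))
    values = centers[assign] + rng.normal(scale=spec.noise_sd,
                                          size=(spec.n_rows, spec.n_cols))
    m = LabeledMatrix(
        values=values,
        row_labels=_labels(spec.n_rows, "R"),
        col_labels=_labels(spec.n_cols, "C"),
    )
    return m, assign


@dataclass(frozen=True)
class ReplicateSpec:
    """Replicate signature sets with a target within-experiment cosine.

    ``within_cosine_target`` is the expected cosine similarity between two
    replicates of the same experiment: 1 means identical replicates (ACD 0),
    0 means pure noise (ACD near 1 in high dimension).
    """

    n_compounds: int = 20
    experiments_per_compound: int = 10
    replicates_per_experiment: int = 3
    g: int = 978
    within_cosine_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_experiment < 2:
            raise ValueError("need >= 2 replicates per experiment")
        if not (0.0 <= self.within_cosine_target <= 1.0):
            raise ValueError("within_cosine_target must lie in [0, 1]")


def _noise_sigma(target: float, g: int) -> float:
    # replicate = u + sigma*eps with |u| = 1, eps ~ N(0, I_g):
    # E[x.y] = 1, E[|x|^2] = 1 + sigma^2 g, so the expected cosine between
    # two replicates is ~ 1 / (1 + sigma^2 g); invert for sigma.
    return float(np.sqrt((1.0 - target) / (target * g)))


def replicate_signatures(spec: ReplicateSpec) -> SignatureSet:
    """Synthetic replicate-level signature set.

    Each compound gets a latent unit direction on the g-sphere; each
    replicate is that direction plus isotropic Gaussian noise with the sd
    that makes the expected within-experiment cosine similarity equal the
    target. At target 0 the latent direction is dropped entirely (pure
    noise). Compounds are named ``CPD-AA`` style; experiments are keyed
    ``<compound>:eN``.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = string.ascii_uppercase
    names = []
    i = 0
    while len(names) < spec.n_compounds:
        names.append("CPD-" + alpha[i // 26] + alpha[i % 26])
        i += 1

    rows, compounds, groups, row_ids = [], [], [], []
    pure_noise = spec.within_cosine_target == 0.0
    sigma = None if pure_noise else _noise_sigma(spec.within_cosine_target, spec.g)
    for name in names:
        u = rng.normal(size=spec.g)
        u /= np.linalg.norm(u)
        for e in range(spec.experiments_per_compound):
            gkey = f"{name}:e{e}"
            for r in range(spec.replicates_per_experiment):
                if pure_noise:
                    x = rng.normal(size=spec.g)
                elif sigma == 0.0:
                    x = u.copy()
                else:
                    x = u + sigma * rng.normal(size=spec.g)
                rows.append(x)
                compounds.append(name)
                groups.append(gkey)
                row_ids.append(f"{gkey}:r{r}")

    df = pd.DataFrame(
        np.vstack(rows),
        index=row_ids,
        columns=[f"G{j:03d}" for j in range(spec.g)],
    )
    return SignatureSet(
        signatures=df,
        compound=pd.Series(compounds, index=row_ids),
        replicate_group=pd.Series(groups, index=row_ids),
    )
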