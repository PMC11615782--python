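"""Phylogeny-aware OTU embeddings.

Each OTU is represented by its vector of patristic distances to every OTU;
PCA of these vectors (rows of the distance matrix, columns mean-centered)
yields a dense low-dimensional embedding per OTU. Also provides the
phylogenetic-signal-removal ablation used to probe how much the embeddings
contribute to downstream models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "EmbeddingMatrix",
    "pca_embed",
    "remove_phylo_signal",
    "DEFAULT_EMBED_DIM",
]

#: Default embedding dimension, clipped to the leaf count for small trees.
DEFAULT_EMBED_DIM = 64


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative leaf-by-leaf distance matrix with labels."""

    D: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("distance matrix must be square")
        if self.D.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")

    @property
    def m(self) -> int:
        return self.D.shape[0]


@dataclass
class EmbeddingMatrix:
    """Per-OTU embedding rows, columns ordered by nonincreasing variance."""

    X: np.ndarray
    labels: list[str]
    explained_variance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("label count does not match row count")
        if self.explained_variance is None:
            self.explained_variance = np.zeros(self.X.shape[1])
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def pca_embed(distances: DistanceMatrix, d: int = DEFAULT_EMBED_DIM) -> EmbeddingMatrix:
    """First ``d`` principal-component scores of the distance-matrix rows.

    Columns are mean-centered, no unit-variance scaling. The sign of each
    component is fixed so that the largest-magnitude loading is positive,
    making outputs reproducible across linear-algebra backends.

    Raises
    ------
    ValueError
        If ``d`` is not in ``[1, m]`` or the matrix contains non-finite
        entries.
    """
    m = distances.m
    if d < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {d}")
    if d > m:
        raise ValueError(f"embedding dimension {d} exceeds leaf count {m}")
    D = distances.D
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")

    centered = D - D.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    U, S, Vt = U[:, :d], S[:d], Vt[:d]

    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(d), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = U * S * flip

    explained = S**2 / max(m - 1, 1)
    return EmbeddingMatrix(X=scores, labels=list(distances.labels), explained_variance=explained)


def remove_phylo_signal(
    embeddings: EmbeddingMatrix, fraction: float, rng_seed: int
) -> EmbeddingMatrix:
    """Replace a random subset of OTU rows by scale-matched noise.

    Exactly ``round(fraction * m)`` rows, chosen uniformly at random under
    ``rng_seed``, are overwritten with i.i.d. standard-normal draws scaled
    to the per-column standard deviation of the original embeddings. This
    destroys phylogenetic structure while preserving magnitude, so the
    ablation probes information content rather than scale.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    rng = np.random.default_rng(rng_seed)
    m = embeddings.m
    n_replace = int(round(fraction * m))
    X = embeddings.X.copy()
    if n_replace > 0:
        rows = rng.choice(m, size=n_replace, replace=False)
        col_sd = embeddings.X.std(axis=0, ddof=0)
        X[rows] = rng.standard_normal((n_replace, embeddings.d)) * col_sd
    return EmbeddingMatrix(
        X=X,
        labels=list(embeddings.labels),
        explained_variance=embeddings.explained_variance.copy(),
    )
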