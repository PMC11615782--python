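"""Unsupervised feature pipeline and clustering evaluation.

Pipeline: robust centered-log-ratio transform of the abundance table with
zeros treated as missing, low-rank completion to get per-sample abundance
features (RPCA), presence-based summation pooling of OTU embeddings to get
per-sample phylogeny features, and concatenation into fused features.

Evaluation: PERMANOVA pseudo-F on Euclidean distances, K-means adjusted
Rand index, and stratified cross-validated KNN AUPRC/APS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from deepphylo.embed import EmbeddingMatrix
from deepphylo.metrics import threshold_curves
from deepphylo.table import AbundanceTable

__all__ = [
    "SampleFeatures",
    "rclr_transform",
    "rpca_complete",
    "rpca_features",
    "sum_pool_phylo",
    "fuse_features",
    "permanova_f",
    "kmeans_ari",
    "knn_eval",
]


@dataclass
class SampleFeatures:
    """n x q per-sample feature matrix with a provenance tag."""

    F: np.ndarray
    sample_labels: list[str]
    feature_kind: str  # "abundance" | "phylogeny" | "fused"
    converged: bool = True

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] != len(self.sample_labels):
            raise ValueError("feature matrix rows must match sample labels")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("non-finite feature entries")
        if self.feature_kind not in ("abundance", "phylogeny", "fused"):
            raise ValueError(f"unknown feature_kind: {self.feature_kind!r}")

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def q(self) -> int:
        return self.F.shape[1]


def rclr_transform(table: AbundanceTable) -> np.ndarray:
    """Robust centered log-ratio: zeros become NaN (missing), each observed
    entry is log(value) minus the mean log over observed entries of its
    sample (column)."""
    X = table.values
    zero_per_sample = (X == 0).all(axis=0)
    if zero_per_sample.any():
        j = int(np.where(zero_per_sample)[0][0])
        raise ValueError(f"sample {table.sample_labels[j]!r} has no nonzero entries")
    with np.errstate(divide="ignore"):
        L = np.where(X > 0, np.log(np.where(X > 0, X, 1.0)), np.nan)
    col_means = np.nanmean(L, axis=0, keepdims=True)
    return L - col_means


def _truncated_svd(M: np.ndarray, rank: int):
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    return U[:, :rank], S[:rank], Vt[:rank]


def rpca_complete(
    M: np.ndarray, rank: int, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Low-rank completion of an rclr matrix with NaNs as missing entries.

    Iterative imputation: fill missing entries with the current rank-``rank``
    reconstruction, refit a truncated SVD, repeat until the imputed values
    change by less than ``tol`` (RMS) or ``max_iter`` is reached. Returns
    (U, S, Vt, converged).
    """
    missing = np.isnan(M)
    filled = np.where(missing, 0.0, M)
    converged = not missing.any()
    U, S, Vt = _truncated_svd(filled, rank)
    if missing.any():
        for _ in range(max_iter):
            recon = (U * S) @ Vt
            new_filled = np.where(missing, recon, M)
            delta = np.sqrt(np.mean((new_filled[missing] - filled[missing]) ** 2))
            filled = new_filled
            U, S, Vt = _truncated_svd(filled, rank)
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"RPCA did not converge in {max_iter} iterations (last delta {delta:.3g})",
                stacklevel=2,
            )
    return U, S, Vt, converged


def rpca_features(
    table: AbundanceTable,
    rank: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SampleFeatures:
    """Per-sample scores from a low-rank completion of the rclr matrix.

    On non-convergence the result is still returned, with
    ``converged=False`` and a warning (never silently).
    """
    if rank < 1 or rank > min(table.m, table.n):
        raise ValueError(f"rank must be in [1, min(m, n)], got {rank}")
    M = rclr_transform(table)
    U, S, Vt, converged = rpca_complete(M, rank, max_iter=max_iter, tol=tol)

    # deterministic sign: largest-|entry| of each left singular vector positive
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(rank)])
    flip[flip == 0] = 1.0
    scores = (Vt.T * S) * flip  # n x rank
    return SampleFeatures(
        F=scores,
        sample_labels=list(table.sample_labels),
        feature_kind="abundance",
        converged=converged,
    )


def sum_pool_phylo(table: AbundanceTable, embeddings: EmbeddingMatrix) -> SampleFeatures:
    """Per-sample sum of embedding rows over OTUs present in the sample.

    Presence-based: any positive abundance contributes the OTU's embedding
    exactly once, so the result is invariant to rescaling abundances.
    """
    missing = set(table.otu_labels) - set(embeddings.labels)
    if missing:
        raise ValueError(f"OTUs missing from embeddings: {sorted(missing)[:10]}")
    index = {lab: i for i, lab in enumerate(embeddings.labels)}
    rows = np.array([index[lab] for lab in table.otu_labels], dtype=np.intp)
    E = embeddings.X[rows]  # aligned to table OTU order
    presence = (table.values > 0).astype(float)  # m x n
    F = presence.T @ E  # n x d
    return SampleFeatures(F=F, sample_labels=list(table.sample_labels), feature_kind="phylogeny")


def _zscore_block(F: np.ndarray) -> np.ndarray:
    mean = F.mean(axis=0, keepdims=True)
    sd = F.std(axis=0, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (F - mean) / sd


def fuse_features(
    abundance: SampleFeatures,
    phylogeny: SampleFeatures,
    standardize: bool = True,
) -> SampleFeatures:
    """Concatenate abundance and phylogeny blocks per sample.

    With ``standardize`` (default) each block is z-scored per column first,
    since the two blocks live on incommensurate scales.
    """
    if abundance.sample_labels != phylogeny.sample_labels:
        raise ValueError("sample labels differ between feature blocks")
    A = _zscore_block(abundance.F) if standardize else abundance.F
    P = _zscore_block(phylogeny.F) if standardize else phylogeny.F
    return SampleFeatures(
        F=np.hstack([A, P]),
        sample_labels=list(abundance.sample_labels),
        feature_kind="fused",
    )


def permanova_f(
    features: SampleFeatures,
    groups,
    n_permutations: int = 999,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA pseudo-F on Euclidean distances, p-value by permutation.

    F = (SS_between / (a - 1)) / (SS_within / (N - a)) with sums of squares
    defined from pairwise squared distances. SS_within = 0 yields +inf with
    a warning.
    """
    groups = np.asarray(groups)
    F = features.F
    N = F.shape[0]
    if len(groups) != N:
        raise ValueError("group labels must match sample count")
    uniq, counts = np.unique(groups, return_counts=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"groups with < 2 samples: {list(small)}")

    sq = _pairwise_sq_dists(F)

    def pseudo_f(labels: np.ndarray) -> float:
        ss_total = sq.sum() / (2 * N)
        ss_within = 0.0
        for g in uniq:
            idx = np.where(labels == g)[0]
            ss_within += sq[np.ix_(idx, idx)].sum() / (2 * len(idx))
        ss_between = ss_total - ss_within
        if ss_within == 0:
            return np.inf
        return (ss_between / (a - 1)) / (ss_within / (N - a))

    f_obs = pseudo_f(groups)
    if np.isinf(f_obs):
        warnings.warn("SS_within is zero; pseudo-F reported as +inf", stacklevel=2)

    rng = np.random.default_rng(rng_seed)
    exceed = 1
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(groups)) >= f_obs:
            exceed += 1
    p = exceed / (n_permutations + 1)
    return float(f_obs), float(p)


def _pairwise_sq_dists(F: np.ndarray) -> np.ndarray:
    sq_norms = np.sum(F**2, axis=1)
    sq = sq_norms[:, None] + sq_norms[None, :] - 2 * F @ F.T
    np.fill_diagonal(sq, 0.0)
    return np.maximum(sq, 0.0)


def kmeans_ari(
    features: SampleFeatures,
    true_labels,
    k: int,
    n_init: int = 10,
    rng_seed: int = 0,
) -> float:
    """Adjusted Rand index of K-means cluster assignments vs. true labels."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > features.n:
        raise ValueError(f"k={k} exceeds sample count {features.n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed)
    assign = km.fit_predict(features.F)
    return float(adjusted_rand_score(np.asarray(true_labels), assign))


def knn_eval(
    features: SampleFeatures,
    labels,
    k_neighbors: int = 5,
    n_folds: int = 10,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Stratified cross-validated KNN; pooled out-of-fold scores give
    AUPRC (trapezoidal PR area) and APS (step-wise average precision).

    Multiclass labels are macro-averaged one-vs-rest.
    """
    labels = np.asarray(labels)
    F = features.F
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples; "
            f"use n_folds <= {counts.min()}"
        )

    oof = np.zeros((len(labels), len(classes)))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    for train_idx, test_idx in skf.split(F, labels):
        knn = KNeighborsClassifier(n_neighbors=k_neighbors)
        knn.fit(F[train_idx], labels[train_idx])
        proba = knn.predict_proba(F[test_idx])
        cols = [int(np.where(classes == c)[0][0]) for c in knn.classes_]
        oof[np.ix_(test_idx, cols)] = proba

    auprcs, apss = [], []
    for ci, c in enumerate(classes if len(classes) > 2 else classes[1:]):
        col = ci if len(classes) > 2 else 1
        curves = threshold_curves(oof[:, col], (labels == c).astype(int))
        auprcs.append(curves["aupr"])
        apss.append(curves["aps"])
    return float(np.mean(auprcs)), float(np.mean(apss))
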