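"""Synthetic benchmark generator.

Counts: a Gaussian copula ("normal to anything") with correlation decaying
exponentially in patristic distance, mapped through zero-inflated
negative-binomial marginals, gives correlated sparse counts over a random
birth-death tree.

Outcomes: OTUs are partitioned into K phylogenetic clusters
(average-linkage on patristic distances); a random subset of clusters is
outcome-associated, each with effect beta_k ~ N(0, sigma_beta^2); the
per-sample linear predictor eta_i sums beta_k times the relative abundance
of each member OTU (with the sign flipped on a random half of each cluster
in the non-informative condition); y_i ~ Bernoulli(sigmoid(eta_i)).
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import nbinom, norm

from deepphylo.embed import DistanceMatrix
from deepphylo.model import split_dataset
from deepphylo.table import AbundanceTable
from deepphylo.tree import PhyloTree, patristic_distance_matrix

__all__ = [
    "SimulationDesign",
    "OutcomeModel",
    "SimulatedDataset",
    "simulate_tree",
    "cluster_otus",
    "norta_counts",
    "simulate_outcomes",
    "make_benchmark",
]


@dataclass
class SimulationDesign:
    """Knobs of one simulation condition."""

    n_samples: int = 400
    m_otus: int = 927
    K_clusters: int = 20
    signal_density: float = 0.2
    informative: bool = True
    sigma_beta_sq: float = 4.0
    zero_inflation: float = 0.3
    dispersion: float = 0.02
    correlation_decay: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.signal_density <= 1:
            raise ValueError("signal_density must be in (0, 1]")
        if self.sigma_beta_sq <= 0:
            raise ValueError("sigma_beta_sq must be > 0")
        if self.K_clusters > self.m_otus:
            raise ValueError("K_clusters cannot exceed m_otus")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")


@dataclass
class OutcomeModel:
    """The drawn outcome-association structure."""

    clusters: list  # list of np.ndarray of OTU indices, length K
    associated: np.ndarray  # indices of aClusters
    beta: np.ndarray  # effect per aCluster, aligned with `associated`
    inverted: list  # per aCluster: indices with flipped sign (empty if informative)


@dataclass
class SimulatedDataset:
    tree: PhyloTree
    counts: AbundanceTable
    relative_abundances: np.ndarray  # m x n, columns sum to 1
    y: np.ndarray
    p: np.ndarray
    eta: np.ndarray
    design: SimulationDesign
    outcome_model: OutcomeModel
    split: tuple = field(default=None)  # (train_idx, val_idx, test_idx)


def simulate_tree(m_otus: int, rng_seed: int) -> PhyloTree:
    """Random birth-death tree with ``m_otus`` leaves labeled OTU_0001..."""
    if m_otus < 2:
        raise ValueError("need at least 2 leaves")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.2,
        num_extant_tips=m_otus,
        rng=_pyrandom.Random(rng_seed),
    )
    # relabel leaves deterministically in post-order
    width = max(4, len(str(m_otus)))
    i = 0
    ns = dendropy.TaxonNamespace()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i += 1
            node.taxon = ns.new_taxon(f"OTU_{i:0{width}d}")
        if node.edge.tail_node is not None and (node.edge.length is None or node.edge.length <= 0):
            node.edge.length = 1e-8
    tree.taxon_namespace = ns
    return PhyloTree(tree)


def cluster_otus(tree: PhyloTree, K: int, distances: DistanceMatrix | None = None) -> list:
    """Partition leaves into exactly K groups by average-linkage clustering
    of the patristic distance matrix. Returns index arrays in canonical
    leaf order."""
    m = tree.n_leaves
    if not 1 <= K <= m:
        raise ValueError(f"K must be in [1, {m}], got {K}")
    if K == m:
        return [np.array([i]) for i in range(m)]
    if K == 1:
        return [np.arange(m)]
    D = distances.D if distances is not None else patristic_distance_matrix(tree).D
    Z = linkage(squareform(D, checks=False), method="average")
    assign = cut_tree(Z, n_clusters=K).ravel()
    return [np.flatnonzero(assign == k) for k in range(K)]


def _nearest_psd_correlation(C: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, V = np.linalg.eigh((C + C.T) / 2)
    if w.min() >= floor:
        return C
    w = np.maximum(w, floor)
    C2 = (V * w) @ V.T
    s = np.sqrt(np.diag(C2))
    return C2 / np.outer(s, s)


def default_marginals(m_otus: int, design: SimulationDesign, rng: np.random.Generator) -> dict:
    """Zero-inflated negative-binomial marginal parameters per OTU: lognormal
    mean abundances, shared dispersion and zero-inflation."""
    mu = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=m_otus)
    return {
        "mu": mu,
        "r": np.full(m_otus, design.dispersion),
        "pi": np.full(m_otus, design.zero_inflation),
    }


def norta_counts(
    design: SimulationDesign,
    correlation: np.ndarray,
    marginals: dict,
    rng_seed: int,
    otu_labels: list[str] | None = None,
) -> AbundanceTable:
    """Correlated counts via the Gaussian copula.

    Multivariate-normal draws with the target correlation are pushed
    through the standard-normal CDF and then each OTU's inverse
    zero-inflated negative-binomial CDF.
    """
    m, n = design.m_otus, design.n_samples
    if correlation.shape != (m, m):
        raise ValueError("correlation must be m x m")
    rng = np.random.default_rng(rng_seed)
    C = _nearest_psd_correlation(correlation)
    try:
        Lc = np.linalg.cholesky(C + 1e-10 * np.eye(m))
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive semi-definite") from exc
    Z = rng.standard_normal((n, m)) @ Lc.T
    U = norm.cdf(Z)

    pi, r, mu = marginals["pi"], marginals["r"], marginals["mu"]
    p_nb = r / (r + mu)
    q = np.clip((U - pi) / (1.0 - pi), 0.0, 1.0 - 1e-12)
    # scipy's discrete ppf maps q=0 to -1 (below the support); clamp to 0
    counts = np.maximum(nbinom.ppf(q, r[None, :], p_nb[None, :]), 0.0)  # n x m

    # guarantee every sample has at least one observed OTU
    empty = counts.sum(axis=1) == 0
    if empty.any():
        top = np.argmax(U[empty], axis=1)
        counts[np.flatnonzero(empty), top] = 1.0

    if otu_labels is None:
        width = max(4, len(str(m)))
        otu_labels = [f"OTU_{i + 1:0{width}d}" for i in range(m)]
    sample_labels = [f"S{i + 1:04d}" for i in range(n)]
    return AbundanceTable(counts.T, list(otu_labels), sample_labels)


def simulate_outcomes(
    rel_abund: np.ndarray,
    clusters: list,
    design: SimulationDesign,
    rng_seed: int,
) -> tuple[OutcomeModel, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the association structure and Bernoulli outcomes.

    ``rel_abund`` is m x n with columns summing to 1. Returns
    (outcome_model, y, p, eta).
    """
    if not np.allclose(rel_abund.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("relative-abundance columns must sum to 1")
    K = len(clusters)
    n_assoc = int(round(design.signal_density * K))
    if n_assoc == 0:
        raise ValueError(
            f"signal_density {design.signal_density} with K={K} yields zero aClusters"
        )
    rng = np.random.default_rng(rng_seed)
    associated = np.sort(rng.choice(K, size=n_assoc, replace=False))
    beta = rng.normal(0.0, np.sqrt(design.sigma_beta_sq), size=n_assoc)

    n = rel_abund.shape[1]
    eta = np.zeros(n)
    inverted = []
    for bk, k in zip(beta, associated):
        members = clusters[k]
        if design.informative:
            inv = np.array([], dtype=np.intp)
        else:
            inv = np.sort(rng.choice(members, size=len(members) // 2, replace=False))
        inverted.append(inv)
        sign = np.ones(len(members))
        sign[np.isin(members, inv)] = -1.0
        eta += bk * (sign @ rel_abund[members, :])

    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    model = OutcomeModel(clusters=clusters, associated=associated, beta=beta, inverted=inverted)
    return model, y, p, eta


def make_benchmark(design: SimulationDesign) -> SimulatedDataset:
    """One full simulation condition: tree, counts, outcomes, 50:25:25 split."""
    rng = np.random.default_rng(design.rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    tree = simulate_tree(design.m_otus, int(seeds[0]))
    dist = patristic_distance_matrix(tree)
    # normalize distances so the decay rate is scale-free across trees
    Dn = dist.D / np.mean(dist.D[np.triu_indices(design.m_otus, k=1)])
    correlation = np.exp(-design.correlation_decay * Dn)

    marginals = default_marginals(design.m_otus, design, np.random.default_rng(int(seeds[1])))
    counts = norta_counts(design, correlation, marginals, int(seeds[2]), otu_labels=dist.labels)
    rel = counts.relative_abundances()

    clusters = cluster_otus(tree, design.K_clusters, distances=dist)
    model, y, p, eta = simulate_outcomes(rel, clusters, design, int(seeds[3]))

    split = split_dataset(
        design.n_samples, (50, 25, 25), stratify_labels=y, rng_seed=design.rng_seed
    )
    return SimulatedDataset(
        tree=tree,
        counts=counts,
        relative_abundances=rel,
        y=y,
        p=p,
        eta=eta,
        design=design,
        outcome_model=model,
        split=split,
    )
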