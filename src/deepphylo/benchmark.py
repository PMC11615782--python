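"""Simulation-backed evaluation protocols.

These drive the end-to-end checks on synthetic data: the paper-style
supervised benchmark (model vs. permuted-label control vs. full
phylogenetic-signal ablation), the informative/non-informative tree
contrast, the signal-removal ablation curve, and the unsupervised fusion
gain. Scales (m, epochs, widths) are parameters so callers can trade
fidelity for runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from deepphylo.embed import pca_embed, remove_phylo_signal
from deepphylo.model import Dataset, DeepPhyloModel, ModelConfig, train
from deepphylo.simulate import SimulationDesign, make_benchmark
from deepphylo.tree import patristic_distance_matrix
from deepphylo.unsupervised import (
    fuse_features,
    kmeans_ari,
    permanova_f,
    rpca_features,
    sum_pool_phylo,
)

__all__ = [
    "BenchmarkScale",
    "run_supervised_condition",
    "supervised_gaps",
    "informativeness_contrast",
    "ablation_curve",
    "clade_contrast_dataset",
    "fusion_gain",
]


@dataclass(frozen=True)
class BenchmarkScale:
    """Training/embedding scale knobs for simulation benchmarks."""

    embed_dim: int = 32
    hidden_dim: int = 32
    max_epochs: int = 120
    patience: int = 15
    learning_rate: float = 3e-3
    dropout_rate: float = 0.2
    weight_decay: float = 1e-3


def _train_and_score(sim, emb, y, scale: BenchmarkScale, seed: int) -> float:
    tr, val, te = sim.split
    ds = Dataset.from_table(sim.counts, emb, y)
    cfg = ModelConfig(
        abundance_dim=sim.counts.m,
        embed_dim=emb.d,
        hidden_dim=scale.hidden_dim,
        learning_rate=scale.learning_rate,
        dropout_rate=scale.dropout_rate,
        weight_decay=scale.weight_decay,
        max_epochs=scale.max_epochs,
        patience=scale.patience,
        task="binary",
        rng_seed=seed,
    )
    model = DeepPhyloModel(cfg)
    train(model, ds, tr, val)
    preds = model.predict(ds, te)
    return float(np.mean((preds >= 0.5) == sim.y[te]))


def run_supervised_condition(
    design: SimulationDesign,
    mode: str = "full",
    scale: BenchmarkScale = BenchmarkScale(),
) -> float:
    """Test accuracy for one simulated dataset under one condition.

    Modes: ``full`` (the dual-tower model), ``permute`` (labels of the
    train/validation sets shuffled — chance control), ``ablate`` (embeddings
    with 100% of the phylogenetic signal removed).
    """
    if mode not in ("full", "permute", "ablate"):
        raise ValueError(f"unknown mode {mode!r}")
    seed = design.rng_seed
    sim = make_benchmark(design)
    emb = pca_embed(patristic_distance_matrix(sim.tree), min(scale.embed_dim, sim.counts.m))
    if mode == "ablate":
        emb = remove_phylo_signal(emb, 1.0, rng_seed=seed)
    y = sim.y.copy()
    if mode == "permute":
        prng = np.random.default_rng(seed + 10_000)
        tr, val, _ = sim.split
        y[tr] = prng.permutation(y[tr])
        y[val] = prng.permutation(y[val])
    return _train_and_score(sim, emb, y, scale, seed)


def supervised_gaps(
    base_design: SimulationDesign,
    seeds=range(5),
    scale: BenchmarkScale = BenchmarkScale(),
) -> dict:
    """Mean accuracies of full model, permuted control and 100% ablation."""
    out = {"full": [], "permute": [], "ablate": []}
    for seed in seeds:
        design = replace(base_design, rng_seed=int(seed))
        for mode in out:
            out[mode].append(run_supervised_condition(design, mode, scale))
    return {
        "accuracy_full": float(np.mean(out["full"])),
        "accuracy_permuted": float(np.mean(out["permute"])),
        "accuracy_ablated": float(np.mean(out["ablate"])),
        "per_seed": out,
    }


def informativeness_contrast(
    base_design: SimulationDesign,
    seeds=range(5),
    scale: BenchmarkScale = BenchmarkScale(),
) -> dict:
    """Mean accuracy under informative vs. non-informative trees."""
    accs = {True: [], False: []}
    for informative in (True, False):
        for seed in seeds:
            design = replace(base_design, informative=informative, rng_seed=int(seed))
            accs[informative].append(run_supervised_condition(design, "full", scale))
    return {
        "accuracy_informative": float(np.mean(accs[True])),
        "accuracy_noninformative": float(np.mean(accs[False])),
        "per_seed": {"informative": accs[True], "noninformative": accs[False]},
    }


def ablation_curve(
    base_design: SimulationDesign,
    fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_repeats: int = 10,
    scale: BenchmarkScale = BenchmarkScale(),
) -> dict:
    """Mean accuracy per signal-removal fraction, plus the linear trend slope.

    Each repeat draws its own dataset and its own random OTU subset per
    fraction (matching the repeated-removal protocol).
    """
    fractions = list(fractions)
    accs = {f: [] for f in fractions}
    for rep in range(n_repeats):
        design = replace(base_design, rng_seed=int(base_design.rng_seed + rep))
        sim = make_benchmark(design)
        emb0 = pca_embed(
            patristic_distance_matrix(sim.tree), min(scale.embed_dim, sim.counts.m)
        )
        for fi, frac in enumerate(fractions):
            emb = remove_phylo_signal(emb0, frac, rng_seed=1000 * rep + fi)
            accs[frac].append(_train_and_score(sim, emb, sim.y.copy(), scale, design.rng_seed))
    means = np.array([np.mean(accs[f]) for f in fractions])
    slope = float(np.polyfit(fractions, means, 1)[0])
    return {
        "fractions": fractions,
        "mean_accuracies": means.tolist(),
        "slope": slope,
        "per_fraction": {f: accs[f] for f in fractions},
    }


def clade_contrast_dataset(seed: int = 0, n_per_group: int = 30, m: int = 60):
    """Two sample groups enriched for different clades of a random tree.

    Group 1 samples draw most of their present OTUs from one of the two
    top-level clades, group 2 from the other, with a thinner background from
    the opposite clade. Returns (table, embeddings, group labels).
    """
    from deepphylo.simulate import cluster_otus, simulate_tree
    from deepphylo.table import AbundanceTable

    rng = np.random.default_rng(seed)
    tree = simulate_tree(m, seed)
    dist = patristic_distance_matrix(tree)
    clades = cluster_otus(tree, 2, distances=dist)
    X = np.zeros((m, 2 * n_per_group))
    for j in range(2 * n_per_group):
        group = j >= n_per_group
        main, other = (clades[1], clades[0]) if group else (clades[0], clades[1])
        chosen = rng.choice(main, size=max(len(main) // 2, 1), replace=False)
        X[chosen, j] = rng.gamma(2.0, 10.0, size=len(chosen))
        bg = rng.choice(other, size=max(len(other) // 4, 1), replace=False)
        X[bg, j] = rng.gamma(2.0, 10.0, size=len(bg))
    X[rng.integers(0, m), X.sum(axis=0) == 0] = 1.0
    table = AbundanceTable(X, list(dist.labels), [f"S{i}" for i in range(2 * n_per_group)])
    groups = np.array(["g1"] * n_per_group + ["g2"] * n_per_group)
    return table, pca_embed(dist, d=8), groups


def fusion_gain(table, embeddings, groups, rank: int = 3, rng_seed: int = 0) -> dict:
    """PERMANOVA F and K-means ARI for fused vs. abundance-only features."""
    abund = rpca_features(table, rank=rank)
    phylo = sum_pool_phylo(table, embeddings)
    fused = fuse_features(abund, phylo)
    k = len(np.unique(groups))
    f_ab, _ = permanova_f(abund, groups, n_permutations=99, rng_seed=rng_seed)
    f_fu, _ = permanova_f(fused, groups, n_permutations=99, rng_seed=rng_seed)
    return {
        "permanova_f_abundance": f_ab,
        "permanova_f_fused": f_fu,
        "ari_abundance": kmeans_ari(abund, groups, k=max(k, 2), rng_seed=rng_seed),
        "ari_fused": kmeans_ari(fused, groups, k=max(k, 2), rng_seed=rng_seed),
    }
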