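# deepphylo

Phylogeny-aware microbiome analysis: dense per-OTU embeddings derived from a
phylogenetic tree (PCA of the patristic distance matrix) are fused with
abundance information, both for unsupervised beta-diversity-style sample
features and for a supervised dual-tower neural model. A copula-based
simulator generates correlated zero-inflated counts over a tree with
phylogenetically clustered outcome effects so every component is testable on
synthetic data.

## Components

| Module | Purpose |
| --- | --- |
| `deepphylo.tree` | Newick I/O (dendropy-backed), canonical post-order leaf order, patristic distance matrices |
| `deepphylo.embed` | PCA embedding of distance-matrix rows; phylogenetic-signal-removal ablation |
| `deepphylo.unsupervised` | rclr + low-rank completion (RPCA) abundance features, presence-based summation pooling of OTU embeddings, feature fusion, PERMANOVA pseudo-F / K-means ARI / cross-validated KNN evaluation |
| `deepphylo.model` | Dual-tower network (dense abundance tower ⊗ 1-D conv phylogeny tower, element-wise fusion), regression/binary/multilabel heads, AdamW-style training with early stopping, feed-forward baseline, 68:12:20 and leave-one-dataset-out split utilities. Pure NumPy with analytic gradients |
| `deepphylo.metrics` | Sensitivity/specificity/accuracy/precision/F1/MCC, ROC/PR curves with AUC/AUPR/APS, R² |
| `deepphylo.simulate` | Birth-death trees, Gaussian-copula ("normal to anything") zero-inflated negative-binomial counts with tree-structured correlation, cluster-level outcome effects with informativeness control |
| `deepphylo.benchmark` | End-to-end simulation benchmarks (permuted-label control, signal-removal ablation curves, informativeness contrast, unsupervised fusion gain) |
| `deepphylo.io` / `deepphylo.cli` | TSV/Newick readers and writers, run manifests, command-line interface |

Tables are **OTU rows × sample columns** everywhere (first TSV column is the
OTU id). This matches the on-disk convention of amplicon feature tables; the
transpose is the most common user error.

## CLI

```bash
# simulate a benchmark dataset
deepphylo simulate --n 400 --m 200 --clusters 20 --density 0.4 --informative \
    --seed 1 --out simdir/

# embed OTUs from a tree
deepphylo embed --tree simdir/tree.nwk --dim 64 --out emb.tsv

# ablate a fraction of the embeddings (signal-removal experiment)
deepphylo ablate-embeddings --embeddings emb.tsv --fraction 0.5 --seed 1 --out emb_abl.tsv

# unsupervised pipeline: RPCA + summation pooling + fusion, then evaluation
deepphylo fuse --table simdir/counts.tsv --embeddings emb.tsv --rank 3 --out fused.tsv
deepphylo cluster-eval --features fused.tsv --metadata simdir/labels.tsv --group y --seed 1

# supervised pipeline
deepphylo train --table simdir/counts.tsv --embeddings emb.tsv \
    --labels simdir/labels.tsv --label-col y --task binary --seed 1 --out run/
deepphylo predict --checkpoint run/ --table simdir/counts.tsv --embeddings emb.tsv \
    --out preds.tsv
deepphylo evaluate --preds preds.tsv --labels simdir/labels.tsv --label-col y --task binary

# leave-one-dataset-out over a study column
deepphylo lodo --table X.tsv --embeddings emb.tsv --labels meta.tsv \
    --label-col disease --study-col study_id --seed 1 --out lodo_run/
```

Model hyperparameters can be given as a flat `key = value` config file
(`--config cfg.txt`); unknown keys are rejected. Every run writes a
`manifest.json` with parameters, seed and input checksums.

## Notes

- The dual-tower model is implemented in NumPy with hand-written
  backpropagation (verified against finite differences to <1e-6 relative
  error) and decoupled weight decay; training is deterministic under a seed.
- Convolution input order is the canonical post-order tree leaf order
  restricted to the OTUs present in each sample; samples with fewer present
  OTUs than the filter width are zero-padded to one window.
- RPCA = robust centered log-ratio transform (zeros treated as missing)
  followed by iterative low-rank matrix completion.
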