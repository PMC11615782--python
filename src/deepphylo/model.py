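"""Supervised dual-tower network, feed-forward baseline, and split utilities.

The network has two input towers. The abundance tower is a dense layer on
the raw abundance vector: ``f_A = a(W x^A + b)``. The phylogeny tower runs
1-D valid convolutions (h filters, window ``l``) along the OTU axis over
the embeddings of the OTUs present in each sample, rows ordered by the
canonical tree leaf order, followed by a max-pool over positions:
``f_P[j] = max_i a(sum_k W[j,k] . x^P_{i+k-1} + b_j)``. The towers are
fused by element-wise product ``f = f_A * f_P`` and passed through linear
output layers; binary/multilabel tasks apply a sigmoid per output.

Everything is NumPy with hand-written backpropagation and a decoupled
weight-decay (AdamW-style) optimizer, so gradients are fully inspectable
and training is deterministic under a seed. The feed-forward baseline is
the same architecture with the phylogeny tower replaced by the constant
vector of ones (same number of fully connected layers).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from deepphylo.embed import EmbeddingMatrix
from deepphylo.table import AbundanceTable

__all__ = [
    "ModelConfig",
    "DeepPhyloModel",
    "Dataset",
    "TrainReport",
    "train",
    "split_dataset",
    "lodo_folds",
]

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}

_EPS = 1e-7  # BCE probability clamp


@dataclass
class ModelConfig:
    """Hyperparameters of the dual-tower model.

    ``hidden_dim`` is simultaneously the abundance-tower width and the
    number of convolution filters: the element-wise fusion forces the two
    to be equal. ``n_output_layers`` counts the linear layers of the output
    module (default 2: one hidden layer plus the final projection).
    """

    abundance_dim: int
    embed_dim: int
    hidden_dim: int = 64
    filter_size: int = 3
    activation: str = "relu"
    n_output_layers: int = 2
    task: str = "binary"  # regression | binary | multilabel
    n_labels: int = 1
    dropout_rate: float = 0.1
    weight_decay: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    rng_seed: int = 0
    use_phylo: bool = True

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.filter_size < 1:
            raise ValueError("filter_size must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.task not in ("regression", "binary", "multilabel"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.n_output_layers < 1:
            raise ValueError("n_output_layers must be >= 1")

    @property
    def n_out(self) -> int:
        return self.n_labels if self.task == "multilabel" else 1


class Dataset:
    """Aligned model inputs: abundance rows, present-OTU lists, targets.

    ``present`` holds, per sample, the indices (in canonical tree order) of
    OTUs with positive abundance; the phylogeny tower consumes the embedding
    rows at those indices.
    """

    def __init__(self, X_a: np.ndarray, embeddings: np.ndarray, y: np.ndarray):
        self.X_a = np.asarray(X_a, dtype=float)
        self.embeddings = np.asarray(embeddings, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X_a.ndim != 2:
            raise ValueError("X_a must be (n_samples, m)")
        if self.X_a.shape[1] != self.embeddings.shape[0]:
            raise ValueError("abundance width must equal embedding row count")
        self.present = [np.flatnonzero(row > 0) for row in self.X_a]
        empty = [i for i, p in enumerate(self.present) if len(p) == 0]
        if empty:
            raise ValueError(f"samples with zero present OTUs: {empty[:5]}")

    @classmethod
    def from_table(
        cls, table: AbundanceTable, embeddings: EmbeddingMatrix, y: np.ndarray
    ) -> "Dataset":
        if table.otu_labels != embeddings.labels:
            table = table.reorder_otus(embeddings.labels)
        return cls(table.relative_abundances().T, embeddings.X, y)

    def __len__(self) -> int:
        return self.X_a.shape[0]

    def batch(self, idx: np.ndarray, filter_size: int):
        """Gather a padded batch: abundance rows, embedding tensor, counts."""
        idx = np.asarray(idx, dtype=np.intp)
        counts = np.array([len(self.present[i]) for i in idx])
        L = max(int(counts.max()), filter_size)
        d = self.embeddings.shape[1]
        E = np.zeros((len(idx), L, d))
        for b, i in enumerate(idx):
            rows = self.present[i]
            E[b, : len(rows)] = self.embeddings[rows]
        return self.X_a[idx], E, counts, self.y[idx]


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict:
    h, m, d, l = config.hidden_dim, config.abundance_dim, config.embed_dim, config.filter_size
    params = {
        "W_a": rng.standard_normal((h, m)) * np.sqrt(2.0 / m),
        "b_a": np.zeros(h),
    }
    if config.use_phylo:
        params["W_c"] = rng.standard_normal((h, l, d)) * np.sqrt(2.0 / (l * d))
        params["b_c"] = np.zeros(h)
    width = h
    for i in range(config.n_output_layers - 1):
        params[f"W_o{i}"] = rng.standard_normal((width, width)) * np.sqrt(2.0 / width)
        params[f"b_o{i}"] = np.zeros(width)
    params["W_out"] = rng.standard_normal((config.n_out, width)) * np.sqrt(1.0 / width)
    params["b_out"] = np.zeros(config.n_out)
    return params


class DeepPhyloModel:
    """The dual-tower network (or the abundance-only baseline when
    ``config.use_phylo`` is false)."""

    def __init__(self, config: ModelConfig, params: dict | None = None):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        self.params = params if params is not None else _init_params(config, rng)
        self._rng = rng

    # ----- forward -----------------------------------------------------

    def forward(self, X_a, E, counts, dropout_rng: np.random.Generator | None = None):
        """Compute logits; returns (logits, cache) with everything needed
        for the backward pass. ``dropout_rng`` enables dropout (training)."""
        cfg = self.config
        act, _ = _ACTIVATIONS[cfg.activation]
        cache: dict = {"X_a": X_a, "E": E, "counts": counts}

        z_a = X_a @ self.params["W_a"].T + self.params["b_a"]
        f_a = act(z_a)
        cache["z_a"], cache["f_a"] = z_a, f_a

        if cfg.use_phylo:
            z_c, valid = self._conv(E, counts)
            F_map = act(z_c)
            neg = np.where(valid, F_map, -np.inf)
            argmax = np.argmax(neg, axis=1)  # (B, h)
            f_p = np.take_along_axis(neg, argmax[:, None, :], axis=1)[:, 0, :]
            cache.update(z_c=z_c, valid=valid, argmax=argmax, f_p=f_p)
        else:
            f_p = np.ones_like(f_a)
            cache["f_p"] = f_p

        fused = f_a * f_p
        if dropout_rng is not None and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            mask = (dropout_rng.random(fused.shape) < keep) / keep
        else:
            mask = np.ones_like(fused)
        cache["fused"], cache["drop_mask"] = fused, mask
        u = fused * mask

        hidden_caches = []
        for i in range(cfg.n_output_layers - 1):
            z = u @ self.params[f"W_o{i}"].T + self.params[f"b_o{i}"]
            hidden_caches.append((u, z))
            u = act(z)
        cache["hidden"] = hidden_caches
        cache["u_final"] = u
        s = u @ self.params["W_out"].T + self.params["b_out"]
        return s, cache

    def _conv(self, E: np.ndarray, counts: np.ndarray):
        """Valid 1-D convolution along OTU rows. Window v of sample b is
        valid when it lies within the first max(counts[b], l) rows (short
        samples are zero-padded up to one full window)."""
        l = self.config.filter_size
        B, L, d = E.shape
        V = L - l + 1
        win = np.lib.stride_tricks.sliding_window_view(E, l, axis=1)  # (B,V,d,l)
        z = np.einsum("bvdk,jkd->bvj", win, self.params["W_c"]) + self.params["b_c"]
        n_valid = np.maximum(counts - l + 1, 1)  # (B,)
        valid = (np.arange(V)[None, :] < n_valid[:, None])[:, :, None]
        return z, np.broadcast_to(valid, z.shape)

    def predict(self, dataset: Dataset, idx: np.ndarray | None = None) -> np.ndarray:
        """Predictions on the natural scale: raw s for regression,
        sigmoid probabilities otherwise."""
        if idx is None:
            idx = np.arange(len(dataset))
        out = []
        for start in range(0, len(idx), 256):
            chunk = np.asarray(idx)[start : start + 256]
            X_a, E, counts, _ = dataset.batch(chunk, self.config.filter_size)
            s, _ = self.forward(X_a, E, counts)
            out.append(s)
        s = np.vstack(out)
        if self.config.task == "regression":
            return s[:, 0]
        p = _sigmoid(s)
        return p[:, 0] if self.config.task == "binary" else p

    # ----- loss and gradients ------------------------------------------

    def loss_and_grads(self, X_a, E, counts, y, dropout_rng=None):
        """Mean loss over the batch and analytic gradients per parameter."""
        cfg = self.config
        s, cache = self.forward(X_a, E, counts, dropout_rng=dropout_rng)
        B = X_a.shape[0]
        y = np.asarray(y, dtype=float)

        if cfg.task == "regression":
            target = y.reshape(B, 1)
            loss = float(np.mean((s - target) ** 2))
            ds = 2.0 * (s - target) / B
        else:
            target = y.reshape(B, cfg.n_out)
            p = np.clip(_sigmoid(s), _EPS, 1 - _EPS)
            loss = float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
            ds = (_sigmoid(s) - target) / (B * cfg.n_out)

        grads = self._backward(ds, cache)
        return loss, grads

    def _backward(self, ds: np.ndarray, cache: dict) -> dict:
        cfg = self.config
        _, dact = _ACTIVATIONS[cfg.activation]
        grads = {}

        grads["W_out"] = ds.T @ cache["u_final"]
        grads["b_out"] = ds.sum(axis=0)
        du = ds @ self.params["W_out"]
        for i in range(cfg.n_output_layers - 2, -1, -1):
            u_in, z = cache["hidden"][i]
            dz = du * dact(z)
            grads[f"W_o{i}"] = dz.T @ u_in
            grads[f"b_o{i}"] = dz.sum(axis=0)
            du = dz @ self.params[f"W_o{i}"]

        dfused = du * cache["drop_mask"]
        df_a = dfused * cache["f_p"]
        dz_a = df_a * dact(cache["z_a"])
        grads["W_a"] = dz_a.T @ cache["X_a"]
        grads["b_a"] = dz_a.sum(axis=0)

        if cfg.use_phylo:
            df_p = dfused * cache["f_a"]
            z_c, argmax = cache["z_c"], cache["argmax"]
            dz_c = np.zeros_like(z_c)
            np.put_along_axis(
                dz_c, argmax[:, None, :], df_p[:, None, :] * np.take_along_axis(
                    dact(z_c), argmax[:, None, :], axis=1
                ), axis=1,
            )
            l = cfg.filter_size
            win = np.lib.stride_tricks.sliding_window_view(cache["E"], l, axis=1)
            grads["W_c"] = np.einsum("bvj,bvdk->jkd", dz_c, win)
            grads["b_c"] = dz_c.sum(axis=(0, 1))
        return grads


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class AdamW:
    """Adam with decoupled weight decay. Decay applies to weight matrices
    only (parameter names starting with ``W``), never to biases."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            params[k] -= self.lr * update
            if self.wd > 0 and k.startswith("W"):
                params[k] -= self.lr * self.wd * params[k]


@dataclass
class TrainReport:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: float = np.inf
    config: dict = field(default_factory=dict)


def train(
    model: DeepPhyloModel,
    dataset: Dataset,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
) -> TrainReport:
    """Mini-batch AdamW training with early stopping on validation loss.

    Best-validation parameters are restored before returning. Fully
    deterministic under ``model.config.rng_seed``: batch order, dropout and
    initialization all draw from one seeded generator.
    """
    cfg = model.config
    train_idx = np.asarray(train_idx, dtype=np.intp)
    val_idx = np.asarray(val_idx, dtype=np.intp)
    if len(train_idx) == 0:
        raise ValueError("empty training set")
    if set(train_idx) & set(val_idx):
        raise ValueError("train and validation sets overlap")

    rng = np.random.default_rng(cfg.rng_seed + 1)
    opt = AdamW(model.params, cfg.learning_rate, cfg.weight_decay)
    report = TrainReport(config=asdict(cfg))
    best_params = copy.deepcopy(model.params)
    epochs_since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            X_a, E, counts, y = dataset.batch(batch_idx, cfg.filter_size)
            loss, grads = model.loss_and_grads(X_a, E, counts, y, dropout_rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"loss diverged (value {loss}) at epoch {epoch}")
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        report.train_losses.append(epoch_loss / n_batches)

        val_loss = _eval_loss(model, dataset, val_idx)
        report.val_losses.append(val_loss)
        if val_loss < report.best_val_loss - 1e-12:
            report.best_val_loss = val_loss
            report.best_epoch = epoch
            best_params = copy.deepcopy(model.params)
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                break

    model.params = best_params
    return report


def _eval_loss(model: DeepPhyloModel, dataset: Dataset, idx: np.ndarray) -> float:
    total, n = 0.0, 0
    for start in range(0, len(idx), 256):
        chunk = idx[start : start + 256]
        X_a, E, counts, y = dataset.batch(chunk, model.config.filter_size)
        loss, _ = model.loss_and_grads(X_a, E, counts, y)
        total += loss * len(chunk)
        n += len(chunk)
    return total / n


# ----- split protocols -------------------------------------------------


def split_dataset(
    n_samples: int,
    ratios: tuple[int, int, int] = (68, 12, 20),
    stratify_labels=None,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test index sets.

    Sizes follow the ratio by largest-remainder rounding, so e.g. 100
    samples at 68:12:20 give exactly 68/12/20. Stratified when labels are
    supplied; deterministic under ``rng_seed``.
    """
    if sum(ratios) != 100:
        raise ValueError(f"ratios must sum to 100, got {ratios}")
    exact = [n_samples * r / 100 for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for i in sorted(range(3), key=lambda i: -remainders[i])[: n_samples - sum(sizes)]:
        sizes[i] += 1
    if min(sizes) == 0:
        raise ValueError(f"ratios {ratios} yield an empty split for n={n_samples}")

    indices = np.arange(n_samples)
    strat = None if stratify_labels is None else np.asarray(stratify_labels)
    rest, test = train_test_split(
        indices, test_size=sizes[2], stratify=strat, random_state=rng_seed
    )
    strat_rest = None if strat is None else strat[rest]
    tr, val = train_test_split(
        rest, test_size=sizes[1], stratify=strat_rest, random_state=rng_seed
    )
    return np.sort(tr), np.sort(val), np.sort(test)


def lodo_folds(study_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-dataset-out folds: each study is the test set once."""
    study_ids = np.asarray(study_ids)
    studies = list(dict.fromkeys(study_ids.tolist()))  # order of appearance
    if len(studies) < 2:
        raise ValueError("LODO requires at least 2 distinct studies")
    folds = []
    for s in studies:
        test = np.flatnonzero(study_ids == s)
        train_ = np.flatnonzero(study_ids != s)
        folds.append((train_, test))
    return folds
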