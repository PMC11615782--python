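import numpy as np
import pytest

from deepphylo.model import (
    Dataset,
    DeepPhyloModel,
    ModelConfig,
    _sigmoid,
    lodo_folds,
    split_dataset,
    train,
)


def tiny_config(**kw):
    defaults = dict(
        abundance_dim=6,
        embed_dim=3,
        hidden_dim=2,
        filter_size=2,
        activation="tanh",
        dropout_rate=0.0,
        n_output_layers=2,
        task="binary",
        rng_seed=1,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def tiny_batch(rng, B=4, m=6, L=5, d=3):
    X_a = rng.random((B, m)) + 0.05
    E = rng.standard_normal((B, L, d))
    counts = np.array([L, 3, 2, 1][:B])
    y = (rng.random(B) < 0.5).astype(float)
    return X_a, E, counts, y


class TestAbundanceTower:
    def test_zero_map(self):
        cfg = tiny_config(activation="identity", use_phylo=False)
        model = DeepPhyloModel(cfg)
        model.params["W_a"][:] = 0.0
        model.params["b_a"][:] = 0.0
        _, cache = model.forward(np.ones((1, 6)), np.zeros((1, 2, 3)), np.array([2]))
        np.testing.assert_allclose(cache["f_a"], 0.0)

    def test_hand_matrix_product(self):
        cfg = ModelConfig(abundance_dim=2, embed_dim=3, hidden_dim=1, filter_size=1,
                          activation="identity", dropout_rate=0.0, use_phylo=False)
        model = DeepPhyloModel(cfg)
        model.params["W_a"] = np.array([[1.0, -1.0]])
        model.params["b_a"] = np.array([0.5])
        _, cache = model.forward(np.array([[2.0, 1.0]]), np.zeros((1, 1, 3)), np.array([1]))
        assert cache["f_a"][0, 0] == pytest.approx(1.5)

    def test_relu_nonnegative(self, rng):
        cfg = tiny_config(activation="relu", use_phylo=False)
        model = DeepPhyloModel(cfg)
        _, cache = model.forward(rng.standard_normal((5, 6)), np.zeros((5, 2, 3)),
                                 np.full(5, 2))
        assert np.all(cache["f_a"] >= 0)


class TestPhyloTower:
    def test_window1_unit_filter_takes_max(self):
        cfg = ModelConfig(abundance_dim=2, embed_dim=3, hidden_dim=1, filter_size=1,
                          activation="identity", dropout_rate=0.0)
        model = DeepPhyloModel(cfg)
        model.params["W_c"] = np.zeros((1, 1, 3))
        model.params["W_c"][0, 0, 0] = 1.0  # unit vector on embedding column 1
        model.params["b_c"][:] = 0.0
        E = np.zeros((1, 3, 3))
        E[0, :, 0] = [0.2, -1.0, 0.7]
        _, cache = model.forward(np.ones((1, 2)), E, np.array([3]))
        assert cache["f_p"][0, 0] == pytest.approx(0.7)

    def test_valid_convolution_length(self, rng):
        cfg = tiny_config()
        model = DeepPhyloModel(cfg)
        X_a = rng.random((1, 6))
        E = rng.standard_normal((1, 3, 3))
        _, cache = model.forward(X_a, E, np.array([3]))
        assert cache["z_c"].shape[1] == 2  # 3 - 2 + 1

    def test_window1_permutation_invariant(self, rng):
        cfg = tiny_config(filter_size=1)
        model = DeepPhyloModel(cfg)
        X_a = rng.random((1, 6))
        E = rng.standard_normal((1, 4, 3))
        _, c1 = model.forward(X_a, E, np.array([4]))
        perm = E[:, [2, 0, 3, 1], :]
        _, c2 = model.forward(X_a, perm, np.array([4]))
        np.testing.assert_allclose(c1["f_p"], c2["f_p"], atol=1e-12)

    def test_window2_order_sensitive(self, rng):
        cfg = tiny_config(filter_size=2)
        model = DeepPhyloModel(cfg)
        X_a = rng.random((1, 6))
        E = rng.standard_normal((1, 4, 3))
        _, c1 = model.forward(X_a, E, np.array([4]))
        _, c2 = model.forward(X_a, E[:, ::-1, :].copy(), np.array([4]))
        assert not np.allclose(c1["f_p"], c2["f_p"])

    def test_short_sample_padded_to_one_window(self, rng):
        cfg = tiny_config(filter_size=3)
        model = DeepPhyloModel(cfg)
        ds_E = np.zeros((1, 3, 3))
        ds_E[0, 0] = rng.standard_normal(3)  # only one present OTU
        s, cache = model.forward(rng.random((1, 6)), ds_E, np.array([1]))
        assert np.all(np.isfinite(cache["f_p"]))

    def test_zero_present_otus_rejected(self, rng):
        with pytest.raises(ValueError, match="zero present"):
            Dataset(np.zeros((1, 4)), rng.standard_normal((4, 2)), np.zeros(1))


class TestFusionAndHead:
    def test_elementwise_product(self, rng):
        cfg = tiny_config()
        model = DeepPhyloModel(cfg)
        X_a, E, counts, _ = tiny_batch(rng)
        _, cache = model.forward(X_a, E, counts)
        np.testing.assert_allclose(cache["fused"], cache["f_a"] * cache["f_p"])

    def test_baseline_fused_equals_abundance(self, rng):
        cfg = tiny_config(use_phylo=False)
        model = DeepPhyloModel(cfg)
        X_a, E, counts, _ = tiny_batch(rng)
        _, cache = model.forward(X_a, E, counts)
        np.testing.assert_array_equal(cache["fused"], cache["f_a"])

    def test_zero_abundance_tower_gives_bias_output(self, rng):
        cfg = tiny_config(n_output_layers=1)
        model = DeepPhyloModel(cfg)
        model.params["W_a"][:] = 0.0
        model.params["b_a"][:] = 0.0
        X_a, E, counts, _ = tiny_batch(rng)
        s, _ = model.forward(X_a, E, counts)
        np.testing.assert_allclose(s, np.broadcast_to(model.params["b_out"], s.shape))

    def test_sigmoid_closed_forms(self):
        assert _sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)
        assert _sigmoid(np.array([np.log(3.0)]))[0] == pytest.approx(0.75)

    def test_multilabel_prediction_shape_and_range(self, rng):
        cfg = tiny_config(task="multilabel", n_labels=4)
        model = DeepPhyloModel(cfg)
        ds = Dataset(rng.random((6, 6)) + 0.01, rng.standard_normal((6, 3)),
                     (rng.random((6, 4)) < 0.5).astype(float))
        preds = model.predict(ds)
        assert preds.shape == (6, 4)
        assert np.all((preds > 0) & (preds < 1))

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(task="ordinal")


class TestLoss:
    def test_perfect_regression_zero_loss(self, rng):
        cfg = tiny_config(task="regression")
        model = DeepPhyloModel(cfg)
        X_a, E, counts, _ = tiny_batch(rng)
        s, _ = model.forward(X_a, E, counts)
        loss, _ = model.loss_and_grads(X_a, E, counts, s[:, 0])
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_bce_half_probability(self, rng):
        cfg = tiny_config()
        model = DeepPhyloModel(cfg)
        for k in model.params:
            model.params[k][:] = 0.0  # s = 0 -> p = 0.5
        X_a, E, counts, y = tiny_batch(rng)
        loss, _ = model.loss_and_grads(X_a, E, counts, y)
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_bce_closed_form(self):
        # y=1, p=0.75: loss = -ln 0.75
        cfg = ModelConfig(abundance_dim=1, embed_dim=1, hidden_dim=1, filter_size=1,
                          activation="identity", dropout_rate=0.0, n_output_layers=1,
                          use_phylo=False)
        model = DeepPhyloModel(cfg)
        model.params["W_a"][:] = 0.0
        model.params["b_a"][:] = 1.0
        model.params["W_out"] = np.array([[np.log(3.0)]])
        model.params["b_out"][:] = 0.0
        loss, _ = model.loss_and_grads(np.ones((1, 1)), np.ones((1, 1, 1)),
                                       np.array([1]), np.array([1.0]))
        assert loss == pytest.approx(-np.log(0.75), abs=1e-10)


class TestGradients:
    @pytest.mark.parametrize("task,n_labels", [("binary", 1), ("regression", 1),
                                               ("multilabel", 3)])
    def test_analytic_matches_finite_difference(self, task, n_labels, rng):
        cfg = tiny_config(task=task, n_labels=n_labels, rng_seed=3)
        model = DeepPhyloModel(cfg)
        X_a, E, counts, _ = tiny_batch(rng)
        if task == "multilabel":
            y = (rng.random((4, 3)) < 0.5).astype(float)
        elif task == "regression":
            y = rng.standard_normal(4)
        else:
            y = (rng.random(4) < 0.5).astype(float)
        _, grads = model.loss_and_grads(X_a, E, counts, y)
        eps = 1e-6
        for key, grad in grads.items():
            p = model.params[key]
            flat_idx = np.random.default_rng(0).choice(p.size, size=min(p.size, 10),
                                                       replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, p.shape)
                old = p[ix]
                p[ix] = old + eps
                lp, _ = model.loss_and_grads(X_a, E, counts, y)
                p[ix] = old - eps
                lm, _ = model.loss_and_grads(X_a, E, counts, y)
                p[ix] = old
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(grad[ix]), 1e-6)
                assert abs(num - grad[ix]) / denom < 1e-4, f"{key}{ix}"


def toy_dataset(rng, n=60, m=8, d=3):
    X = rng.random((n, m)) + 0.01
    emb = rng.standard_normal((m, d))
    w = rng.standard_normal(m)
    y = ((X @ w) > np.median(X @ w)).astype(float)
    return Dataset(X, emb, y)


class TestTraining:
    def test_seeded_determinism(self, rng):
        ds = toy_dataset(rng)
        reports, preds = [], []
        for _ in range(2):
            cfg = tiny_config(abundance_dim=8, max_epochs=5, batch_size=16, rng_seed=9)
            model = DeepPhyloModel(cfg)
            rep = train(model, ds, np.arange(40), np.arange(40, 50))
            reports.append(rep)
            preds.append(model.predict(ds, np.arange(50, 60)))
        assert reports[0].train_losses == reports[1].train_losses
        assert reports[0].val_losses == reports[1].val_losses
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_large_weight_decay_shrinks_weights(self, rng):
        ds = toy_dataset(rng)
        accs = {}
        for wd in (0.0, 1e3):
            cfg = tiny_config(abundance_dim=8, max_epochs=30, patience=30,
                              weight_decay=wd, rng_seed=2)
            model = DeepPhyloModel(cfg)
            train(model, ds, np.arange(40), np.arange(40, 50))
            accs[wd] = np.linalg.norm(model.params["W_a"])
            if wd == 1e3:
                preds = model.predict(ds, np.arange(50, 60))
                assert np.ptp(preds) < 0.05  # near-constant output
        assert accs[1e3] < accs[0.0] * 0.1

    def test_empty_training_set_rejected(self, rng):
        ds = toy_dataset(rng)
        cfg = tiny_config(abundance_dim=8)
        with pytest.raises(ValueError, match="empty training"):
            train(DeepPhyloModel(cfg), ds, np.array([], dtype=int), np.arange(5))

    def test_overlapping_sets_rejected(self, rng):
        ds = toy_dataset(rng)
        cfg = tiny_config(abundance_dim=8)
        with pytest.raises(ValueError, match="overlap"):
            train(DeepPhyloModel(cfg), ds, np.arange(10), np.arange(5, 15))

    def test_divergent_loss_aborts(self, rng):
        ds = toy_dataset(rng)
        ds.y = ds.y.copy()
        ds.y[3] = np.nan  # NaN target propagates to a NaN loss
        cfg = tiny_config(abundance_dim=8, task="regression", batch_size=60,
                          max_epochs=5, patience=5)
        with pytest.raises(RuntimeError, match="diverged"):
            train(DeepPhyloModel(cfg), ds, np.arange(40), np.arange(40, 50))

    def test_best_epoch_restored(self, rng):
        ds = toy_dataset(rng)
        cfg = tiny_config(abundance_dim=8, max_epochs=20, patience=3, rng_seed=4)
        model = DeepPhyloModel(cfg)
        rep = train(model, ds, np.arange(40), np.arange(40, 50))
        assert rep.best_epoch <= len(rep.val_losses) - 1
        assert rep.best_val_loss == pytest.approx(min(rep.val_losses))


class TestSplits:
    def test_68_12_20(self):
        tr, val, te = split_dataset(100, (68, 12, 20))
        assert (len(tr), len(val), len(te)) == (68, 12, 20)

    def test_200_100_100(self):
        tr, val, te = split_dataset(400, (50, 25, 25))
        assert (len(tr), len(val), len(te)) == (200, 100, 100)

    def test_partition(self):
        tr, val, te = split_dataset(97, (68, 12, 20), rng_seed=5)
        all_idx = np.concatenate([tr, val, te])
        assert len(all_idx) == 97
        assert len(np.unique(all_idx)) == 97

    def test_stratified_preserves_proportions(self):
        labels = np.array([0] * 300 + [1] * 100)
        tr, val, te = split_dataset(400, (50, 25, 25), stratify_labels=labels)
        assert labels[te].mean() == pytest.approx(0.25, abs=0.02)
        assert labels[tr].mean() == pytest.approx(0.25, abs=0.02)

    def test_deterministic(self):
        a = split_dataset(50, (68, 12, 20), rng_seed=3)
        b = split_dataset(50, (68, 12, 20), rng_seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(100, (60, 20, 10))

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(3, (98, 1, 1))


class TestLodo:
    def test_fifteen_studies(self):
        studies = np.repeat([f"study{i}" for i in range(15)], 10)
        folds = lodo_folds(studies)
        assert len(folds) == 15
        tested = np.concatenate([te for _, te in folds])
        assert len(tested) == 150 and len(np.unique(tested)) == 150

    def test_two_studies_complementary(self):
        folds = lodo_folds(["a", "a", "b", "b", "b"])
        assert len(folds) == 2
        np.testing.assert_array_equal(folds[0][1], [0, 1])
        np.testing.assert_array_equal(folds[0][0], [2, 3, 4])

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            lodo_folds(["only"] * 5)
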