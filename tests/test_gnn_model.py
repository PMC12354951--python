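import dataclasses
import json

import numpy as np
import pytest

from guidegraph import gnn_model as M
from guidegraph.graph_builder import build_dataset
from guidegraph.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="module")
def tiny_graphs():
    spec = SyntheticSpec(
        n=12, length=8, seed=3, important_positions=(1, 2), hairpin_fraction=0.0
    )
    return build_dataset(generate_dataset(spec)).graphs


@pytest.fixture(scope="module")
def tiny_model_cfg():
    return M.ModelConfig(hidden_dim=8, attention_heads=2, seed=0)


class TestConfig:
    def test_defaults_valid(self):
        M.ModelConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hidden_dim": 0},
            {"attention_heads": 0},
            {"dropout": 1.0},
            {"dropout": -0.1},
            {"learning_rate": 0.0},
            {"pooling": "median"},
            {"hidden_dim": 10, "attention_heads": 4},  # not divisible
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            M.ModelConfig(**kwargs)


class TestInit:
    def test_deterministic(self, tiny_model_cfg):
        a = M.init_model(tiny_model_cfg, 4)
        b = M.init_model(tiny_model_cfg, 4)
        assert set(a.params) == set(b.params)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_feature_dim_accepted(self, tiny_model_cfg):
        assert M.init_model(tiny_model_cfg, 4).feature_dim == 4

    def test_feature_dim_zero_rejected(self, tiny_model_cfg):
        with pytest.raises(ValueError):
            M.init_model(tiny_model_cfg, 0)


class TestForward:
    def test_pure_function(self, tiny_graphs, tiny_model_cfg):
        model = M.init_model(tiny_model_cfg, 4)
        g = tiny_graphs[0]
        assert M.forward(model, g) == M.forward(model, g)

    def test_attention_rows_sum_to_one(self, tiny_graphs, tiny_model_cfg):
        model = M.init_model(tiny_model_cfg, 4)
        _, layers = M.forward(model, tiny_graphs[0], return_attention=True)
        for layer in layers:
            n = tiny_graphs[0].n_nodes
            for node in range(n):
                mask = layer["dst"] == node
                sums = layer["weights"][mask].sum(axis=0)
                assert np.allclose(sums, 1.0, atol=1e-6)

    def test_single_node_graph(self, tiny_model_cfg):
        from guidegraph.graph_builder import GuideGraph

        g = GuideGraph(
            node_features=np.array([[1.0, 0, 0, 0]]),
            arc_src=np.zeros(0, dtype=np.int64),
            arc_dst=np.zeros(0, dtype=np.int64),
            arc_type=np.zeros(0, dtype=np.int64),
        )
        model = M.init_model(tiny_model_cfg, 4)
        assert np.isfinite(M.forward(model, g))

    def test_dimension_mismatch(self, tiny_graphs, tiny_model_cfg):
        model = M.init_model(tiny_model_cfg, 5)
        with pytest.raises(ValueError, match="feature dimension"):
            M.forward(model, tiny_graphs[0])

    def test_permutation_equivariance(self, tiny_graphs, tiny_model_cfg):
        from guidegraph.graph_builder import GuideGraph

        model = M.init_model(tiny_model_cfg, 4)
        g = tiny_graphs[1]
        rng = np.random.default_rng(9)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        permuted = GuideGraph(
            node_features=g.node_features[inv],
            arc_src=perm[g.arc_src],
            arc_dst=perm[g.arc_dst],
            arc_type=g.arc_type.copy(),
            label=g.label,
        )
        assert abs(M.forward(model, g) - M.forward(model, permuted)) < 1e-5


@pytest.mark.parametrize("pooling", ["mean", "sum", "max"])
def test_gradients_match_numerical(tiny_graphs, pooling):
    """Independent oracle: central finite differences on the full loss."""
    cfg = M.ModelConfig(hidden_dim=8, attention_heads=2, seed=0, pooling=pooling)
    model = M.init_model(cfg, 4)
    batch = M._make_batch(tiny_graphs[:6], require_labels=True)
    _, grads, _ = M._loss_and_grads(model.params, batch, cfg)
    rng = np.random.default_rng(0)
    for k, v in model.params.items():
        flat = v.ravel()
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            eps, orig = 1e-6, flat[idx]
            flat[idx] = orig + eps
            lp, _, _ = M._loss_and_grads(model.params, batch, cfg)
            flat[idx] = orig - eps
            lm, _, _ = M._loss_and_grads(model.params, batch, cfg)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[k].ravel()[idx]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num), abs(ana)), k


class TestTrain:
    def test_constant_labels_learned(self, tiny_model_cfg):
        spec = SyntheticSpec(
            n=30,
            length=8,
            seed=5,
            base_level=40.0,
            structure_weight=0.0,
            position_weight_sd=0.0,
            noise_sd=0.0,
            hairpin_fraction=0.0,
            important_positions=(1, 2),
        )
        graphs = build_dataset(generate_dataset(spec)).graphs
        assert all(g.label == 40.0 for g in graphs)
        cfg = dataclasses.replace(
            tiny_model_cfg,
            max_epochs=300,
            patience=300,
            learning_rate=5e-2,
            batch_size=16,
        )
        fitted = M.train(M.init_model(cfg, 4), graphs[5:], graphs[:5], cfg)
        assert min(fitted.history.val_loss) < 1.0
        preds = M.predict(fitted, graphs[:5])
        assert np.allclose(preds, 40.0, atol=3.0)

    def test_seeded_determinism(self, tiny_graphs, tiny_model_cfg):
        cfg = dataclasses.replace(tiny_model_cfg, max_epochs=4)
        a = M.train(M.init_model(cfg, 4), tiny_graphs[4:], tiny_graphs[:4], cfg)
        b = M.train(M.init_model(cfg, 4), tiny_graphs[4:], tiny_graphs[:4], cfg)
        assert a.history.train_loss == b.history.train_loss
        assert a.history.val_loss == b.history.val_loss
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_history_invariants(self, trained_small):
        h = trained_small.history
        assert len(h.train_loss) == len(h.val_loss)
        assert h.best_epoch == int(np.argmin(h.val_loss))

    def test_unlabelled_graph_rejected(self, tiny_graphs, tiny_model_cfg):
        import copy

        bad = copy.deepcopy(tiny_graphs[0])
        bad.label = None
        with pytest.raises(ValueError, match="label"):
            M.train(
                M.init_model(tiny_model_cfg, 4),
                [bad] + tiny_graphs[4:6],
                tiny_graphs[1:3],
                tiny_model_cfg,
            )

    def test_empty_split_rejected(self, tiny_graphs, tiny_model_cfg):
        with pytest.raises(ValueError):
            M.train(M.init_model(tiny_model_cfg, 4), [], tiny_graphs[:2], tiny_model_cfg)

    def test_train_val_overlap_rejected(self, tiny_graphs, tiny_model_cfg):
        with pytest.raises(ValueError, match="overlap"):
            M.train(
                M.init_model(tiny_model_cfg, 4),
                tiny_graphs[:4],
                tiny_graphs[3:5],
                tiny_model_cfg,
            )


class TestPredict:
    def test_empty(self, trained_small):
        assert M.predict(trained_small, []).shape == (0,)

    def test_single(self, trained_small, small_graphs):
        assert M.predict(trained_small, small_graphs[:1]).shape == (1,)

    def test_repeatable(self, trained_small, small_graphs):
        a = M.predict(trained_small, small_graphs[:10])
        b = M.predict(trained_small, small_graphs[:10])
        assert np.array_equal(a, b)

    def test_incompatible_graph_index_reported(self, trained_small, tiny_graphs):
        bad = tiny_graphs[0]  # feature dim 4 matches, so fabricate a mismatch
        import copy

        bad = copy.deepcopy(bad)
        bad.node_features = np.ones((bad.n_nodes, 7))
        with pytest.raises(ValueError, match="index 1"):
            M.predict(trained_small, [tiny_graphs[1], bad])

    def test_matches_forward(self, trained_small, small_graphs):
        batch_preds = M.predict(trained_small, small_graphs[:5])
        single = [M.forward(trained_small, g) for g in small_graphs[:5]]
        assert np.allclose(batch_preds, single, atol=1e-9)


class TestFineTune:
    def test_zero_epochs_unchanged(self, trained_small, small_graphs):
        cfg = dataclasses.replace(trained_small.config, max_epochs=0)
        tuned = M.fine_tune(trained_small, small_graphs[8:], cfg)
        for k in trained_small.params:
            assert np.array_equal(tuned.params[k], trained_small.params[k])

    def test_stability_on_own_training_data(self, trained_small, small_graphs):
        val = small_graphs[:8]
        before = M._eval_mse(trained_small.params, val, trained_small.config)
        cfg = dataclasses.replace(
            trained_small.config,
            max_epochs=3,
            learning_rate=trained_small.config.learning_rate * 0.1,
        )
        tuned = M.fine_tune(trained_small, small_graphs[8:], cfg)
        after = M._eval_mse(tuned.params, val, tuned.config)
        assert after <= before * 1.10

    def test_empty_dataset_rejected(self, trained_small):
        with pytest.raises(ValueError):
            M.fine_tune(trained_small, [])


class TestRandomSearch:
    def test_single_trial_returns_it(self, tiny_graphs, tiny_model_cfg):
        base = dataclasses.replace(tiny_model_cfg, max_epochs=2)
        best, table = M.random_search(
            {"hidden_dim": [8]},
            1,
            tiny_graphs[4:],
            tiny_graphs[:4],
            seed=0,
            base_cfg=base,
        )
        assert best.hidden_dim == 8
        assert len(table) == 1

    def test_seeded_repeatability(self, tiny_graphs, tiny_model_cfg):
        base = dataclasses.replace(tiny_model_cfg, max_epochs=2)
        space = {"hidden_dim": [8, 16], "learning_rate": (1e-4, 1e-2)}
        r1 = M.random_search(space, 3, tiny_graphs[4:], tiny_graphs[:4], 5, base)
        r2 = M.random_search(space, 3, tiny_graphs[4:], tiny_graphs[:4], 5, base)
        assert r1[1] == r2[1]
        assert r1[0] == r2[0]

    def test_degenerate_space(self, tiny_graphs, tiny_model_cfg):
        base = dataclasses.replace(tiny_model_cfg, max_epochs=2)
        best, _ = M.random_search(
            {"hidden_dim": [16], "attention_heads": [2]},
            2,
            tiny_graphs[4:],
            tiny_graphs[:4],
            seed=1,
            base_cfg=base,
        )
        assert best.hidden_dim == 16 and best.attention_heads == 2

    def test_empty_space_rejected(self, tiny_graphs):
        with pytest.raises(ValueError):
            M.random_search({}, 1, tiny_graphs[4:], tiny_graphs[:4])

    def test_best_is_argmin(self, tiny_graphs, tiny_model_cfg):
        base = dataclasses.replace(tiny_model_cfg, max_epochs=2)
        best, table = M.random_search(
            {"hidden_dim": [8, 16]},
            4,
            tiny_graphs[4:],
            tiny_graphs[:4],
            seed=2,
            base_cfg=base,
        )
        best_row = min(table, key=lambda r: r["val_mse"])
        assert best.hidden_dim == best_row["hidden_dim"]


class TestCheckpoint:
    def test_round_trip_predictions(self, trained_small, small_graphs, tmp_path):
        path = tmp_path / "model.npz"
        M.save_checkpoint(trained_small, path)
        loaded = M.load_checkpoint(path)
        a = M.predict(trained_small, small_graphs[:10])
        b = M.predict(loaded, small_graphs[:10])
        assert np.array_equal(a, b)

    def test_sidecar_is_structured_text(self, trained_small, tmp_path):
        path = tmp_path / "model.npz"
        M.save_checkpoint(trained_small, path)
        meta = json.loads((tmp_path / "model.npz.meta.json").read_text())
        assert meta["feature_dim"] == trained_small.feature_dim
        assert meta["config"]["hidden_dim"] == trained_small.config.hidden_dim
        assert "sha256" in meta

    def test_corruption_detected(self, trained_small, tmp_path):
        path = tmp_path / "model.npz"
        M.save_checkpoint(trained_small, path)
        data = bytearray(path.read_bytes())
        data[100] ^= 0xFF
        path.write_bytes(bytes(data))
        with pytest.raises(M.CheckpointError):
            M.load_checkpoint(path)

    def test_mismatched_feature_dim_detected(self, trained_small, tmp_path):
        path = tmp_path / "model.npz"
        M.save_checkpoint(trained_small, path)
        meta_path = tmp_path / "model.npz.meta.json"
        meta = json.loads(meta_path.read_text())
        meta["feature_dim"] = trained_small.feature_dim + 3
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(M.CheckpointError):
            M.load_checkpoint(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(M.CheckpointError):
            M.load_checkpoint(tmp_path / "nope.npz")

    def test_history_preserved(self, trained_small, tmp_path):
        path = tmp_path / "model.npz"
        M.save_checkpoint(trained_small, path)
        loaded = M.load_checkpoint(path)
        assert loaded.history.best_epoch == trained_small.history.best_epoch
        assert loaded.history.val_loss == pytest.approx(trained_small.history.val_loss)


def test_dropout_training_only(tiny_graphs):
    cfg = M.ModelConfig(
        hidden_dim=8, attention_heads=2, dropout=0.3, max_epochs=2, seed=1
    )
    model = M.init_model(cfg, 4)
    fitted = M.train(model, tiny_graphs[4:], tiny_graphs[:4], cfg)
    # evaluation-mode predictions are deterministic despite dropout config
    a = M.predict(fitted, tiny_graphs[:4])
    b = M.predict(fitted, tiny_graphs[:4])
    assert np.array_equal(a, b)
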