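import numpy as np
import pytest

from rinmut.gat import (
    GATConfig,
    GATModel,
    TrainConfig,
    TrainedModel,
    attention_coefficients,
    pack_subgraphs,
    predict_nodes,
    prepare_subgraph,
    train_classifier,
    _softmax_xent,
)
from rinmut.mutations import LabeledDataset
from rinmut.rin import ResidueEdge, simplify
from rinmut.subgraphs import LHopConfig, Subgraph, lhop_subgraph, make_extractor


def star_subgraph(k):
    """Target 0 connected to k leaves."""
    return Subgraph(
        nodes=np.arange(k + 1),
        edge_src=np.zeros(k, dtype=int),
        edge_dst=np.arange(1, k + 1),
        edge_weight=np.ones(k),
        target_index=0,
    )


def small_model(in_dim=2, **kwargs):
    defaults = dict(
        n_layers=2, heads=2, hidden_dim=8, dropout=0.0, drop_edge=0.0,
        dtype="float64",
    )
    defaults.update(kwargs)
    return GATModel(GATConfig(**defaults), in_dim=in_dim, rng=np.random.default_rng(3))


class TestAttention:
    def test_identical_features_uniform_weights(self):
        """k identical neighbors (plus self) each get weight 1/(k+1)."""
        for k in (1, 4):
            sg = star_subgraph(k)
            X = np.tile([[0.3, 0.7]], (k + 1, 1))
            model = small_model()
            batch = pack_subgraphs([prepare_subgraph(sg)], X, dtype=np.float64)
            src, dst, alpha = attention_coefficients(model, batch, layer=0)
            incoming = alpha[dst == 0]
            assert incoming.shape[0] == k + 1
            assert np.allclose(incoming, 1.0 / (k + 1))

    def test_rows_sum_to_one_every_layer_and_head(self):
        rng = np.random.default_rng(0)
        sg = star_subgraph(5)
        X = rng.random((6, 2))
        model = small_model(n_layers=3)
        batch = pack_subgraphs([prepare_subgraph(sg)], X, dtype=np.float64)
        for layer in range(3):
            src, dst, alpha = attention_coefficients(model, batch, layer=layer)
            for node in range(6):
                sums = alpha[dst == node].sum(axis=0)
                assert np.allclose(sums, 1.0, atol=1e-6)
            assert np.all(alpha >= 0)

    def test_layer_out_of_range(self):
        model = small_model()
        batch = pack_subgraphs(
            [prepare_subgraph(star_subgraph(2))], np.zeros((3, 2)),
            dtype=np.float64,
        )
        with pytest.raises(ValueError):
            attention_coefficients(model, batch, layer=7)


class TestForward:
    def test_eval_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.random((4, 2))
        model = small_model()
        batch = pack_subgraphs([prepare_subgraph(star_subgraph(3))], X, dtype=np.float64)
        l1, _ = model.forward(batch, training=False)
        l2, _ = model.forward(batch, training=False)
        assert np.array_equal(l1, l2)

    def test_singleton_subgraph(self):
        sg = Subgraph(
            nodes=np.array([0]), edge_src=np.empty(0, int),
            edge_dst=np.empty(0, int), edge_weight=np.empty(0),
            target_index=0,
        )
        model = small_model()
        batch = pack_subgraphs([prepare_subgraph(sg)], np.array([[0.1, 0.9]]),
                               dtype=np.float64)
        logits, _ = model.forward(batch, training=False)
        assert logits.shape == (1, 2)
        assert np.all(np.isfinite(logits))

    def test_zeroed_parameters_give_bias_logits(self):
        model = small_model()
        for k in model.params:
            model.params[k][:] = 0.0
        batch = pack_subgraphs(
            [prepare_subgraph(star_subgraph(2))],
            np.random.default_rng(0).random((3, 2)), dtype=np.float64,
        )
        logits, _ = model.forward(batch, training=False)
        assert np.allclose(logits, 0.0)

    def test_permutation_equivariance(self):
        """Relabeling subgraph nodes leaves the target logits unchanged."""
        rng = np.random.default_rng(5)
        edges = [ResidueEdge(0, 1, "sc_sc", 1.0), ResidueEdge(1, 2, "sc_sc", 1.0),
                 ResidueEdge(0, 3, "sc_sc", 1.0), ResidueEdge(2, 3, "sc_sc", 1.0)]
        net = simplify(edges, 4)
        X = rng.random((4, 2))
        sg = lhop_subgraph(net, 0, LHopConfig(depth=2, budget=10))
        model = small_model(n_layers=3)
        batch = pack_subgraphs([prepare_subgraph(sg)], X, dtype=np.float64)
        base, _ = model.forward(batch, training=False)

        perm = np.array([2, 0, 3, 1])  # new id of each old node
        pedges = [ResidueEdge(int(perm[e.u]), int(perm[e.v]), "sc_sc", 1.0)
                  for e in edges]
        pnet = simplify(pedges, 4)
        pX = np.empty_like(X)
        pX[perm] = X
        psg = lhop_subgraph(pnet, int(perm[0]), LHopConfig(depth=2, budget=10))
        pbatch = pack_subgraphs([prepare_subgraph(psg)], pX, dtype=np.float64)
        permuted, _ = model.forward(pbatch, training=False)
        assert np.allclose(base, permuted, atol=1e-5)


class TestBackward:
    def test_matches_finite_differences(self):
        """Analytic gradients agree with central differences (float64)."""
        rng = np.random.default_rng(2)
        edges = [ResidueEdge(i, j, "sc_sc", float(i + j))
                 for i in range(6) for j in range(i + 1, 6) if (i + j) % 2]
        net = simplify(edges, 6)
        X = rng.random((6, 3))
        subs = [prepare_subgraph(lhop_subgraph(net, t, LHopConfig(depth=2, budget=4, seed=1)))
                for t in range(4)]
        labels = np.array([0, 1, 1, 0])
        batch = pack_subgraphs(subs, X, labels=labels, dtype=np.float64)
        model = small_model(in_dim=3, n_layers=3, readout="target_plus_meanpool")
        for k in model.params:  # open the residual gates so every path carries
            if k.startswith("gate"):
                model.params[k][:] = 0.7

        logits, cache = model.forward(batch, training=False, keep_cache=True)
        _, dlogits = _softmax_xent(logits, batch.labels)
        grads = model.backward(cache, dlogits)

        def loss():
            lg, _ = model.forward(batch, training=False)
            return _softmax_xent(lg, batch.labels)[0]

        check_rng = np.random.default_rng(0)
        for name, p in model.params.items():
            flat = p.ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                eps = 1e-6
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name].ravel()[i]
                assert numeric == pytest.approx(analytic, rel=1e-3, abs=1e-8), name


def linear_fixture(n=64, seed=0):
    """Planted dataset where the label is a threshold on feature 0."""
    rng = np.random.default_rng(seed)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.08:
                edges.append(ResidueEdge(i, j, "sc_sc", 1.0))
    net = simplify(edges, n)
    X = rng.random((n, 2))
    labels = (X[:, 0] > 0.5).astype(int)
    dataset = LabeledDataset(
        node_ids=np.arange(n), labels=labels,
        positions=np.arange(1, n + 1), label_scheme="severity",
    )
    return net, X, dataset


class TestTraining:
    def test_learns_linearly_separable_rule(self):
        net, X, dataset = linear_fixture()
        ext = make_extractor("lhop", lhop=LHopConfig(depth=2, budget=10, seed=0))
        gat = GATConfig(n_layers=3, hidden_dim=32)
        tr = TrainConfig(max_epochs=120, patience=120, seed=0, batch_size=32,
                         val_fraction=0.0)
        trained = train_classifier(gat, tr, dataset, net, X, ext)
        probs = predict_nodes(trained, net, X, dataset.node_ids, ext)
        acc = (probs.argmax(axis=1) == dataset.labels).mean()
        assert acc >= 0.95

    def test_loss_decreases_early_for_all_variants(self):
        net, X, dataset = linear_fixture()
        for kind in ("lhop", "ppr"):
            for layers in (3, 5):
                ext = make_extractor(kind, lhop=LHopConfig(seed=0))
                gat = GATConfig(n_layers=layers, hidden_dim=32)
                tr = TrainConfig(max_epochs=6, patience=10, seed=1,
                                 batch_size=16, val_fraction=0.0)
                trained = train_classifier(gat, tr, dataset, net, X, ext)
                losses = [h["train_loss"] for h in trained.history]
                assert min(losses[1:6]) < losses[0], (kind, layers)

    def test_same_seed_identical_history(self):
        net, X, dataset = linear_fixture()
        ext = make_extractor("lhop", lhop=LHopConfig(seed=0))
        gat = GATConfig(n_layers=3, hidden_dim=16)
        tr = TrainConfig(max_epochs=5, patience=10, seed=7, batch_size=32)
        h1 = train_classifier(gat, tr, dataset, net, X, ext).history
        h2 = train_classifier(gat, tr, dataset, net, X, ext).history
        assert h1 == h2

    def test_single_class_rejected(self):
        net, X, dataset = linear_fixture()
        dataset.labels[:] = 1
        ext = make_extractor("lhop")
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(GATConfig(), TrainConfig(), dataset, net, X, ext)


class TestPredict:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained():
        net, X, dataset = linear_fixture(n=40, seed=3)
        ext = make_extractor("lhop", lhop=LHopConfig(seed=0))
        gat = GATConfig(n_layers=3, hidden_dim=16)
        tr = TrainConfig(max_epochs=15, patience=20, seed=0, batch_size=32)
        model = train_classifier(gat, tr, dataset, net, X, ext)
        return model, net, X, ext

    def test_rows_sum_to_one(self, trained):
        model, net, X, ext = trained
        probs = predict_nodes(model, net, X, range(10), ext)
        assert probs.shape == (10, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_node_identical_rows(self, trained):
        model, net, X, ext = trained
        probs = predict_nodes(model, net, X, [4, 4], ext)
        assert np.array_equal(probs[0], probs[1])

    def test_all_nodes_scored(self, trained):
        model, net, X, ext = trained
        probs = predict_nodes(model, net, X, range(40), ext)
        assert probs.shape == (40, 2)

    def test_untrained_model_rejected(self, trained):
        _, net, X, ext = trained
        gat = GATConfig(n_layers=3, hidden_dim=16)
        blank = TrainedModel(
            model=GATModel(gat, in_dim=2), gat_config=gat,
            train_config=TrainConfig(),
        )
        with pytest.raises(ValueError, match="train"):
            predict_nodes(blank, net, X, [0], ext)


def test_checkpoint_roundtrip(tmp_path):
    net, X, dataset = linear_fixture(n=30, seed=2)
    ext = make_extractor("lhop", lhop=LHopConfig(seed=0))
    gat = GATConfig(n_layers=3, hidden_dim=16)
    tr = TrainConfig(max_epochs=3, patience=5, seed=0, batch_size=16)
    trained = train_classifier(gat, tr, dataset, net, X, ext)
    path = tmp_path / "model.npz"
    trained.save(path)
    loaded = TrainedModel.load(path)
    p1 = predict_nodes(trained, net, X, range(5), ext)
    p2 = predict_nodes(loaded, net, X, range(5), ext)
    assert np.allclose(p1, p2)
    assert loaded.history == trained.history
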