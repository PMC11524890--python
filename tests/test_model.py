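"""Dual-view network contracts and estimator behavior."""

import numpy as np
import pandas as pd
import pytest

from dualsyn import (
    DualSynClassifier,
    DualSynRegressor,
    ModelConfig,
    build_joint_graph,
    nn,
    smiles_to_graph,
)
from dualsyn.model import DualViewNetwork

from conftest import tiny_estimator_kwargs


@pytest.fixture(scope="module")
def tiny_config():
    return ModelConfig(n_genes=16, fp_bits=64, heads=2, gat_hidden=8,
                       cell_hidden=(16, 8), embed_dim=16,
                       prednet_dims=(16, 8, 4), dropout=0.0)


@pytest.fixture(scope="module")
def network(tiny_config):
    return DualViewNetwork(tiny_config, np.random.default_rng(0))


def _joint_batch(network, smiles_a="CC(=O)Oc1ccccc1C(=O)O", smiles_b="CCO",
                 method="super_edge"):
    joint = build_joint_graph(smiles_to_graph(smiles_a),
                              smiles_to_graph(smiles_b), method)
    src, dst = joint.edge_arrays()
    return joint, src, dst


class TestGATForward:
    @pytest.mark.parametrize("method", ["super_edge", "all_nodes",
                                        "one_super_node", "three_super_nodes"])
    def test_attention_sums_to_one_per_layer_and_head(self, network, method):
        joint, src, dst = _joint_batch(network, method=method)
        _, alphas = network.encode_graph(
            joint.node_features, src, dst,
            np.zeros(joint.n_nodes, dtype=int), 1, return_alpha=True)
        assert len(alphas) == 3  # three attention layers
        for alpha in alphas:
            sums = np.zeros((joint.n_nodes, network.config.heads))
            np.add.at(sums, dst, alpha.data)
            assert np.allclose(sums, 1.0, atol=1e-5)

    def test_permutation_invariance_of_pooled_embedding(self, network):
        joint, src, dst = _joint_batch(network)
        ids = np.zeros(joint.n_nodes, dtype=int)
        z = network.encode_graph(joint.node_features, src, dst, ids, 1)
        perm = np.random.default_rng(1).permutation(joint.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(joint.n_nodes)
        z_p = network.encode_graph(joint.node_features[perm],
                                   inv[src], inv[dst], ids, 1)
        assert np.allclose(z.data, z_p.data, atol=1e-5)

    def test_single_node_graph_pooling_identity(self, tiny_config):
        """With one node, pooling returns that node's transformed features."""
        net = DualViewNetwork(tiny_config, np.random.default_rng(3))
        g = smiles_to_graph("C")
        src = dst = np.array([0])
        h = nn.Tensor(np.zeros((1, 78)))
        h.data[0] = g.node_features[0]
        z = net.encode_graph(h, src, dst, np.array([0]), 1)
        x = h
        for gat in net.gats:
            x = gat(x, src, dst, 1).relu()
        assert np.allclose(z.data, x.data)

    def test_50_atom_graph_all_methods(self, network):
        big = smiles_to_graph("CCCCCCCCCCCCCCCCCCCCCCCCC")  # 25 heavy atoms
        for method in ["super_edge", "all_nodes", "one_super_node",
                       "three_super_nodes"]:
            joint = build_joint_graph(big, big, method)
            assert joint.n_nodes >= 50
            src, dst = joint.edge_arrays()
            z = network.encode_graph(joint.node_features, src, dst,
                                     np.zeros(joint.n_nodes, dtype=int), 1)
            assert np.all(np.isfinite(z.data))


class TestViews:
    def test_view1_nonnegative_and_cell_sensitive(self, network):
        joint, src, dst = _joint_batch(network)
        ids = np.zeros(joint.n_nodes, dtype=int)
        z_ab = network.encode_graph(joint.node_features, src, dst, ids, 1)
        rng = np.random.default_rng(0)
        cell1 = rng.standard_normal((1, 16))
        cell2 = cell1 + 0.5
        z1 = network.encode_view1(z_ab, network.encode_cell(cell1))
        z2 = network.encode_view1(z_ab, network.encode_cell(cell2))
        assert np.all(z1.data >= 0)
        assert not np.allclose(z1.data, z2.data)

    def test_view2_shared_drug_encoder(self, network):
        rng = np.random.default_rng(1)
        fp = (rng.random((1, 64)) > 0.5).astype(float)
        cell = rng.standard_normal((1, 16))
        z_cell = network.encode_cell(cell)
        fa = nn.Tensor(fp)
        z_dca = network.drug_cell(nn.concat([z_cell, fa])).relu()
        z_dcb = network.drug_cell(nn.concat([z_cell, fa])).relu()
        assert np.array_equal(z_dca.data, z_dcb.data)  # same weights, same fp

    def test_view2_order_sensitive(self, network):
        rng = np.random.default_rng(2)
        fa = (rng.random((1, 64)) > 0.5).astype(float)
        fb = (rng.random((1, 64)) > 0.5).astype(float)
        z_cell = network.encode_cell(rng.standard_normal((1, 16)))
        z_ab = network.encode_view2(fa, fb, z_cell)
        z_ba = network.encode_view2(fb, fa, z_cell)
        assert np.all(z_ab.data >= 0)
        assert not np.allclose(z_ab.data, z_ba.data)

    def test_head_bias_with_zeroed_prediction_net(self, tiny_config):
        net = DualViewNetwork(tiny_config, np.random.default_rng(4))
        for layer in net.prednet.layers:
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        net.head.weight.data[:] = 0.0
        net.head.bias.data[:] = 1.5
        rng = np.random.default_rng(5)
        out = net.predict_head(nn.Tensor(rng.standard_normal((3, 16))),
                               nn.Tensor(rng.standard_normal((3, 16))))
        assert np.allclose(out.data, 1.5)


@pytest.fixture(scope="module")
def fitted(small_fixture, small_xy):
    _, drugs, expr, _ = small_fixture
    X, y = small_xy
    est = DualSynRegressor(**tiny_estimator_kwargs(drugs, expr))
    return est.fit(X, y), X, y


class TestEstimators:
    def test_predict_symmetric_in_drug_order(self, fitted):
        est, X, _ = fitted
        swapped = X.rename(columns={"drug1": "drug2", "drug2": "drug1"})
        assert np.array_equal(est.predict(X.head(20)),
                              est.predict(swapped.head(20)))

    def test_deterministic_refit(self, small_fixture, small_xy):
        """Same seed, same data -> bitwise-identical training history."""
        _, drugs, expr, _ = small_fixture
        X, y = small_xy
        kw = tiny_estimator_kwargs(drugs, expr, epochs=2)
        a = DualSynRegressor(**kw).fit(X, y)
        b = DualSynRegressor(**kw).fit(X, y)
        assert a.history_ == b.history_
        assert all(np.array_equal(p, q)
                   for p, q in zip(a.get_weights(), b.get_weights()))

    def test_training_loss_decreases(self, fitted):
        est, _, _ = fitted
        losses = [h["train_loss"] for h in est.history_]
        assert losses[-1] < losses[0]

    def test_finetune_empty_is_noop(self, fitted):
        est, _, _ = fitted
        before = est.get_weights()
        est.fine_tune(pd.DataFrame(columns=["drug1", "drug2", "cell"]), [])
        after = est.get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_finetune_updates_weights(self, fitted):
        est, X, y = fitted
        before = [w.copy() for w in est.get_weights()]
        est.fine_tune(X.head(8), y[:8], lr=1e-4, epochs=1, patience=None)
        after = est.get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))
        est.set_weights(before)  # restore for other tests

    def test_parameter_count_pair_independent(self, fitted):
        est, _, _ = fitted
        assert len(est.get_weights()) == len(est.network_.parameters())

    def test_checkpoint_roundtrip(self, fitted, small_fixture, tmp_path):
        est, X, _ = fitted
        _, _, expr, _ = small_fixture
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = DualSynRegressor.load(path, expression=expr)
        assert np.allclose(est.predict(X.head(5)), loaded.predict(X.head(5)))

    def test_checkpoint_estimator_mismatch_refused(self, fitted, tmp_path):
        est, _, _ = fitted
        path = tmp_path / "model.npz"
        est.save(path)
        with pytest.raises(ValueError, match="DualSynRegressor"):
            DualSynClassifier.load(path)

    def test_sklearn_params_roundtrip(self):
        est = DualSynRegressor(heads=3, lr=5e-4)
        params = est.get_params()
        assert params["heads"] == 3
        est.set_params(heads=5)
        assert est.get_params()["heads"] == 5


class TestClassifier:
    def test_probabilities_sum_to_one_and_classes(self, small_fixture, small_xy):
        _, drugs, expr, _ = small_fixture
        X, y = small_xy
        labels = np.where(y > np.median(y), "synergistic", "antagonistic")
        est = DualSynClassifier(**tiny_estimator_kwargs(drugs, expr, epochs=2))
        est.fit(X, labels)
        proba = est.predict_proba(X.head(15))
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(est.predict(X.head(15))) <= {"synergistic", "antagonistic"}
        assert list(est.classes_) == ["antagonistic", "synergistic"]
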