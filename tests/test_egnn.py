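"""The equivariant network: attention, layer mechanics, invariances."""

import numpy as np
import pytest

import eqscore as eq
from eqscore.egnn import (ModelConfig, ModelParams, attention_scores,
                          egnn_layer, init_params, predict, replace_head)
from conftest import rigid_motion


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _silu(x):
    return x * _sigmoid(x)


@pytest.fixture(scope="module")
def params():
    return init_params(ModelConfig.desk(seed=3))


class TestAttentionScores:
    def test_scores_lie_in_unit_interval(self, params):
        rng = np.random.default_rng(0)
        scores = attention_scores(params, rng.normal(size=(50, 32)) * 5)
        assert np.all(scores >= 0) and np.all(scores <= 1)

    def test_identical_embeddings_get_identical_scores(self, params):
        embedding = np.full((2, 32), 0.37)
        scores = attention_scores(params, embedding)
        assert scores[0] == scores[1]

    def test_matches_hand_rolled_forward_pass(self, params):
        """Oracle: explicit two-matrix forward computation of the same MLP."""
        rng = np.random.default_rng(1)
        embeddings = rng.normal(size=(100, 32))
        dist2 = rng.uniform(0, 1, size=(100, 1))
        layer = params.config.n_layers - 1
        w0 = params.values[f"layer{layer}.att.W0"]
        b0 = params.values[f"layer{layer}.att.b0"]
        w1 = params.values[f"layer{layer}.att.W1"]
        b1 = params.values[f"layer{layer}.att.b1"]
        stacked = np.concatenate([embeddings, dist2], axis=1)
        expected = _sigmoid(_silu(stacked @ w0 + b0) @ w1 + b1).ravel()
        np.testing.assert_allclose(
            attention_scores(params, embeddings, dist2),
            expected, atol=1e-12)

    def test_nonfinite_embeddings_rejected(self, params):
        bad = np.full((3, 32), np.nan)
        with pytest.raises(ValueError):
            attention_scores(params, bad)


class TestEgnnLayer:
    def test_zero_edges_reduce_to_self_term(self, params):
        rng = np.random.default_rng(2)
        h = rng.normal(size=(4, 32))
        x = rng.normal(size=(4, 3))
        empty = np.zeros((2, 0), dtype=int)
        h_new, x_new, att = egnn_layer(params, 0, h, x, empty,
                                       np.zeros((0, 3)))
        assert att.size == 0
        np.testing.assert_allclose(x_new, x)
        # aggregate is zero, so the update depends on h only
        w0 = params.values["layer0.node.W0"]
        b0 = params.values["layer0.node.b0"]
        w1 = params.values["layer0.node.W1"]
        b1 = params.values["layer0.node.b1"]
        expected = h + _silu(np.concatenate([h, np.zeros_like(h)], axis=1)
                             @ w0 + b0) @ w1 + b1
        np.testing.assert_allclose(h_new, expected, atol=1e-12)

    def test_positions_are_equivariant(self, params):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(6, 32))
        x = rng.normal(size=(6, 3)) * 3
        edge_index = np.array([[0, 1, 2, 3, 4, 5], [1, 0, 3, 2, 5, 4]])
        edge_attrs = np.tile([0, 1, 0], (6, 1))
        rotation, translation = rigid_motion(rng)
        h1, x1, _ = egnn_layer(params, 0, h, x, edge_index, edge_attrs)
        h2, x2, _ = egnn_layer(params, 0, h, x @ rotation.T + translation,
                               edge_index, edge_attrs)
        np.testing.assert_allclose(h2, h1, atol=1e-9)
        np.testing.assert_allclose(x2, x1 @ rotation.T + translation,
                                   atol=1e-9)

    def test_aggregate_matches_explicit_edge_loop(self, params):
        """Oracle: loop over edges accumulating e_ij * m_ij per node."""
        rng = np.random.default_rng(4)
        n = 6
        h = rng.normal(size=(n, 32))
        x = rng.normal(size=(n, 3)) * 2
        edge_index = np.array(
            [[0, 1, 1, 2, 3, 4, 5, 2], [1, 0, 2, 1, 4, 3, 2, 5]])
        m = edge_index.shape[1]
        edge_attrs = np.tile([0, 1, 0], (m, 1)).astype(float)

        values = params.values
        src, dst = edge_index
        rel = x[dst] - x[src]
        dist2 = (rel**2).sum(axis=1, keepdims=True) / 100.0
        edge_in = np.concatenate([h[dst], h[src], dist2, edge_attrs], axis=1)
        messages = np.tanh(_silu(edge_in @ values["layer0.edge.W0"]
                                 + values["layer0.edge.b0"])
                           @ values["layer0.edge.W1"]
                           + values["layer0.edge.b1"])
        att_in = np.concatenate([messages, dist2], axis=1)
        att = _sigmoid(_silu(att_in @ values["layer0.att.W0"]
                             + values["layer0.att.b0"])
                       @ values["layer0.att.W1"]
                       + values["layer0.att.b1"]).ravel()
        aggregate = np.zeros((n, 32))
        for e in range(m):  # naive accumulation
            aggregate[dst[e]] += att[e] * messages[e]
        node_in = np.concatenate([h, aggregate], axis=1)
        expected_h = h + _silu(node_in @ values["layer0.node.W0"]
                               + values["layer0.node.b0"]) \
            @ values["layer0.node.W1"] + values["layer0.node.b1"]

        h_new, _, att_out = egnn_layer(params, 0, h, x, edge_index,
                                       edge_attrs)
        np.testing.assert_allclose(att_out, att, atol=1e-12)
        np.testing.assert_allclose(h_new, expected_h, atol=1e-10)

    def test_edge_to_missing_node_raises(self, params):
        h = np.zeros((3, 32))
        x = np.zeros((3, 3))
        with pytest.raises(IndexError):
            egnn_layer(params, 0, h, x, np.array([[0], [5]]),
                       np.array([[0, 1, 0]]))


class TestPredict:
    def test_pose_head_in_unit_interval(self, synthetic_graph, params):
        graph, _, _ = synthetic_graph
        assert 0.0 <= predict(graph, params).score <= 1.0

    def test_affinity_head_nonnegative(self, synthetic_graph, params):
        graph, _, _ = synthetic_graph
        affinity = replace_head(params, "affinity", seed=9)
        assert predict(graph, affinity).score >= 0.0

    @pytest.mark.parametrize("head", ["pose", "affinity"])
    def test_invariant_under_rigid_motions_and_permutations(
            self, synthetic_graph, params, head):
        graph, complex_, _ = synthetic_graph
        model = params if head == "pose" else replace_head(params, "affinity",
                                                           seed=9)
        baseline = predict(graph, model).score
        rng = np.random.default_rng(42)
        for trial in range(20):
            rotation, translation = rigid_motion(rng,
                                                 reflect=bool(trial % 2))
            moved = complex_.transformed(rotation, translation)
            atoms = list(moved.atoms)
            rng.shuffle(atoms)
            shuffled = type(moved)(moved.complex_id, atoms,
                                   moved.pocket_applied)
            score = predict(eq.featurize(shuffled), model).score
            assert abs(score - baseline) < 1e-4

    def test_zeroed_attention_equals_edge_deletion(self, synthetic_graph,
                                                   params):
        graph, _, _ = synthetic_graph
        rng = np.random.default_rng(5)
        drop = rng.random(graph.n_edges) < 0.1
        mask = np.where(drop, 0.0, 1.0)
        masked = predict(graph, params, edge_mask=mask).score
        deleted = predict(graph.without_edges(drop), params).score
        assert abs(masked - deleted) < 1e-12

    def test_doubling_layers_preserves_shape_and_invariance(
            self, synthetic_graph):
        graph, complex_, _ = synthetic_graph
        deep = init_params(ModelConfig.desk(n_layers=8, seed=3))
        baseline = predict(graph, deep)
        assert np.isscalar(baseline.score)
        assert baseline.attention.shape == (graph.n_edges,)
        rng = np.random.default_rng(6)
        rotation, translation = rigid_motion(rng)
        moved = predict(eq.featurize(
            complex_.transformed(rotation, translation)), deep).score
        assert abs(moved - baseline.score) < 1e-4

    def test_final_layer_attention_exported(self, synthetic_graph, params):
        graph, _, _ = synthetic_graph
        result = predict(graph, params)
        assert len(result.attention_layers) == params.config.n_layers
        np.testing.assert_array_equal(result.attention,
                                      result.attention_layers[-1])
        for att in result.attention_layers:
            assert np.all((att >= 0) & (att <= 1))


class TestParamsSerialization:
    def test_checkpoint_round_trips_bit_exactly(self, params, tmp_path):
        path = tmp_path / "model.ckpt.npz"
        params.save(path)
        loaded = ModelParams.load(path)
        assert loaded.config == params.config
        assert loaded.head_replaced == params.head_replaced
        for key, value in params.values.items():
            np.testing.assert_array_equal(loaded.values[key], value)

    def test_flatten_unflatten_round_trip(self, params):
        flat = params.flatten()
        rebuilt = params.unflatten(flat)
        for key, value in params.values.items():
            np.testing.assert_array_equal(rebuilt.values[key], value)


def test_gradients_match_finite_differences():
    """The autodiff engine against central finite differences on a tiny
    network with every op the model uses."""
    from eqscore import autodiff as ad
    from eqscore.autodiff import Tensor

    rng = np.random.default_rng(10)
    w = rng.normal(size=(4, 3))
    h = rng.normal(size=(5, 4))
    idx = np.array([0, 2, 4, 1])

    def forward(w_arr):
        wt = Tensor(w_arr)
        out = ad.silu(Tensor(h) @ wt)
        gathered = ad.gather_rows(out, idx)
        seg = ad.segment_sum(gathered * ad.sigmoid(gathered), idx % 3, 3)
        return (ad.tanh(seg) + ad.softplus(seg) * 0.5).sum(), wt

    loss, wt = forward(w)
    loss.backward()
    grad = wt.grad
    eps = 1e-6
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            w_plus, w_minus = w.copy(), w.copy()
            w_plus[i, j] += eps
            w_minus[i, j] -= eps
            numeric = (forward(w_plus)[0].item()
                       - forward(w_minus)[0].item()) / (2 * eps)
            assert abs(grad[i, j] - numeric) < 1e-6
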