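"""Encoder, hierarchy and gate: worked examples and structural invariants."""

import numpy as np
import pytest

from sebiograph.autodiff import Tensor
from sebiograph.config import RunConfig
from sebiograph.encoder_gate import (
    aggregate_levels,
    assign_nodes,
    build_hierarchy,
    coarsen,
    compute_gate,
    encode,
    init_params,
    level_representation,
)
from sebiograph.graph_io import BioGraph, GraphBank
from sebiograph.meta_trainer import train
from sebiograph.nn import ModelParams, normalize_adjacency

from .conftest import two_triangle_graph


def path3_graph(h=1):
    adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    feats = np.array([[1.0], [2.0], [3.0]])[:, :h]
    return BioGraph(["a", "b", "c"], adj, feats)


class TestEncode:
    def test_zero_weights_give_zero_embeddings(self, toy_graph, toy_cfg):
        rng = np.random.default_rng(0)
        params = init_params(2, toy_cfg, 6, rng)
        for _, p in params.items():
            p.data[:] = 0.0
        out = encode(toy_graph, params, toy_cfg)
        assert np.all(out.data == 0.0)

    def test_two_layer_propagation_equals_hand_computed_a_hat_squared(self):
        """Identity 1x1 weights, linear activation: output is Â²N."""
        g = path3_graph()
        cfg = RunConfig(hidden_dim=1, activation="identity", cluster_counts=[2])
        params = ModelParams({
            "enc_W0": Tensor(np.eye(1), requires_grad=True),
            "alpha": Tensor(np.eye(1), requires_grad=True),
        })
        a_hat = normalize_adjacency(g.adjacency)
        expected = a_hat @ a_hat @ g.features
        out = encode(g, params, cfg)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_permutation_equivariance(self, toy_graph, toy_cfg):
        rng = np.random.default_rng(1)
        params = init_params(2, toy_cfg, 6, rng)
        perm = rng.permutation(6)
        out = encode(toy_graph, params, toy_cfg).data
        out_p = encode(toy_graph.permuted(perm), params, toy_cfg).data
        assert np.max(np.abs(out_p - out[perm])) < 1e-9

    def test_gate_shape_mismatch_rejected(self, toy_graph, toy_cfg):
        rng = np.random.default_rng(2)
        params = init_params(2, toy_cfg, 6, rng)
        with pytest.raises(ValueError, match="gate shape"):
            encode(toy_graph, params, toy_cfg, gate=np.ones(3))


class TestAssignNodes:
    def test_equal_logits_give_uniform_rows(self):
        a = Tensor(np.zeros((4, 4)))
        n = Tensor(np.ones((4, 2)))
        w = Tensor(np.zeros((2, 3)), requires_grad=True)
        p = assign_nodes(a, n, w, 3)
        np.testing.assert_allclose(p.data, 1.0 / 3.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        a = Tensor((lambda m: m + m.T)(rng.random((5, 5))) * (1 - np.eye(5)))
        n = Tensor(rng.standard_normal((5, 3)))
        w = Tensor(rng.standard_normal((3, 2)), requires_grad=True)
        p = assign_nodes(a, n, w, 2)
        np.testing.assert_allclose(p.data.sum(axis=1), 1.0, atol=1e-6)

    def test_hand_computed_softmax_row(self):
        """Logits (1, 2) -> (e, e²)/(e + e²) ≈ (0.2689, 0.7311)."""
        a = Tensor(np.zeros((1, 1)))     # Â = [[1]] after self-loop
        n = Tensor(np.ones((1, 1)))
        w = Tensor(np.array([[1.0, 2.0]]), requires_grad=True)
        p = assign_nodes(a, n, w, 2)
        e1, e2 = np.exp(1.0), np.exp(2.0)
        np.testing.assert_allclose(
            p.data, [[e1 / (e1 + e2), e2 / (e1 + e2)]], atol=1e-12
        )


class TestCoarsen:
    def test_identity_assignment_preserves_adjacency(self, toy_graph):
        a = Tensor(toy_graph.adjacency)
        n = Tensor(toy_graph.features)
        p = Tensor(np.eye(6))
        w = Tensor(np.eye(2), requires_grad=True)
        a_next, _ = coarsen(a, n, p, w)
        np.testing.assert_allclose(a_next.data, toy_graph.adjacency)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(4)
        raw = rng.random((7, 7))
        a = Tensor((raw + raw.T) * (1 - np.eye(7)))
        n = Tensor(rng.standard_normal((7, 3)))
        logits = Tensor(rng.standard_normal((7, 3)))
        p = Tensor(np.exp(logits.data) / np.exp(logits.data).sum(1, keepdims=True))
        w = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
        a_next, _ = coarsen(a, n, p, w)
        assert np.max(np.abs(a_next.data - a_next.data.T)) < 1e-12

    def test_two_nodes_into_one_cluster(self):
        a = Tensor(np.array([[0.0, 1.0], [1.0, 0.0]]))
        n = Tensor(np.ones((2, 1)))
        p = Tensor(np.array([[1.0], [1.0]]))
        w = Tensor(np.eye(1), requires_grad=True)
        a_next, _ = coarsen(a, n, p, w)
        np.testing.assert_allclose(a_next.data, [[2.0]])


class TestLevelRepresentation:
    def _setup(self, n_rows):
        """Empty adjacency + identity fusion weights: fused rows = features."""
        a = Tensor(np.zeros((2, 2)))
        n = Tensor(np.asarray(n_rows, dtype=float))
        w = Tensor(np.eye(2), requires_grad=True)
        return a, n, w

    def test_coordinatewise_max_of_rows(self):
        a, n, w = self._setup([[1.0, 5.0], [3.0, 2.0]])
        h = level_representation(a, n, Tensor(np.eye(2)), w)
        np.testing.assert_allclose(h.data, [3.0, 5.0])

    def test_single_cluster_returns_its_row(self):
        a, n, w = self._setup([[1.0, 5.0], [3.0, 2.0]])
        p = Tensor(np.array([[1.0], [1.0]]))
        h = level_representation(a, n, p, w)
        np.testing.assert_allclose(h.data, [4.0, 7.0])  # the summed cluster row

    def test_duplicated_coarse_row_leaves_max_unchanged(self):
        a, n, w = self._setup([[1.0, 5.0], [3.0, 2.0]])
        p1 = Tensor(np.eye(2))
        p2 = Tensor(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]]))
        h1 = level_representation(a, n, p1, w)
        h2 = level_representation(a, n, p2, w)
        np.testing.assert_allclose(h1.data, h2.data)

    def test_empty_level_rejected(self):
        a, n, w = self._setup([[1.0, 5.0], [3.0, 2.0]])
        with pytest.raises(ValueError, match="empty level"):
            level_representation(a, n, Tensor(np.zeros((2, 0))), w)


class TestAggregateLevels:
    def test_single_level_is_identity(self):
        h1 = Tensor(np.array([1.0, -2.0, 3.0]))
        q = Tensor(np.array([0.5, 0.5, 0.5]), requires_grad=True)
        out = aggregate_levels([h1], q)
        np.testing.assert_allclose(out.data, h1.data)

    def test_equal_scores_give_unweighted_mean(self):
        reps = [Tensor(np.array([1.0, 0.0])), Tensor(np.array([3.0, 2.0]))]
        q = Tensor(np.zeros(2), requires_grad=True)  # all scores 0
        out = aggregate_levels(reps, q)
        np.testing.assert_allclose(out.data, [2.0, 1.0])

    def test_weights_sum_to_one_over_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            reps = [Tensor(rng.standard_normal(4)) for _ in range(3)]
            q = Tensor(rng.standard_normal(4), requires_grad=True)
            _, w = aggregate_levels(reps, q, return_weights=True)
            assert abs(w.data.sum() - 1.0) < 1e-9

    def test_ratio_mode_matches_literal_formula_for_positive_scores(self):
        reps = [Tensor(np.array([1.0, 2.0])), Tensor(np.array([2.0, 1.0]))]
        q = Tensor(np.array([1.0, 1.0]), requires_grad=True)  # scores 3, 3
        out = aggregate_levels(reps, q, attn_norm="ratio")
        np.testing.assert_allclose(out.data, [1.5, 1.5])


class TestComputeGate:
    def test_zero_map_gives_half_everywhere(self):
        g = compute_gate(
            Tensor(np.ones(3)),
            Tensor(np.zeros((2, 3)), requires_grad=True),
            Tensor(np.zeros(2), requires_grad=True),
        )
        np.testing.assert_allclose(g.data, 0.5)

    def test_large_bias_saturates_to_one(self):
        g = compute_gate(
            Tensor(np.ones(2)),
            Tensor(np.zeros((2, 2)), requires_grad=True),
            Tensor(np.full(2, 1e3), requires_grad=True),
        )
        np.testing.assert_allclose(g.data, 1.0)

    def test_hand_computed_sigmoid_values(self):
        """Pre-activation (0, ln 3) -> (1/2, 3/4)."""
        g = compute_gate(
            Tensor(np.array([0.0, np.log(3.0)])),
            Tensor(np.eye(2), requires_grad=True),
            Tensor(np.zeros(2), requires_grad=True),
        )
        np.testing.assert_allclose(g.data, [0.5, 0.75], atol=1e-12)


class TestBuildHierarchy:
    def test_composed_invariants(self, toy_graph, toy_cfg):
        rng = np.random.default_rng(6)
        params = init_params(2, toy_cfg, 6, rng)
        hier = build_hierarchy(toy_graph, params, toy_cfg)
        for lvl in hier.levels:
            if lvl.assignment is not None:
                np.testing.assert_allclose(
                    lvl.assignment.data.sum(axis=1), 1.0, atol=1e-6
                )
            np.testing.assert_allclose(
                lvl.adjacency.data, lvl.adjacency.data.T, atol=1e-10
            )
        assert np.all(hier.gate.data > 0) and np.all(hier.gate.data < 1)

    def test_single_level_uses_input_graph_only(self, toy_graph):
        """D=1: gate comes from the max-pooled fused input features."""
        cfg = RunConfig(hidden_dim=4, levels=1, cluster_counts=None)
        rng = np.random.default_rng(7)
        params = init_params(2, cfg, 6, rng)
        hier = build_hierarchy(toy_graph, params, cfg)
        a_hat = normalize_adjacency(toy_graph.adjacency)
        fused = a_hat @ toy_graph.features @ params["fgnn_0"].data
        np.testing.assert_allclose(hier.level_reps[0].data, fused.max(axis=0))
        assert len(hier.levels) == 1 and hier.levels[0].assignment is None

    def test_gate_invariant_under_node_permutation(self, toy_graph, toy_cfg):
        rng = np.random.default_rng(8)
        params = init_params(2, toy_cfg, 6, rng)
        g1 = build_hierarchy(toy_graph, params, toy_cfg).gate.data
        g2 = build_hierarchy(
            toy_graph.permuted(rng.permutation(6)), params, toy_cfg
        ).gate.data
        assert np.max(np.abs(g1 - g2)) < 1e-6

    def test_trained_assignment_separates_two_triangles(self, toy_graph):
        """After training, the two triangles get distinct argmax communities.

        Brute-force enumeration of 2-cluster partitions shows the two
        triangles maximize within-cluster edge mass; the learned softmax
        assignment should agree.
        """
        from itertools import combinations

        adj = toy_graph.adjacency
        best_mass, best_half = -1.0, None
        for r in range(1, 6):
            for grp in combinations(range(6), r):
                s = set(grp)
                t = set(range(6)) - s
                mass = sum(adj[i, j] for i in s for j in s if i < j)
                mass += sum(adj[i, j] for i in t for j in t if i < j)
                if mass > best_mass:
                    best_mass, best_half = mass, s
        assert best_half in ({0, 1, 2}, {3, 4, 5})

        cfg = RunConfig(
            hidden_dim=8, decoder_dim=4, ways=2, shots=2, queries=1,
            cluster_counts=[2], optimizer="adam", gamma=0.01,
            episodes_per_epoch=50, epochs=4, seed=0,
        )
        bank = GraphBank([toy_graph], ["auxiliary"])
        state = train(bank, cfg)
        assignment = build_hierarchy(toy_graph, state.params, cfg)
        labels = assignment.levels[0].assignment.data.argmax(axis=1)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]


class TestGateNeutrality:
    def test_huge_bias_recovers_ungated_encoder(self, toy_graph, toy_cfg):
        """As b_g -> +inf, g -> 1 and the gated output matches gate=None."""
        rng = np.random.default_rng(9)
        params = init_params(2, toy_cfg, 6, rng)
        params.params["b_g"].data[:] = 50.0
        hier = build_hierarchy(toy_graph, params, toy_cfg)
        gated = encode(toy_graph, params, toy_cfg, gate=hier.gate).data
        ungated = encode(toy_graph, params, toy_cfg).data
        assert np.max(np.abs(gated - ungated)) < 1e-9
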