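"""Relation graphs, prototypes, episode loss and nearest-prototype labels."""

import numpy as np
import pytest

from sebiograph.autodiff import Tensor
from sebiograph.config import RunConfig
from sebiograph.graph_io import BioGraph
from sebiograph.nn import ModelParams
from sebiograph.prototype_metric import (
    ClassRelationGraph,
    Episode,
    PrototypeSet,
    build_prototypes,
    build_relation_graph,
    classify,
    compute_prototype,
    episode_loss,
)

CFG = RunConfig()


def line_graph(n, extra_edges=()):
    adj = np.zeros((n, n))
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1.0
    for i, j in extra_edges:
        adj[i, j] = adj[j, i] = 1.0
    return BioGraph([f"n{i}" for i in range(n)], adj, np.zeros((n, 1)))


class TestEpisode:
    def test_overlapping_support_query_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Episode(0, [(0, 1)], [(0, 1)])

    def test_query_class_must_be_supported(self):
        with pytest.raises(ValueError, match="absent"):
            Episode(0, [(0, 1)], [(1, 2)])


class TestRelationGraph:
    def test_single_member_is_one_by_one_zero(self):
        g = line_graph(3)
        r = build_relation_graph(g, [1])
        assert r.adjacency.shape == (1, 1) and r.adjacency[0, 0] == 0.0

    def test_isolated_adjacent_pair_weight_half(self):
        """Two adjacent nodes with no other neighbors: spd term only."""
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        g = BioGraph(list("abcd"), adj, np.zeros((4, 1)))
        r = build_relation_graph(g, [0, 1], k_hop=1)
        np.testing.assert_allclose(r.adjacency, [[0.0, 0.5], [0.5, 0.0]])

    def test_disconnected_members_weight_zero(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        g = BioGraph(list("abcd"), adj, np.zeros((4, 1)))
        r = build_relation_graph(g, [0, 2], k_hop=1)
        np.testing.assert_allclose(r.adjacency, 0.0)

    def test_shared_neighborhood_term(self):
        """Triangle 0-1-2: members 0,2 share neighbor 1 and each other."""
        g = line_graph(3, extra_edges=[(0, 2)])
        r = build_relation_graph(g, [0, 2], k_hop=1, relation_lambda=1.0)
        # spd(0,2)=1; 1-hop hoods {1,2} and {0,1}: common {1}, union {0,1,2}
        expected = 1.0 / 2.0 + 1.0 / 3.0
        np.testing.assert_allclose(r.adjacency[0, 1], expected)

    def test_invalid_relation_matrix_rejected(self):
        with pytest.raises(ValueError):
            ClassRelationGraph(1, [0, 1], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestComputePrototype:
    def _params(self, d=2):
        return ModelParams({"pgnn": Tensor(np.eye(d), requires_grad=True)})

    def test_singleton_class_returns_member_embedding(self):
        r = ClassRelationGraph(1, [5], np.zeros((1, 1)))
        emb = Tensor(np.array([[2.0, -3.0]]))
        c = compute_prototype(r, emb, self._params(), CFG)
        np.testing.assert_allclose(c.data, [2.0, -3.0])

    def test_empty_relation_reduces_to_coordinatewise_max(self):
        """Zero relation weights leave only self-loops: max of rows."""
        r = ClassRelationGraph(1, [0, 1], np.zeros((2, 2)))
        emb = Tensor(np.array([[1.0, 4.0], [3.0, 2.0]]))
        c = compute_prototype(r, emb, self._params(), CFG)
        np.testing.assert_allclose(c.data, [3.0, 4.0])

    def test_duplicated_member_row_leaves_prototype_unchanged(self):
        r2 = ClassRelationGraph(1, [0, 1], np.zeros((2, 2)))
        r3 = ClassRelationGraph(1, [0, 1, 2], np.zeros((3, 3)))
        e2 = Tensor(np.array([[1.0, 4.0], [3.0, 2.0]]))
        e3 = Tensor(np.array([[1.0, 4.0], [3.0, 2.0], [3.0, 2.0]]))
        c2 = compute_prototype(r2, e2, self._params(), CFG)
        c3 = compute_prototype(r3, e3, self._params(), CFG)
        np.testing.assert_allclose(c2.data, c3.data)

    def test_mean_mode_returns_class_mean(self):
        cfg = CFG.replace(prototype="mean")
        r = ClassRelationGraph(1, [0, 1], np.zeros((2, 2)))
        emb = Tensor(np.array([[1.0, 4.0], [3.0, 2.0]]))
        c = compute_prototype(r, emb, self._params(), cfg)
        np.testing.assert_allclose(c.data, [2.0, 3.0])


def _episode_with(embeddings, protos_xy, query_rows, query_labels):
    """Loss for explicit prototypes and query embeddings (2 support rows 0,1)."""
    support = [(0, 1), (1, 2)][: len(protos_xy)]
    query = list(zip(query_rows, query_labels))
    ep = Episode(0, support, query)
    protos = PrototypeSet(
        classes=np.arange(1, len(protos_xy) + 1),
        vectors=Tensor(np.asarray(protos_xy, dtype=float)),
    )
    return episode_loss(ep, Tensor(np.asarray(embeddings, dtype=float)), protos, CFG)


class TestEpisodeLoss:
    def test_single_class_loss_is_exactly_zero(self):
        loss = _episode_with(
            [[0.0, 0.0], [9.0, 9.0], [5.0, 5.0]], [[1.0, 1.0]], [2], [1]
        )
        assert loss.item() == 0.0

    def test_equidistant_two_prototypes_give_ln2(self):
        loss = _episode_with(
            [[0.0, 0.0], [0.0, 0.0], [0.0, 1.0]],
            [[-1.0, 1.0], [1.0, 1.0]],
            [2],
            [1],
        )
        np.testing.assert_allclose(loss.item(), np.log(2.0), atol=1e-12)

    def test_worked_example_ln_1_plus_exp_minus_3(self):
        """Prototypes (0,0), (3,0); query (1,0) class 1: d=(1,4) -> ln(1+e⁻³)."""
        loss = _episode_with(
            [[9.0, 9.0], [9.0, 9.0], [1.0, 0.0]],
            [[0.0, 0.0], [3.0, 0.0]],
            [2],
            [1],
        )
        np.testing.assert_allclose(loss.item(), np.log(1 + np.exp(-3)), atol=1e-12)

    def test_loss_nonnegative_on_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            emb = rng.standard_normal((6, 3))
            protos = rng.standard_normal((2, 3))
            loss = _episode_with(emb, protos, [2, 3, 4], [1, 2, 1])
            assert loss.item() >= 0.0

    def test_invariant_under_class_relabeling_and_order(self, toy_graph, toy_cfg):
        rng = np.random.default_rng(12)
        emb = Tensor(rng.standard_normal((6, 4)))
        protos = PrototypeSet(
            classes=np.array([1, 2]), vectors=Tensor(rng.standard_normal((2, 4)))
        )
        protos_relabeled = PrototypeSet(
            classes=np.array([5, 9]), vectors=Tensor(protos.vectors.data.copy())
        )
        sup = [(0, 1), (1, 2)]
        qry = [(2, 1), (3, 2), (4, 1)]
        base = episode_loss(Episode(0, sup, qry), emb, protos, CFG).item()
        relab = episode_loss(
            Episode(0, [(0, 5), (1, 9)], [(2, 5), (3, 9), (4, 5)]),
            emb, protos_relabeled, CFG,
        ).item()
        shuffled = episode_loss(
            Episode(0, sup[::-1], qry[::-1]), emb, protos, CFG
        ).item()
        np.testing.assert_allclose([relab, shuffled], base, atol=1e-12)

    def test_missing_prototype_for_query_class_rejected(self):
        protos = PrototypeSet(classes=np.array([1]), vectors=Tensor(np.zeros((1, 2))))
        ep = Episode(0, [(0, 1), (1, 2)], [(2, 2)])
        with pytest.raises(ValueError, match="without prototypes"):
            episode_loss(ep, Tensor(np.zeros((3, 2))), protos, CFG)


class TestClassify:
    def test_node_at_prototype_location_wins(self):
        protos = PrototypeSet(
            classes=np.array([1, 2, 3]),
            vectors=Tensor(np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])),
        )
        labels, probs = classify(np.array([[5.0, 0.0]]), protos, CFG)
        assert labels[0] == 2
        assert probs[0, 1] > 1.0 / 3.0

    def test_exact_tie_goes_to_lowest_class(self):
        protos = PrototypeSet(
            classes=np.array([2, 5]),
            vectors=Tensor(np.array([[-1.0, 0.0], [1.0, 0.0]])),
        )
        labels, _ = classify(np.array([[0.0, 0.0]]), protos, CFG)
        assert labels[0] == 2

    def test_probabilities_sum_to_one_on_random_draws(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            protos = PrototypeSet(
                classes=np.array([1, 2, 3]),
                vectors=Tensor(rng.standard_normal((3, 4))),
            )
            _, probs = classify(rng.standard_normal((5, 4)), protos, CFG)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_cosine_distance_option(self):
        cfg = CFG.replace(distance="cosine")
        protos = PrototypeSet(
            classes=np.array([1, 2]),
            vectors=Tensor(np.array([[1.0, 0.0], [0.0, 1.0]])),
        )
        labels, _ = classify(np.array([[10.0, 0.1]]), protos, cfg)
        assert labels[0] == 1


class TestBuildPrototypes:
    def test_one_prototype_per_class_sorted(self, toy_graph, toy_cfg):
        rng = np.random.default_rng(14)
        emb = Tensor(rng.standard_normal((6, 8)))
        params = ModelParams({"pgnn": Tensor(np.eye(8), requires_grad=True)})
        sup = [(0, 2), (1, 2), (3, 1), (4, 1)]
        protos = build_prototypes(toy_graph, sup, emb, params, toy_cfg)
        np.testing.assert_array_equal(protos.classes, [1, 2])
        assert protos.vectors.shape == (2, 8)
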