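"""Structured class prototypes and the distance-softmax episode loss.

A class prototype is not a bare mean: the support nodes of a class are first
linked into an intra-class *relation graph* whose weights combine inverse
shortest-path distance with shared k-hop neighborhood overlap, a one-layer
prototype convolution (PGNN) propagates the members' embeddings over that
relation graph, and the prototype is the coordinate-wise max over members.
``prototype="mean"`` falls back to the plain support-mean prototype of
classic prototypical networks.

Queries are scored by a softmax over negated distances to the prototypes;
the episode loss is the negative log-likelihood of the query labels,
computed with log-sum-exp stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.csgraph as csgraph

from .autodiff import Tensor, logsumexp, stack
from .config import RunConfig
from .graph_io import BioGraph
from .nn import ModelParams, normalize_adjacency

__all__ = [
    "Episode",
    "ClassRelationGraph",
    "PrototypeSet",
    "build_relation_graph",
    "compute_prototype",
    "build_prototypes",
    "episode_loss",
    "classify",
]


@dataclass
class Episode:
    """One few-shot task: a graph with disjoint support and query node sets."""

    graph_index: int
    support: list[tuple[int, int]]  # (node index, class label)
    query: list[tuple[int, int]]

    def __post_init__(self):
        s_nodes = {n for n, _ in self.support}
        q_nodes = {n for n, _ in self.query}
        if s_nodes & q_nodes:
            raise ValueError(f"support and query overlap: {sorted(s_nodes & q_nodes)}")
        if not self.support:
            raise ValueError("empty support set")
        s_classes = self.support_classes()
        missing = {y for _, y in self.query} - set(s_classes)
        if missing:
            raise ValueError(f"query classes absent from support: {sorted(missing)}")

    def support_classes(self) -> np.ndarray:
        return np.unique([y for _, y in self.support])

    @property
    def ways(self) -> int:
        return self.support_classes().size


@dataclass
class ClassRelationGraph:
    """Similarity graph over one class's support nodes."""

    cls: int
    members: np.ndarray          # node indices into the host graph
    adjacency: np.ndarray        # symmetric, zero-diagonal, non-negative

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=np.int64)
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        n = self.members.size
        if self.adjacency.shape != (n, n):
            raise ValueError("relation adjacency must be square over members")
        if np.any(self.adjacency < 0) or np.any(np.diag(self.adjacency) != 0):
            raise ValueError("relation weights must be non-negative, zero diagonal")


@dataclass
class PrototypeSet:
    """One prototype vector per support class, rows aligned with classes."""

    classes: np.ndarray          # sorted class labels
    vectors: Tensor              # (K, h')

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if self.vectors.shape[0] != self.classes.size:
            raise ValueError("one prototype per class required")
        if not np.all(np.isfinite(self.vectors.data)):
            raise ValueError("non-finite prototype entries")


def build_relation_graph(
    graph: BioGraph,
    members,
    k_hop: int = 2,
    relation_lambda: float = 1.0,
) -> ClassRelationGraph:
    """Intra-class relation graph over ``members`` of the host graph.

    weight(u, v) = 1/(1 + spd(u, v))
                 + λ · |k-hop nbhd(u) ∩ k-hop nbhd(v)| / max(1, |union|)

    with spd the unweighted shortest-path distance in the full graph;
    disconnected pairs contribute 0 to the first term.
    """
    members = np.asarray(members, dtype=np.int64)
    if members.size == 0:
        raise ValueError("members must be non-empty")
    if k_hop < 1:
        raise ValueError("k_hop must be >= 1")
    n = members.size
    adj = np.zeros((n, n))
    if n > 1:
        # BFS distances from every member to all nodes, in one C call.
        dist = csgraph.dijkstra(
            graph.csr(), directed=False, unweighted=True, indices=members
        )
        hoods = [
            set(np.flatnonzero((dist[i] >= 1) & (dist[i] <= k_hop)))
            for i in range(n)
        ]
        for i in range(n):
            for j in range(i + 1, n):
                spd = dist[i, members[j]]
                w = 0.0 if np.isinf(spd) else 1.0 / (1.0 + spd)
                union = hoods[i] | hoods[j]
                common = hoods[i] & hoods[j]
                w += relation_lambda * len(common) / max(1, len(union))
                adj[i, j] = adj[j, i] = w
    cls = int(graph.labels[members[0]]) if graph.labels is not None else 0
    return ClassRelationGraph(cls=cls, members=members, adjacency=adj)


def compute_prototype(
    relation: ClassRelationGraph,
    member_embeddings: Tensor,
    params: ModelParams,
    config: RunConfig,
) -> Tensor:
    """Prototype c^k: PGNN over the relation graph, then max over members.

    With ``config.prototype == "mean"`` the relation graph and PGNN are
    bypassed and the plain mean of the member embeddings is returned.
    """
    if member_embeddings.shape[0] != relation.members.size:
        raise ValueError("embedding rows must align with relation members")
    if relation.members.size == 0:
        raise ValueError("empty member set")
    if config.prototype == "mean":
        return member_embeddings.mean(axis=0)
    a_hat = Tensor(normalize_adjacency(relation.adjacency))
    z = a_hat @ member_embeddings @ params["pgnn"]
    return z.max(axis=0)


def build_prototypes(
    graph: BioGraph,
    support: list[tuple[int, int]],
    embeddings: Tensor,
    params: ModelParams,
    config: RunConfig,
) -> PrototypeSet:
    """One structured prototype per support class, classes sorted ascending."""
    classes = np.unique([y for _, y in support])
    vectors = []
    for cls in classes:
        members = np.asarray([n for n, y in support if y == cls], dtype=np.int64)
        member_emb = embeddings.take_rows(members)
        if config.prototype == "mean":
            vectors.append(member_emb.mean(axis=0))
        else:
            relation = build_relation_graph(
                graph, members, config.relation_k_hop, config.relation_lambda
            )
            vectors.append(compute_prototype(relation, member_emb, params, config))
    return PrototypeSet(classes=classes, vectors=stack(vectors, axis=0))


def _pairwise_distance(queries: Tensor, protos: Tensor, metric: str) -> Tensor:
    """(Q, K) distance matrix between query embeddings and prototypes."""
    if metric == "sqeuclidean":
        q2 = (queries * queries).sum(axis=1, keepdims=True)        # (Q, 1)
        c2 = (protos * protos).sum(axis=1).reshape(1, protos.shape[0])
        return q2 + c2 - 2.0 * (queries @ protos.T)
    if metric == "cosine":
        qn = queries * ((queries * queries).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
        cn = protos * ((protos * protos).sum(axis=1, keepdims=True) + 1e-12) ** -0.5
        return 1.0 - qn @ cn.T
    raise ValueError(f"unknown distance metric {metric!r}")


def episode_loss(
    episode: Episode,
    embeddings: Tensor,
    prototypes: PrototypeSet,
    config: RunConfig,
) -> Tensor:
    """Negative log-likelihood of query labels under the distance softmax.

    L = − Σ_{(n,y)∈Q} log[ exp(−d(f(n), c^y)) / Σ_k exp(−d(f(n), c^k)) ],
    averaged (default) or summed over queries.
    """
    class_pos = {int(c): i for i, c in enumerate(prototypes.classes)}
    missing = {y for _, y in episode.query} - set(class_pos)
    if missing:
        raise ValueError(f"query classes without prototypes: {sorted(missing)}")
    q_idx = np.asarray([n for n, _ in episode.query], dtype=np.int64)
    y_idx = np.asarray([class_pos[y] for _, y in episode.query], dtype=np.int64)
    queries = embeddings.take_rows(q_idx)
    d = _pairwise_distance(queries, prototypes.vectors, config.distance)
    logits = -d
    one_hot = np.zeros(d.shape)
    one_hot[np.arange(y_idx.size), y_idx] = 1.0
    per_query = logsumexp(logits, axis=1) - (logits * Tensor(one_hot)).sum(axis=1)
    if config.loss_reduction == "sum":
        return per_query.sum()
    return per_query.mean()


def classify(
    embeddings: np.ndarray | Tensor,
    prototypes: PrototypeSet,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-prototype labels and distance-softmax class probabilities.

    Ties go to the lowest class index (classes are sorted, argmin takes the
    first minimum).  Inference only: operates on plain arrays.
    """
    if prototypes.classes.size == 0:
        raise ValueError("empty prototype set")
    emb = embeddings.data if isinstance(embeddings, Tensor) else np.asarray(embeddings)
    d = _pairwise_distance(
        Tensor(emb), Tensor(prototypes.vectors.data), config.distance
    ).data
    logits = -d
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    labels = prototypes.classes[np.argmin(d, axis=1)]
    return labels, probs
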