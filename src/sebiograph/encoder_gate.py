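"""Gated node encoder and the hierarchical graph-representation gate.

The encoder f_θ is a two-layer graph convolution whose output-layer weight
block α is *globally shared* across graphs.  Before encoding a particular
graph, a hierarchy of coarsened views of that graph is summarized into a
vector h_i, mapped through a sigmoid gate g_i = σ(W_g h_i + b_g), and α is
modulated element-wise: α_i = g_i ∘ α.  Similar graphs therefore steer the
shared parameters toward similar metric spaces, which is the transfer
mechanism of the whole model.

The hierarchy itself alternates three stages per level:

* ``assign_nodes`` — a one-layer assignment convolution (AGNN) produces a
  row-stochastic matrix P mapping the K^d current nodes onto K^{d+1}
  communities (softmax over community logits);
* ``coarsen``      — A^{d+1} = Pᵀ A^d P and N^{d+1} = Pᵀ·FGNN(A^d, N^d),
  with FGNN a one-layer fusion convolution;
* ``level_representation`` — coordinate-wise max over the coarsened rows.

Level summaries are combined by attention against a learnable query vector
q, normalized with a softmax by default (the literal ratio form is available
as ``attn_norm="ratio"`` but is undefined for non-positive scores).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax, stack
from .config import RunConfig
from .graph_io import BioGraph, GraphBank
from .nn import ModelParams, get_activation, normalize_adjacency_t

logger = logging.getLogger(__name__)

__all__ = [
    "HierarchyState",
    "LevelState",
    "init_params",
    "resolve_cluster_counts",
    "encode",
    "assign_nodes",
    "coarsen",
    "level_representation",
    "aggregate_levels",
    "compute_gate",
    "build_hierarchy",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def resolve_cluster_counts(config: RunConfig, m: int) -> list[int]:
    """Community counts K^2 > K^3 > ... for a graph of m nodes."""
    if config.cluster_counts is not None:
        return list(config.cluster_counts)
    counts = []
    k = m
    for _ in range(config.levels - 1):
        k = max(2, math.ceil(k / 4))
        counts.append(k)
    return counts


def init_params(
    feature_dim: int,
    config: RunConfig,
    m_ref: int,
    rng: np.random.Generator,
    decoder: bool = True,
) -> ModelParams:
    """Zero-mean Gaussian initialization of all learnable parameters Φ.

    ``m_ref`` is the reference node count used to resolve default community
    counts (AGNN output widths are fixed at build time and shared by every
    graph; node counts may still vary since AGNN maps features, not nodes).
    """
    config.validate()
    hd = config.hidden_dim
    std = config.init_std
    counts = resolve_cluster_counts(config, m_ref)

    def gauss(*shape):
        return Tensor(std * rng.standard_normal(shape), requires_grad=True)

    p: dict[str, Tensor] = {}
    # Encoder: (layers-1) hidden maps followed by the shared, gated block α.
    widths = [feature_dim] + [hd] * (config.layers - 1)
    for i in range(config.layers - 1):
        p[f"enc_W{i}"] = gauss(widths[i], widths[i + 1])
    p["alpha"] = gauss(widths[-1], hd)
    # Gate head and level-attention query.
    p["W_g"] = gauss(hd, hd)
    p["b_g"] = Tensor(np.zeros(hd), requires_grad=True)
    p["q"] = gauss(hd)
    # Hierarchy convolutions: input width is h at level 1, hidden afterwards.
    in_dims = [feature_dim] + [hd] * (config.levels - 1)
    for d in range(config.levels - 1):
        p[f"agnn_{d}"] = gauss(in_dims[d], counts[d])
    for d in range(config.levels):
        p[f"fgnn_{d}"] = gauss(in_dims[d], hd)
    # Prototype convolution over intra-class relation graphs.
    p["pgnn"] = gauss(hd, hd)
    if decoder:
        p["dec_W"] = gauss(hd, config.decoder_dim)
    return ModelParams(p)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def encode(
    graph: BioGraph,
    params: ModelParams,
    config: RunConfig,
    gate: Tensor | np.ndarray | None = None,
) -> Tensor:
    """Node embeddings f_θ(A, N), optionally with gate-modulated α.

    Two rounds of renormalized neighborhood aggregation, a nonlinearity
    between them and a linear output layer.  When ``gate`` is given, the
    output block α is replaced by g_i ∘ α (g_i broadcast across columns).
    """
    if graph.features.shape[1] != params["enc_W0"].shape[0]:
        raise ValueError(
            f"feature width {graph.features.shape[1]} does not match encoder "
            f"input width {params['enc_W0'].shape[0]}"
        )
    act = get_activation(config.activation)
    a_hat = Tensor(graph.normalized_adjacency())
    x = Tensor(graph.features)
    for i in range(config.layers - 1):
        x = act(a_hat @ x @ params[f"enc_W{i}"])
    alpha = params["alpha"]
    if gate is not None:
        g = _as_tensor(gate)
        if g.shape != (alpha.shape[0],):
            raise ValueError(
                f"gate shape {g.shape} does not match alpha rows {alpha.shape[0]}"
            )
        alpha = g.reshape(alpha.shape[0], 1) * alpha
    return a_hat @ x @ alpha


# ---------------------------------------------------------------------------
# hierarchy stages
# ---------------------------------------------------------------------------


def assign_nodes(a_d: Tensor, n_d: Tensor, w_agnn: Tensor, k_next: int) -> Tensor:
    """Row-stochastic assignment of K^d nodes onto k_next communities."""
    if k_next < 1:
        raise ValueError("k_next must be >= 1")
    if k_next > a_d.shape[0]:
        logger.warning(
            "over-clustering: %d communities requested for %d nodes",
            k_next, a_d.shape[0],
        )
    a_hat = normalize_adjacency_t(_as_tensor(a_d))
    logits = a_hat @ _as_tensor(n_d) @ w_agnn
    if not np.all(np.isfinite(logits.data)):
        raise FloatingPointError("non-finite assignment logits")
    if logits.shape[1] != k_next:
        raise ValueError(
            f"assignment weights produce {logits.shape[1]} communities, "
            f"expected {k_next}"
        )
    return softmax(logits, axis=1)


def _fuse(a_d: Tensor, n_d: Tensor, w_fgnn: Tensor) -> Tensor:
    """One-layer fusion convolution FGNN(A^d, N^d)."""
    return normalize_adjacency_t(_as_tensor(a_d)) @ _as_tensor(n_d) @ w_fgnn


def coarsen(
    a_d: Tensor, n_d: Tensor, p: Tensor, w_fgnn: Tensor
) -> tuple[Tensor, Tensor]:
    """Next-level adjacency PᵀA^dP and features Pᵀ·FGNN(A^d, N^d)."""
    a_d, n_d, p = _as_tensor(a_d), _as_tensor(n_d), _as_tensor(p)
    if p.shape[0] != a_d.shape[0]:
        raise ValueError(
            f"assignment rows {p.shape[0]} do not match adjacency {a_d.shape[0]}"
        )
    a_next = p.T @ a_d @ p
    n_next = p.T @ _fuse(a_d, n_d, w_fgnn)
    return a_next, n_next


def level_representation(
    a_d: Tensor, n_d: Tensor, p: Tensor, w_fgnn: Tensor
) -> Tensor:
    """Coordinate-wise max over the coarsened node rows Pᵀ·FGNN(A^d, N^d)."""
    p = _as_tensor(p)
    if p.shape[1] == 0:
        raise ValueError("empty level: no communities to pool over")
    return (p.T @ _fuse(a_d, n_d, w_fgnn)).max(axis=0)


def aggregate_levels(
    level_reps: list[Tensor],
    q: Tensor,
    attn_norm: str = "softmax",
    return_weights: bool = False,
):
    """Attention-weighted combination h_i = Σ_d w_d h^d, weights from qᵀh^d.

    Weights are normalized to sum to 1; with ``return_weights`` the
    (h_i, weights) pair is returned for inspection.
    """
    if not level_reps:
        raise ValueError("need at least one level representation")
    reps = stack([_as_tensor(r) for r in level_reps], axis=0)  # (D, width)
    scores = reps @ q
    if not np.all(np.isfinite(scores.data)):
        raise FloatingPointError("non-finite attention scores")
    if attn_norm == "softmax":
        weights = softmax(scores, axis=0)
    elif attn_norm == "ratio":
        total = scores.sum()
        if abs(total.item()) < 1e-12:
            raise FloatingPointError("ratio attention normalizer is ~0")
        weights = scores / total
    else:
        raise ValueError(f"unknown attn_norm {attn_norm!r}")
    out = weights @ reps
    return (out, weights) if return_weights else out


def compute_gate(h_i: Tensor, w_g: Tensor, b_g: Tensor) -> Tensor:
    """Sigmoid gate g_i = σ(W_g h_i + b_g); entries strictly in (0, 1)."""
    return (w_g @ _as_tensor(h_i) + b_g).sigmoid()


# ---------------------------------------------------------------------------
# full hierarchy
# ---------------------------------------------------------------------------


@dataclass
class LevelState:
    """One hierarchy level: its view of the graph and its assignment."""

    adjacency: Tensor
    features: Tensor
    assignment: Tensor | None  # None at the terminal level


@dataclass
class HierarchyState:
    levels: list[LevelState]
    level_reps: list[Tensor]
    h_i: Tensor
    gate: Tensor


def build_hierarchy(
    graph: BioGraph, params: ModelParams, config: RunConfig
) -> HierarchyState:
    """Coarsen the graph level by level and compute its gate vector.

    For d = 1..D-1 the graph is assigned onto K^{d+1} communities and
    coarsened; each level's representation is the max-pooled coarsened
    feature block.  The terminal level is summarized without further
    coarsening (with D=1 the gate is computed from the max-pooled fused
    node features of the input graph alone).
    """
    a = Tensor(graph.adjacency)
    n = Tensor(graph.features)
    counts = resolve_cluster_counts(config, graph.m)
    levels: list[LevelState] = []
    reps: list[Tensor] = []
    for d in range(config.levels):
        w_fgnn = params[f"fgnn_{d}"]
        if d < config.levels - 1:
            p = assign_nodes(a, n, params[f"agnn_{d}"], counts[d])
            a_next, n_next = coarsen(a, n, p, w_fgnn)
            # Identical to level_representation(a, n, p, w_fgnn): the
            # coarsened feature block is reused instead of recomputed.
            reps.append(n_next.max(axis=0))
            levels.append(LevelState(adjacency=a, features=n, assignment=p))
            a, n = a_next, n_next
        else:
            reps.append(_fuse(a, n, w_fgnn).max(axis=0))
            levels.append(LevelState(adjacency=a, features=n, assignment=None))
    h_i = aggregate_levels(reps, params["q"], config.attn_norm)
    gate = compute_gate(h_i, params["W_g"], params["b_g"])
    return HierarchyState(levels=levels, level_reps=reps, h_i=h_i, gate=gate)
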