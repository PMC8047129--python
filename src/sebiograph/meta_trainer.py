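"""Episodic meta-training over a graph bank, evaluation and checkpointing.

Each training step samples a few-shot episode from a uniformly chosen
auxiliary graph, runs the full pipeline — hierarchy gate, gated encoding,
structured prototypes, distance-softmax loss — adds the weighted
reconstruction constraint, and updates all parameters Φ by gradient descent
(Φ ← Φ − γ∇Φ with the plain optimizer; Adam is the practical option).

At evaluation time the meta-learned parameters are frozen by default:
prototypes are built from the target graph's small support set and the
held-out labeled queries are classified by nearest prototype.  Link
prediction reuses the same machinery on Hadamard pair embeddings with an
edge/non-edge class pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import KFold

from .autodiff import Tensor
from .auxiliary_decoder import reconstruction_loss
from .config import RunConfig
from .encoder_gate import build_hierarchy, encode, init_params
from .graph_io import UNLABELED, BioGraph, GraphBank
from .nn import ModelParams, make_optimizer
from .prototype_metric import (
    Episode,
    PrototypeSet,
    build_prototypes,
    classify,
    episode_loss,
)

__all__ = [
    "TrainState",
    "sample_episode",
    "episode_objective",
    "train",
    "embed_graph",
    "node_eval_split",
    "evaluate_node_classification",
    "train_scratch_baseline",
    "transfer_comparison",
    "evaluate_link_prediction",
    "link_harness_accuracy",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainState:
    """Learned parameters plus the full training trace."""

    params: ModelParams
    config: RunConfig
    epoch: int
    history: dict[str, list[float]] = field(default_factory=dict)
    rng_state: dict | None = None
    feature_dim: int = 0
    m_ref: int = 0


# ---------------------------------------------------------------------------
# episode sampling and the joint objective
# ---------------------------------------------------------------------------


def sample_episode(
    bank: GraphBank, config: RunConfig, rng: np.random.Generator
) -> Episode:
    """Draw an episode from a uniformly chosen auxiliary graph.

    Classes and nodes are drawn without replacement; support and query are
    disjoint by construction.
    """
    aux_indices = [i for i, r in enumerate(bank.roles) if r == "auxiliary"]
    if not aux_indices:
        raise ValueError("bank has no auxiliary graphs to sample from")
    gi = aux_indices[rng.integers(len(aux_indices))]
    graph = bank.graphs[gi]
    if graph.labels is None:
        raise ValueError(f"graph {gi} has no labels")
    need = config.shots + config.queries
    eligible = []
    for cls in graph.classes():
        count = int(np.sum(graph.labels == cls))
        if count >= need:
            eligible.append(int(cls))
    if len(eligible) < config.ways:
        raise ValueError(
            f"graph {gi}: only {len(eligible)} classes have >= {need} labeled "
            f"nodes (classes {eligible}), but ways={config.ways}"
        )
    chosen = rng.choice(np.asarray(eligible), size=config.ways, replace=False)
    support: list[tuple[int, int]] = []
    query: list[tuple[int, int]] = []
    for cls in sorted(int(c) for c in chosen):
        members = np.flatnonzero(graph.labels == cls)
        picked = rng.choice(members, size=need, replace=False)
        support += [(int(n), cls) for n in picked[: config.shots]]
        query += [(int(n), cls) for n in picked[config.shots :]]
    return Episode(graph_index=gi, support=support, query=query)


def episode_objective(
    graph: BioGraph, params: ModelParams, episode: Episode, config: RunConfig
) -> tuple[Tensor, float, float]:
    """Total loss L_i + β·L_d for one episode; returns (loss, L_i, L_d)."""
    hier = build_hierarchy(graph, params, config)
    h = encode(graph, params, config, gate=hier.gate)
    protos = build_prototypes(graph, episode.support, h, params, config)
    l_i = episode_loss(episode, h, protos, config)
    if config.beta > 0 and "dec_W" in params:
        l_d = reconstruction_loss(graph, h, params, config)
        total = l_i + config.beta * l_d
        return total, l_i.item(), l_d.item()
    return l_i, l_i.item(), 0.0


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    bank: GraphBank,
    config: RunConfig,
    initial: ModelParams | None = None,
    log_path: str | Path | None = None,
) -> TrainState:
    """Meta-train over the bank's auxiliary graphs; reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m_ref = min(g.m for g in bank.graphs)
    params = initial if initial is not None else init_params(
        bank.h, config, m_ref, rng
    )
    opt = make_optimizer(config.optimizer, params, config.gamma)
    history: dict[str, list[float]] = {
        "episode_loss": [], "recon_loss": [], "total_loss": []
    }
    log_fh = open(log_path, "a") if log_path is not None else None
    if log_fh is not None:
        log_fh.write(json.dumps({
            "event": "start", "config_hash": config.config_hash(),
            "seed": config.seed, "config": config.to_dict(),
        }) + "\n")
    best = np.inf
    bad_epochs = 0
    epoch = 0
    try:
        for epoch in range(1, config.epochs + 1):
            for k in range(config.episodes_per_epoch):
                episode = sample_episode(bank, config, rng)
                graph = bank.graphs[episode.graph_index]
                total, l_i, l_d = episode_objective(graph, params, episode, config)
                if not np.isfinite(total.item()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, episode {k} "
                        f"(graph {episode.graph_index}): "
                        f"L_i={l_i}, L_d={l_d}"
                    )
                params.zero_grad()
                total.backward()
                opt.step()
                history["episode_loss"].append(l_i)
                history["recon_loss"].append(l_d)
                history["total_loss"].append(total.item())
            epoch_mean = float(
                np.mean(history["total_loss"][-config.episodes_per_epoch:])
            )
            if log_fh is not None:
                log_fh.write(json.dumps(
                    {"event": "epoch", "epoch": epoch, "mean_total": epoch_mean}
                ) + "\n")
            if config.patience > 0:
                if epoch_mean < best - 1e-12:
                    best = epoch_mean
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs > config.patience:
                        break
    finally:
        if log_fh is not None:
            log_fh.close()
    return TrainState(
        params=params,
        config=config,
        epoch=epoch,
        history=history,
        rng_state=rng.bit_generator.state,
        feature_dim=bank.h,
        m_ref=m_ref,
    )


# ---------------------------------------------------------------------------
# evaluation: node classification
# ---------------------------------------------------------------------------


def embed_graph(
    graph: BioGraph, params: ModelParams, config: RunConfig
) -> np.ndarray:
    """Gated node embeddings of one graph (inference; plain array out)."""
    hier = build_hierarchy(graph, params, config)
    return encode(graph, params, config, gate=hier.gate).data


def node_eval_split(
    target: BioGraph, config: RunConfig, split: int = 0
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Deterministic per-class support/query split of the target's labels.

    ``eval_shots`` support nodes per class; all remaining labeled nodes are
    queries.  ``split`` indexes independent resamples of the split.  Errors
    if any class lacks a held-out query.
    """
    if target.labels is None:
        raise ValueError("target graph has no labels")
    rng = np.random.default_rng([config.seed, 1, split])
    support: list[tuple[int, int]] = []
    query: list[tuple[int, int]] = []
    for cls in target.classes():
        members = np.flatnonzero(target.labels == cls)
        if members.size < config.eval_shots + 1:
            raise ValueError(
                f"class {int(cls)} has {members.size} labeled nodes; need "
                f"{config.eval_shots} support plus at least one query"
            )
        perm = rng.permutation(members)
        support += [(int(n), int(cls)) for n in perm[: config.eval_shots]]
        query += [(int(n), int(cls)) for n in perm[config.eval_shots :]]
    return support, query


def _support_only_graph(
    target: BioGraph, support: list[tuple[int, int]]
) -> BioGraph:
    labels = np.full(target.m, UNLABELED, dtype=np.int64)
    for n, y in support:
        labels[n] = y
    return BioGraph(
        node_ids=list(target.node_ids),
        adjacency=target.adjacency,
        features=target.features,
        labels=labels,
    )


def _fine_tune(
    state: TrainState, graph: BioGraph, support: list[tuple[int, int]],
    config: RunConfig,
) -> ModelParams:
    """Optional target adaptation: episodes drawn inside the support set."""
    params = state.params.copy()
    inner_shots = max(1, config.eval_shots // 2)
    inner_queries = max(1, config.eval_shots - inner_shots)
    n_classes = len({y for _, y in support})
    inner = config.replace(
        ways=min(config.ways, n_classes),
        shots=inner_shots,
        queries=inner_queries,
        episodes_per_epoch=config.fine_tune_episodes,
        epochs=1,
        patience=0,
    )
    bank = GraphBank([_support_only_graph(graph, support)], ["auxiliary"])
    return train(bank, inner, initial=params).params


def _eval_one_split(
    params: ModelParams,
    target: BioGraph,
    config: RunConfig,
    support: list[tuple[int, int]],
    query: list[tuple[int, int]],
) -> tuple[float, float]:
    hier = build_hierarchy(target, params, config)
    h = encode(target, params, config, gate=hier.gate)
    protos = build_prototypes(target, support, h, params, config)
    q_idx = np.asarray([n for n, _ in query])
    y_true = np.asarray([y for _, y in query])
    missing = set(y_true) - set(int(c) for c in protos.classes)
    if missing:
        raise ValueError(f"query classes absent from support: {sorted(missing)}")
    y_pred, _ = classify(h.data[q_idx], protos, config)
    return (
        float(f1_score(y_true, y_pred, average="micro")),
        float(f1_score(y_true, y_pred, average="macro")),
    )


def evaluate_node_classification(
    state: TrainState, target: BioGraph, config: RunConfig
) -> tuple[float, float]:
    """(Micro-F1, Macro-F1) of nearest-prototype classification on the target.

    Prototypes come from the target's ``eval_shots``-per-class support set;
    metrics are averaged over ``eval_splits`` independent support/query
    resamples (few-shot metrics on a single small split are dominated by
    split noise).  The meta-learned parameters stay frozen unless
    ``fine_tune_episodes`` is set.
    """
    micros, macros = [], []
    for split in range(config.eval_splits):
        support, query = node_eval_split(target, config, split)
        params = state.params
        if config.fine_tune_episodes > 0:
            params = _fine_tune(state, target, support, config)
        micro, macro = _eval_one_split(params, target, config, support, query)
        micros.append(micro)
        macros.append(macro)
    return float(np.mean(micros)), float(np.mean(macros))


def _scratch_config(config: RunConfig, n_classes: int) -> RunConfig:
    inner_shots = max(1, config.eval_shots // 2)
    inner_queries = max(1, config.eval_shots - inner_shots)
    return config.replace(
        ways=min(config.ways, n_classes),
        shots=inner_shots,
        queries=inner_queries,
    )


def train_scratch_baseline(
    target: BioGraph, config: RunConfig, split: int = 0
) -> TrainState:
    """No-transfer control: same architecture trained on the target support.

    Uses exactly the support set that evaluation split ``split`` will use,
    with episodes drawn inside it, so the comparison isolates the value of
    the auxiliary graphs.
    """
    support, _ = node_eval_split(target, config, split)
    n_classes = len({y for _, y in support})
    inner = _scratch_config(config, n_classes)
    bank = GraphBank([_support_only_graph(target, support)], ["auxiliary"])
    return train(bank, inner)


def transfer_comparison(
    bank: GraphBank, config: RunConfig
) -> tuple[float, float]:
    """Mean target Micro-F1 of the meta-trained model vs the scratch control.

    The meta model is trained once on the auxiliary graphs and kept frozen;
    a fresh scratch model is trained per evaluation split on that split's
    support alone.  Both are scored on the identical splits and averaged.
    """
    target = bank.target()
    meta = train(bank, config)
    meta_scores, scratch_scores = [], []
    for split in range(config.eval_splits):
        support, query = node_eval_split(target, config, split)
        meta_scores.append(
            _eval_one_split(meta.params, target, config, support, query)[0]
        )
        scratch = train_scratch_baseline(target, config, split)
        scratch_scores.append(
            _eval_one_split(scratch.params, target, config, support, query)[0]
        )
    return float(np.mean(meta_scores)), float(np.mean(scratch_scores))


# ---------------------------------------------------------------------------
# evaluation: link prediction
# ---------------------------------------------------------------------------


def _pair_embeddings(
    h: np.ndarray, pairs: np.ndarray, mode: str
) -> np.ndarray:
    u, v = pairs[:, 0], pairs[:, 1]
    if mode == "hadamard":
        return h[u] * h[v]
    if mode == "concat":  # order-averaged to stay symmetric
        return 0.5 * (
            np.concatenate([h[u], h[v]], axis=1)
            + np.concatenate([h[v], h[u]], axis=1)
        )
    raise ValueError(f"unknown pair_feature {mode!r}")


def _mean_prototypes(
    x: np.ndarray, y: np.ndarray, classes: np.ndarray
) -> PrototypeSet:
    vectors = np.stack([x[y == c].mean(axis=0) for c in classes])
    return PrototypeSet(classes=classes, vectors=Tensor(vectors))


def link_harness_accuracy(
    pair_embeddings: np.ndarray,
    labels: np.ndarray,
    shots: int,
    seed: int = 0,
    config: RunConfig | None = None,
) -> float:
    """Nearest-mean-prototype accuracy on pair embeddings.

    ``shots`` support examples per class (seeded draw) build the
    prototypes; accuracy is reported on every remaining pair.
    """
    config = config or RunConfig()
    x = np.asarray(pair_embeddings, dtype=np.float64)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    sup_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(y == c)
        if members.size <= shots:
            raise ValueError(f"class {c} has {members.size} pairs; need > {shots}")
        sup_idx += list(rng.choice(members, size=shots, replace=False))
    sup = np.asarray(sup_idx)
    rest = np.setdiff1d(np.arange(y.size), sup)
    protos = _mean_prototypes(x[sup], y[sup], classes)
    y_pred, _ = classify(x[rest], protos, config)
    return float(np.mean(y_pred == y[rest]))


def _sample_nonedges(
    rng: np.random.Generator, adjacency: np.ndarray, n: int,
    exclude: set[tuple[int, int]],
) -> np.ndarray:
    m = adjacency.shape[0]
    out: list[tuple[int, int]] = []
    taken = set(exclude)
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 1000:
            raise RuntimeError("could not sample enough non-edges")
        cand = rng.integers(0, m, size=(4 * n, 2))
        for i, j in cand:
            if i == j:
                continue
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            if adjacency[a, b] != 0 or (a, b) in taken:
                continue
            taken.add((a, b))
            out.append((a, b))
            if len(out) == n:
                break
    return np.asarray(out)


NON_EDGE, EDGE = 1, 2  # class alphabet for the pair classifier


def evaluate_link_prediction(
    state: TrainState,
    target: BioGraph,
    config: RunConfig,
    grid: list[dict] | None = None,
) -> float:
    """Held-out link-prediction accuracy on the target graph.

    Edges are split 80/20 (exact to one pair); an equal number of uniformly
    sampled non-edges matches each side.  Candidate pairs are embedded as
    the coordinate-wise product of their endpoints' gated embeddings and
    classified by the prototype machinery with an ``eval_shots``-per-class
    support drawn from the training split.  An optional hyperparameter
    ``grid`` is selected by 5-fold cross-validation on the training pairs.
    """
    rng = np.random.default_rng([config.seed, 2])
    iu, ju = np.triu_indices(target.m, k=1)
    mask = target.adjacency[iu, ju] != 0
    edges = np.stack([iu[mask], ju[mask]], axis=1)
    n_edges = edges.shape[0]
    n_test = int(round(0.2 * n_edges))
    if n_edges - n_test < config.eval_shots:
        raise ValueError(
            f"only {n_edges - n_test} training edges; need >= {config.eval_shots}"
        )
    perm = rng.permutation(n_edges)
    test_edges = edges[perm[:n_test]]
    train_edges = edges[perm[n_test:]]
    edge_set = {(int(a), int(b)) for a, b in edges}
    negatives = _sample_nonedges(rng, target.adjacency, n_edges, edge_set)
    test_negs = negatives[:n_test]
    train_negs = negatives[n_test:]

    h = embed_graph(target, state.params, config)

    def pool(edge_pairs, neg_pairs, cfg):
        pairs = np.concatenate([edge_pairs, neg_pairs], axis=0)
        y = np.concatenate([
            np.full(len(edge_pairs), EDGE), np.full(len(neg_pairs), NON_EDGE)
        ])
        return _pair_embeddings(h, pairs, cfg.pair_feature), y

    chosen_cfg = config
    if grid:
        x_tr, y_tr = pool(train_edges, train_negs, config)
        best_acc = -1.0
        for cand in grid:
            cfg_c = config.replace(**cand)
            x_c, _ = pool(train_edges, train_negs, cfg_c)
            kf = KFold(n_splits=5, shuffle=True, random_state=config.seed % (2**31))
            accs = []
            for tr, va in kf.split(x_c):
                protos = _mean_prototypes(
                    x_c[tr], y_tr[tr], np.asarray([NON_EDGE, EDGE])
                )
                pred, _ = classify(x_c[va], protos, cfg_c)
                accs.append(np.mean(pred == y_tr[va]))
            if np.mean(accs) > best_acc:
                best_acc = float(np.mean(accs))
                chosen_cfg = cfg_c

    x_train, y_train = pool(train_edges, train_negs, chosen_cfg)
    sup_idx = []
    for cls in (NON_EDGE, EDGE):
        members = np.flatnonzero(y_train == cls)
        sup_idx += list(rng.choice(members, size=config.eval_shots, replace=False))
    sup = np.asarray(sup_idx)
    protos = _mean_prototypes(x_train[sup], y_train[sup],
                              np.asarray([NON_EDGE, EDGE]))
    x_test, y_test = pool(test_edges, test_negs, chosen_cfg)
    y_pred, _ = classify(x_test, protos, chosen_cfg)
    return float(np.mean(y_pred == y_test))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Versioned npz checkpoint: parameters + config + training trace."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": state.config.to_dict(),
        "epoch": state.epoch,
        "history": state.history,
        "rng_state": state.rng_state,
        "feature_dim": state.feature_dim,
        "m_ref": state.m_ref,
    }
    arrays = {f"param::{k}": v for k, v in state.params.state_dict().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> TrainState:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        params = ModelParams({
            k.removeprefix("param::"): Tensor(data[k], requires_grad=True)
            for k in data.files if k.startswith("param::")
        })
    return TrainState(
        params=params,
        config=RunConfig.from_dict(meta["config"]),
        epoch=meta["epoch"],
        history=meta["history"],
        rng_state=meta["rng_state"],
        feature_dim=meta["feature_dim"],
        m_ref=meta["m_ref"],
    )
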