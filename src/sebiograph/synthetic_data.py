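"""Seeded generator of graph banks with the structure the model assumes.

Each bank is a set of undirected graphs whose topology follows a stochastic
block model planted on the node classes (edge probability ``p_in`` within a
class, ``p_out`` between classes) and whose node features are class-
conditional Gaussians with unit noise.  The class mean vectors are drawn
once per bank and shared by every graph — this shared class-conditional
structure is exactly what makes knowledge learned on auxiliary graphs
transferable to the target graph.

Class means are ``s`` times orthonormal random directions, so ``s`` is the
between-class separation in units of the per-coordinate feature noise σ=1.
Only a fraction of each graph's nodes carries an observed label; the labeled
subset is drawn stratified per class so that few-shot support sets of the
documented sizes always exist.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_io import UNLABELED, BioGraph, GraphBank, write_bank

__all__ = ["SimPreset", "preset", "generate_bank"]

_MAX_RESAMPLE = 20


@dataclass(frozen=True)
class SimPreset:
    """Parameters of one synthetic bank."""

    n_auxiliary: int = 5
    nodes: int = 200          # m, nodes per graph
    classes: int = 4          # K
    feature_dim: int = 16     # h
    p_in: float = 0.15        # within-class edge probability
    p_out: float = 0.01       # between-class edge probability
    separation: float = 5.0   # class-mean separation s, in feature-σ units
    label_fraction: float = 0.3
    balanced_classes: bool = True  # balanced planted partition vs iid draw
    seed: int = 0

    def validate(self) -> None:
        if not (1 >= self.p_in >= self.p_out >= 0):
            raise ValueError("require 1 >= p_in >= p_out >= 0")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not (0 < self.label_fraction <= 1):
            raise ValueError("label_fraction must be in (0, 1]")
        if self.classes < 1 or self.nodes < self.classes:
            raise ValueError("need at least one node per class")


_PRESETS = {
    # Well-separated features and strong communities: every stage of the
    # pipeline should recover labels near-perfectly.
    "easy": SimPreset(p_in=0.15, p_out=0.01, separation=5.0),
    # Overlapping feature clouds and weak communities: transfer from the
    # auxiliary graphs has to carry real weight.
    "hard": SimPreset(p_in=0.08, p_out=0.03, separation=1.5),
}


def preset(name: str, seed: int | None = None) -> SimPreset:
    """A named study condition; ``seed`` overrides the preset's default."""
    try:
        p = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    if seed is not None:
        p = dataclasses.replace(p, seed=seed)
    return p


def _class_means(rng: np.random.Generator, k: int, h: int, s: float) -> np.ndarray:
    """K mean vectors at pairwise distance s·√2 (orthonormal directions)."""
    if k <= h:
        q, _ = np.linalg.qr(rng.standard_normal((h, k)))
        dirs = q.T
    else:  # more classes than dimensions: fall back to random unit vectors
        dirs = rng.standard_normal((k, h))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return s * dirs


def _draw_labels(
    rng: np.random.Generator, m: int, k: int, balanced: bool
) -> np.ndarray:
    """Class assignment: balanced planted partition, or uniform iid draw.

    The balanced mode shuffles near-equal class blocks (sizes differ by at
    most one), which keeps every class large enough for the documented
    support-set sizes at the default label fraction.  The iid mode resamples
    if a class comes up empty.
    """
    if balanced:
        y = np.arange(m) % k + 1
        rng.shuffle(y)
        return y
    for _ in range(_MAX_RESAMPLE):
        y = rng.integers(1, k + 1, size=m)
        if np.unique(y).size == k:
            return y
    raise RuntimeError(
        f"failed to draw {m} labels covering all {k} classes "
        f"after {_MAX_RESAMPLE} attempts"
    )


def _sbm_adjacency(
    rng: np.random.Generator, y: np.ndarray, p_in: float, p_out: float
) -> np.ndarray:
    m = y.size
    same = y[:, None] == y[None, :]
    prob = np.where(same, p_in, p_out)
    iu, ju = np.triu_indices(m, k=1)
    draws = rng.random(iu.size) < prob[iu, ju]
    adj = np.zeros((m, m))
    adj[iu[draws], ju[draws]] = 1.0
    return adj + adj.T


def _observe_labels(
    rng: np.random.Generator, y: np.ndarray, fraction: float
) -> np.ndarray:
    """Stratified per-class label exposure at the given fraction."""
    observed = np.full(y.size, UNLABELED, dtype=np.int64)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        n_obs = max(1, round(fraction * members.size))
        chosen = rng.choice(members, size=n_obs, replace=False)
        observed[chosen] = cls
    return observed


def _one_graph(
    rng: np.random.Generator,
    p: SimPreset,
    means: np.ndarray,
    name: str,
) -> BioGraph:
    y = _draw_labels(rng, p.nodes, p.classes, p.balanced_classes)
    adj = _sbm_adjacency(rng, y, p.p_in, p.p_out)
    feats = means[y - 1] + rng.standard_normal((p.nodes, p.feature_dim))
    labels = _observe_labels(rng, y, p.label_fraction)
    ids = [f"{name}_n{i:04d}" for i in range(p.nodes)]
    return BioGraph(node_ids=ids, adjacency=adj, features=feats, labels=labels)


def generate_bank(
    p: SimPreset, out_dir: str | Path | None = None
) -> GraphBank:
    """Generate a bank of auxiliary graphs plus one target graph.

    Fully determined by ``p.seed``; when ``out_dir`` is given the graph_io
    file formats plus a ``preset.json`` manifest are written there.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    means = _class_means(rng, p.classes, p.feature_dim, p.separation)
    graphs, roles = [], []
    for i in range(p.n_auxiliary):
        graphs.append(_one_graph(rng, p, means, f"aux{i}"))
        roles.append("auxiliary")
    graphs.append(_one_graph(rng, p, means, "target"))
    roles.append("target")
    bank = GraphBank(graphs=graphs, roles=roles)
    if out_dir is not None:
        out = Path(out_dir)
        write_bank(bank, out)
        (out / "preset.json").write_text(
            json.dumps(dataclasses.asdict(p), indent=2) + "\n"
        )
    return bank
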