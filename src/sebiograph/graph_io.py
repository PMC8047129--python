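"""Readers, writers and validation for graphs, feature tables and label tables.

On-disk formats (all plain TSV, ``#`` comment lines ignored in edge lists):

* edge list   — ``<u>\\t<v>`` or ``<u>\\t<v>\\t<w>`` (weighted)
* feature table — ``<id>\\t<f1>\\t...\\t<fh>``, one row per node; row order
  defines the internal 0-based node order
* label table — ``<id>\\t<class>`` with classes as positive integers; nodes
  absent from the table are unlabeled

Graphs are undirected: input edges are symmetrized, duplicates collapsed,
self-loops never stored (the encoder adds its own).  Nodes that appear only
in the feature table are kept as isolated nodes so their labels remain
predictable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .nn import normalize_adjacency

UNLABELED = -1

__all__ = [
    "UNLABELED",
    "GraphFormatError",
    "BioGraph",
    "GraphBank",
    "read_graph",
    "read_graph_dir",
    "write_graph",
    "read_embeddings",
    "write_embeddings",
    "read_bank",
    "write_bank",
]


class GraphFormatError(ValueError):
    """Raised when an on-disk artifact violates the documented format."""


@dataclass(eq=False)
class BioGraph:
    """One graph: symmetric adjacency, aligned node features, optional labels.

    ``labels[i] == UNLABELED`` marks an unlabeled node; labeled entries are
    positive integers from a bank-wide class alphabet.
    """

    node_ids: list[str]
    adjacency: np.ndarray
    features: np.ndarray
    labels: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        m = len(self.node_ids)
        if self.adjacency.shape != (m, m):
            raise GraphFormatError(
                f"adjacency shape {self.adjacency.shape} != ({m}, {m})"
            )
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise GraphFormatError("adjacency is not symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise GraphFormatError("adjacency has stored self-loops")
        if np.any(self.adjacency < 0):
            raise GraphFormatError("adjacency has negative weights")
        if self.features.ndim != 2 or self.features.shape[0] != m:
            raise GraphFormatError(
                f"feature rows {self.features.shape} do not match {m} nodes"
            )
        if not np.all(np.isfinite(self.features)):
            raise GraphFormatError("non-finite feature values")
        if self.labels is not None:
            if self.labels.shape != (m,):
                raise GraphFormatError("label vector length mismatch")
            lab = self.labels[self.labels != UNLABELED]
            if lab.size and lab.min() < 1:
                raise GraphFormatError("labels must be positive integers")
        if len(set(self.node_ids)) != m:
            raise GraphFormatError("duplicate node ids")

    # -- views ---------------------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.node_ids)

    @property
    def h(self) -> int:
        return self.features.shape[1]

    @property
    def index_of(self) -> dict[str, int]:
        if "index_of" not in self._cache:
            self._cache["index_of"] = {nid: i for i, nid in enumerate(self.node_ids)}
        return self._cache["index_of"]

    def labeled_indices(self) -> np.ndarray:
        if self.labels is None:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero(self.labels != UNLABELED)

    def classes(self) -> np.ndarray:
        """Sorted distinct classes present among labeled nodes."""
        if self.labels is None:
            return np.empty(0, dtype=np.int64)
        lab = self.labels[self.labels != UNLABELED]
        return np.unique(lab)

    def normalized_adjacency(self) -> np.ndarray:
        if "a_hat" not in self._cache:
            self._cache["a_hat"] = normalize_adjacency(self.adjacency)
        return self._cache["a_hat"]

    def csr(self) -> sp.csr_matrix:
        if "csr" not in self._cache:
            self._cache["csr"] = sp.csr_matrix(self.adjacency)
        return self._cache["csr"]

    def permuted(self, perm: np.ndarray) -> "BioGraph":
        """Graph with node order ``perm`` applied (for equivariance checks)."""
        perm = np.asarray(perm)
        return BioGraph(
            node_ids=[self.node_ids[i] for i in perm],
            adjacency=self.adjacency[np.ix_(perm, perm)],
            features=self.features[perm],
            labels=None if self.labels is None else self.labels[perm],
        )


@dataclass(eq=False)
class GraphBank:
    """An ordered collection of graphs tagged auxiliary or target."""

    graphs: list[BioGraph]
    roles: list[str]

    def __post_init__(self):
        if len(self.graphs) != len(self.roles):
            raise GraphFormatError("one role per graph required")
        bad = [r for r in self.roles if r not in ("auxiliary", "target")]
        if bad:
            raise GraphFormatError(f"unknown roles: {bad}")
        widths = {g.h for g in self.graphs}
        if len(widths) > 1:
            raise GraphFormatError(f"inconsistent feature widths: {sorted(widths)}")

    @property
    def h(self) -> int:
        return self.graphs[0].h

    def auxiliary(self) -> list[BioGraph]:
        return [g for g, r in zip(self.graphs, self.roles) if r == "auxiliary"]

    def target(self) -> BioGraph:
        targets = [g for g, r in zip(self.graphs, self.roles) if r == "target"]
        if not targets:
            raise GraphFormatError("bank has no target graph")
        return targets[0]

    def classes(self) -> np.ndarray:
        all_lab = [g.classes() for g in self.graphs if g.labels is not None]
        if not all_lab:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(all_lab))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_features(path: Path) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[list[float]] = []
    width = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        nid, cells = parts[0], parts[1:]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise GraphFormatError(
                f"{path}:{ln}: expected {width} feature columns, got {len(cells)}"
            )
        row = []
        for col, cell in enumerate(cells, start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise GraphFormatError(
                    f"{path}:{ln}: non-numeric feature cell {cell!r} "
                    f"(row {ln}, column {col})"
                ) from None
        ids.append(nid)
        rows.append(row)
    if not ids:
        return [], np.empty((0, 0))
    return ids, np.asarray(rows, dtype=np.float64)


def _parse_edges(path: Path) -> list[tuple[str, str, float]]:
    edges = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise GraphFormatError(
                f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}"
            )
        w = 1.0
        if len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError:
                raise GraphFormatError(
                    f"{path}:{ln}: non-numeric edge weight {parts[2]!r}"
                ) from None
        edges.append((parts[0], parts[1], w))
    return edges


def read_graph(
    edge_list_path: str | Path,
    features_path: str | Path,
    labels_path: str | Path | None = None,
) -> BioGraph:
    """Read one graph from its edge-list, feature and (optional) label files.

    The feature table defines the node universe and internal order; every
    edge endpoint and labeled id must appear in it.
    """
    node_ids, features = _parse_features(Path(features_path))
    index = {nid: i for i, nid in enumerate(node_ids)}
    m = len(node_ids)

    adjacency = np.zeros((m, m))
    seen: dict[tuple[int, int], float] = {}
    for u, v, w in _parse_edges(Path(edge_list_path)):
        for endpoint in (u, v):
            if endpoint not in index:
                raise GraphFormatError(
                    f"edge endpoint {endpoint!r} has no feature row"
                )
        i, j = index[u], index[v]
        if i == j:
            continue  # self-loops are never stored
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != w:
            raise GraphFormatError(
                f"conflicting weights for undirected edge "
                f"({u!r}, {v!r}): {seen[key]} vs {w}"
            )
        seen[key] = w
    for (i, j), w in seen.items():
        adjacency[i, j] = adjacency[j, i] = w

    labels = None
    if labels_path is not None:
        labels = np.full(m, UNLABELED, dtype=np.int64)
        for ln, line in enumerate(Path(labels_path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{labels_path}:{ln}: expected '<id>\\t<class>'"
                )
            nid, cls = parts
            if nid not in index:
                raise GraphFormatError(f"labeled node {nid!r} has no feature row")
            try:
                c = int(cls)
            except ValueError:
                raise GraphFormatError(
                    f"{labels_path}:{ln}: non-integer class {cls!r}"
                ) from None
            if c < 1:
                raise GraphFormatError(
                    f"{labels_path}:{ln}: classes must be positive, got {c}"
                )
            labels[index[nid]] = c

    return BioGraph(node_ids=node_ids, adjacency=adjacency,
                    features=features, labels=labels)


EDGES_NAME = "edges.tsv"
FEATURES_NAME = "features.tsv"
LABELS_NAME = "labels.tsv"


def read_graph_dir(directory: str | Path) -> BioGraph:
    d = Path(directory)
    labels = d / LABELS_NAME
    return read_graph(
        d / EDGES_NAME, d / FEATURES_NAME, labels if labels.exists() else None
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_graph(graph: BioGraph, directory: str | Path) -> None:
    """Write edge-list/feature/label files; round-trips through read_graph_dir."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    iu, ju = np.triu_indices(graph.m, k=1)
    mask = graph.adjacency[iu, ju] != 0
    lines = []
    weighted = not np.all(np.isin(graph.adjacency[iu, ju][mask], [1.0]))
    for i, j in zip(iu[mask], ju[mask]):
        u, v = graph.node_ids[i], graph.node_ids[j]
        if weighted:
            lines.append(f"{u}\t{v}\t{_fmt(graph.adjacency[i, j])}")
        else:
            lines.append(f"{u}\t{v}")
    (d / EDGES_NAME).write_text("\n".join(lines) + ("\n" if lines else ""))

    feat_lines = [
        "\t".join([nid] + [_fmt(x) for x in row])
        for nid, row in zip(graph.node_ids, graph.features)
    ]
    (d / FEATURES_NAME).write_text(
        "\n".join(feat_lines) + ("\n" if feat_lines else "")
    )

    if graph.labels is not None:
        lab_lines = [
            f"{graph.node_ids[i]}\t{graph.labels[i]}"
            for i in range(graph.m)
            if graph.labels[i] != UNLABELED
        ]
        (d / LABELS_NAME).write_text(
            "\n".join(lab_lines) + ("\n" if lab_lines else "")
        )


def write_embeddings(graph: BioGraph, embeddings: np.ndarray, path: str | Path) -> None:
    """TSV of external node id + embedding columns; full-precision round trip."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.ndim != 2 or embeddings.shape[0] != graph.m:
        raise GraphFormatError(
            f"embedding rows {embeddings.shape} do not match {graph.m} nodes"
        )
    lines = [
        "\t".join([nid] + [_fmt(x) for x in row])
        for nid, row in zip(graph.node_ids, embeddings)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    ids, matrix = _parse_features(Path(path))
    return ids, matrix


# ---------------------------------------------------------------------------
# banks
# ---------------------------------------------------------------------------

BANK_MANIFEST = "bank.json"


def write_bank(bank: GraphBank, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    dirs = []
    counters = {"auxiliary": 0, "target": 0}
    for graph, role in zip(bank.graphs, bank.roles):
        name = f"{'aux' if role == 'auxiliary' else 'target'}_{counters[role]:03d}"
        counters[role] += 1
        write_graph(graph, d / name)
        dirs.append(name)
    manifest = {"version": 1, "dirs": dirs, "roles": list(bank.roles)}
    (d / BANK_MANIFEST).write_text(json.dumps(manifest, indent=2) + "\n")


def read_bank(directory: str | Path) -> GraphBank:
    d = Path(directory)
    manifest_path = d / BANK_MANIFEST
    if not manifest_path.exists():
        raise GraphFormatError(f"no {BANK_MANIFEST} in {d}")
    manifest = json.loads(manifest_path.read_text())
    graphs = [read_graph_dir(d / sub) for sub in manifest["dirs"]]
    return GraphBank(graphs=graphs, roles=list(manifest["roles"]))
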