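"""Social-network construction: synthetic topologies, edge-list IO, social-transitivity
weights, and node influence.

Simulations run on weighted, directed interaction graphs derived from simple
undirected graphs.  Each undirected edge {i, j} becomes the two directed edges
i->j and j->i, weighted by *social transitivity*::

    w_ij = (1 + |N(i) ∩ N(j)|) / |N(i)|

where N(.) is the undirected neighbor set and i is the predecessor (speaker)
node.  The weight is the probability that a speaker-listener pair actually
interacts in a given step.  Node *influence*, used to rank nodes for content
moderation, is the mean of normalized degree centrality and normalized
betweenness centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

_FAMILIES = (
    "complete",
    "watts_strogatz",
    "erdos_renyi",
    "barabasi_albert",
    "grid_2d",
    "barbell",
    "edge_list",
)


class ConfigurationError(ValueError):
    """Invalid graph or run configuration."""


class EdgeListParseError(ValueError):
    """Malformed edge-list input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class GraphSpec:
    """Parameters for one graph topology.

    ``family`` selects the generator; the remaining fields are interpreted per
    family (``n`` nodes; ``k``/``p`` for Watts-Strogatz; ``p`` for
    Erdős-Rényi; ``m`` for Barabási-Albert attachment; ``m``x``n`` grid;
    ``m1``/``m2`` barbell bells and bridge; ``path`` for edge lists).
    ``seed`` drives generator randomness and makes construction deterministic.
    """

    family: str
    n: int | None = None
    k: int | None = None
    p: float | None = None
    m: int | None = None
    m1: int | None = None
    m2: int | None = None
    path: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown graph family {self.family!r}; expected one of {_FAMILIES}"
            )
        for name in ("n", "k", "m", "m1"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, (int, np.integer)) or v <= 0):
                raise ConfigurationError(f"field {name!r} must be a positive integer, got {v!r}")
        if self.m2 is not None and (not isinstance(self.m2, (int, np.integer)) or self.m2 < 0):
            raise ConfigurationError(f"field 'm2' must be a non-negative integer, got {self.m2!r}")
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ConfigurationError(f"field 'p' must lie in [0, 1], got {self.p!r}")
        required = {
            "complete": ("n",),
            "watts_strogatz": ("n", "k", "p"),
            "erdos_renyi": ("n", "p"),
            "barabasi_albert": ("n", "m"),
            "grid_2d": ("m", "n"),
            "barbell": ("m1", "m2"),
            "edge_list": ("path",),
        }[self.family]
        for name in required:
            if getattr(self, name) is None:
                raise ConfigurationError(
                    f"graph family {self.family!r} requires field {name!r}"
                )


def _require(spec: GraphSpec, *names: str) -> None:
    for name in names:
        if getattr(spec, name) is None:
            raise ConfigurationError(
                f"graph family {spec.family!r} requires field {name!r}"
            )


def build_graph(spec: GraphSpec) -> nx.Graph:
    """Construct the simple undirected graph described by ``spec``.

    Deterministic given ``spec.seed``.  Node ids are relabeled to dense
    integers 0..n-1 (sorted original order); the original labels are kept in
    the ``"label"`` node attribute when they differ.
    """
    fam = spec.family
    if fam == "complete":
        _require(spec, "n")
        g = nx.complete_graph(spec.n)
    elif fam == "watts_strogatz":
        _require(spec, "n", "k", "p")
        if spec.k >= spec.n:
            raise ConfigurationError(f"watts_strogatz needs k < n (k={spec.k}, n={spec.n})")
        g = nx.watts_strogatz_graph(spec.n, spec.k, spec.p, seed=spec.seed)
    elif fam == "erdos_renyi":
        _require(spec, "n", "p")
        g = nx.erdos_renyi_graph(spec.n, spec.p, seed=spec.seed)
    elif fam == "barabasi_albert":
        _require(spec, "n", "m")
        if spec.m >= spec.n:
            raise ConfigurationError(f"barabasi_albert needs m < n (m={spec.m}, n={spec.n})")
        g = nx.barabasi_albert_graph(spec.n, spec.m, seed=spec.seed)
    elif fam == "grid_2d":
        _require(spec, "m", "n")
        g = nx.grid_2d_graph(spec.m, spec.n)
    elif fam == "barbell":
        _require(spec, "m1", "m2")
        if spec.m1 < 3:
            raise ConfigurationError(f"barbell needs m1 >= 3, got m1={spec.m1}")
        g = nx.barbell_graph(spec.m1, spec.m2)
    elif fam == "edge_list":
        _require(spec, "path")
        return load_edge_list(spec.path)
    else:  # pragma: no cover - guarded by GraphSpec validation
        raise ConfigurationError(f"unknown graph family {fam!r}")
    return _to_dense_int_labels(g)


def _to_dense_int_labels(g: nx.Graph) -> nx.Graph:
    nodes = sorted(g.nodes())
    if list(g.nodes()) == list(range(g.number_of_nodes())):
        return g
    mapping = {lab: i for i, lab in enumerate(nodes)}
    h = nx.relabel_nodes(g, mapping, copy=True)
    nx.set_node_attributes(h, {i: lab for lab, i in mapping.items()}, "label")
    return h


def load_edge_list(source) -> nx.Graph:
    """Read a two-column undirected edge list (whitespace- or comma-separated).

    Lines starting with ``#`` are comments.  Duplicate and reversed-duplicate
    lines collapse to a single edge; self-loops are dropped with a warning.
    ``source`` may be a path or an open text handle.  Labels are mapped to
    dense integer ids (kept in the ``"label"`` attribute).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    g = nx.Graph()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.replace(",", " ").split()
        if len(tokens) != 2:
            raise EdgeListParseError(
                f"expected two node tokens, got {len(tokens)} in {raw!r}", lineno
            )
        u, v = tokens
        if u == v:
            logger.warning("dropping self-loop %r at line %d", raw.strip(), lineno)
            g.add_node(u)
            continue
        g.add_edge(u, v)
    return _to_dense_int_labels(g)


@dataclass
class SocialGraph:
    """Weighted, directed interaction graph in CSR form.

    ``indptr``/``indices``/``weights`` hold, for each node, its out-edges
    sorted by neighbor id; adjacency is symmetric (i->j exists iff j->i) but
    weights are directional.  ``undirected`` keeps the source topology for
    centrality and layout computations.
    """

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    weights: np.ndarray
    undirected: nx.Graph | None = None
    labels: dict | None = field(default=None, repr=False)

    def out_edges(self, i: int) -> list[tuple[int, float]]:
        lo, hi = self.indptr[i], self.indptr[i + 1]
        return [(int(j), float(w)) for j, w in zip(self.indices[lo:hi], self.weights[lo:hi])]

    def degree(self, i: int) -> int:
        return int(self.indptr[i + 1] - self.indptr[i])

    def weight(self, i: int, j: int) -> float:
        """Weight of the directed edge i->j (binary search over sorted row)."""
        lo, hi = self.indptr[i], self.indptr[i + 1]
        pos = lo + np.searchsorted(self.indices[lo:hi], j)
        if pos >= hi or self.indices[pos] != j:
            raise KeyError(f"no edge {i}->{j}")
        return float(self.weights[pos])

    @property
    def number_of_directed_edges(self) -> int:
        return int(self.indices.shape[0])


def assign_weights(g: nx.Graph) -> SocialGraph:
    """Convert a simple undirected graph into a weighted directed SocialGraph.

    Each edge {i, j} yields w(i->j) = (1 + shared(i, j)) / deg(i) and the
    mirror w(j->i) with deg(j) in the denominator.  The shared-neighbor counts
    are obtained exactly from the square of the sparse adjacency matrix.
    Isolated nodes simply have no out-edges.  Weights always lie in (0, 1]
    because shared(i, j) <= deg(i) - 1.
    """
    n = g.number_of_nodes()
    adj = nx.to_scipy_sparse_array(g, nodelist=range(n), format="csr", dtype=np.float64)
    if adj.nnz == 0:
        return SocialGraph(
            n=n,
            indptr=np.zeros(n + 1, dtype=np.int64),
            indices=np.empty(0, dtype=np.int64),
            weights=np.empty(0, dtype=np.float64),
            undirected=g,
            labels=nx.get_node_attributes(g, "label") or None,
        )
    shared = (adj @ adj).tocsr()  # (i, j) -> number of length-2 paths = shared neighbors
    # restrict to edge positions; +1 for the edge itself
    numer = (adj + adj.multiply(shared)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    w = numer.copy()
    w.data = w.data / np.repeat(deg, np.diff(numer.indptr))
    w.sort_indices()
    return SocialGraph(
        n=n,
        indptr=w.indptr.astype(np.int64),
        indices=w.indices.astype(np.int64),
        weights=w.data.astype(np.float64),
        undirected=g,
        labels=nx.get_node_attributes(g, "label") or None,
    )


@dataclass(frozen=True)
class InfluenceScore:
    node: int
    degree_centrality: float
    betweenness_centrality: float
    influence: float


def influence_scores(g: nx.Graph) -> list[InfluenceScore]:
    """Node influence I(v) = (C_D(v) + C_B(v)) / 2 on the undirected topology.

    C_D is degree centrality deg(v)/(n-1); C_B is shortest-path betweenness
    with the standard (n-1)(n-2)/2 pair normalization, endpoints excluded.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ConfigurationError("influence scores need a graph with at least 2 nodes")
    cd = nx.degree_centrality(g)
    cb = nx.betweenness_centrality(g, normalized=True)
    return [
        InfluenceScore(v, cd[v], cb[v], 0.5 * (cd[v] + cb[v]))
        for v in sorted(g.nodes())
    ]


def export_edge_list(sg: SocialGraph, path) -> None:
    """Write the directed weighted edge list as ``src dst w`` (10 sig digits)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for i in range(sg.n):
            for j, w in sg.out_edges(i):
                fh.write(f"{i} {j} {w:.10g}\n")


def remove_nodes(sg: SocialGraph, nodes: Iterable[int]) -> tuple[SocialGraph, np.ndarray]:
    """Drop ``nodes`` and their incident edges, keeping surviving weights frozen.

    Returns the reduced graph (ids re-densified to 0..n'-1) and the array
    mapping new ids to old ids.  Weights of surviving edges are NOT
    recomputed: node removal models banning users after the interaction
    strengths were established.
    """
    drop = np.zeros(sg.n, dtype=bool)
    drop[list(nodes)] = True
    keep_old = np.flatnonzero(~drop)
    new_id = -np.ones(sg.n, dtype=np.int64)
    new_id[keep_old] = np.arange(keep_old.size)

    indptr = [0]
    indices: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for i in keep_old:
        lo, hi = sg.indptr[i], sg.indptr[i + 1]
        row_idx = sg.indices[lo:hi]
        row_w = sg.weights[lo:hi]
        mask = ~drop[row_idx]
        indices.append(new_id[row_idx[mask]])
        weights.append(row_w[mask])
        indptr.append(indptr[-1] + int(mask.sum()))
    und = None
    if sg.undirected is not None:
        und = nx.relabel_nodes(
            sg.undirected.subgraph(keep_old.tolist()),
            {int(o): int(n_) for o, n_ in zip(keep_old, new_id[keep_old])},
            copy=True,
        )
    reduced = SocialGraph(
        n=keep_old.size,
        indptr=np.asarray(indptr, dtype=np.int64),
        indices=(np.concatenate(indices) if indices else np.empty(0, dtype=np.int64)),
        weights=(np.concatenate(weights) if weights else np.empty(0, dtype=np.float64)),
        undirected=und,
    )
    return reduced, keep_old
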