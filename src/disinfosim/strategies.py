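"""Mitigation strategies applied to a (graph, population) pair at setup time.

Six strategies around three policies:

* content moderation — remove a fraction of the total node count from the
  committed disinformation minority before the run, either the most
  influential members (mean of degree and betweenness centrality) or a
  uniform random sample;
* education / skepticism — committed agents get a partial commitment level c
  drawn from a triangular density rising on [c_min, 1], and abandon their
  commitment with probability 1 - c when hearing the opposing opinion;
* education / attention — a truth bias beta (default 0.1) makes mixed-state
  agents preferentially voice the truth and B-holders resist switching;
* counter-campaign — a second minority committed to the truth, seeded on the
  opposite side of a force-directed layout from the disinformation minority.

Fractional node counts use round-half-up throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .networks import ConfigurationError, SocialGraph, influence_scores, remove_nodes


def round_half_up(x: float) -> int:
    """Round-half-up used for every fraction-of-population count."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ModerationConfig:
    """Fraction of the TOTAL node count to remove, and how to pick victims."""

    removal_fraction: float
    mode: str = "influence"  # "influence" | "random"

    def __post_init__(self):
        if not (0.0 <= self.removal_fraction < 1.0):
            raise ConfigurationError("removal_fraction must lie in [0, 1)")
        if self.mode not in ("influence", "random"):
            raise ConfigurationError(f"unknown moderation mode {self.mode!r}")


@dataclass(frozen=True)
class SkepticismConfig:
    c_min: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.c_min < 1.0):
            raise ConfigurationError("c_min must lie in (0, 1)")


@dataclass(frozen=True)
class AttentionConfig:
    beta: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.beta < 1.0):
            raise ConfigurationError("beta must lie in [0, 1)")


@dataclass(frozen=True)
class CounterCampaignConfig:
    """Size of the truth-committed minority and the layout seed for placement."""

    p_b: float = 0.05
    layout_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_b <= 1.0):
            raise ConfigurationError("p_b must lie in [0, 1]")


def select_committed(n_nodes: int, p_a: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform random committed-A set of size round(p_a * n); others stay
    uncommitted-B."""
    if not (0.0 <= p_a <= 1.0):
        raise ConfigurationError("p_a must lie in [0, 1]")
    k = round_half_up(p_a * n_nodes)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.choice(n_nodes, size=k, replace=False)).astype(np.int64)


def moderate(
    sg: SocialGraph,
    committed: np.ndarray,
    cfg: ModerationConfig,
    rng: np.random.Generator,
) -> tuple[SocialGraph, np.ndarray, np.ndarray]:
    """Remove committed nodes before the run; weights of survivors are frozen.

    Returns (reduced graph, committed set in NEW ids, new->old id map).
    Influence mode removes the top-influence committed nodes (ties broken by
    ascending node id); random mode removes a uniform sample.  The removal
    count is round(removal_fraction * total nodes) and must not exceed the
    committed count.
    """
    committed = np.asarray(sorted(committed), dtype=np.int64)
    k = round_half_up(cfg.removal_fraction * sg.n)
    if k > committed.size:
        raise ConfigurationError(
            f"removal count {k} exceeds committed minority size {committed.size}"
        )
    if k == 0:
        return sg, committed, np.arange(sg.n, dtype=np.int64)
    if cfg.mode == "influence":
        if sg.undirected is None:
            raise ConfigurationError("influence moderation needs the undirected topology")
        scores = {s.node: s.influence for s in influence_scores(sg.undirected)}
        # descending influence, ascending id on ties
        order = sorted(committed.tolist(), key=lambda v: (-scores[v], v))
        victims = np.asarray(order[:k], dtype=np.int64)
    else:
        victims = rng.choice(committed, size=k, replace=False)
    reduced, keep_old = remove_nodes(sg, victims)
    old_to_new = -np.ones(sg.n, dtype=np.int64)
    old_to_new[keep_old] = np.arange(keep_old.size)
    survivors = np.setdiff1d(committed, victims)
    return reduced, old_to_new[survivors], keep_old


def sample_commitment(c_min: float, rng: np.random.Generator, size=None):
    """Draw commitment levels from the triangular density
    p(c) = 2(c - c_min)/(1 - c_min)^2 on [c_min, 1].

    Inverse-CDF sampling: c = c_min + (1 - c_min) * sqrt(U).  As c_min -> 1
    the density concentrates at c = 1 (full commitment, the base model).
    """
    if not (0.0 < c_min < 1.0):
        raise ConfigurationError("c_min must lie in (0, 1)")
    u = rng.random(size)
    return c_min + (1.0 - c_min) * np.sqrt(u)


def layout_positions(g: nx.Graph, layout_seed: int) -> np.ndarray:
    """Fruchterman-Reingold positions in [-1, 1]^2, indexed by node id."""
    pos = nx.spring_layout(g, seed=layout_seed)
    return np.asarray([pos[i] for i in range(g.number_of_nodes())])


def init_counter_campaign(
    sg: SocialGraph,
    p_a: float,
    cfg: CounterCampaignConfig,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Place opposed committed minorities on opposite layout halves.

    Committed-A nodes are sampled uniformly from nodes with negative first
    layout coordinate, committed-B from nodes with positive first coordinate
    (x = 0 exactly qualifies for neither pool); the topology is untouched.
    Returns (committed_A, committed_B) node id arrays.
    """
    if p_a + cfg.p_b > 1.0:
        raise ConfigurationError(f"p_a + p_b = {p_a + cfg.p_b:.3f} exceeds 1")
    if positions is None:
        if sg.undirected is None:
            raise ConfigurationError("counter-campaign needs the undirected topology")
        positions = layout_positions(sg.undirected, cfg.layout_seed)
    x = positions[:, 0]
    left = np.flatnonzero(x < 0.0)
    right = np.flatnonzero(x > 0.0)
    k_a = round_half_up(p_a * sg.n)
    k_b = round_half_up(cfg.p_b * sg.n)
    if k_a > left.size or k_b > right.size:
        raise ConfigurationError(
            f"layout halves too small: left holds {left.size} nodes (need {k_a} "
            f"committed-A), right holds {right.size} (need {k_b} committed-B)"
        )
    committed_a = np.sort(rng.choice(left, size=k_a, replace=False)) if k_a else np.empty(0, dtype=np.int64)
    committed_b = np.sort(rng.choice(right, size=k_b, replace=False)) if k_b else np.empty(0, dtype=np.int64)
    return committed_a.astype(np.int64), committed_b.astype(np.int64)
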