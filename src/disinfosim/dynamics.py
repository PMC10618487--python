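"""Binary agreement (naming-game) dynamics with committed minorities.

Agents hold one of three opinions — A (disinformation), B (the truth) or the
mixed state AB — and update pairwise through speaker/listener interactions:

========================  =================
speaker --voiced--> listener   outcome (speaker-listener)
========================  =================
A  --A--> A                A - A
A  --A--> B                A - AB
A  --A--> AB               A - A
B  --B--> A                B - AB
B  --B--> B                B - B
B  --B--> AB               B - B
AB --A--> A                A - A
AB --A--> B                AB - AB
AB --A--> AB               A - A
AB --B--> A                AB - AB
AB --B--> B                B - B
AB --B--> AB               B - B
========================  =================

Mixed-state speakers voice one of their two opinions; a mixed speaker
collapses to the voiced opinion exactly when the post-interaction listener
holds that single opinion.  Committed agents never change opinion, except
under the skepticism strategy where a partially committed listener (c < 1)
hearing the opposing opinion abandons its commitment (becoming uncommitted
AB) with probability 1 - c.  Under the attention strategy with truth bias
beta, mixed speakers voice B with probability (1 + beta)/2 and an uncommitted
B-listener hearing A switches to AB only with probability 1 - beta.

One *step* sweeps every node in index order: the node draws a uniform random
neighbor, speaker/listener roles are assigned uniformly, and with probability
w(speaker -> listener) the pair interacts (updates are in place, visible to
later pairs within the sweep).  A run stops when a completed sweep changed no
agent and all agents hold the same single opinion, or at the step cap.

Two equivalent engines are provided: :func:`step`/:func:`run_python` in pure
Python over ``numpy.random.RandomState``, and the numba-compiled
:func:`run` hot path.  Both consume the Mersenne-Twister stream in the same
documented order (neighbor, role, interaction coin, voicing, gate), so
trajectories are bitwise identical for equal seeds; the test suite asserts
this.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .networks import SocialGraph


class Opinion(IntEnum):
    A = 0
    B = 1
    AB = 2


class NumericalError(RuntimeError):
    """Mean-field solver failed to converge."""


@dataclass(frozen=True)
class Agent:
    """One agent: an opinion, an optional commitment, and a commitment level.

    ``committed_to`` is None for uncommitted agents; ``c`` is the commitment
    level in (0, 1], meaningful only while committed (c = 1 means full
    commitment, the base model).
    """

    opinion: Opinion
    committed_to: Opinion | None = None
    c: float = 1.0

    def __post_init__(self):
        if self.committed_to is not None:
            if self.committed_to == Opinion.AB:
                raise ValueError("agents can only be committed to a single opinion")
            if self.opinion != self.committed_to:
                raise ValueError(
                    f"committed-{self.committed_to.name} agent must hold opinion "
                    f"{self.committed_to.name}, not {self.opinion.name}"
                )
        if not (0.0 < self.c <= 1.0):
            raise ValueError(f"commitment level must lie in (0, 1], got {self.c}")


@dataclass(frozen=True)
class ModelConfig:
    """Dynamics parameters.

    ``attention_beta`` is the truth bias: 0 disables the attention strategy
    (base voicing and switching); the attention strategy uses 0.1.
    ``skepticism_active`` only documents intent — the dynamics read each
    agent's commitment level directly.
    """

    max_steps: int = 5000
    attention_beta: float = 0.0
    skepticism_active: bool = False

    def __post_init__(self):
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not (0.0 <= self.attention_beta < 1.0):
            raise ValueError("attention_beta must lie in [0, 1)")


# integer codes shared by the array state and the kernel
_NONE, _COMMIT_A, _COMMIT_B = 0, 1, 2


@dataclass
class SimState:
    """Array-backed population state on a SocialGraph."""

    graph: SocialGraph
    opinion: np.ndarray  # int8, Opinion codes
    committed: np.ndarray  # int8, 0 none / 1 A / 2 B
    c: np.ndarray  # float64 commitment levels
    step_count: int = 0

    @classmethod
    def initial(
        cls,
        graph: SocialGraph,
        committed_a=(),
        committed_b=(),
        commitment_levels: dict | None = None,
    ) -> "SimState":
        """All agents uncommitted-B except the given committed sets.

        ``commitment_levels`` maps committed-A node -> c (skepticism); absent
        nodes get c = 1.
        """
        n = graph.n
        opinion = np.full(n, Opinion.B, dtype=np.int8)
        committed = np.zeros(n, dtype=np.int8)
        c = np.ones(n, dtype=np.float64)
        ca = np.asarray(sorted(committed_a), dtype=np.int64)
        cb = np.asarray(sorted(committed_b), dtype=np.int64)
        if np.intersect1d(ca, cb).size:
            raise ValueError("a node cannot be committed to both opinions")
        opinion[ca] = Opinion.A
        committed[ca] = _COMMIT_A
        committed[cb] = _COMMIT_B
        if commitment_levels:
            for node, level in commitment_levels.items():
                if committed[node] != _COMMIT_A:
                    raise ValueError("commitment levels apply to committed-A agents only")
                if not (0.0 < level <= 1.0):
                    raise ValueError(f"commitment level must lie in (0, 1], got {level}")
                c[node] = level
        return cls(graph=graph, opinion=opinion, committed=committed, c=c)

    def agent(self, i: int) -> Agent:
        com = {_NONE: None, _COMMIT_A: Opinion.A, _COMMIT_B: Opinion.B}[int(self.committed[i])]
        return Agent(Opinion(int(self.opinion[i])), com, float(self.c[i]))

    def copy(self) -> "SimState":
        return SimState(
            graph=self.graph,
            opinion=self.opinion.copy(),
            committed=self.committed.copy(),
            c=self.c.copy(),
            step_count=self.step_count,
        )


@dataclass(frozen=True)
class SimResult:
    n_A: float
    n_B: float
    n_AB: float
    steps: int
    terminated_by: str  # "consensus" | "step_cap"


def densities(state: SimState) -> tuple[float, float, float]:
    """Fractions of agents holding A, B and AB over the current node count."""
    n = state.opinion.shape[0]
    if n == 0:
        raise ValueError("densities undefined on an empty graph")
    n_a = float(np.count_nonzero(state.opinion == Opinion.A)) / n
    n_b = float(np.count_nonzero(state.opinion == Opinion.B)) / n
    return n_a, n_b, 1.0 - n_a - n_b


def choose_shared_opinion(speaker: Agent, config: ModelConfig, rng) -> Opinion:
    """The single opinion a speaker voices.

    Single-opinion speakers voice their opinion (no randomness).  Mixed-state
    speakers voice B with probability (1 + beta)/2, A otherwise; beta = 0
    recovers the symmetric base model.
    """
    if speaker.opinion != Opinion.AB:
        return speaker.opinion
    p_b = 0.5 * (1.0 + config.attention_beta)
    return Opinion.B if rng.random_sample() < p_b else Opinion.A


def interact(
    speaker: Agent, listener: Agent, voiced: Opinion, config: ModelConfig, rng
) -> tuple[Agent, Agent]:
    """Apply one speaker->listener interaction; returns the updated pair.

    The listener adopts or advances toward the voiced opinion (opposite
    single opinion -> AB; AB -> voiced), gated by commitment and by the
    attention bias; a mixed-state speaker collapses to the voiced opinion iff
    the post-interaction listener holds it.
    """
    if voiced == Opinion.AB:
        raise AssertionError("voiced opinion must be a single opinion")
    if speaker.opinion != Opinion.AB and speaker.opinion != voiced:
        raise AssertionError(
            f"{speaker.opinion.name} speaker cannot voice {voiced.name}"
        )
    beta = config.attention_beta

    new_listener = listener
    if listener.committed_to is not None:
        if listener.c < 1.0 and voiced != listener.committed_to:
            # skepticism: abandon commitment with probability 1 - c
            if rng.random_sample() < 1.0 - listener.c:
                new_listener = Agent(Opinion.AB, None, 1.0)
    elif listener.opinion == Opinion.AB:
        new_listener = Agent(voiced, None, 1.0)
    elif listener.opinion != voiced:
        if beta > 0.0 and listener.opinion == Opinion.B and voiced == Opinion.A:
            if rng.random_sample() < 1.0 - beta:
                new_listener = Agent(Opinion.AB, None, 1.0)
        else:
            new_listener = Agent(Opinion.AB, None, 1.0)

    new_speaker = speaker
    if speaker.opinion == Opinion.AB and new_listener.opinion == voiced:
        new_speaker = Agent(voiced, None, 1.0)
    return new_speaker, new_listener


def step(state: SimState, config: ModelConfig, rng) -> bool:
    """One full sweep in pure Python; mutates ``state``, returns ``changed``.

    ``rng`` must be a ``numpy.random.RandomState`` so the stream matches the
    compiled kernel.  Draw order per focal node: neighbor, role, interaction
    coin, voicing (mixed speakers only), gate (when applicable).
    """
    g = state.graph
    opinion, committed, c = state.opinion, state.committed, state.c
    beta = config.attention_beta
    p_voice_b = 0.5 * (1.0 + beta)
    changed = False
    for i in range(g.n):
        lo, hi = int(g.indptr[i]), int(g.indptr[i + 1])
        deg = hi - lo
        if deg == 0:
            continue
        k = int(rng.random_sample() * deg)
        pos = lo + k
        j = int(g.indices[pos])
        if rng.random_sample() < 0.5:
            s, l, w = i, j, float(g.weights[pos])
        else:
            s, l = j, i
            w = g.weight(j, i)
        if rng.random_sample() >= w:
            continue
        s_op = int(opinion[s])
        if s_op == Opinion.AB:
            voiced = Opinion.B if rng.random_sample() < p_voice_b else Opinion.A
        else:
            voiced = Opinion(s_op)
        l_op, l_com = int(opinion[l]), int(committed[l])
        if l_com != _NONE:
            opposing = (l_com == _COMMIT_A) != (voiced == Opinion.A)
            if c[l] < 1.0 and opposing:
                if rng.random_sample() < 1.0 - c[l]:
                    opinion[l] = Opinion.AB
                    committed[l] = _NONE
                    c[l] = 1.0
        elif l_op == Opinion.AB:
            opinion[l] = voiced
        elif l_op != voiced:
            if beta > 0.0 and l_op == Opinion.B and voiced == Opinion.A:
                if rng.random_sample() < 1.0 - beta:
                    opinion[l] = Opinion.AB
            else:
                opinion[l] = Opinion.AB
        if s_op == Opinion.AB and int(opinion[l]) == voiced:
            opinion[s] = voiced
        if int(opinion[l]) != l_op or int(committed[l]) != l_com:
            changed = True
        if int(opinion[s]) != s_op:
            changed = True
    state.step_count += 1
    return changed


@njit(cache=True)
def _simulate(indptr, indices, weights, opinion, committed, c, beta, max_steps, seed):
    """Compiled sweep loop; mutates the state arrays.

    Returns (steps, reason) with reason 1 = consensus, 0 = step cap.  The RNG
    is numpy's legacy Mersenne Twister, consumed in the same order as
    :func:`step`.
    """
    np.random.seed(seed)
    n = opinion.shape[0]
    p_voice_b = 0.5 * (1.0 + beta)
    steps = 0
    for _ in range(max_steps):
        changed = False
        for i in range(n):
            lo = indptr[i]
            hi = indptr[i + 1]
            deg = hi - lo
            if deg == 0:
                continue
            k = int(np.random.random() * deg)
            pos = lo + k
            j = indices[pos]
            if np.random.random() < 0.5:
                s = i
                l = j
                w = weights[pos]
            else:
                s = j
                l = i
                jlo = indptr[j]
                jhi = indptr[j + 1]
                p2 = jlo + np.searchsorted(indices[jlo:jhi], i)
                w = weights[p2]
            if np.random.random() >= w:
                continue
            s_op = opinion[s]
            if s_op == 2:  # AB speaker voices
                voiced = 1 if np.random.random() < p_voice_b else 0
            else:
                voiced = s_op
            l_op = opinion[l]
            l_com = committed[l]
            if l_com != 0:
                opposing = (l_com == 1) != (voiced == 0)
                if c[l] < 1.0 and opposing:
                    if np.random.random() < 1.0 - c[l]:
                        opinion[l] = 2
                        committed[l] = 0
                        c[l] = 1.0
            elif l_op == 2:
                opinion[l] = voiced
            elif l_op != voiced:
                if beta > 0.0 and l_op == 1 and voiced == 0:
                    if np.random.random() < 1.0 - beta:
                        opinion[l] = 2
                else:
                    opinion[l] = 2
            if s_op == 2 and opinion[l] == voiced:
                opinion[s] = voiced
            if opinion[l] != l_op or committed[l] != l_com:
                changed = True
            if opinion[s] != s_op:
                changed = True
        steps += 1
        if not changed:
            first = opinion[0]
            consensus = first != 2
            if consensus:
                for i in range(1, n):
                    if opinion[i] != first:
                        consensus = False
                        break
            if consensus:
                return steps, 1
    return steps, 0


def run(state: SimState, config: ModelConfig, seed: int) -> SimResult:
    """Run the dynamics to termination using the compiled kernel.

    Mutates ``state`` to its terminal configuration.  Stops early when a
    completed sweep changed no agent and every agent holds the same single
    opinion; otherwise at ``config.max_steps``.
    """
    g = state.graph
    steps, reason = _simulate(
        g.indptr,
        g.indices,
        g.weights,
        state.opinion,
        state.committed,
        state.c,
        float(config.attention_beta),
        int(config.max_steps),
        np.uint32(seed),
    )
    state.step_count += int(steps)
    n_a, n_b, n_ab = densities(state)
    return SimResult(n_a, n_b, n_ab, state.step_count, "consensus" if reason else "step_cap")


def run_python(state: SimState, config: ModelConfig, seed: int) -> SimResult:
    """Reference implementation of :func:`run` built on :func:`step`."""
    rng = np.random.RandomState(seed)
    for _ in range(config.max_steps):
        changed = step(state, config, rng)
        if not changed:
            ops = np.unique(state.opinion)
            if ops.size == 1 and ops[0] != Opinion.AB:
                return SimResult(
                    *densities(state), state.step_count, "consensus"
                )
    return SimResult(*densities(state), state.step_count, "step_cap")


# ---------------------------------------------------------------------------
# Mean-field (uniform mixing) approximation
# ---------------------------------------------------------------------------
#
# Categories: committed-A (constant density p), uncommitted A (a), uncommitted
# B (b), mixed AB (m); a + b + m = 1 - p.  Each mean-field event samples an
# ordered speaker-listener pair by density product and applies the update
# table above, with the beta-modified voicing and B-listener gate.  The
# right-hand side of the ODE system is assembled by literally enumerating the
# categories, voicings and gate branches rather than from a closed form, so
# the derivation is testable against the interaction rules themselves.

_CAT_AC, _CAT_A, _CAT_B, _CAT_M = 0, 1, 2, 3


def _meanfield_rhs(y: np.ndarray, p: float, beta: float) -> np.ndarray:
    a, b, m = y
    dens = (p, a, b, m)
    d = np.zeros(3)  # d(a, b, m)/dt

    def add(weight, cat_from, cat_to):
        # density bookkeeping for uncommitted categories only
        if cat_from == cat_to:
            return
        if cat_from != _CAT_AC:
            d[cat_from - 1] -= weight
        if cat_to != _CAT_AC:
            d[cat_to - 1] += weight

    for s_cat in (_CAT_AC, _CAT_A, _CAT_B, _CAT_M):
        for l_cat in (_CAT_AC, _CAT_A, _CAT_B, _CAT_M):
            pair = dens[s_cat] * dens[l_cat]
            if pair == 0.0:
                continue
            if s_cat in (_CAT_AC, _CAT_A):
                voicings = ((Opinion.A, 1.0),)
            elif s_cat == _CAT_B:
                voicings = ((Opinion.B, 1.0),)
            else:
                voicings = (
                    (Opinion.B, 0.5 * (1.0 + beta)),
                    (Opinion.A, 0.5 * (1.0 - beta)),
                )
            for voiced, pv in voicings:
                base = pair * pv
                if base == 0.0:
                    continue
                # listener branches: (probability, post category)
                if l_cat == _CAT_AC:
                    branches = ((1.0, _CAT_AC),)
                elif l_cat == _CAT_A:
                    branches = ((1.0, _CAT_A if voiced == Opinion.A else _CAT_M),)
                elif l_cat == _CAT_B:
                    if voiced == Opinion.B:
                        branches = ((1.0, _CAT_B),)
                    else:
                        g = 1.0 - beta  # attention gate (1 when beta = 0)
                        branches = ((g, _CAT_M), (1.0 - g, _CAT_B))
                else:  # mixed listener adopts the voiced opinion
                    branches = ((1.0, _CAT_A if voiced == Opinion.A else _CAT_B),)
                for pb, l_post in branches:
                    w = base * pb
                    if w == 0.0:
                        continue
                    add(w, l_cat, l_post)
                    if s_cat == _CAT_M:
                        listener_holds_voiced = (
                            (l_post in (_CAT_AC, _CAT_A) and voiced == Opinion.A)
                            or (l_post == _CAT_B and voiced == Opinion.B)
                        )
                        if listener_holds_voiced:
                            add(w, _CAT_M, _CAT_A if voiced == Opinion.A else _CAT_B)
    return d


def meanfield_fixed_point(
    p_a: float, beta: float = 0.0, t_max: float = 5000.0, tol: float = 1e-9
) -> tuple[float, float, float]:
    """Stable fixed point reached from the all-B initial condition.

    Integrates the uniform-mixing ODE system for the uncommitted densities
    (a, b, m) with committed-A fraction ``p_a``, then polishes the endpoint
    with a root solve.  Returns total densities (n_A, n_B, n_AB) where n_A
    includes the committed minority.
    """
    if not (0.0 <= p_a < 1.0):
        raise ValueError("p_a must lie in [0, 1)")
    y0 = np.array([0.0, 1.0 - p_a, 0.0])
    sol = solve_ivp(
        lambda _, y: _meanfield_rhs(y, p_a, beta),
        (0.0, t_max),
        y0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise NumericalError(f"mean-field integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    y_fp, info, ier, msg = fsolve(
        lambda y: _meanfield_rhs(y, p_a, beta), y_end, full_output=True
    )
    if ier == 1 and np.max(np.abs(y_fp - y_end)) < 0.05:
        y_end = y_fp
    resid = float(np.max(np.abs(_meanfield_rhs(y_end, p_a, beta))))
    if resid > tol:
        raise NumericalError(
            f"mean-field fixed point did not converge (residual {resid:.2e} at "
            f"p_a={p_a}, beta={beta})"
        )
    a, b, m = (float(min(1.0, max(0.0, v))) for v in y_end)
    return p_a + a, b, m


def meanfield_critical_point(
    beta: float = 0.0, lo: float = 0.0, hi: float = 0.3, tol: float = 1e-4
) -> float:
    """Smallest committed-A fraction at which the B-dominant branch disappears.

    Bisection on whether the fixed point reached from all-B keeps n_B above
    0.5; below the critical fraction the population stays truth-dominant,
    above it the committed minority takes over.
    """

    def b_dominant(p):
        return meanfield_fixed_point(p, beta)[1] > 0.5

    if not b_dominant(lo):
        raise ValueError(f"lower bracket p_a={lo} is already A-dominant")
    if b_dominant(hi):
        raise ValueError(f"upper bracket p_a={hi} is still B-dominant")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if b_dominant(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
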