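# Methods

## Model

`disinfosim` implements a binary agreement (naming-game) model on weighted,
directed graphs. Agents hold `A` (disinformation), `B` (truth) or the mixed
state `AB`. A speaker voices a single opinion (mixed speakers pick one);
the listener then moves one notch toward the voiced opinion (opposite single
opinion → `AB`, `AB` → voiced), and a mixed speaker collapses to the voiced
opinion exactly when the post-interaction listener holds it. These twelve
speaker/listener transitions are enumerated in `dynamics.py` and covered
exhaustively by tests. A fraction `p_a` of agents is committed to `A`:
their opinion never changes (except under skepticism, below). All other
agents start as uncommitted `B`.

**Stepping.** One step sweeps all nodes in fixed index order. Each focal
node draws a uniform neighbor, speaker/listener roles are assigned uniformly,
and the pair interacts with probability equal to the speaker→listener edge
weight. Updates are asynchronous (in place within the sweep), the standard
choice for naming-game models and the one consistent with strictly pairwise
interactions.

**Weights.** An undirected simple graph is converted to a directed graph
with the social-transitivity weight w_ij = (1 + shared(i,j)) / deg(i), where
the denominator is the *speaker's* degree: a listener sharing many neighbors
with the speaker is more likely to be reached. By construction
0 < w_ij ≤ 1, and complete graphs have all weights exactly 1. Shared-neighbor
counts come from the square of the sparse adjacency matrix, restricted to
edge positions, so they are exact integers.

**Termination.** A run ends when a completed sweep changed no agent *and*
all agents hold the same single opinion, or at `max_steps = 5000`. The
consensus requirement avoids spurious stops on weighted graphs, where a
sweep can change nothing by chance while mixed single opinions persist; in
every truly absorbing state the two criteria coincide. With two opposed
committed groups no consensus is possible and runs always use the full step
budget.

**Densities.** Terminal fractions n_A, n_B, n_AB are taken over the current
node count (after any moderation removals) and sum to 1; committed agents
count toward their opinion.

## Mean-field oracle

For uniform mixing, the uncommitted densities (a, b, m) with committed-A
fraction p obey an ODE system whose right-hand side is assembled in
`dynamics._meanfield_rhs` by literally enumerating ordered
speaker–listener category pairs, voicing probabilities and gate branches —
the same transition table the simulator uses, so the derivation is testable
rather than transcribed. `meanfield_fixed_point` integrates from the all-B
state (LSODA, rtol 1e-10) and polishes the endpoint with a root solve; a
residual above 1e-9 raises a numerical error rather than returning a bogus
point. Bisection on the disappearance of the B-dominant branch gives the
critical committed fraction p_c ≈ 0.0979 for β = 0, and simulations on the
complete graph with N = 400 agree with the fixed points to within 0.05 in
n_B away from criticality (tested at p_a = 0.05 and 0.15).

## Strategies

Exactly one strategy applies per simulation (the combined
skepticism+attention mode counts as one).

* **Content moderation** removes `round_half_up(fraction × N)` committed
  nodes before the run, either the most influential (influence
  I(v) = (C_D + C_B)/2, mean of normalized degree and betweenness
  centrality; ties broken by ascending node id, relevant on grids/barbells
  where many nodes tie) or uniformly at random. The removal fraction is a
  fraction of the *total* node count and must not exceed the committed
  count — exceeding it is a configuration error, never a silent clamp.
  Surviving edge weights are **frozen**, not recomputed on the reduced
  graph: removal models banning users after interaction strengths formed,
  and freezing isolates the removal effect. Reported `p_a` stays the
  pre-removal fraction of the original N (so curves for different removal
  fractions share one axis) while densities use the post-removal population;
  this shifts curves and is deliberate.
* **Skepticism** draws each committed agent's commitment level c once, at
  initialization, from the triangular density p(c) = 2(c − c_min)/(1 −
  c_min)² on [c_min, 1] (inverse CDF: c = c_min + (1 − c_min)√U; default
  c_min = 1/2, giving E[c] = 5/6). A partially committed listener hearing
  the opposing opinion de-commits — becomes uncommitted `AB` with its c
  reset to 1 — with probability 1 − c. This is the only reading consistent
  with the limit c_min → 1, where the density collapses to a point mass at
  c = 1 and the base model is recovered. The draw is per lifetime, not per
  interaction, treating skepticism as a persistent trait; agents with c ≈ 1
  therefore anchor the minority. Under this operationalization the
  complete-graph tipping point moves from ~0.10 to ~0.22–0.25 (the
  acceptance script computes it); per-interaction draws or uniform
  commitment levels would move it further (to ~0.25–0.30 in side
  experiments) but are weaker readings of the density. Counter-committed
  (`B`) agents always keep c = 1; skepticism models education aimed at the
  disinformed minority.
* **Attention** (truth bias β, default 0.1) makes exactly two
  modifications: mixed speakers voice `B` with probability (1 + β)/2, and an
  uncommitted `B` listener hearing `A` switches to `AB` only with
  probability 1 − β. Mixed listeners hearing `A` are not gated. β = 0
  disables the strategy and takes the identical code path as the base model
  (bitwise-equal trajectories, tested).
* **Counter-campaigns** add a second minority of size `round_half_up(p_b ×
  N)` committed to `B`. To emulate campaigns that start locally (echo
  chambers), a seeded Fruchterman–Reingold layout in [−1, 1]² positions all
  nodes; committed-A members are sampled uniformly from nodes with x < 0 and
  committed-B from x > 0 (x = 0 exactly joins neither pool). The topology is
  untouched — locality is achieved by sampling, not by relocating nodes.
  Both groups are re-sampled per simulation. Committed-B agents never
  convert, so terminal n_B ≥ p_b structurally.

## Experiment harness

A sweep runs `pa_grid × replicates` simulations of one strategy on one
topology. Seeds derive from `SeedSequence([base_seed, replicate,
grid_index])`, making every run independent of execution order and the whole
sweep reproducible from one integer. By default one graph instantiation
serves the whole sweep; `new_graph_per_replicate` rebuilds the topology per
replicate for random families (both interpretations of "a new
instantiation" are supported since either is defensible).

The tipping point of a mean n_B-vs-p_a curve is operationalized as the
*first grid value whose mean n_B falls below 0.5* (threshold configurable).
Qualitative smoothing of the transition is reported as the maximum drop in
mean n_B between adjacent grid points, not auto-classified. Default grids:
11 points, 0.03–0.13 step 0.01, for the base model and moderation (whose
removal counts stay below the committed count there); 15 points,
0.025–0.375 step 0.025, for education and counter-campaigns, wide enough to
contain tipping points above 0.3.

## Synthetic topologies and what they do (not) show

The generator produces the study conditions directly: complete,
Watts–Strogatz (k ∈ {8, 40, 100} with rewiring 0.5 or 1.0), Erdős–Rényi
(p ∈ {0.02, 0.1, 0.25}), Barabási–Albert (m ∈ {4, 24, 50}), 2-D grid,
and barbell(199, 2) graphs, all at N = 400 (the 200×200 grid is supported
in code but not exercised at full size). These capture degree
heterogeneity, clustering and community bottlenecks, but not directed
follower asymmetries, dynamic rewiring, or the heavy-tailed sizes of real
platforms; passing tests demonstrate the model's behavior under these
controlled conditions, not forecasts for any particular real network. Real
edge lists can be loaded from two-column text files; none are bundled.

## Numerical choices

* The hot loop is a numba kernel over CSR arrays using numpy's legacy
  Mersenne Twister; the pure-Python `step` consumes the identical draw
  sequence (neighbor, role, interaction coin, voicing, gate — neighbor
  choice uses ⌊U·deg⌋ so both paths draw the same variates), and tests
  assert bitwise-equal trajectories. One RNG per simulation; strategy
  setup uses a separate generator derived from the same seed tuple.
* All fraction-of-population counts use round-half-up, applied identically
  everywhere.
* Centralities and influence are computed on the undirected, unweighted
  topology, with the standard (n−1)(n−2)/2 betweenness normalization,
  endpoints excluded; disconnected graphs need no special casing.
* Isolated nodes are skipped in sweeps and simply have no out-edges.
* CSVs round floats to 6 decimals; the round trip reproduces curves exactly
  at that precision.

## Problem sizes

Acceptance-style runs use N = 400 with 5–10 replicates per grid point —
about 400 simulations of at most 5000 sweeps each in total, a few minutes on
one CPU. Published studies of this model family use ~30 replicates across
more topologies; the scaled-down replicate counts widen the spread of
detected tipping points by roughly one grid step but do not move their
location systematically.

## Known limitations

* The skepticism tipping point depends on how the commitment density is
  turned into a per-interaction change probability (see above); results for
  that strategy should be read as specific to the 1 − c lifetime-draw
  operationalization.
* The tipping detector reads a threshold crossing of the replicate mean; on
  curves with high replicate variance near the transition the detected
  value can move by one grid step between seeds.
* The mean-field oracle assumes uniform mixing and covers the base model
  and attention bias; it does not model skepticism (whose committed state
  is not autonomous) or spatially initialized counter-campaigns.
* No multi-opinion extensions, dynamic topologies, or strategy stacking
  beyond skepticism+attention.
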