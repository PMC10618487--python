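"""Sweep harness: committed-fraction sweeps with replicates, tipping-point
detection, and CSV persistence.

A sweep runs the dynamics for every point of an ascending ``p_a`` grid times
``replicates`` independent runs, applying exactly one mitigation strategy
(or none, the base model) per simulation.  Replicate seeds derive from
``(base_seed, replicate, p_a index)`` so any execution order gives identical
results.  The tipping point of a mean n_B-vs-p_a curve is read as the first
grid point whose mean terminal truth density falls below a threshold
(default 0.5).

Under content moderation the reported ``p_a`` stays the PRE-removal committed
fraction of the original node count (curves for several removal fractions
share one axis), while terminal densities use the post-removal population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import ModelConfig, SimResult, SimState, run
from .networks import ConfigurationError, GraphSpec, SocialGraph, assign_weights, build_graph
from .strategies import (
    AttentionConfig,
    CounterCampaignConfig,
    ModerationConfig,
    SkepticismConfig,
    init_counter_campaign,
    layout_positions,
    moderate,
    sample_commitment,
    select_committed,
)

STRATEGY_KINDS = (
    "none",
    "moderation",
    "skepticism",
    "attention",
    "education_both",
    "counter_campaign",
)

#: default committed-fraction grids; moderation (and the base model) use the
#: 11-point grid, education and counter-campaigns a 15-point grid wide enough
#: to cover skepticism tipping points above 30%.
DEFAULT_GRID_MODERATION = tuple(np.round(np.arange(0.03, 0.135, 0.01), 10))
DEFAULT_GRID_WIDE = tuple(np.round(np.arange(0.025, 0.376, 0.025), 10))


@dataclass(frozen=True)
class Strategy:
    """Tagged union of the mitigation strategies; exactly one is active.

    ``education_both`` combines skepticism and attention, the only supported
    combination.
    """

    kind: str = "none"
    moderation: ModerationConfig | None = None
    skepticism: SkepticismConfig | None = None
    attention: AttentionConfig | None = None
    counter: CounterCampaignConfig | None = None

    def __post_init__(self):
        if self.kind not in STRATEGY_KINDS:
            raise ConfigurationError(
                f"unknown strategy {self.kind!r}; expected one of {STRATEGY_KINDS}"
            )
        needs = {
            "none": (),
            "moderation": ("moderation",),
            "skepticism": ("skepticism",),
            "attention": ("attention",),
            "education_both": ("skepticism", "attention"),
            "counter_campaign": ("counter",),
        }[self.kind]
        for name in needs:
            if getattr(self, name) is None:
                object.__setattr__(
                    self,
                    name,
                    {
                        "moderation": ModerationConfig(0.0),
                        "skepticism": SkepticismConfig(),
                        "attention": AttentionConfig(),
                        "counter": CounterCampaignConfig(),
                    }[name],
                )
        for name in ("moderation", "skepticism", "attention", "counter"):
            if name not in needs and getattr(self, name) is not None:
                raise ConfigurationError(
                    f"strategy {self.kind!r} does not take a {name!r} config"
                )

    def default_grid(self) -> tuple[float, ...]:
        if self.kind in ("none", "moderation"):
            return DEFAULT_GRID_MODERATION
        return DEFAULT_GRID_WIDE


@dataclass(frozen=True)
class SweepConfig:
    graph_spec: GraphSpec
    strategy: Strategy = Strategy()
    pa_grid: tuple[float, ...] | None = None
    replicates: int = 30
    base_seed: int = 0
    new_graph_per_replicate: bool = False
    max_steps: int = 5000
    tipping_threshold: float = 0.5

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        grid = self.pa_grid
        if grid is not None:
            grid = tuple(float(p) for p in grid)
            if any(not (0.0 <= p <= 1.0) for p in grid):
                raise ConfigurationError("pa_grid values must lie in [0, 1]")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ConfigurationError("pa_grid must be strictly ascending")
            object.__setattr__(self, "pa_grid", grid)

    @property
    def resolved_grid(self) -> tuple[float, ...]:
        return self.pa_grid if self.pa_grid is not None else self.strategy.default_grid()


@dataclass
class TippingCurve:
    """Per-replicate terminal truth densities over a committed-fraction grid."""

    detail: pd.DataFrame  # strategy, graph_family, pa, replicate, n_B, steps, terminated_by, seed
    pa_grid: tuple[float, ...]
    threshold: float = 0.5

    @property
    def mean_nB(self) -> pd.Series:
        return self.detail.groupby("pa", sort=True)["n_B"].mean()

    @property
    def sd_nB(self) -> pd.Series:
        return self.detail.groupby("pa", sort=True)["n_B"].std(ddof=1).fillna(0.0)

    @property
    def tipping_pa(self) -> float | None:
        return detect_tipping(self, self.threshold)

    @property
    def max_drop(self) -> float:
        """Largest decrease in mean n_B between adjacent grid points."""
        m = self.mean_nB.to_numpy()
        if m.size < 2:
            return 0.0
        return float(np.max(m[:-1] - m[1:]))

    def __eq__(self, other):
        return (
            isinstance(other, TippingCurve)
            and self.pa_grid == other.pa_grid
            and self.threshold == other.threshold
            and self.detail.equals(other.detail)
        )


def detect_tipping(curve: TippingCurve, threshold: float = 0.5) -> float | None:
    """Smallest grid p_a whose mean terminal n_B falls below ``threshold``."""
    if curve.detail.empty:
        raise ValueError("cannot detect a tipping point on an empty curve")
    means = curve.mean_nB
    below = means[means < threshold]
    return float(below.index[0]) if len(below) else None


def _derive_seeds(base_seed: int, replicate: int, pa_index: int) -> tuple[int, int]:
    """(strategy rng seed, simulation kernel seed) for one run."""
    state = np.random.SeedSequence([base_seed, replicate, pa_index]).generate_state(2)
    return int(state[0]), int(state[1])


def _graph_seed(spec: GraphSpec, base_seed: int, replicate: int | None) -> int:
    entropy = [base_seed if spec.seed is None else spec.seed]
    if replicate is not None:
        entropy = [base_seed, replicate] if spec.seed is None else [spec.seed, replicate]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] >> 1)


def _prepare_run(sg: SocialGraph, positions, strategy: Strategy, pa: float, rng):
    """Apply one strategy; returns the initialized state and model config."""
    model = ModelConfig()
    if strategy.kind == "counter_campaign":
        committed_a, committed_b = init_counter_campaign(
            sg, pa, strategy.counter, rng, positions=positions
        )
        state = SimState.initial(sg, committed_a, committed_b)
        return state, model
    committed = select_committed(sg.n, pa, rng)
    levels = None
    if strategy.kind == "moderation":
        sg, committed, _ = moderate(sg, committed, strategy.moderation, rng)
    elif strategy.kind in ("skepticism", "education_both"):
        c = sample_commitment(strategy.skepticism.c_min, rng, size=committed.size)
        levels = dict(zip(committed.tolist(), c.tolist()))
    if strategy.kind in ("attention", "education_both"):
        model = ModelConfig(attention_beta=strategy.attention.beta)
    state = SimState.initial(sg, committed, (), commitment_levels=levels)
    return state, model


def sweep(cfg: SweepConfig) -> TippingCurve:
    """Run the full p_a grid x replicates for one topology and strategy."""
    grid = cfg.resolved_grid
    strategy = cfg.strategy
    family = cfg.graph_spec.family

    graph_cache: dict[int | None, tuple[SocialGraph, np.ndarray | None]] = {}

    def get_graph(replicate: int) -> tuple[SocialGraph, np.ndarray | None]:
        key = replicate if cfg.new_graph_per_replicate else None
        if key not in graph_cache:
            seed = _graph_seed(cfg.graph_spec, cfg.base_seed, key)
            spec = replace(cfg.graph_spec, seed=seed)
            g = build_graph(spec)
            sg = assign_weights(g)
            positions = None
            if strategy.kind == "counter_campaign":
                positions = layout_positions(g, strategy.counter.layout_seed)
            graph_cache[key] = (sg, positions)
        return graph_cache[key]

    rows = []
    for ip, pa in enumerate(grid):
        for rep in range(cfg.replicates):
            strat_seed, sim_seed = _derive_seeds(cfg.base_seed, rep, ip)
            sg, positions = get_graph(rep)
            rng = np.random.default_rng(strat_seed)
            try:
                state, model = _prepare_run(sg, positions, strategy, pa, rng)
                if cfg.max_steps != model.max_steps:
                    model = replace(model, max_steps=cfg.max_steps)
                result = run(state, model, sim_seed)
            except Exception as exc:
                raise type(exc)(
                    f"{exc} (at pa={pa}, replicate={rep})"
                ) from exc
            rows.append(
                {
                    "strategy": strategy.kind,
                    "graph_family": family,
                    "pa": float(pa),
                    "replicate": rep,
                    "n_B": result.n_B,
                    "steps": result.steps,
                    "terminated_by": result.terminated_by,
                    "seed": sim_seed,
                }
            )
    detail = pd.DataFrame(rows)
    return TippingCurve(detail=detail, pa_grid=tuple(float(p) for p in grid),
                        threshold=cfg.tipping_threshold)


def summary_path(detail_path) -> str:
    p = str(detail_path)
    return (p[: -len(".csv")] if p.endswith(".csv") else p) + "_summary.csv"


def write_results(curve: TippingCurve, path) -> None:
    """Persist the curve: long-format detail CSV plus a summary CSV alongside.

    Floats are written at 6 decimals; :func:`read_results` reproduces the
    curve exactly at that precision.
    """
    if curve.detail.empty:
        raise ValueError("refusing to write an empty curve")
    curve.detail.to_csv(path, index=False, float_format="%.6f")
    means, sds = curve.mean_nB, curve.sd_nB
    tip = curve.tipping_pa
    summary = pd.DataFrame(
        {
            "pa": means.index,
            "mean_nB": means.to_numpy(),
            "sd_nB": sds.to_numpy(),
            "tipping_flag": [tip is not None and p == tip for p in means.index],
        }
    )
    summary.to_csv(summary_path(path), index=False, float_format="%.6f")


def read_results(path, threshold: float = 0.5) -> TippingCurve:
    detail = pd.read_csv(path)
    return TippingCurve(
        detail=detail,
        pa_grid=tuple(sorted(detail["pa"].unique().tolist())),
        threshold=threshold,
    )


def plot_curve(curve: TippingCurve, path, title: str | None = None) -> None:
    """Optional mean-curve plot with transparent per-replicate scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(curve.detail["pa"], curve.detail["n_B"], alpha=0.2, s=10, label="replicates")
    means = curve.mean_nB
    ax.plot(means.index, means.to_numpy(), "o-", color="C1", label="mean")
    tip = curve.tipping_pa
    if tip is not None:
        ax.axvline(tip, color="k", ls="--", lw=0.8, label=f"tipping {tip:g}")
    ax.set_xlabel(r"committed disinformation fraction $p_a$")
    ax.set_ylabel(r"terminal truth density $n_B$")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
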