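"""Stochastic drive to the striatal circuit.

The model receives no external data; all input is generated here.

*Background*: every neuron is driven by its own independent Poisson event
stream at a kHz aggregate rate (one equivalent generator per neuron), which
maintains the spontaneous state.  Background realizations are re-drawn for
every trial.

*Cortical stimulus*: two "source" pools of cortical neurons fire 10 Hz
Poisson trains.  Each MSN of group M_a draws a fixed indegree ``k_ctx`` of
inputs (with replacement, so multapses occur and are counted with their
multiplicity) from pool A; group M_b draws from pool B.  The pools have size
``n_ctx`` each and share ``n_ol`` sources.  This parameterizes input sharing:

    W_in = k_ctx / n_ctx      (within-group sharing)
    B_in = n_ol / n_ctx       (between-group sharing)

so the nominal between-group input correlation is B_in * W_in.  FSIs draw
``k_ctx`` inputs from *each* pool (at half the synaptic weight), since they
listen to both cortical sources.  Cortical trains and wiring are frozen
across the trials of one experiment; only the background varies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._rng import spawn_rng
from .network_builder import PopulationLayout, sample_weights

__all__ = [
    "BackgroundConfig",
    "CorticalPoolConfig",
    "CtxWiring",
    "FrozenInputSet",
    "pool_sizes_from_sharing",
    "generate_poisson_trains",
    "wire_ctx_to_msn",
    "wire_ctx_to_fsi",
    "build_frozen_inputs",
    "expected_input_correlation",
    "expected_count_correlation",
]

# nominal synaptic parameters of the input projections
CTX_MSN_WEIGHT = 4.8  # nS (lognormal mean)
CTX_FSI_WEIGHT = 0.25  # nS, halved relative to 0.5 for double-pool convergence
CTX_DELAY_MEAN = 1.0  # ms
CTX_DELAY_HALFWIDTH = 1.0  # ms; lower edge clamped to min_delay
WEIGHT_LOG_SD = 0.5


@dataclass(frozen=True)
class BackgroundConfig:
    """Per-neuron independent Poisson background (rates in kHz, weights in nS).

    The MSN rate drops from 5.95 to 3.2 kHz in the control condition without
    FSIs, to keep evoked MSN firing comparable once feedforward inhibition is
    absent.
    """

    msn_rate: float = 5.95
    fsi_rate: float = 5.75
    gpe_rate: float = 7.0
    msn_weight: float = 2.0
    fsi_weight: float = 1.0
    gpe_weight: float | None = None  # calibrated against a 40 Hz GPe baseline

    MSN_RATE_NO_FSI = 3.2

    def __post_init__(self) -> None:
        if min(self.msn_rate, self.fsi_rate, self.gpe_rate) < 0:
            raise ValueError("background rates must be non-negative")

    @classmethod
    def for_layout(cls, layout: PopulationLayout, **kw) -> "BackgroundConfig":
        """Default background for a layout, applying the no-FSI control rate."""
        cfg = cls(**kw)
        if layout.n_fsi == 0:
            cfg = replace(cfg, msn_rate=cls.MSN_RATE_NO_FSI)
        return cfg


@dataclass(frozen=True)
class CorticalPoolConfig:
    """Sizes and overlap of the two cortical source pools.

    ``w_in`` and ``b_in`` record the requested sharing levels; the realized
    values implied by the integer pool sizes are exposed as properties.
    """

    n_ctx: int
    n_ol: int
    k_ctx: int = 100
    source_rate: float = 10.0  # Hz
    w_in: float | None = None  # requested, for bookkeeping
    b_in: float | None = None

    def __post_init__(self) -> None:
        if self.n_ctx < 1:
            raise ValueError("n_ctx must be at least 1")
        if not 0 <= self.n_ol <= self.n_ctx:
            raise ValueError("n_ol must lie in [0, n_ctx]")
        if self.k_ctx < 1:
            raise ValueError("k_ctx must be at least 1")

    @property
    def n_sources(self) -> int:
        """Total number of distinct cortical sources (two pools minus overlap)."""
        return 2 * self.n_ctx - self.n_ol

    @property
    def w_in_realized(self) -> float:
        return self.k_ctx / self.n_ctx

    @property
    def b_in_realized(self) -> float:
        return self.n_ol / self.n_ctx

    @property
    def pool_a(self) -> np.ndarray:
        return np.arange(self.n_ctx)

    @property
    def pool_b(self) -> np.ndarray:
        # the last n_ol sources of pool A are the first n_ol of pool B
        return np.arange(self.n_ctx - self.n_ol, self.n_sources)

    @classmethod
    def from_sharing(
        cls, w_in: float, b_in: float, k_ctx: int = 100, source_rate: float = 10.0
    ) -> "CorticalPoolConfig":
        n_ctx, n_ol = pool_sizes_from_sharing(w_in, b_in, k_ctx)
        return cls(
            n_ctx=n_ctx, n_ol=n_ol, k_ctx=k_ctx, source_rate=source_rate,
            w_in=w_in, b_in=b_in,
        )


def pool_sizes_from_sharing(w_in: float, b_in: float, k_ctx: int = 100) -> tuple[int, int]:
    """Invert the sharing definitions: n_ctx = round(k_ctx / w_in),
    n_ol = round(b_in * n_ctx).  Rounding is half-up."""
    if not 0 < w_in <= 1:
        raise ValueError("w_in must lie in (0, 1]")
    if not 0 <= b_in <= 1:
        raise ValueError("b_in must lie in [0, 1]")
    n_ctx = int(math.floor(k_ctx / w_in + 0.5))
    n_ol = int(math.floor(b_in * n_ctx + 0.5))
    return n_ctx, n_ol


def generate_poisson_trains(
    rate: float, n_sources: int, duration: float, seed: int | np.random.Generator
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains.

    Parameters: ``rate`` in Hz, ``duration`` in ms.  Returns one sorted array
    of spike times (ms) per source.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected = rate * duration / 1000.0
    counts = rng.poisson(expected, size=n_sources)
    return [np.sort(rng.uniform(0.0, duration, size=c)) for c in counts]


@dataclass
class CtxWiring:
    """Cortical source -> striatal target synapse list (multapses explicit)."""

    source: np.ndarray  # ctx source ids
    target: np.ndarray  # striatal neuron ids
    weight: np.ndarray  # nS
    delay: np.ndarray  # ms

    @property
    def n_synapses(self) -> int:
        return len(self.source)

    def indegree_of(self, target_id: int) -> int:
        return int((self.target == target_id).sum())

    @staticmethod
    def empty() -> "CtxWiring":
        z = np.empty(0)
        return CtxWiring(z.astype(np.int64), z.astype(np.int64), z.copy(), z.copy())


def _draw_wiring(
    rng: np.random.Generator,
    pools: list[tuple[np.ndarray, np.ndarray]],
    k_ctx: int,
    weight_mean: float,
    min_delay: float,
) -> CtxWiring:
    """k_ctx draws with replacement from each (pool, targets) pairing."""
    src_parts, tgt_parts = [], []
    for pool, targets in pools:
        if len(targets) == 0:
            continue
        src_parts.append(rng.choice(pool, size=(len(targets), k_ctx), replace=True).ravel())
        tgt_parts.append(np.repeat(targets, k_ctx))
    if not src_parts:
        return CtxWiring.empty()
    source = np.concatenate(src_parts)
    target = np.concatenate(tgt_parts)
    n = len(source)
    weight = sample_weights(weight_mean, WEIGHT_LOG_SD, n, rng)
    lo = max(CTX_DELAY_MEAN - CTX_DELAY_HALFWIDTH, min_delay)
    delay = rng.uniform(lo, CTX_DELAY_MEAN + CTX_DELAY_HALFWIDTH, size=n)
    return CtxWiring(source, target, weight, delay)


def wire_ctx_to_msn(
    pool: CorticalPoolConfig,
    layout: PopulationLayout,
    seed: int | np.random.Generator,
    weight_mean: float = CTX_MSN_WEIGHT,
    min_delay: float = 0.1,
) -> CtxWiring:
    """Each M_a neuron draws k_ctx sources from pool A, each M_b neuron from
    pool B (with replacement; multapses keep their multiplicity)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_wiring(
        rng,
        [(pool.pool_a, layout.group_a), (pool.pool_b, layout.group_b)],
        pool.k_ctx,
        weight_mean,
        min_delay,
    )


def wire_ctx_to_fsi(
    pool: CorticalPoolConfig,
    layout: PopulationLayout,
    seed: int | np.random.Generator,
    weight_mean: float = CTX_FSI_WEIGHT,
    min_delay: float = 0.1,
    mode: str = "per_source",
) -> CtxWiring:
    """Cortical drive to FSIs, which listen to both sources.

    ``mode="per_source"`` (default): k_ctx draws from each pool, i.e. 200
    inputs per FSI at the default indegree, at half the MSN cortical weight,
    so the total cortical conductance flux per FSI matches that per MSN.
    Sources in the overlap belong to both pools and hence get double the
    expected multiplicity.  ``mode="total"``: k_ctx draws from the union of
    the two pools.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if layout.n_fsi == 0:
        return CtxWiring.empty()
    if mode == "per_source":
        pools = [(pool.pool_a, layout.fsi_ids), (pool.pool_b, layout.fsi_ids)]
    elif mode == "total":
        pools = [(np.arange(pool.n_sources), layout.fsi_ids)]
    else:
        raise ValueError("mode must be 'per_source' or 'total'")
    return _draw_wiring(rng, pools, pool.k_ctx, weight_mean, min_delay)


@dataclass
class FrozenInputSet:
    """One stimulus realization, shared by every trial of a trial set:
    the cortical source trains plus the source->MSN and source->FSI wiring."""

    pool: CorticalPoolConfig
    trains: list[np.ndarray]  # per source, spike times ms
    msn_wiring: CtxWiring
    fsi_wiring: CtxWiring
    duration: float  # ms

    def trains_to_csv(self, path_or_buf) -> None:
        import pandas as pd

        src = np.concatenate([np.full(len(t), i) for i, t in enumerate(self.trains)])
        times = np.concatenate(self.trains) if self.trains else np.empty(0)
        pd.DataFrame({"source_id": src.astype(int), "time_ms": times}).to_csv(
            path_or_buf, index=False
        )


def build_frozen_inputs(
    pool: CorticalPoolConfig,
    layout: PopulationLayout,
    duration: float,
    master_seed: int,
    fsi_mode: str = "per_source",
    min_delay: float = 0.1,
) -> FrozenInputSet:
    """Draw the cortical realization for one experiment: spike trains from
    the ``ctx-trains`` stream and wiring from the ``ctx-wiring`` stream of
    the master seed."""
    trains = generate_poisson_trains(
        pool.source_rate, pool.n_sources, duration, spawn_rng(master_seed, "ctx-trains")
    )
    wiring_rng = spawn_rng(master_seed, "ctx-wiring")
    msn_wiring = wire_ctx_to_msn(pool, layout, wiring_rng, min_delay=min_delay)
    fsi_wiring = wire_ctx_to_fsi(pool, layout, wiring_rng, min_delay=min_delay, mode=fsi_mode)
    return FrozenInputSet(pool, trains, msn_wiring, fsi_wiring, duration)


def expected_input_correlation(pool: CorticalPoolConfig) -> tuple[float, float]:
    """Nominal (within, between) correlation of summed cortical input counts:
    (W_in, B_in * W_in), using the realized sharing fractions."""
    w = pool.w_in_realized
    return w, pool.b_in_realized * w


def expected_count_correlation(pool: CorticalPoolConfig) -> tuple[float, float]:
    """Exact (within, between) correlation of summed input counts under
    with-replacement wiring.

    Multapses inflate the private variance of each target's summed input
    (E[sum m^2] = k + k(k-1)/n for k draws from n sources), so the exact
    within-group correlation is k/(n + k - 1) rather than the nominal
    k/n; the between-group value is B_in times the within value.  The two
    agree closely for small W_in and diverge as W_in grows.
    """
    k, n = pool.k_ctx, pool.n_ctx
    within = k / (n + k - 1)
    return within, pool.b_in_realized * within
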