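"""Construction of the striatal microcircuit as an explicit synapse list.

The circuit contains 2500 medium spiny neurons (MSNs), split into two equal
groups M_a and M_b that differ only in their cortical input pools, plus a
variable number of fast-spiking interneurons (FSIs).  Connectivity follows a
fixed-indegree rule: every MSN receives exactly 250 lateral inhibitory inputs
drawn uniformly with replacement from the MSN population (autapses allowed)
and exactly 15 inhibitory inputs drawn with replacement from the FSI
population.  Because the FSI indegree is fixed, the FSI population size
N_fsi alone controls how strongly feedforward inhibition is *shared* among
MSNs (sharing fraction = indegree / N_fsi: 60% at N_fsi=25, 6% at
N_fsi=250, with N_fsi=0 as a control without any FFI).

Peak conductances are sampled from a lognormal distribution whose arithmetic
mean equals the nominal value and whose log-scale sd is 0.5; delays are
sampled uniformly within a halfwidth (default +/-1 ms) around the nominal
delay.  There are no MSN->FSI and no FSI->FSI synapses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import spawn_rng

__all__ = [
    "PopulationLayout",
    "ConnectionRule",
    "Network",
    "default_rules",
    "build_striatum",
    "sample_weights",
    "sample_delays",
    "ffi_sharing_fraction",
]

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass(frozen=True)
class PopulationLayout:
    """Sizes and id blocks of the striatal populations.

    Neuron ids are 0-based and contiguous: group M_a occupies
    [0, n_msn/2), M_b occupies [n_msn/2, n_msn) and FSIs occupy
    [n_msn, n_msn + n_fsi).
    """

    n_msn: int = 2500
    n_fsi: int = 250

    def __post_init__(self) -> None:
        if self.n_msn <= 0 or self.n_msn % 2:
            raise ValueError("n_msn must be positive and even (two equal groups)")
        if self.n_fsi < 0:
            raise ValueError("n_fsi must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_msn + self.n_fsi

    @property
    def msn_ids(self) -> np.ndarray:
        return np.arange(self.n_msn)

    @property
    def group_a(self) -> np.ndarray:
        return np.arange(self.n_msn // 2)

    @property
    def group_b(self) -> np.ndarray:
        return np.arange(self.n_msn // 2, self.n_msn)

    @property
    def fsi_ids(self) -> np.ndarray:
        return np.arange(self.n_msn, self.n_total)

    def group_of(self, neuron_id: int) -> str:
        if 0 <= neuron_id < self.n_msn // 2:
            return "M_a"
        if neuron_id < self.n_msn:
            return "M_b"
        if neuron_id < self.n_total:
            return "FSI"
        raise ValueError(f"neuron id {neuron_id} out of range")


@dataclass(frozen=True)
class ConnectionRule:
    """Fixed-indegree projection between two populations."""

    source: str  # "MSN" or "FSI"
    target: str
    indegree: int
    weight_mean: float  # nS, arithmetic mean of the lognormal
    delay_mean: float  # ms
    weight_log_sd: float = 0.5
    delay_halfwidth: float = 1.0
    syn_type: str = INHIBITORY
    allow_autapse: bool = False
    allow_multapse: bool = True

    def __post_init__(self) -> None:
        if self.indegree < 0:
            raise ValueError("indegree must be non-negative")
        if self.weight_mean < 0:
            raise ValueError("weight_mean must be non-negative")
        if self.delay_mean - self.delay_halfwidth <= 0:
            raise ValueError("delay lower bound must be positive")


def default_rules() -> dict[str, ConnectionRule]:
    """The two striatal projections: weak sparse MSN lateral inhibition and
    strong dense FSI feedforward inhibition."""
    return {
        "msn_msn": ConnectionRule(
            source="MSN", target="MSN", indegree=250,
            weight_mean=0.03, delay_mean=2.0, allow_autapse=True,
        ),
        "fsi_msn": ConnectionRule(
            source="FSI", target="MSN", indegree=15,
            weight_mean=0.5, delay_mean=2.0,
        ),
    }


@dataclass
class Network:
    """Explicit synapse list plus population layout.

    Synapses are stored as parallel arrays (pre, post, weight nS, delay ms)
    with a string type array ("excitatory"/"inhibitory").  Multapses appear
    as repeated (pre, post) entries with their own weights and delays.
    """

    layout: PopulationLayout
    pre: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    post: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    syn_type: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    weight: np.ndarray = field(default_factory=lambda: np.empty(0))
    delay: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None
    rules: dict | None = None

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def synapses_onto(self, post_id: int) -> np.ndarray:
        return np.flatnonzero(self.post == post_id)

    def indegree_from(self, post_id: int, source_ids: np.ndarray) -> int:
        mask = (self.post == post_id) & np.isin(self.pre, source_ids)
        return int(mask.sum())

    def to_csv(self, path_or_buf) -> None:
        """Edge list as CSV: pre_id, post_id, type, conductance_nS, delay_ms."""
        import pandas as pd

        pd.DataFrame(
            {
                "pre_id": self.pre,
                "post_id": self.post,
                "type": self.syn_type,
                "conductance_nS": self.weight,
                "delay_ms": self.delay,
            }
        ).to_csv(path_or_buf, index=False)

    def header_json(self) -> str:
        """Layout, connection rules and build seed, for exact regeneration."""
        from dataclasses import asdict

        return json.dumps(
            {
                "n_msn": self.layout.n_msn,
                "n_fsi": self.layout.n_fsi,
                "n_synapses": self.n_synapses,
                "seed": self.seed,
                "rules": {k: asdict(r) for k, r in (self.rules or {}).items()},
            }
        )


def sample_weights(
    mean: float, log_sd: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Lognormal peak conductances with *arithmetic* mean ``mean`` and
    log-scale sd ``log_sd`` (so mu = ln(mean) - log_sd**2 / 2)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if log_sd < 0:
        raise ValueError("log_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if log_sd == 0:
        return np.full(n, float(mean))
    mu = math.log(mean) - 0.5 * log_sd**2
    return rng.lognormal(mean=mu, sigma=log_sd, size=n)


def sample_delays(
    mean: float, halfwidth: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform delays on [mean - halfwidth, mean + halfwidth] ms."""
    if mean - halfwidth <= 0:
        raise ValueError("delay lower bound must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(mean - halfwidth, mean + halfwidth, size=n)


def ffi_sharing_fraction(ffi_indegree: int, n_fsi: int) -> float:
    """Fraction of the FSI population seen by each MSN (indegree / N_fsi).

    Undefined in the control condition without FSIs.
    """
    if n_fsi <= 0:
        raise ZeroDivisionError(
            "FFI sharing fraction is undefined for the control condition n_fsi=0"
        )
    return ffi_indegree / n_fsi


def _source_ids(layout: PopulationLayout, name: str) -> np.ndarray:
    if name == "MSN":
        return layout.msn_ids
    if name == "FSI":
        return layout.fsi_ids
    raise ValueError(f"unknown population {name!r}")


def build_striatum(
    layout: PopulationLayout,
    rules: dict[str, ConnectionRule] | None = None,
    seed: int = 0,
) -> Network:
    """Draw one realization of the striatal synapse list.

    For every rule and every target neuron, exactly ``indegree`` presynaptic
    partners are drawn uniformly with replacement from the source population
    (multapses permitted; autapses only where the rule allows them), then
    per-synapse weights and delays are sampled.  Reproducible for a fixed
    seed.
    """
    if rules is None:
        rules = default_rules()
    if layout.n_fsi > 0 and not any(r.source == "FSI" for r in rules.values()):
        raise ValueError("layout has FSIs but no FSI projection rule was given")

    rng = spawn_rng(seed, "network")
    pre_parts, post_parts, type_parts, w_parts, d_parts = [], [], [], [], []
    for name in sorted(rules):
        rule = rules[name]
        sources = _source_ids(layout, rule.source)
        targets = _source_ids(layout, rule.target)
        if rule.source == "FSI" and layout.n_fsi == 0:
            continue  # control condition: no feedforward inhibition
        if rule.indegree == 0:
            continue
        if len(sources) == 0:
            raise ValueError(f"rule {name}: positive indegree from empty population")

        n_syn = rule.indegree * len(targets)
        if rule.allow_multapse:
            pre = rng.choice(sources, size=(len(targets), rule.indegree), replace=True)
        else:
            pre = np.stack(
                [rng.choice(sources, size=rule.indegree, replace=False) for _ in targets]
            )
        post = np.repeat(targets, rule.indegree).reshape(len(targets), rule.indegree)
        if not rule.allow_autapse and rule.source == rule.target:
            # redraw self-connections in place
            bad = pre == post
            while bad.any():
                pre[bad] = rng.choice(sources, size=int(bad.sum()), replace=True)
                bad = pre == post
        pre_parts.append(pre.ravel())
        post_parts.append(post.ravel())
        type_parts.append(np.full(n_syn, rule.syn_type, dtype=object))
        w_parts.append(sample_weights(rule.weight_mean, rule.weight_log_sd, n_syn, rng))
        if rule.delay_halfwidth > 0:
            d_parts.append(sample_delays(rule.delay_mean, rule.delay_halfwidth, n_syn, rng))
        else:
            d_parts.append(np.full(n_syn, rule.delay_mean))

    if pre_parts:
        return Network(
            layout=layout,
            pre=np.concatenate(pre_parts),
            post=np.concatenate(post_parts),
            syn_type=np.concatenate(type_parts),
            weight=np.concatenate(w_parts),
            delay=np.concatenate(d_parts),
            seed=seed,
            rules=dict(rules),
        )
    return Network(layout=layout, seed=seed, rules=dict(rules))
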