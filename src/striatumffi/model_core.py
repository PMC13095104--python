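"""Single-neuron and single-synapse primitives.

All cells are conductance-based leaky integrate-and-fire (LIF) neurons

    C_m dV/dt = -g_L (V - E_L) - sum_c g_c(t) (V - E_c)

where the sum runs over synaptic conductance channels (background excitation,
cortical excitation, recurrent MSN inhibition, FSI feedforward inhibition).
A spike is emitted when V crosses ``V_th``; V is reset to ``V_reset`` and
clamped there for the refractory period ``t_r`` while conductances keep
evolving.

Each presynaptic spike triggers an alpha-shaped conductance transient.  The
kernel used here is peak-normalised,

    g(t) = g_peak * e * ((t - t0)/tau) * exp(-(t - t0)/tau) * H(t - t0),

so that the transient attains exactly ``g_peak`` a time ``tau`` after spike
arrival (the convention of NEST-style alpha synapses).  The literal
un-normalised form (peaking at ``g_peak``/e) can be selected with
``peak_normalized=False`` where relevant.

This module also provides the closed-form LIF utilities (rheobase, DC f-I
curve) used as independent oracles for the clock-driven integrator, and
normal resampling of neuron parameters for the heterogeneous-population
variant of the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseEvent",
    "HeterogeneitySpec",
    "CELL_CLASSES",
    "default_params",
    "rheobase",
    "dc_firing_rate",
    "alpha_conductance",
    "sample_heterogeneous",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF parameters of one cell class.

    Units: capacitance pF, conductance nS, potentials mV, times ms.
    (pF/nS = ms, so the membrane time constant C_m/g_L is in ms and
    g*(V) products are in pA.)
    """

    C_m: float
    g_L: float
    E_L: float
    V_th: float
    V_reset: float
    t_r: float
    E_e: float = 0.0
    E_i: float = -85.0
    tau_e: float = 0.2
    tau_i: float = 15.0

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.t_r < 0:
            raise ValueError("refractory period must be non-negative")
        if not self.V_reset < self.V_th:
            raise ValueError("V_reset must lie below V_th")
        if not self.E_L < self.V_th:
            raise ValueError("E_L must lie below V_th")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_L in ms."""
        return self.C_m / self.g_L

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


@dataclass(frozen=True)
class SynapseEvent:
    """One presynaptic spike arriving at a conductance channel."""

    arrival_time: float  # ms
    peak_conductance: float  # nS
    tau: float  # ms
    reversal: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.peak_conductance < 0:
            raise ValueError("peak_conductance must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Normal jitter applied to C_m, g_L, V_th and t_r (sd = |mean| * relative_sd)
    and to tau_i (mean ``tau_i_mean``, variance ``tau_i_variance``).

    The default relative_sd of 1/30 keeps essentially all draws (3 sigma)
    within +/-10% of the base value.
    """

    relative_sd: float = 1.0 / 30.0
    tau_i_mean: float = 15.0
    tau_i_variance: float = 0.5

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")
        if self.tau_i_variance < 0:
            raise ValueError("tau_i_variance must be non-negative")


# Cell-class parameter table (MSN = medium spiny neuron, FSI = fast-spiking
# interneuron, GPE = external globus pallidus readout neuron).
_PARAM_TABLE: dict[str, NeuronParams] = {
    "MSN": NeuronParams(C_m=80.0, g_L=10.0, E_L=-80.0, V_th=-45.0, V_reset=-70.0, t_r=2.0),
    "FSI": NeuronParams(C_m=70.0, g_L=5.0, E_L=-70.0, V_th=-40.0, V_reset=-60.0, t_r=2.0),
    "GPE": NeuronParams(C_m=70.0, g_L=2.5, E_L=-70.0, V_th=-45.0, V_reset=-60.0, t_r=2.0),
}

CELL_CLASSES = tuple(_PARAM_TABLE)


def default_params(cell_class: str) -> NeuronParams:
    """Return the standard parameter set for ``cell_class`` (MSN, FSI or GPE)."""
    key = cell_class.upper()
    if key not in _PARAM_TABLE:
        raise ValueError(
            f"unknown cell class {cell_class!r}; expected one of {sorted(_PARAM_TABLE)}"
        )
    return _PARAM_TABLE[key]


def rheobase(params: NeuronParams) -> float:
    """Minimal DC current (pA) for which the steady-state voltage reaches threshold.

    For the LIF neuron this is exactly g_L * (V_th - E_L).
    """
    return params.g_L * (params.V_th - params.E_L)


def dc_firing_rate(params: NeuronParams, I: float) -> float:
    """Stationary firing rate (Hz) of the LIF neuron under constant current ``I`` (pA).

    Zero at or below rheobase; above it, the closed-form period is
    t_r + tau_m * ln((V_ss - V_reset)/(V_ss - V_th)) with V_ss = E_L + I/g_L.
    """
    i_rh = rheobase(params)
    if I <= i_rh:
        return 0.0
    v_ss = params.E_L + I / params.g_L
    period_ms = params.t_r + params.tau_m * math.log(
        (v_ss - params.V_reset) / (v_ss - params.V_th)
    )
    return 1000.0 / period_ms


def alpha_conductance(
    events: list[SynapseEvent] | tuple[SynapseEvent, ...],
    t: float | np.ndarray,
    peak_normalized: bool = True,
) -> float | np.ndarray:
    """Total conductance (nS) at time(s) ``t`` from a set of synaptic events.

    Linear superposition of alpha kernels, each zero before its arrival time.
    With ``peak_normalized`` (default) each kernel peaks at exactly the
    event's ``peak_conductance`` at ``arrival_time + tau``; otherwise the
    literal alpha form is used, which peaks at ``peak_conductance / e``.
    """
    t_arr = np.asarray(t, dtype=float)
    g = np.zeros_like(t_arr, dtype=float)
    scale = math.e if peak_normalized else 1.0
    for ev in events:
        s = np.clip((t_arr - ev.arrival_time) / ev.tau, 0.0, None)  # Heaviside gate
        g += scale * ev.peak_conductance * s * np.exp(-s)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(g)
    return g


_JITTERED_FIELDS = ("C_m", "g_L", "V_th", "t_r")
_MAX_REDRAWS = 1000


def sample_heterogeneous(
    base: NeuronParams,
    spec: HeterogeneitySpec,
    n: int,
    seed: int | np.random.Generator,
) -> list[NeuronParams]:
    """Draw ``n`` jittered parameter sets around ``base``.

    C_m, g_L, V_th and t_r are drawn independently from normals centred on
    the base value with sd = |base| * relative_sd; tau_i is drawn from
    N(tau_i_mean, tau_i_variance).  Draws violating the NeuronParams
    invariants are rejected and redrawn, so no probability mass piles up at
    the bounds.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tau_i_sd = math.sqrt(spec.tau_i_variance)
    out: list[NeuronParams] = []
    for _ in range(n):
        for _attempt in range(_MAX_REDRAWS):
            draw = {}
            for field in _JITTERED_FIELDS:
                mean = getattr(base, field)
                draw[field] = rng.normal(mean, abs(mean) * spec.relative_sd)
            draw["tau_i"] = rng.normal(spec.tau_i_mean, tau_i_sd)
            try:
                out.append(replace(base, **draw))
                break
            except ValueError:
                continue
        else:  # pragma: no cover - unreachable at sane relative_sd
            raise RuntimeError("could not draw valid heterogeneous parameters")
    return out
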