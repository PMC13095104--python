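"""Trial-based network simulation.

The integrator advances all neurons on a fixed time grid (default
dt = 0.1 ms) with exponential-Euler membrane updates and exact exponential
updates of the alpha-conductance channels (see ``_kernel``).  A trial lasts
``t_total`` ms; the first ``t_warmup`` ms let the network settle and are
excluded from every statistic.

The trial protocol separates frozen and fresh randomness: the cortical
stimulus (source spike trains and their wiring onto the striatum) is drawn
once per experiment and *identical in every trial*, while the background
Poisson drive and the initial membrane potentials are re-drawn per trial
from trial-indexed sub-streams of the master seed.  Across-trial statistics
therefore measure the response variability to one fixed stimulus under
independent background noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from scipy import stats

from . import _kernel
from ._rng import spawn_rng, substream
from .model_core import HeterogeneitySpec, NeuronParams, default_params, sample_heterogeneous
from .network_builder import INHIBITORY, Network, PopulationLayout
from .synthetic_inputs import BackgroundConfig, FrozenInputSet

__all__ = [
    "SimConfig",
    "SpikeRecord",
    "TrialSet",
    "Simulation",
    "integrate_trial",
    "run_trials",
    "spontaneous_state_check",
    "simulate_dc_neuron",
]


@dataclass(frozen=True)
class SimConfig:
    """Integration and trial-protocol settings (times in ms)."""

    dt: float = 0.1
    t_total: float = 2500.0
    t_warmup: float = 500.0
    n_trials: int = 100
    master_seed: int = 0
    heterogeneous: bool = False
    init_mode: str = "uniform"  # "uniform" in [E_L, V_th) or "e_l"
    alpha_peak_normalized: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.t_warmup < self.t_total:
            raise ValueError("t_warmup must be smaller than t_total")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.init_mode not in ("uniform", "e_l"):
            raise ValueError("init_mode must be 'uniform' or 'e_l'")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (self.t_warmup, self.t_total)

    @property
    def analysis_duration(self) -> float:
        return self.t_total - self.t_warmup


@dataclass
class SpikeRecord:
    """Spikes of one trial: parallel (neuron id, time ms) arrays, time-sorted."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    def spike_times(self, neuron_id: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == neuron_id])

    def subset(self, ids: np.ndarray) -> "SpikeRecord":
        mask = np.zeros(self.n_neurons, dtype=bool)
        mask[ids] = True
        keep = mask[self.neuron_ids]
        return SpikeRecord(self.neuron_ids[keep], self.times[keep], self.n_neurons, self.duration)

    def count_in_window(self, ids: np.ndarray, window: tuple[float, float]) -> int:
        mask = np.zeros(self.n_neurons, dtype=bool)
        mask[ids] = True
        sel = mask[self.neuron_ids] & (self.times > window[0]) & (self.times <= window[1])
        return int(sel.sum())

    def mean_rate(self, ids: np.ndarray, window: tuple[float, float]) -> float:
        """Mean firing rate (Hz) of the given neurons over the window."""
        dur_s = (window[1] - window[0]) / 1000.0
        return self.count_in_window(ids, window) / (len(ids) * dur_s)

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        pd.DataFrame({"neuron_id": self.neuron_ids, "time_ms": self.times}).to_csv(
            path_or_buf, index=False
        )


@dataclass
class TrialSet:
    """Spike records of repeated trials sharing one frozen stimulus."""

    records: list[SpikeRecord]
    config: SimConfig
    layout: PopulationLayout
    frozen_inputs: FrozenInputSet | None = None

    @property
    def n_trials(self) -> int:
        return len(self.records)

    def mean_rate(self, ids: np.ndarray) -> float:
        w = self.config.analysis_window
        return float(np.mean([r.mean_rate(ids, w) for r in self.records]))


def _per_neuron_arrays(
    params_list: list[NeuronParams],
) -> dict[str, np.ndarray]:
    def arr(f):
        return np.array([getattr(p, f) for p in params_list], dtype=float)

    return {f: arr(f) for f in ("C_m", "g_L", "E_L", "V_th", "V_reset", "t_r", "E_e", "E_i", "tau_e", "tau_i")}


def _poisson_cdf_table(lams: list[float], tail: float = 1e-14) -> np.ndarray:
    """Per-row Poisson CDF tables used for in-kernel count sampling.

    The last column is a sentinel > 1 so table inversion always terminates.
    """
    kmax = 1
    for lam in lams:
        while lam > 0 and stats.poisson.sf(kmax, lam) > tail:
            kmax += 1
    table = np.full((len(lams), kmax + 2), 2.0)
    for r, lam in enumerate(lams):
        table[r, : kmax + 1] = stats.poisson.cdf(np.arange(kmax + 1), lam) if lam > 0 else 1.0
    return table


def _stream_seed32(master_seed: int, name: str, *indices: int) -> int:
    """32-bit seed for the kernel-internal background stream."""
    return int(substream(master_seed, name, *indices).generate_state(1, np.uint32)[0])


def _event_csr(
    times: np.ndarray,
    targets: np.ndarray,
    kicks: np.ndarray,
    channels: np.ndarray,
    dt: float,
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bucket precomputed delivery events by arrival step (half-up rounding)."""
    step = np.floor(times / dt + 0.5).astype(np.int64)
    keep = (step >= 0) & (step < n_steps)
    step, targets, kicks, channels = step[keep], targets[keep], kicks[keep], channels[keep]
    order = np.argsort(step, kind="stable")
    ptr = np.zeros(n_steps + 1, dtype=np.int64)
    np.cumsum(np.bincount(step, minlength=n_steps), out=ptr[1:])
    return (
        ptr,
        targets[order].astype(np.int64),
        kicks[order].astype(float),
        channels[order].astype(np.int64),
    )


def _group_ranges(rep: np.ndarray) -> np.ndarray:
    """[0..rep[0]-1, 0..rep[1]-1, ...] without a Python loop."""
    total = int(rep.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(rep)
    starts = ends - rep
    return np.arange(total, dtype=np.int64) - np.repeat(starts, rep) + 0


def _wiring_events(
    wiring, trains: list[np.ndarray], kick_scale: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand (source -> target) synapses into per-spike delivery events.

    ``kick_scale[i]`` converts the weight of a synapse onto target ``i``
    into the z-kick of the receiving channel.
    """
    if wiring.n_synapses == 0:
        e = np.empty(0)
        return e, e.astype(np.int64), e.copy()
    lens = np.array([len(t) for t in trains], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    all_times = np.concatenate(trains) if lens.sum() else np.empty(0)
    rep = lens[wiring.source]
    idx = np.repeat(offsets[wiring.source], rep) + _group_ranges(rep)
    ev_times = all_times[idx] + np.repeat(wiring.delay, rep)
    ev_tgt = np.repeat(wiring.target, rep)
    ev_kick = np.repeat(wiring.weight, rep) * kick_scale[ev_tgt]
    return ev_times, ev_tgt, ev_kick


class Simulation:
    """Compiled simulation of one network + one frozen stimulus.

    Precomputes the per-neuron parameter arrays, the recurrent out-adjacency
    (CSR by presynaptic neuron, delays rounded to the step grid, half-up)
    and the per-step cortical delivery lists, then runs trials that differ
    only in background noise and initial conditions.
    """

    def __init__(
        self,
        network: Network,
        config: SimConfig,
        frozen_inputs: FrozenInputSet | None = None,
        background: BackgroundConfig | None = None,
        params_by_class: dict[str, NeuronParams] | None = None,
    ):
        self.network = network
        self.config = config
        self.layout = network.layout
        self.frozen_inputs = frozen_inputs
        self.background = background if background is not None else BackgroundConfig.for_layout(self.layout)

        layout = self.layout
        n = layout.n_total
        self.n_neurons = n
        base = params_by_class or {
            "MSN": default_params("MSN"),
            "FSI": default_params("FSI"),
        }
        if config.heterogeneous:
            spec = HeterogeneitySpec()
            rng = spawn_rng(config.master_seed, "hetero")
            params = sample_heterogeneous(base["MSN"], spec, layout.n_msn, rng)
            if layout.n_fsi:
                params += sample_heterogeneous(base["FSI"], spec, layout.n_fsi, rng)
        else:
            params = [base["MSN"]] * layout.n_msn + [base["FSI"]] * layout.n_fsi
        self._p = _per_neuron_arrays(params)
        dt = config.dt
        self._dec_e = np.exp(-dt / self._p["tau_e"])
        self._dec_i = np.exp(-dt / self._p["tau_i"])
        self._tr_steps = np.round(self._p["t_r"] / dt).astype(np.int64)
        self._kick_scale = math.e if config.alpha_peak_normalized else 1.0
        self.I_dc = np.zeros(n)

        # --- recurrent synapses -> out-adjacency CSR ---
        net = network
        if net.n_synapses:
            if not np.all(net.syn_type == INHIBITORY):
                raise ValueError("recurrent striatal synapses must all be inhibitory")
            delay_steps = np.floor(net.delay / dt + 0.5).astype(np.int64)
            if np.any(delay_steps < 1):
                raise ValueError("synaptic delays must be at least one time step")
            order = np.argsort(net.pre, kind="stable")
            self._out_tgt = net.post[order].astype(np.int64)
            self._out_delay = delay_steps[order]
            kick = net.weight[order] * self._kick_scale / self._p["tau_i"][self._out_tgt]
            self._out_kick = kick
            ptr = np.zeros(n + 1, dtype=np.int64)
            np.cumsum(np.bincount(net.pre, minlength=n), out=ptr[1:])
            self._out_ptr = ptr
            self._ring_len = int(self._out_delay.max()) + 2
        else:
            self._out_ptr = np.zeros(n + 1, dtype=np.int64)
            self._out_tgt = np.empty(0, dtype=np.int64)
            self._out_kick = np.empty(0)
            self._out_delay = np.empty(0, dtype=np.int64)
            self._ring_len = 2

        # --- frozen cortical drive -> per-step delivery CSR ---
        if frozen_inputs is not None:
            ctx_kick_scale = self._kick_scale / self._p["tau_e"]
            parts = []
            for wiring in (frozen_inputs.msn_wiring, frozen_inputs.fsi_wiring):
                t_, tgt_, k_ = _wiring_events(wiring, frozen_inputs.trains, ctx_kick_scale)
                parts.append((t_, tgt_, k_))
            times = np.concatenate([p[0] for p in parts])
            tgts = np.concatenate([p[1] for p in parts]).astype(np.int64)
            kicks = np.concatenate([p[2] for p in parts])
            chans = np.full(len(times), _kernel.EV_EXC, dtype=np.int64)
            self._ctx = _event_csr(times, tgts, kicks, chans, dt, config.n_steps)
        else:
            self._ctx = (
                np.zeros(config.n_steps + 1, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty(0),
                np.empty(0, dtype=np.int64),
            )

        # --- background rate/weight per neuron ---
        bg = self.background
        # kHz * ms = expected events per step
        self._bkg_cdf = _poisson_cdf_table([bg.msn_rate * dt, bg.fsi_rate * dt])
        self._bkg_group = (np.arange(n) >= layout.n_msn).astype(np.int64)
        bkg_weight = np.empty(n)
        bkg_weight[: layout.n_msn] = bg.msn_weight
        bkg_weight[layout.n_msn :] = bg.fsi_weight
        self._bkg_kick = bkg_weight * self._kick_scale / self._p["tau_e"]

        spikes_cap_rate = 250.0  # Hz per neuron, generous buffer bound
        self._cap = int(n * max(1.0, config.t_total / 1000.0) * spikes_cap_rate) + 1000

    def _initial_v(self, rng: np.random.Generator) -> np.ndarray:
        p = self._p
        if self.config.init_mode == "uniform":
            return rng.uniform(p["E_L"], p["V_th"])
        return p["E_L"].copy()

    def run_trial(self, trial_index: int) -> SpikeRecord:
        """Integrate one trial; background and initial state come from
        trial-indexed sub-streams of the master seed."""
        cfg = self.config
        bkg_seed = _stream_seed32(cfg.master_seed, "background", trial_index)
        init_rng = spawn_rng(cfg.master_seed, "initial-state", trial_index)
        v0 = self._initial_v(init_rng)

        spike_neuron = np.empty(self._cap, dtype=np.int64)
        spike_step = np.empty(self._cap, dtype=np.int64)
        p = self._p
        n_spikes = _kernel.run_network_kernel(
            cfg.n_steps,
            cfg.dt,
            p["C_m"],
            p["g_L"],
            p["E_L"],
            p["V_th"],
            p["V_reset"],
            self._tr_steps,
            p["E_e"],
            p["E_i"],
            p["tau_e"],
            p["tau_i"],
            self._dec_e,
            self._dec_i,
            v0,
            self.I_dc,
            self._out_ptr,
            self._out_tgt,
            self._out_kick,
            self._out_delay,
            *self._ctx,
            self._bkg_cdf,
            self._bkg_group,
            self._bkg_kick,
            bkg_seed,
            self._ring_len,
            spike_neuron,
            spike_step,
        )
        if n_spikes < 0:
            raise RuntimeError("spike buffer overflow: network is firing pathologically fast")
        if np.any(np.isnan(v0)):
            raise FloatingPointError("membrane potential diverged (NaN state)")
        ids = spike_neuron[:n_spikes]
        times = (spike_step[:n_spikes] + 1) * cfg.dt  # spike recorded at step end
        return SpikeRecord(ids.copy(), times.astype(float), self.n_neurons, cfg.t_total)

    def run_trials(self) -> TrialSet:
        records = [self.run_trial(i) for i in range(self.config.n_trials)]
        return TrialSet(records, self.config, self.layout, self.frozen_inputs)


def integrate_trial(
    network: Network,
    frozen_inputs: FrozenInputSet | None,
    config: SimConfig,
    trial_index: int = 0,
    background: BackgroundConfig | None = None,
) -> SpikeRecord:
    """One-shot convenience wrapper around :class:`Simulation`."""
    return Simulation(network, config, frozen_inputs, background).run_trial(trial_index)


def run_trials(
    network: Network,
    frozen_inputs: FrozenInputSet | None,
    config: SimConfig,
    background: BackgroundConfig | None = None,
) -> TrialSet:
    """Run ``config.n_trials`` trials with a shared frozen stimulus."""
    return Simulation(network, config, frozen_inputs, background).run_trials()


def spontaneous_state_check(
    network: Network,
    config: SimConfig,
    background: BackgroundConfig | None = None,
) -> tuple[float, float]:
    """Mean (MSN, FSI) firing rates in Hz with background drive only."""
    ts = run_trials(network, None, config, background)
    layout = network.layout
    msn = ts.mean_rate(layout.msn_ids)
    fsi = ts.mean_rate(layout.fsi_ids) if layout.n_fsi else float("nan")
    return msn, fsi


def simulate_dc_neuron(
    params: NeuronParams,
    I: float,
    duration: float = 5000.0,
    dt: float = 0.1,
    v0: float | None = None,
) -> float:
    """Firing rate (Hz) of a single isolated neuron under DC current ``I`` (pA).

    Independent of the network machinery's random streams; used to check the
    integrator against the closed-form LIF rate.
    """
    n_steps = int(round(duration / dt))
    arrs = _per_neuron_arrays([params])
    cap = int(duration / max(params.t_r, dt)) + 10
    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)
    n_spikes = _kernel.run_network_kernel(
        n_steps,
        dt,
        arrs["C_m"],
        arrs["g_L"],
        arrs["E_L"],
        arrs["V_th"],
        arrs["V_reset"],
        np.round(arrs["t_r"] / dt).astype(np.int64),
        arrs["E_e"],
        arrs["E_i"],
        arrs["tau_e"],
        arrs["tau_i"],
        np.exp(-dt / arrs["tau_e"]),
        np.exp(-dt / arrs["tau_i"]),
        np.array([params.E_L if v0 is None else v0]),
        np.array([float(I)]),
        np.zeros(2, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0),
        np.empty(0, dtype=np.int64),
        np.zeros(n_steps + 1, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0),
        np.empty(0, dtype=np.int64),
        np.array([[2.0]]),
        np.zeros(1, dtype=np.int64),
        np.zeros(1),
        0,
        2,
        spike_neuron,
        spike_step,
    )
    return n_spikes / (duration / 1000.0)
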