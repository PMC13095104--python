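# striatumffi

**Shared feedforward inhibition in a spiking striatal microcircuit.**

Fast-spiking interneurons (FSIs) make up only ~1% of the striatum, yet each
one inhibits a large fraction of the medium spiny neurons (MSNs) within its
reach — feedforward inhibition (FFI) in the striatum is *highly shared*,
unlike in cortex. This package implements a conductance-based leaky
integrate-and-fire model of the cortico-striatal circuit built to quantify
what that sharing does to striatal dynamics: it raises the **across-trial
variability** of the MSN population response to a fixed cortical stimulus,
and it **bidirectionally modulates MSN output correlations** (weakly shared
cortical inputs become more correlated, strongly shared inputs are
decorrelated, relative to a circuit without FSIs). Both effects propagate to
a downstream pallidal (GPe) readout neuron as elevated rate variability and
burstiness.

It is a library for computational neuroscientists: importable building
blocks (neurons, network construction, correlated input pools, a fast
numba-based trial simulator, spike statistics) plus an experiment runner
that sweeps the sharing parameters.

## Model

* **Neurons** — conductance-based LIF:
  `C_m dV/dt = −g_L(V−E_L) − Σ_c g_c(t)(V−E_c)`, with per-class parameters
  for MSN, FSI and GPe; alpha-shaped synaptic conductances
  `g(t) = ḡ·e·(t/τ)·exp(−t/τ)` peaking at the sampled peak conductance ḡ.
* **Circuit** — 2500 MSNs (two groups `M_a`, `M_b`) with fixed-indegree
  random connectivity: 250 lateral MSN→MSN inputs (weak, 0.03 nS) and 15
  FSI→MSN inputs (strong, 0.5 nS) per MSN, drawn with replacement. The FSI
  count `N_fsi` sets the FFI sharing fraction `15/N_fsi` (60% at 25 FSIs,
  6% at 250, `N_fsi=0` as control).
* **Inputs** — independent per-neuron Poisson background (5.95/5.75 kHz)
  maintaining a ~1 Hz / ~7 Hz spontaneous state, plus two overlapping pools
  of 10 Hz cortical sources wired with indegree 100; pool size and overlap
  encode the input sharing `W_in = 100/N_ctx`, `B_in = N_ol/N_ctx`.
* **Protocol** — 2.5 s trials at dt = 0.1 ms, 0.5 s warmup; the cortical
  realization is frozen across trials while background noise and initial
  states are redrawn, so trial-to-trial scatter isolates the circuit's noise
  response.
* **Statistics** — across-trial population Fano factor `FF_MSN` (2 ms
  bins), pairwise output correlations `W_out`/`B_out` (20 ms bins), GPe
  spike-count Fano factor and burst index.

See `docs/methods.md` for assumptions, parameter tables, numerical choices
and limitations.

## Worked example

`examples/evoked_variability.py` repeats one frozen cortical stimulus
(`W_in=0.1`, `B_in=0.9`) over 8 trials for two FFI-sharing conditions:

```
N_fsi=250 (sharing  6.0%): MSN rate 5.63 Hz, FF_MSN 0.95
N_fsi= 25 (sharing 60.0%): MSN rate 5.89 Hz, FF_MSN 2.46
```

Mean rates barely move, but the across-trial Fano factor of the population
rate trajectory more than doubles under 60% sharing: the noise carried by a
few widely-shared FSIs appears as population-level fluctuations that differ
from trial to trial. `examples/correlation_transfer.py` shows the
correlation side:

```
control (no FSI): W_out=0.0123  B_out=0.0118
       N_fsi=250: W_out=0.0094  B_out=0.0105
        N_fsi=25: W_out=0.0220  B_out=0.0196
```

Weakly shared FFI decorrelates MSN output below the no-FSI control; highly
shared FFI over-corrects and re-correlates it — the bidirectional
modulation. `examples/downstream_readout.py` feeds one MSN group into the
GPe readout (background calibrated to the ~40 Hz pallidal working point at
the baseline condition):

```
N_fsi=250: GPe rate  40.1 Hz  FF_GPe 0.44  BI_GPe 0.012
N_fsi= 25: GPe rate  35.1 Hz  FF_GPe 0.29  BI_GPe 0.053
```

The burst index rises with FFI sharing; the across-trial count Fano factor
does too on average, though at 8 trials it is a noisy estimate (the test
suite aggregates it over seeds and input settings). The other examples
(`single_neuron_fi.py`, `spontaneous_activity.py`, `input_pools.py`) check
the closed-form LIF oracle, the spontaneous state, and the input-pool
correlation structure.

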