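# Model and methods

## The circuit

The package simulates a simplified cortico-striatal microcircuit built to ask
one question: what does the *sharing* of feedforward inhibition (FFI) do to
the trial-to-trial variability and the pairwise correlations of striatal
output?

The network contains 2500 medium spiny neurons (MSNs), split into two equal
groups `M_a` and `M_b` that differ only in their cortical input pools, and a
variable number `N_fsi` of fast-spiking interneurons (FSIs). Connectivity is
fixed-indegree with multapses: every MSN receives exactly 250 lateral
inhibitory inputs drawn with replacement from the MSN population (autapses
allowed) and exactly 15 inhibitory inputs drawn with replacement from the
FSI population. Because the FSI indegree is fixed, `N_fsi` alone sets how
much of the FSI population any two MSNs share: the sharing fraction
`15 / N_fsi` ranges from 60% at `N_fsi = 25` to 6% at `N_fsi = 250`, with
`N_fsi = 0` as a no-FFI control. There are no MSN→FSI and no FSI↔FSI
connections. FSI→MSN synapses are strong (0.5 nS) and MSN→MSN synapses weak
(0.03 nS), so the two inhibitory systems deliver comparable total conductance
through opposite connectivity styles.

## Neurons and synapses

All cells are conductance-based leaky integrate-and-fire neurons,

    C_m dV/dt = -g_L (V - E_L) - Σ_c g_c(t) (V - E_c),

with per-class parameters (C_m, g_L, E_L, V_th, V_reset, t_r, reversals,
synaptic time constants) for MSN, FSI and GPe. A spike resets V to V_reset
and clamps it for the 2 ms refractory period; synaptic conductances keep
evolving during refractoriness. Each presynaptic event produces an
alpha-shaped conductance transient. The printed alpha form peaks at ḡ/e; we
use the peak-normalized convention (factor e included) so the transient peaks
at exactly the sampled peak conductance ḡ a time τ after arrival, matching
the definition of ḡ as "the peak conductance" and the convention of
NEST-style alpha synapses. The literal form is selectable
(`alpha_conductance(..., peak_normalized=False)`,
`SimConfig(alpha_peak_normalized=False)`).

Peak conductances are lognormal with log-scale sd σ = 0.5; the nominal table
value is the *arithmetic mean* (log-mean = ln(mean) − σ²/2). Delays are
uniform within ±1 ms of the nominal value; the cortical (excitatory, 1 ms
nominal) delays are clamped below at one time step, since a 0 ms delay is
not representable in a clock-driven scheme.

Heterogeneous-neuron mode resamples C_m, g_L, V_th and t_r per neuron from
normals with sd = |mean|/30 (so 3σ ≈ ±10%) and τ_i from N(15 ms, 0.5 ms²),
with rejection resampling for draws violating parameter invariants.

## Inputs

All drive is generated internally; there is no external data.

*Background*: each neuron receives an independent Poisson event stream at an
aggregate rate (5.95 kHz → MSNs, 5.75 kHz → FSIs; 3.2 kHz → MSNs in the
no-FSI control so that evoked rates stay comparable), modeled as a single
equivalent generator per neuron with fixed event weight (2.0 / 1.0 nS).
This maintains the spontaneous state (~1 Hz MSN, ~7 Hz FSI).

*Cortical stimulus*: two source pools of N_ctx cortical neurons firing 10 Hz
Poisson trains, overlapping in N_ol sources. Each `M_a` MSN draws k_ctx=100
inputs with replacement from pool A, each `M_b` MSN from pool B, at 4.8 nS
nominal weight; FSIs draw 100 from *each* pool (200 total) at 0.25 nS, the
0.5 nS single-pool value halved to account for the double-pool convergence.
The alternative single-pool-union reading (100 draws total)
is available via `wire_ctx_to_fsi(..., mode="total")`. Sharing is
parameterized as W_in = k_ctx/N_ctx and B_in = N_ol/N_ctx; requested values
are inverted to integer pool sizes by half-up rounding and the realized
fractions are reported alongside.

Because draws are with replacement, multapses occur (and are the reason
evoked MSN rates grow with W_in). They also inflate the private variance of
each neuron's summed input, so the exact within-group correlation of summed
input counts is k/(N_ctx + k − 1) rather than the nominal W_in = k/N_ctx —
indistinguishable below W_in ≈ 0.15 and visibly smaller above (0.33 vs 0.5
at W_in = 0.5). Both forms are exposed (`expected_input_correlation`,
`expected_count_correlation`); validation tests check the measured
correlations against the exact form across the grid and against the nominal
form in the low-sharing regime. The between/within ratio equals B_in in
both forms.

## Trial protocol

A trial lasts 2.5 s at dt = 0.1 ms; the first 500 ms are warmup and excluded
from all statistics. Across the trials of one experiment the cortical
realization (trains + wiring) is frozen; the background streams and initial
membrane potentials (uniform in [E_L, V_th) by default, fixed-at-E_L
optional) are redrawn per trial. Seeding is hierarchical: one master seed
spawns named sub-streams (`network`, `ctx-trains`, `ctx-wiring`,
`background[trial]`, `initial-state[trial]`, `hetero`, GPe streams), so any
component can be regenerated in isolation and grid points are reproducible
independently of execution order.

## Integration scheme

Clock-driven, fixed dt = 0.1 ms. Each alpha channel is the two-state linear
system dz/dt = −z/τ, dg/dt = −g/τ + z, advanced *exactly* per step; an event
adds w·e/τ to z. Within each polarity the input types share τ and reversal,
so their states superpose and the kernel carries one excitatory and one
inhibitory channel pair per neuron (the four named input types of the model
are bookkeeping on top of this).

The membrane uses an exponential-Euler step driven by the exact time-average
of the conductance over the step, ∫g dt/dt = [τ(g₀−g₁) + τ²(z₀−z₁)]/dt.
This matters: with τ_e = 0.2 ms at dt = 0.1 ms, point-sampled conductances
lose ~4% of synaptic charge and depress FSI rates by ~30%; with the exact
step average, population rates change by <1% when dt is halved or quartered
(FSI spontaneous rate 6.77/6.77/6.79 Hz at dt = 0.1/0.05/0.02 ms). The
relaxation factor exp(−dt·G/C_m) is evaluated by a fifth-order polynomial
(argument < 0.1 for all cell classes; relative error ~1e-10, far below
discretization error).

Threshold is tested at step end (no crossing interpolation); the spike time
is the step-end time. Delays are rounded to the nearest grid step (ties up,
minimum one step) and delivered through a ring buffer. Background Poisson
counts are drawn in-kernel per neuron per step by CDF-table inversion from a
dedicated xorshift64* stream seeded per trial from the named seed hierarchy
(~69 million draws per trial; generating them outside the kernel would cost
more than the integration itself). All randomness is reproducible: identical
seeds give bit-identical spike records.

## Statistics

* **FF_MSN** — across-trial population Fano factor: 2 ms bins of the summed
  spike count of one MSN group (group `M_a` by default; configurable), per-bin
  variance/mean across trials (sample variance, ddof 1), averaged over bins
  with nonzero mean. Computed on raw population counts, not scaled rates:
  the Poisson null is then exactly 1, and comparisons across conditions are
  unaffected because the population size is fixed.
* **W_out / B_out** — mean pairwise Pearson correlation of 20 ms binned
  single-neuron counts, within each group and between groups, per trial and
  then trial-averaged. W_out is the mean of the two group means, which
  equals the symmetric normalized pair-sum formula for equal group sizes.
  Zero-variance units are excluded pairwise (counted, not imputed as 0).
  Pairs are uniformly subsampled (default 5000 per category in the library,
  2000 in the experiment runner) with a fixed seed; full enumeration is a
  flag away.
* **FF_GPe** — Fano factor of the GPe total spike count across trials.
* **BI_GPe** — burst index: a burst is a maximal run of consecutive
  inter-spike intervals < 10 ms containing more than three spikes (≥ 4; the
  ≥ 3 convention is available via `min_spikes=3`); BI is the burst-spike
  fraction averaged over trials with spikes.

## Downstream GPe readout

A single GPe neuron receives 7 kHz excitatory background plus one inhibitory
synapse from each of the 1250 MSNs of one group (lognormal weights, mean
0.02 nS, σ = 0.5; uniform 1–3 ms delays; wiring frozen across trials). The
background weight is not a circuit parameter; it is defined operationally by
calibration to the ~40 Hz pallidal working rate. Two calibrations are
provided. `calibrate_background` bisects the weight for a target rate with
the neuron in isolation (optionally with surrogate Poisson MSN inhibition at
a chosen rate). However, the isolated 40 Hz point sits just above the
mean-driven threshold, and evoked striatal inhibition (~2.8 nS mean) then
silences the cell entirely — incompatible with the published 20–50 Hz
operating range. The experiment pipeline therefore uses
`calibrate_background_on_trialset`: the weight is bisected until the *full
circuit* fires 40 Hz on the baseline (largest `N_fsi`) condition of each
input setting, and that weight is shared by the other `N_fsi` conditions,
mirroring the baseline-referenced design of the downstream comparison. With
this working point the GPe runs at ~36–41 Hz across sharing conditions, and
both its across-trial count Fano factor and its burst index increase when
FFI sharing rises.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions exactly as modeled: stationary
independent Poisson backgrounds, stationary 10 Hz cortical sources, frozen
stimulus across trials, fixed indegrees with multapses. It does not emulate
non-stationary or rate-modulated cortical signals, within-background
correlations, D1/D2 MSN distinctions, FSI gap junctions, or spatial
structure — so passing tests validate the mechanism (sharing of inhibition
reshaping population covariance), not a quantitative prediction for any
particular in-vivo dataset.

## Problem sizes and numerical tolerances

Default experiment scale is deliberately reduced relative to the full study
protocol (100 trials per condition, 11×5 input grid): the experiment runner
defaults to 15 trials on a 3×2×3 grid, and the test suite runs its trend
checks with 10 trials per condition, input settings (W_in, B_in) ∈
{(0.05, 0.1), (0.25, 0.9)}, `N_fsi` ∈ {0, 25, 250}, two master seeds
(homogeneous) and one (heterogeneous), always at full network size and full
trial duration. These sizes are the package's own default verification
scale; the helpers are parameterized so larger replications are one argument
away. Observed effect margins are large relative to this scale (e.g. FF_MSN
≈ 2.3 vs ≈ 1.0 between the 60% and 6% sharing conditions).

Key tolerances: simulated single-neuron DC rates match the closed form
within 2% at dt = 0.1 ms; the numerically bisected rheobase matches
g_L(V_th−E_L) within 1% (note the closed form gives 350/150/62.5 pA for
MSN/FSI/GPe; quoted values of ~320/140/60 pA elsewhere reflect a different,
unstated measurement protocol and are not targeted); statistical-null
checks use ±0.05 on the Poisson Fano factor and ±0.02 on input-correlation
recovery; spontaneous rates are checked at ±0.5 Hz (MSN) and ±2 Hz (FSI),
evoked rates within 20% of their tuned values.

## Known limitations

* The burst index of the GPe is sensitive to its mean-rate working point;
  at reduced trial counts BI differences between sharing conditions are
  small (BI is near zero below ~30 Hz), so the downstream trend checks
  aggregate over seeds and input settings.
* Exact bitwise reproducibility holds for fixed package and numba versions
  on one platform; across compilers/CPUs, floating-point codegen may differ
  harmlessly at the statistical level.
* The integrator is specialized to this model family (alpha conductances,
  two synaptic time constants per neuron); it is not a general-purpose
  simulator.
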