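"""Downstream GPe readout of striatal FFI sharing.

Feeds the spike trains of one MSN group through a single GPe neuron whose
excitatory background is calibrated to a ~40 Hz working point at the
baseline (N_fsi=250) condition.  With highly shared FFI (N_fsi=25) the
GPe inherits the striatal statistics: a higher burst index and, on average
over seeds, a larger across-trial spike-count Fano factor at a similar mean
rate (the Fano factor is a noisy estimate at small trial counts).
"""

from striatumffi import ExperimentConfig
from striatumffi.experiments import run_condition

cfg = ExperimentConfig(name="downstream", n_trials=8, master_seed=3)
weight = None
for n_fsi in (250, 25):
    row = run_condition(cfg, 0.1, 0.9, n_fsi, gpe_background_weight=weight)
    weight = row["gpe_background_weight"]
    print(
        f"N_fsi={n_fsi:3d}: GPe rate {row['gpe_rate']:5.1f} Hz  "
        f"FF_GPe {row['ff_gpe']:.2f}  BI_GPe {row['bi_gpe']:.3f}"
    )
print(f"(background weight calibrated once at baseline: {weight:.3f} nS)")
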