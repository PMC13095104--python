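"""Spontaneous state of the striatal network.

Builds the full circuit (2500 MSNs, 250 FSIs), drives it with independent
per-neuron Poisson background only (5.95 kHz to MSNs, 5.75 kHz to FSIs) and
measures population rates over the post-warmup window.  The circuit is tuned
to the in-vivo baseline: ~1 Hz for MSNs, ~7 Hz for FSIs.
"""

from striatumffi import PopulationLayout, SimConfig, build_striatum, spontaneous_state_check

layout = PopulationLayout(n_msn=2500, n_fsi=250)
network = build_striatum(layout, seed=1)
config = SimConfig(n_trials=2, master_seed=1)
msn_rate, fsi_rate = spontaneous_state_check(network, config)
print(f"spontaneous MSN rate: {msn_rate:.2f} Hz   (expected ~1 Hz)")
print(f"spontaneous FSI rate: {fsi_rate:.2f} Hz   (expected ~7 Hz)")
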