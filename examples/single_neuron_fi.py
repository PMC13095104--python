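"""Single-neuron f-I curves: closed-form LIF theory vs the clock-driven integrator.

Prints the rheobase of each cell class and compares simulated DC firing
rates against the analytic rate 1/(t_r + tau_m ln[(V_ss-V_reset)/(V_ss-V_th)]).
Agreement within ~2% validates the integration scheme at dt = 0.1 ms.
"""

from striatumffi import dc_firing_rate, default_params, rheobase, simulate_dc_neuron

for cls in ("MSN", "FSI", "GPE"):
    p = default_params(cls)
    rb = rheobase(p)
    print(f"{cls}: rheobase {rb:.1f} pA (g_L*(V_th-E_L))")
    for factor in (1.1, 1.5, 2.0):
        I = factor * rb
        theory = dc_firing_rate(p, I)
        sim = simulate_dc_neuron(p, I, duration=5000.0)
        print(f"  I = {I:6.1f} pA: theory {theory:6.2f} Hz, simulated {sim:6.2f} Hz")
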