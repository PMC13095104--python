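"""Cortical input pools: how pool sizes encode input sharing.

W_in = k_ctx / N_ctx sets the within-group sharing of cortical drive;
B_in = N_ol / N_ctx the between-group overlap.  The script sizes the pools
for a few sharing levels, wires them onto MSNs, and compares the measured
correlation of summed input counts against the nominal targets and the
exact with-replacement closed form (which corrects for multapse variance).
"""

import numpy as np

from striatumffi import (
    CorticalPoolConfig,
    PopulationLayout,
    expected_count_correlation,
    expected_input_correlation,
    wire_ctx_to_msn,
)

layout = PopulationLayout(120, 0)
rng = np.random.default_rng(0)
for w_in, b_in in [(0.05, 0.5), (0.1, 0.9), (0.5, 0.9)]:
    pool = CorticalPoolConfig.from_sharing(w_in, b_in)
    wiring = wire_ctx_to_msn(pool, layout, rng)
    mult = np.zeros((layout.n_msn, pool.n_sources))
    np.add.at(mult, (wiring.target, wiring.source), 1)
    counts = mult @ rng.poisson(1.0, size=(pool.n_sources, 2000))
    z = (counts - counts.mean(1, keepdims=True)) / counts.std(1, keepdims=True)
    iu = np.triu_indices(60, 1)
    within = (z[:60][iu[0]] * z[:60][iu[1]]).mean(1).mean()
    between = (z[:60] @ z[60:].T).mean() / 2000
    nom = expected_input_correlation(pool)
    exact = expected_count_correlation(pool)
    print(
        f"W_in={w_in:4.2f} B_in={b_in:3.1f}  pools: N_ctx={pool.n_ctx} N_ol={pool.n_ol}  "
        f"measured ({within:.3f}, {between:.3f})  nominal ({nom[0]:.3f}, {nom[1]:.3f})  "
        f"exact ({exact[0]:.3f}, {exact[1]:.3f})"
    )
print("note: multapses inflate private variance, so measured values track the")
print("exact form; the nominal (W_in, B_in*W_in) targets hold for small W_in.")
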