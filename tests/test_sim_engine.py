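import numpy as np
import pytest

from striatumffi import (
    BackgroundConfig,
    ConnectionRule,
    CorticalPoolConfig,
    PopulationLayout,
    SimConfig,
    Simulation,
    build_frozen_inputs,
    build_striatum,
    dc_firing_rate,
    default_params,
    rheobase,
    simulate_dc_neuron,
)
from conftest import small_layout, small_rules


class TestSingleNeuronOracle:
    @pytest.mark.parametrize("cls,I", [("MSN", 400.0), ("MSN", 360.0), ("FSI", 200.0), ("GPE", 100.0)])
    def test_dc_rate_matches_closed_form(self, cls, I):
        p = default_params(cls)
        assert simulate_dc_neuron(p, I, duration=5000.0) == pytest.approx(
            dc_firing_rate(p, I), rel=0.02
        )

    def test_equilibrium_without_input(self):
        p = default_params("MSN")
        assert simulate_dc_neuron(p, 0.0, duration=1000.0) == 0.0

    def test_numerical_rheobase_matches_closed_form(self):
        """Bisection on the simulated neuron (5 s window) locates the
        threshold current within 1% of g_L*(V_th - E_L)."""
        p = default_params("MSN")
        lo, hi = 300.0, 400.0
        for _ in range(14):
            mid = 0.5 * (lo + hi)
            if simulate_dc_neuron(p, mid, duration=5000.0) > 0:
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(rheobase(p), rel=0.01)


class TestDeterminismAndProtocol:
    def test_identical_seeds_identical_records(self, small_network, small_config):
        a = Simulation(small_network, small_config).run_trial(0)
        b = Simulation(small_network, small_config).run_trial(0)
        assert np.array_equal(a.neuron_ids, b.neuron_ids)
        assert np.array_equal(a.times, b.times)

    def test_trials_differ_in_background_only(self, small_trialset):
        r0, r1 = small_trialset.records[0], small_trialset.records[1]
        assert not (
            len(r0.times) == len(r1.times) and np.array_equal(r0.times, r1.times)
        )

    def test_frozen_stimulus_shared_across_trials(self, small_config):
        lay = small_layout()
        net = build_striatum(lay, small_rules(), seed=1)
        pool = CorticalPoolConfig.from_sharing(0.5, 0.5, k_ctx=20)
        frozen = build_frozen_inputs(pool, lay, small_config.t_total, 3)
        ts = Simulation(net, small_config, frozen).run_trials()
        assert ts.frozen_inputs is frozen
        assert all(r.duration == small_config.t_total for r in ts.records)

    def test_analysis_window_defaults(self):
        cfg = SimConfig()
        assert cfg.analysis_window == (500.0, 2500.0)
        assert cfg.analysis_duration == 2000.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(t_total=400.0, t_warmup=500.0)
        with pytest.raises(ValueError):
            SimConfig(n_trials=0)

    def test_subthreshold_delay_rejected(self):
        lay = PopulationLayout(4, 0)
        rules = {
            "msn_msn": ConnectionRule(
                source="MSN", target="MSN", indegree=1, weight_mean=0.03,
                delay_mean=0.04, delay_halfwidth=0.0, allow_autapse=True,
            )
        }
        net = build_striatum(lay, rules, seed=0)
        with pytest.raises(ValueError, match="at least one time step"):
            Simulation(net, SimConfig(t_total=100.0, t_warmup=10.0))


class TestDynamicsInvariants:
    def test_refractory_interval_respected(self, small_trialset):
        for rec in small_trialset.records:
            for nid in np.unique(rec.neuron_ids):
                isi = np.diff(rec.spike_times(nid))
                assert np.all(isi >= 2.0 - 1e-9)

    def test_zero_background_zero_spikes(self, small_network, small_config):
        quiet = BackgroundConfig(msn_rate=0.0, fsi_rate=0.0)
        rec = Simulation(small_network, small_config, background=quiet).run_trial(0)
        assert len(rec.times) == 0

    def test_inhibitory_delivery_silences_target(self):
        """A spiking neuron's inhibitory synapse suppresses a target held
        just above rheobase (checks spike delivery through the ring buffer)."""
        lay = PopulationLayout(2, 0)
        rules = {
            "msn_msn": ConnectionRule(
                source="MSN", target="MSN", indegree=1, weight_mean=20.0,
                weight_log_sd=0.0, delay_mean=2.0, delay_halfwidth=0.0,
                allow_autapse=True,
            )
        }
        net = build_striatum(lay, rules, seed=12)
        cfg = SimConfig(t_total=2000.0, t_warmup=100.0, n_trials=1, master_seed=0, init_mode="e_l")
        quiet = BackgroundConfig(msn_rate=0.0, fsi_rate=0.0)
        sim = Simulation(net, cfg, background=quiet)
        sim.I_dc[:] = 355.0  # just above the 350 pA rheobase
        rec = sim.run_trial(0)
        rates = [len(rec.spike_times(i)) for i in range(2)]
        free = dc_firing_rate(default_params("MSN"), 355.0) * 2.0
        # with mutual strong inhibition both neurons fire well below the free rate
        assert all(0 < r < 0.7 * free for r in rates)

    def test_removing_inhibition_never_lowers_msn_rate(self):
        lay = small_layout()
        rules = small_rules()
        net = build_striatum(lay, rules, seed=8)
        cfg = SimConfig(t_total=1200.0, t_warmup=200.0, n_trials=2, master_seed=5)
        with_ffi = Simulation(net, cfg).run_trials()
        no_weights = build_striatum(lay, rules, seed=8)
        fsi_syn = no_weights.pre >= lay.n_msn
        no_weights.weight[fsi_syn] = 1e-12
        without_ffi = Simulation(no_weights, cfg).run_trials()
        w = cfg.analysis_window
        assert without_ffi.mean_rate(lay.msn_ids) >= with_ffi.mean_rate(lay.msn_ids)

    def test_dt_convergence_of_population_rates(self):
        """Halving dt changes evoked population rates by < 3%."""
        lay = PopulationLayout(2500, 250)
        net = build_striatum(lay, seed=21)
        pool = CorticalPoolConfig.from_sharing(0.1, 0.9)
        rates = {}
        for dt in (0.1, 0.05):
            cfg = SimConfig(dt=dt, t_total=1500.0, t_warmup=500.0, n_trials=1, master_seed=13)
            frozen = build_frozen_inputs(pool, lay, cfg.t_total, 17)
            rec = Simulation(net, cfg, frozen).run_trial(0)
            w = cfg.analysis_window
            rates[dt] = (rec.mean_rate(lay.msn_ids, w), rec.mean_rate(lay.fsi_ids, w))
        for a, b in zip(rates[0.1], rates[0.05]):
            assert a == pytest.approx(b, rel=0.03)


def test_spike_record_csv_round_trip(small_trialset, tmp_path):
    import pandas as pd

    rec = small_trialset.records[0]
    path = tmp_path / "spikes.csv"
    rec.to_csv(path)
    df = pd.read_csv(path)
    assert len(df) == len(rec.times)
    assert list(df.columns) == ["neuron_id", "time_ms"]
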