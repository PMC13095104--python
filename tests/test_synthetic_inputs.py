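import numpy as np
import pytest

from striatumffi import (
    BackgroundConfig,
    CorticalPoolConfig,
    PopulationLayout,
    build_frozen_inputs,
    expected_count_correlation,
    expected_input_correlation,
    generate_poisson_trains,
    pool_sizes_from_sharing,
    wire_ctx_to_fsi,
    wire_ctx_to_msn,
)


class TestPoolSizes:
    @pytest.mark.parametrize(
        "w,b,expected",
        [(0.1, 0.5, (1000, 500)), (1.0, 0.0, (100, 0)), (0.15, 0.1, (667, 67))],
    )
    def test_inversion_and_rounding(self, w, b, expected):
        assert pool_sizes_from_sharing(w, b, 100) == expected

    def test_invalid_sharing_rejected(self):
        with pytest.raises(ValueError):
            pool_sizes_from_sharing(0.0, 0.5)
        with pytest.raises(ValueError):
            pool_sizes_from_sharing(0.5, 1.5)

    def test_pool_overlap_block(self):
        pool = CorticalPoolConfig.from_sharing(0.1, 0.9)
        shared = np.intersect1d(pool.pool_a, pool.pool_b)
        assert len(shared) == pool.n_ol
        assert pool.n_sources == 2 * pool.n_ctx - pool.n_ol


class TestPoissonTrains:
    def test_zero_rate_empty(self):
        trains = generate_poisson_trains(0.0, 5, 1000.0, seed=0)
        assert all(len(t) == 0 for t in trains)

    def test_count_statistics(self):
        trains = generate_poisson_trains(10.0, 1000, 2000.0, seed=1)
        counts = np.array([len(t) for t in trains])
        assert counts.mean() == pytest.approx(20.0, rel=0.05)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.15)

    def test_determinism_and_sorted(self):
        a = generate_poisson_trains(10.0, 20, 500.0, seed=5)
        b = generate_poisson_trains(10.0, 20, 500.0, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert all(np.all(np.diff(t) >= 0) for t in a)

    def test_independence_of_sources(self):
        trains = generate_poisson_trains(50.0, 40, 100_000.0, seed=2)
        edges = np.arange(0, 100_001, 100.0)
        counts = np.array([np.histogram(t, bins=edges)[0] for t in trains])
        z = (counts - counts.mean(1, keepdims=True)) / counts.std(1, keepdims=True)
        iu = np.triu_indices(40, 1)
        r = (z[iu[0]] * z[iu[1]]).mean(axis=1)
        # null sd ~ 1/sqrt(1000 bins); the pair average must sit at zero
        assert abs(r.mean()) < 0.005
        assert np.abs(r).max() < 4.5 / np.sqrt(1000)


class TestCtxWiring:
    layout = PopulationLayout(200, 10)

    def test_msn_indegree_exact(self):
        pool = CorticalPoolConfig.from_sharing(0.25, 0.5)
        wiring = wire_ctx_to_msn(pool, self.layout, np.random.default_rng(0))
        indeg = np.bincount(wiring.target, minlength=self.layout.n_total)
        assert np.all(indeg[: self.layout.n_msn] == 100)
        # group A only draws from pool A, group B from pool B
        a_sources = wiring.source[wiring.target < 100]
        assert a_sources.max() < pool.n_ctx

    def test_multapse_frequency_tracks_pool_size(self):
        rng = np.random.default_rng(1)
        lay = PopulationLayout(100, 0)
        tight = wire_ctx_to_msn(CorticalPoolConfig(n_ctx=100, n_ol=0), lay, rng)
        sparse = wire_ctx_to_msn(CorticalPoolConfig(n_ctx=10_000, n_ol=0), lay, rng)

        def multapse_fraction(w):
            frac = []
            for t in range(100):
                src = w.source[w.target == t]
                frac.append(1 - len(np.unique(src)) / len(src))
            return np.mean(frac)

        assert multapse_fraction(tight) > 0.2  # 100 draws from 100 sources collide often
        assert multapse_fraction(sparse) < 0.02

    def test_fsi_draws_from_both_pools(self):
        pool = CorticalPoolConfig.from_sharing(0.1, 0.5)
        wiring = wire_ctx_to_fsi(pool, self.layout, np.random.default_rng(2))
        indeg = np.bincount(wiring.target, minlength=self.layout.n_total)
        assert np.all(indeg[self.layout.n_msn :] == 200)
        # overlap sources are drawn from both pools: double expected multiplicity
        counts = np.bincount(wiring.source, minlength=pool.n_sources)
        overlap = np.intersect1d(pool.pool_a, pool.pool_b)
        private = np.setdiff1d(np.arange(pool.n_sources), overlap)
        assert counts[overlap].mean() == pytest.approx(2 * counts[private].mean(), rel=0.15)

    def test_fsi_total_mode_and_empty(self):
        pool = CorticalPoolConfig.from_sharing(0.1, 0.5)
        wiring = wire_ctx_to_fsi(pool, self.layout, np.random.default_rng(3), mode="total")
        indeg = np.bincount(wiring.target, minlength=self.layout.n_total)
        assert np.all(indeg[self.layout.n_msn :] == 100)
        empty = wire_ctx_to_fsi(pool, PopulationLayout(200, 0), np.random.default_rng(4))
        assert empty.n_synapses == 0


class TestInputCorrelationOracle:
    @pytest.mark.parametrize("w,b", [(0.1, 0.9), (0.5, 0.0)])
    def test_nominal_formula(self, w, b):
        pool = CorticalPoolConfig.from_sharing(w, b)
        within, between = expected_input_correlation(pool)
        assert within == pytest.approx(w, abs=1e-9)
        assert between == pytest.approx(b * w, abs=1e-9)

    def test_exact_form_reduces_to_nominal_for_large_pools(self):
        pool = CorticalPoolConfig.from_sharing(0.01, 0.5)
        nom = expected_input_correlation(pool)
        exact = expected_count_correlation(pool)
        assert exact[0] == pytest.approx(nom[0], abs=0.001)
        assert exact[1] == pytest.approx(nom[1], abs=0.001)


class TestFrozenInputs:
    def test_frozen_realization_is_reproducible(self):
        lay = PopulationLayout(50, 4)
        pool = CorticalPoolConfig.from_sharing(0.5, 0.5)
        a = build_frozen_inputs(pool, lay, 1000.0, master_seed=9)
        b = build_frozen_inputs(pool, lay, 1000.0, master_seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.trains, b.trains))
        assert np.array_equal(a.msn_wiring.weight, b.msn_wiring.weight)
        assert np.array_equal(a.fsi_wiring.delay, b.fsi_wiring.delay)

    def test_delays_positive_and_bounded(self):
        lay = PopulationLayout(50, 4)
        pool = CorticalPoolConfig.from_sharing(0.5, 0.5)
        f = build_frozen_inputs(pool, lay, 1000.0, master_seed=9)
        for wiring in (f.msn_wiring, f.fsi_wiring):
            assert wiring.delay.min() >= 0.1
            assert wiring.delay.max() <= 2.0

    def test_trains_csv_export(self, tmp_path):
        import pandas as pd

        lay = PopulationLayout(10, 0)
        pool = CorticalPoolConfig.from_sharing(1.0, 0.0)
        f = build_frozen_inputs(pool, lay, 500.0, master_seed=1)
        path = tmp_path / "trains.csv"
        f.trains_to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == sum(len(t) for t in f.trains)


def test_background_control_condition_rate():
    assert BackgroundConfig.for_layout(PopulationLayout(2500, 0)).msn_rate == 3.2
    assert BackgroundConfig.for_layout(PopulationLayout(2500, 250)).msn_rate == 5.95
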