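import numpy as np
import pytest

from striatumffi import (
    PopulationLayout,
    SimConfig,
    SpikeRecord,
    TrialSet,
    across_trial_fano,
    bin_population_counts,
    burst_index,
    correlation_transfer,
    gpe_count_fano,
    pairwise_correlation,
)
from striatumffi.spike_stats import _sample_pairs


def make_trialset(trains_per_trial, n_neurons, t_total=2500.0, t_warmup=500.0):
    """TrialSet from explicit per-trial {neuron: spike times} dicts."""
    layout = PopulationLayout(max(2, n_neurons + n_neurons % 2), 0)
    cfg = SimConfig(t_total=t_total, t_warmup=t_warmup, n_trials=max(1, len(trains_per_trial)))
    records = []
    for trains in trains_per_trial:
        ids = np.concatenate(
            [np.full(len(t), nid, dtype=np.int64) for nid, t in trains.items()]
        ) if trains else np.empty(0, dtype=np.int64)
        times = np.concatenate([np.asarray(t, float) for t in trains.values()]) if trains else np.empty(0)
        records.append(SpikeRecord(ids, times, layout.n_total, t_total))
    return TrialSet(records, cfg, layout)


class TestBinning:
    def test_direct_binning_example(self):
        ts = make_trialset([{0: [1001.0, 1003.0]}], 2)
        counts = bin_population_counts(ts, np.array([0]), 2.0).counts[0]
        nz = np.flatnonzero(counts)
        assert counts.sum() == 2
        assert len(nz) == 2 and nz[1] == nz[0] + 1

    def test_empty_and_conservation(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(500, 2500, 1000))
        ts = make_trialset([{0: spikes, 1: []}], 2)
        counts = bin_population_counts(ts, np.array([0, 1]), 2.0).counts
        assert counts.sum() == np.sum((spikes > 500) & (spikes <= 2500))
        ts0 = make_trialset([{}], 2)
        assert bin_population_counts(ts0, np.array([0]), 2.0).counts.sum() == 0

    def test_empty_subset_rejected(self):
        ts = make_trialset([{0: [600.0]}], 2)
        with pytest.raises(ValueError):
            bin_population_counts(ts, np.array([], dtype=int), 2.0)


class TestAcrossTrialFano:
    def test_identical_trials_give_zero(self):
        trains = {0: np.arange(600.0, 2400.0, 50.0)}
        ts = make_trialset([trains] * 5, 2)
        assert across_trial_fano(ts, np.array([0])).ff == 0.0

    def test_poisson_counts_give_unit_fano(self):
        rng = np.random.default_rng(3)
        trials = [{0: np.sort(rng.uniform(500, 2500, rng.poisson(400)))} for _ in range(60)]
        ts = make_trialset(trials, 2)
        assert across_trial_fano(ts, np.array([0])).ff == pytest.approx(1.0, abs=0.05)

    def test_two_trial_hand_example(self):
        # counts {2, 4} in one bin: sample var 2, mean 3 -> F = 2/3
        ts = make_trialset(
            [{0: [500.5, 501.0]}, {0: [500.2, 500.8, 501.1, 501.9]}],
            2, t_total=502.0, t_warmup=500.0,
        )
        res = across_trial_fano(ts, np.array([0]), bin_ms=2.0)
        assert res.ff == pytest.approx(2.0 / 3.0)

    def test_time_translation_invariance(self):
        rng = np.random.default_rng(4)
        base = [np.sort(rng.uniform(500, 2400, 300)) for _ in range(8)]
        ts_a = make_trialset([{0: t} for t in base], 2)
        ts_b = make_trialset([{0: t + 50.0} for t in base], 2)
        w = (550.0, 2450.0)
        fa = across_trial_fano(ts_a, np.array([0]), window=(500.0, 2400.0)).ff
        fb = across_trial_fano(ts_b, np.array([0]), window=(550.0, 2450.0)).ff
        assert fa == pytest.approx(fb)

    def test_all_silent_undefined(self):
        ts = make_trialset([{}, {}], 2)
        assert np.isnan(across_trial_fano(ts, np.array([0])).ff)


class TestPairwiseCorrelation:
    win = (0.0, 2000.0)

    def test_identical_trains(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 2000, 200))
        assert pairwise_correlation(t, t, 20.0, self.win) == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(1)
        t1 = np.sort(rng.uniform(0, 2000, 10))
        t2 = np.sort(rng.uniform(0, 2000, 10))
        assert abs(pairwise_correlation(t1, t2, 20.0, self.win)) < 0.15

    def test_alternating_bins_anticorrelated(self):
        t1 = np.arange(10.0, 2000.0, 40.0)  # even bins
        t2 = np.arange(30.0, 2000.0, 40.0)  # odd bins
        assert pairwise_correlation(t1, t2, 20.0, self.win) == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        t1 = np.empty(0)
        t2 = np.sort(np.random.default_rng(2).uniform(0, 2000, 50))
        assert np.isnan(pairwise_correlation(t1, t2, 20.0, self.win))


class TestSamplePairs:
    def test_full_enumeration_within(self):
        ids = np.arange(10)
        i, j = _sample_pairs(np.random.default_rng(0), ids, ids, None)
        assert len(i) == 45 and np.all(i < j)

    def test_subsampled_within_valid(self):
        ids = np.arange(100)
        i, j = _sample_pairs(np.random.default_rng(1), ids, ids, 500)
        assert len(i) == 500
        assert np.all(i < j) and np.all(j < 100)
        assert len(set(zip(i.tolist(), j.tolist()))) == 500  # no duplicates

    def test_cross_pairs(self):
        a, b = np.arange(10), np.arange(10, 30)
        i, j = _sample_pairs(np.random.default_rng(2), a, b, 50)
        assert np.all(i < 10) and np.all(j < 20)


class TestCorrelationTransfer:
    def test_identical_trains_full_correlation(self):
        t = np.sort(np.random.default_rng(0).uniform(600, 2400, 300))
        trains = {i: t for i in range(8)}
        ts = make_trialset([trains] * 2, 8)
        res = correlation_transfer(
            ts, np.arange(4), np.arange(4, 8), pair_budget=None
        )
        assert res.w_out == pytest.approx(1.0)
        assert res.b_out == pytest.approx(1.0)

    def test_independent_groups_near_zero(self):
        rng = np.random.default_rng(5)
        trains = {i: np.sort(rng.uniform(500, 2500, 150)) for i in range(20)}
        ts = make_trialset([trains], 20)
        res = correlation_transfer(ts, np.arange(10), np.arange(10, 20), pair_budget=None)
        assert abs(res.w_out) < 0.03 and abs(res.b_out) < 0.03

    def test_shared_fraction_recovery(self):
        """Counts = shared + private Poisson with shared fraction f: the
        measured pairwise correlation recovers f (parameter-recovery oracle)."""
        rng = np.random.default_rng(6)
        f, rate, bin_ms = 0.3, 40.0, 20.0
        t_total = 200_500.0  # 10^4 bins
        win = (500.0, t_total)

        def pool_train(r):
            n = rng.poisson(r * (t_total - 500) / 1000.0)
            return np.sort(rng.uniform(500.0, t_total, n))

        shared_a = pool_train(f * rate)
        shared_b = pool_train(f * rate)
        trains = {}
        for i in range(6):
            trains[i] = np.sort(np.concatenate([shared_a, pool_train((1 - f) * rate)]))
        for i in range(6, 12):
            trains[i] = np.sort(np.concatenate([shared_b, pool_train((1 - f) * rate)]))
        ts = make_trialset([trains], 12, t_total=t_total, t_warmup=500.0)
        res = correlation_transfer(
            ts, np.arange(6), np.arange(6, 12), bin_ms=bin_ms, window=win, pair_budget=None
        )
        assert res.w_out == pytest.approx(f, abs=0.02)
        assert res.b_out == pytest.approx(0.0, abs=0.02)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        trains = {i: np.sort(rng.uniform(500, 2500, 100)) for i in range(10)}
        ts = make_trialset([trains], 10)
        ga, gb = np.arange(5), np.arange(5, 10)
        r1 = correlation_transfer(ts, ga, gb, pair_budget=None)
        r2 = correlation_transfer(ts, ga[::-1], gb[::-1], pair_budget=None)
        assert r1.w_out == pytest.approx(r2.w_out)
        assert r1.b_out == pytest.approx(r2.b_out)

    def test_overlapping_groups_rejected(self):
        ts = make_trialset([{0: [600.0]}], 4)
        with pytest.raises(ValueError):
            correlation_transfer(ts, np.array([0, 1]), np.array([1, 2]))


class TestBurstIndex:
    def test_hand_enumerated_example(self):
        # groups of size 4 (burst), 3 (too small under the >3 rule), 1
        spikes = np.array([0.0, 5.0, 10.0, 15.0, 100.0, 105.0, 110.0, 200.0])
        assert burst_index([spikes]).bi == pytest.approx(0.5)
        # the laxer >=3 convention also counts the middle group
        assert burst_index([spikes], min_spikes=3).bi == pytest.approx(7.0 / 8.0)

    def test_all_fast_single_burst(self):
        spikes = np.arange(0.0, 50.0, 5.0)
        assert burst_index([spikes]).bi == 1.0

    def test_slow_firing_no_bursts(self):
        spikes = np.arange(0.0, 500.0, 50.0)
        assert burst_index([spikes]).bi == 0.0

    def test_empty_trials_excluded(self):
        res = burst_index([np.empty(0), np.arange(0.0, 50.0, 5.0)])
        assert res.bi == 1.0 and res.n_trials_used == 1

    def test_translation_invariance(self):
        spikes = np.array([0.0, 5.0, 10.0, 15.0, 100.0, 105.0, 110.0, 200.0])
        assert burst_index([spikes + 1234.5]).bi == burst_index([spikes]).bi


class TestGpeCountFano:
    win = (500.0, 2500.0)

    def test_hand_example(self):
        trains = [np.sort(np.random.default_rng(i).uniform(500, 2500, n)) for i, n in enumerate((38, 42))]
        assert gpe_count_fano(trains, self.win).ff == pytest.approx(0.2)

    def test_identical_counts_zero(self):
        trains = [np.linspace(600, 2400, 50) for _ in range(4)]
        assert gpe_count_fano(trains, self.win).ff == 0.0

    def test_poisson_counts_near_one(self):
        rng = np.random.default_rng(9)
        trains = [np.sort(rng.uniform(500, 2500, rng.poisson(300))) for _ in range(200)]
        assert gpe_count_fano(trains, self.win).ff == pytest.approx(1.0, abs=0.25)

    def test_zero_mean_undefined(self):
        assert np.isnan(gpe_count_fano([np.empty(0)] * 3, self.win).ff)
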