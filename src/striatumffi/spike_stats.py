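"""Trial-based spike statistics.

Four measures characterize the network response across repeated trials of a
frozen stimulus:

* **Across-trial population Fano factor** (``across_trial_fano``): bin the
  summed spike count of a population at 2 ms, compute per-bin
  variance/mean across trials, and average over bins.  This quantifies how
  much the population rate *trajectory* varies from trial to trial; it is 1
  for Poisson counts and 0 for trial-identical activity.
* **Correlation transfer** (``correlation_transfer``): mean pairwise Pearson
  correlation of 20 ms binned single-neuron spike counts, within each MSN
  group (W_out) and between the two groups (B_out), per trial and then
  trial-averaged.  Pairs in which either neuron has zero count variance are
  excluded (not imputed as zero) and counted.
* **Spike-count Fano factor across trials** (``gpe_count_fano``): variance/
  mean of the total spike count in the analysis window, across trials; used
  for the downstream GPe neuron.
* **Burst index** (``burst_index``): fraction of spikes belonging to bursts,
  where a burst is a maximal run of consecutive inter-spike intervals
  shorter than 10 ms comprising more than three spikes; averaged across
  trials.

All computations use the sample variance (ddof=1) and exclude the warmup
segment through an explicit analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sim_engine import SpikeRecord, TrialSet

__all__ = [
    "BinnedCounts",
    "FanoResult",
    "CorrTransferResult",
    "BurstStats",
    "bin_population_counts",
    "binned_unit_counts",
    "across_trial_fano",
    "pairwise_correlation",
    "correlation_transfer",
    "burst_index",
    "gpe_count_fano",
]


@dataclass
class BinnedCounts:
    """Counts per (trial, bin) for one population subset."""

    counts: np.ndarray  # shape (n_trials, n_bins)
    bin_ms: float
    window: tuple[float, float]


@dataclass
class FanoResult:
    ff: float  # mean over valid bins (nan if none valid)
    per_bin: np.ndarray
    bin_ms: float
    n_trials: int
    n_excluded_bins: int = 0


@dataclass
class CorrTransferResult:
    w_out: float
    b_out: float
    per_trial_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_trial_b: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_pairs_within: int = 0
    n_pairs_between: int = 0
    n_excluded: int = 0


@dataclass
class BurstStats:
    bi: float  # mean over trials with spikes
    burst_spikes: int
    total_spikes: int
    n_trials_used: int


def _bin_edges(window: tuple[float, float], bin_ms: float) -> np.ndarray:
    """Full bins only; a trailing partial bin is dropped."""
    t0, t1 = window
    n_bins = int(np.floor((t1 - t0) / bin_ms + 1e-9))
    if n_bins < 1:
        raise ValueError("analysis window shorter than one bin")
    return t0 + bin_ms * np.arange(n_bins + 1)


def bin_population_counts(
    trialset: TrialSet,
    subset: np.ndarray,
    bin_ms: float = 2.0,
    window: tuple[float, float] | None = None,
) -> BinnedCounts:
    """Summed spike counts of ``subset`` per time bin, per trial."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty neuron subset")
    if window is None:
        window = trialset.config.analysis_window
    edges = _bin_edges(window, bin_ms)
    mask = np.zeros(trialset.records[0].n_neurons, dtype=bool)
    mask[subset] = True
    rows = []
    for rec in trialset.records:
        times = rec.times[mask[rec.neuron_ids]]
        rows.append(np.histogram(times, bins=edges)[0])
    return BinnedCounts(np.array(rows), bin_ms, window)


def binned_unit_counts(
    rec: SpikeRecord,
    ids: np.ndarray,
    bin_ms: float,
    window: tuple[float, float],
) -> np.ndarray:
    """Per-neuron binned counts, shape (len(ids), n_bins)."""
    edges = _bin_edges(window, bin_ms)
    n_bins = len(edges) - 1
    id_pos = -np.ones(rec.n_neurons, dtype=np.int64)
    id_pos[ids] = np.arange(len(ids))
    pos = id_pos[rec.neuron_ids]
    keep = (pos >= 0) & (rec.times > edges[0]) & (rec.times <= edges[-1])
    b = np.ceil((rec.times[keep] - edges[0]) / bin_ms).astype(np.int64) - 1
    b = np.clip(b, 0, n_bins - 1)
    out = np.zeros((len(ids), n_bins), dtype=np.int64)
    np.add.at(out, (pos[keep], b), 1)
    return out


def across_trial_fano(
    trialset: TrialSet,
    subset: np.ndarray,
    bin_ms: float = 2.0,
    window: tuple[float, float] | None = None,
) -> FanoResult:
    """Across-trial Fano factor of the population count trajectory.

    For each bin i, F_i = var_trials(count_i) / mean_trials(count_i) with
    sample variance; bins with zero mean are excluded; the index is the mean
    of the valid F_i.
    """
    if trialset.n_trials < 2:
        raise ValueError("need at least 2 trials for across-trial variance")
    binned = bin_population_counts(trialset, subset, bin_ms, window)
    counts = binned.counts.astype(float)
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    valid = mean > 0
    per_bin = np.full(counts.shape[1], np.nan)
    per_bin[valid] = var[valid] / mean[valid]
    if not valid.any():
        return FanoResult(float("nan"), per_bin, bin_ms, trialset.n_trials, int((~valid).sum()))
    return FanoResult(
        float(np.nanmean(per_bin)), per_bin, bin_ms, trialset.n_trials, int((~valid).sum())
    )


def pairwise_correlation(
    train_i: np.ndarray,
    train_j: np.ndarray,
    bin_ms: float = 20.0,
    window: tuple[float, float] = (0.0, 2000.0),
) -> float:
    """Pearson correlation of binned spike counts of two trains.

    Returns nan (undefined) when either train has zero count variance.
    """
    edges = _bin_edges(window, bin_ms)
    x = np.histogram(train_i, bins=edges)[0].astype(float)
    y = np.histogram(train_j, bins=edges)[0].astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _sample_pairs(
    rng: np.random.Generator, ids_a: np.ndarray, ids_b: np.ndarray, budget: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct-index pairs, uniformly subsampled when over budget.

    For within-group sampling pass ids_a is ids_b; pairs (i, i) are excluded.
    """
    same = ids_a is ids_b or (len(ids_a) == len(ids_b) and np.array_equal(ids_a, ids_b))
    if same:
        n = len(ids_a)
        total = n * (n - 1) // 2
    else:
        total = len(ids_a) * len(ids_b)
    if budget is None or budget >= total:
        if same:
            iu = np.triu_indices(len(ids_a), k=1)
            return iu[0], iu[1]
        i, j = np.meshgrid(np.arange(len(ids_a)), np.arange(len(ids_b)), indexing="ij")
        return i.ravel(), j.ravel()
    if same:
        # rejection-free: draw flat indices over the strict upper triangle
        flat = rng.choice(total, size=budget, replace=False)
        # invert the triangular index
        i = (
            len(ids_a)
            - 2
            - np.floor(np.sqrt(-8 * flat + 4 * len(ids_a) * (len(ids_a) - 1) - 7) / 2 - 0.5)
        ).astype(np.int64)
        j = (flat + i + 1 - i * (2 * len(ids_a) - i - 1) // 2).astype(np.int64)
        return i, j
    flat = rng.choice(total, size=budget, replace=False)
    return flat // len(ids_b), flat % len(ids_b)


def correlation_transfer(
    trialset: TrialSet,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
    bin_ms: float = 20.0,
    window: tuple[float, float] | None = None,
    pair_budget: int | None = 5000,
    seed: int = 0,
) -> CorrTransferResult:
    """Trial-averaged output correlations (W_out, B_out).

    W_out is the mean of the two within-group mean pair correlations (equal
    to the symmetric normalized pair-sum for equal group sizes); B_out the
    mean over cross-group pairs.  Pairs with an undefined correlation
    (zero-variance counts) are excluded from the means.  At the default
    network scale full pair enumeration is quadratic, so ``pair_budget``
    pairs per category are subsampled with a fixed seed (pass None for full
    enumeration); the same pairs are reused for every trial.
    """
    layout = trialset.layout
    if group_a is None:
        group_a = layout.group_a
    if group_b is None:
        group_b = layout.group_b
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    if window is None:
        window = trialset.config.analysis_window

    rng = np.random.default_rng(seed)
    ia1, ia2 = _sample_pairs(rng, group_a, group_a, pair_budget)
    ib1, ib2 = _sample_pairs(rng, group_b, group_b, pair_budget)
    ix, jx = _sample_pairs(rng, group_a, group_b, pair_budget)

    w_trials, b_trials = [], []
    n_excluded = 0
    for rec in trialset.records:
        ca = binned_unit_counts(rec, group_a, bin_ms, window).astype(float)
        cb = binned_unit_counts(rec, group_b, bin_ms, window).astype(float)

        def _zscore(c):
            mu = c.mean(axis=1, keepdims=True)
            sd = c.std(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                z = (c - mu) / sd
            return z, (sd[:, 0] > 0)

        za, va = _zscore(ca)
        zb, vb = _zscore(cb)
        n_bins = ca.shape[1]

        def _mean_r(z1, v1, i1, z2, v2, i2):
            nonlocal n_excluded
            ok = v1[i1] & v2[i2]
            n_excluded += int((~ok).sum())
            if not ok.any():
                return float("nan")
            r = (z1[i1[ok]] * z2[i2[ok]]).sum(axis=1) / n_bins
            return float(r.mean())

        wa = _mean_r(za, va, ia1, za, va, ia2)
        wb = _mean_r(zb, vb, ib1, zb, vb, ib2)
        w_trials.append(np.nanmean([wa, wb]))
        b_trials.append(_mean_r(za, va, ix, zb, vb, jx))

    w_arr = np.array(w_trials)
    b_arr = np.array(b_trials)
    if np.all(np.isnan(w_arr)) and np.all(np.isnan(b_arr)):
        raise ValueError("no valid pairs in any trial")
    return CorrTransferResult(
        w_out=float(np.nanmean(w_arr)),
        b_out=float(np.nanmean(b_arr)),
        per_trial_w=w_arr,
        per_trial_b=b_arr,
        n_pairs_within=len(ia1) + len(ib1),
        n_pairs_between=len(ix),
        n_excluded=n_excluded,
    )


def burst_index(
    trains: list[np.ndarray],
    max_isi_ms: float = 10.0,
    min_spikes: int = 4,
) -> BurstStats:
    """Fraction of spikes in bursts, averaged across trials.

    A burst is a maximal run of consecutive spikes whose inter-spike
    intervals are all below ``max_isi_ms`` and which contains at least
    ``min_spikes`` spikes (default 4, i.e. strictly more than three; pass 3
    for the laxer convention).  Trials without spikes are excluded from the
    average.
    """
    per_trial = []
    burst_total = 0
    spike_total = 0
    for train in trains:
        train = np.sort(np.asarray(train))
        n = len(train)
        spike_total += n
        if n == 0:
            continue
        short = np.diff(train) < max_isi_ms
        # run lengths of consecutive short ISIs -> group sizes
        burst_spikes = 0
        run = 0
        for s in short:
            if s:
                run += 1
            else:
                if run + 1 >= min_spikes:
                    burst_spikes += run + 1
                run = 0
        if run + 1 >= min_spikes:
            burst_spikes += run + 1
        burst_total += burst_spikes
        per_trial.append(burst_spikes / n)
    if not per_trial:
        return BurstStats(float("nan"), 0, spike_total, 0)
    return BurstStats(float(np.mean(per_trial)), burst_total, spike_total, len(per_trial))


def gpe_count_fano(
    trains: list[np.ndarray],
    window: tuple[float, float],
) -> FanoResult:
    """Fano factor of the total spike count in the window, across trials."""
    if len(trains) < 2:
        raise ValueError("need at least 2 trials")
    counts = np.array(
        [np.sum((np.asarray(t) > window[0]) & (np.asarray(t) <= window[1])) for t in trains],
        dtype=float,
    )
    mean = counts.mean()
    if mean == 0:
        return FanoResult(float("nan"), counts, window[1] - window[0], len(trains), 1)
    return FanoResult(
        float(counts.var(ddof=1) / mean), counts, window[1] - window[0], len(trains)
    )
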