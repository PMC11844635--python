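"""Per-unit sharp wave-ripple participation metrics and population PETH.

For each unit: baseline vs in-event rate and their ratio (SPW-R modulation
gain), average spikes per participated event, in-event inter-spike interval,
time of the first in-event spike relative to the event peak, correlation of
binned spiking with ripple-band power, participation fraction, ripple-phase
statistics, and a ZETA-style responsiveness p-value to event peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circular import PhaseStats, phase_stats, spike_phases
from .core import EpochTable, EventTable, SpikeTrain, interval_intersect, interval_union
from .lfp import AnalyticSignal
from .optotag import zeta_test


@dataclass
class SpwrUnitMetrics:
    unit_id: str
    baseline_rate_hz: float
    event_rate_hz: float
    modulation_gain: float  # inf when baseline rate is 0 (flagged degenerate)
    zeta_p: float
    avg_spikes_per_event: float
    isi_in_event_ms: float
    time_to_first_spike_ms: float  # relative to event peak; negative = before
    rate_power_corr: float
    participation_fraction: float
    ripple_phase: PhaseStats


def peth_zscored(
    trains: list[SpikeTrain],
    event_peaks: np.ndarray,
    window_s: float = 0.5,
    bin_s: float = 0.01,
    baseline_frac: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit x bin peri-event z-scored rate matrix centered on event peaks.

    Each unit's rate is z-scored against its own window-edge bins (the outer
    ``baseline_frac`` of bins on each side). Units with no spikes in the
    window give an all-zero row.
    """
    peaks = np.asarray(event_peaks, float)
    if peaks.size < 10:
        raise ValueError("need at least 10 events")
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    n_edge = max(1, int(round(baseline_frac * centers.size / 2)))
    base_idx = np.r_[np.arange(n_edge), np.arange(centers.size - n_edge, centers.size)]
    out = np.zeros((len(trains), centers.size))
    for i, tr in enumerate(trains):
        counts = np.zeros(centers.size)
        for pk in peaks:
            i0 = np.searchsorted(tr.times, pk - window_s)
            i1 = np.searchsorted(tr.times, pk + window_s)
            counts += np.histogram(tr.times[i0:i1] - pk, bins=edges)[0]
        rate = counts / (peaks.size * bin_s)
        mu, sd = rate[base_idx].mean(), rate[base_idx].std()
        if sd > 0:
            out[i] = (rate - mu) / sd
    return centers, out


def _valid_time(
    intervals: np.ndarray, valid_epochs: EpochTable | None, t0: float, t1: float
) -> float:
    iv = interval_union(intervals)
    if valid_epochs is not None and len(valid_epochs):
        iv = interval_intersect(iv, interval_union(valid_epochs.intervals))
    else:
        iv = interval_intersect(iv, np.array([[t0, t1]]))
    return float(np.sum(iv[:, 1] - iv[:, 0])) if len(iv) else 0.0


def rate_power_correlation(
    train: SpikeTrain,
    envelope: np.ndarray,
    fs: float,
    valid_epochs: EpochTable | None = None,
    bin_s: float = 0.01,
) -> float:
    """Pearson correlation of binned spike counts with ripple-band power.

    Spikes and envelope are binned at ``bin_s`` (10 ms default); bins whose
    centers fall outside ``valid_epochs`` are dropped.
    """
    dur = envelope.size / fs
    edges = np.arange(0, dur + bin_s / 2, bin_s)
    if edges.size < 3:
        return np.nan
    counts = np.histogram(train.times, bins=edges)[0].astype(float)
    samp_bin = np.minimum((edges[:-1] * fs).astype(int), envelope.size - 1)
    samp_end = np.minimum((edges[1:] * fs).astype(int), envelope.size)
    env_bin = np.array(
        [envelope[a:b].mean() if b > a else np.nan for a, b in zip(samp_bin, samp_end)]
    )
    centers = (edges[:-1] + edges[1:]) / 2
    keep = ~np.isnan(env_bin)
    if valid_epochs is not None and len(valid_epochs):
        keep &= valid_epochs.contains(centers)
    if keep.sum() < 3 or np.std(counts[keep]) == 0 or np.std(env_bin[keep]) == 0:
        return np.nan
    return float(stats.pearsonr(counts[keep], env_bin[keep])[0])


def spwr_unit_metrics(
    train: SpikeTrain,
    events: EventTable,
    ripple_analytic: AnalyticSignal | None = None,
    valid_epochs: EpochTable | None = None,
    zeta_window_s: float = 0.1,
    zeta_resamples: int = 250,
    rng: np.random.Generator | None = None,
) -> SpwrUnitMetrics:
    """All per-unit SPW-R participation metrics for one spike train.

    ``valid_epochs`` restricts baseline time and rate-power binning (e.g. to
    non-stimulation periods); events are assumed to lie within them.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    t = train.times
    if valid_epochs is not None and len(valid_epochs):
        t0 = float(valid_epochs.start_s[0])
        t1 = float(valid_epochs.stop_s[-1])
        t = t[valid_epochs.contains(t)]
    else:
        t0, t1 = 0.0, float(max(events.stop_s[-1], t[-1] if t.size else 0))

    ev_epochs = events.as_epochs()
    in_ev_mask = ev_epochs.contains(t)
    n_in = int(in_ev_mask.sum())
    n_out = int(t.size - n_in)

    ev_time = _valid_time(events.intervals, valid_epochs, t0, t1)
    total_valid = (
        valid_epochs.total_duration if valid_epochs is not None and len(valid_epochs)
        else t1 - t0
    )
    out_time = total_valid - ev_time
    baseline_rate = n_out / out_time if out_time > 0 else np.nan
    event_rate = n_in / ev_time if ev_time > 0 else np.nan
    gain = (
        event_rate / baseline_rate
        if baseline_rate and baseline_rate > 0
        else np.inf if n_in else np.nan
    )

    # per-event spike counts, ISIs, and first-spike latency from peak
    counts = np.zeros(len(events), int)
    isis: list[np.ndarray] = []
    first_lat = []
    for i, (s, pk, e) in enumerate(zip(events.start_s, events.peak_s, events.stop_s)):
        i0, i1 = np.searchsorted(t, s), np.searchsorted(t, e)
        counts[i] = i1 - i0
        if counts[i] >= 1:
            first_lat.append(t[i0] - pk)
        if counts[i] >= 2:
            isis.append(np.diff(t[i0:i1]))
    participated = counts >= 1
    participation = float(participated.mean())
    avg_spikes = float(counts[participated].mean()) if participated.any() else np.nan
    isi_ms = float(np.concatenate(isis).mean() * 1e3) if isis else np.nan
    ttfs_ms = float(np.mean(first_lat) * 1e3) if first_lat else np.nan

    if ripple_analytic is not None:
        phases = spike_phases(
            t[in_ev_mask], ripple_analytic.phase, ripple_analytic.fs
        )
        ph = phase_stats(phases)
        rpc = rate_power_correlation(
            SpikeTrain(train.unit_id, t), ripple_analytic.envelope,
            ripple_analytic.fs, valid_epochs,
        )
    else:
        ph = phase_stats(np.empty(0))
        rpc = np.nan

    zp = zeta_test(
        SpikeTrain(train.unit_id, t),
        events.peak_s - zeta_window_s / 2,
        zeta_window_s,
        zeta_resamples,
        rng,
    )
    return SpwrUnitMetrics(
        train.unit_id, float(baseline_rate), float(event_rate), float(gain), float(zp),
        avg_spikes, isi_ms, ttfs_ms, float(rpc), participation, ph,
    )


def group_compare_rates(
    baseline_rates: np.ndarray, event_rates: np.ndarray
) -> tuple[float, float, float]:
    """(median baseline, median in-event, Wilcoxon signed-rank p) over units."""
    b = np.asarray(baseline_rates, float)
    e = np.asarray(event_rates, float)
    if b.size != e.size:
        raise ValueError("paired arrays required")
    if np.all(b == e):
        return float(np.median(b)), float(np.median(e)), 1.0
    p = float(stats.wilcoxon(b, e).pvalue)
    return float(np.median(b)), float(np.median(e)), p
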