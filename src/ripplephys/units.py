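"""Per-unit waveform and spike-timing metrics.

Covers trough-to-peak latency, waveform asymmetry (AB ratio), mean rate,
mean inter-spike interval, burst index (fraction of ISIs below 6 ms), the
spike autocorrelogram, and soma depth relative to the pyramidal layer.
"""

from __future__ import annotations

import numpy as np

from .core import SpikeTrain, UnitInfo

BURST_ISI_S = 0.006  # burst index = fraction of ISIs below 6 ms


def trough_to_peak(waveform: np.ndarray, sample_interval_s: float) -> float:
    """Latency (ms) from the global trough to the subsequent maximum.

    Returns NaN for degenerate (monotone or trough-at-end) waveforms.
    """
    w = np.asarray(waveform, float)
    i_trough = int(np.argmin(w))
    if i_trough >= w.size - 1:
        return np.nan
    i_peak = i_trough + int(np.argmax(w[i_trough:]))
    if i_peak == i_trough:
        return np.nan
    return (i_peak - i_trough) * sample_interval_s * 1e3


def ab_ratio(waveform: np.ndarray) -> float:
    """Waveform asymmetry (b - a) / (b + a).

    ``a`` is the positive peak preceding the global trough and ``b`` the
    positive peak following it; an absent positive lobe contributes 0. When
    both lobes are absent the ratio is defined as 0.
    """
    w = np.asarray(waveform, float)
    i_trough = int(np.argmin(w))
    a = float(max(w[:i_trough].max(), 0.0)) if i_trough > 0 else 0.0
    b = float(max(w[i_trough + 1:].max(), 0.0)) if i_trough < w.size - 1 else 0.0
    if a + b == 0:
        return 0.0
    return (b - a) / (b + a)


def rate_isi_burst(
    train: SpikeTrain, total_time_s: float
) -> tuple[float, float, float]:
    """(mean rate Hz, mean ISI ms, burst index) of one spike train.

    ISI metrics are NaN with fewer than two spikes.
    """
    if total_time_s <= 0:
        raise ValueError("total_time_s must be positive")
    n = train.n_spikes
    rate = n / total_time_s
    if n < 2:
        return rate, np.nan, np.nan
    isi = np.diff(train.times)
    return rate, float(isi.mean() * 1e3), float(np.mean(isi < BURST_ISI_S))


def autocorrelogram(
    train: SpikeTrain, bin_ms: float = 1.0, window_ms: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Spike autocorrelogram: pair-lag counts over +-window, zero-lag excluded.

    Returns ``(lags_ms, counts)`` with ``lags_ms`` the bin centers. The ACG is
    symmetric by construction (every ordered pair counted once per sign).
    """
    bin_s, win_s = bin_ms * 1e-3, window_ms * 1e-3
    n_bins = int(round(win_s / bin_s))
    edges = (np.arange(2 * n_bins + 1) - n_bins) * bin_s
    t = train.times
    counts = np.zeros(2 * n_bins, dtype=float)
    if t.size >= 2:
        # forward lags via sorted sweep, then mirror
        for i in range(t.size):
            j = np.searchsorted(t, t[i] + win_s, side="right")
            lags = t[i + 1: j] - t[i]
            counts += np.histogram(lags, bins=edges)[0]
            counts += np.histogram(-lags, bins=edges)[0]
    centers = (edges[:-1] + edges[1:]) / 2 * 1e3
    return centers, counts


def soma_depth(
    unit: UnitInfo, layer_channel: int, channel_depths: np.ndarray
) -> float:
    """Unit depth (um) relative to the pyramidal-layer channel.

    Positive = below the layer center toward stratum radiatum (the library's
    stated convention). NaN when the unit has no peak channel.
    """
    if unit.peak_channel is None:
        return np.nan
    depths = np.asarray(channel_depths, float)
    return float(depths[unit.peak_channel] - depths[layer_channel])
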