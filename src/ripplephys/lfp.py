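"""LFP filtering, analytic signals, ripple detection, and event spectra.

Ripple detection follows the classical envelope-threshold scheme: band-pass
100-250 Hz, Hilbert envelope, Gaussian smoothing, z-score against a baseline
period, events = stretches above a low threshold containing a sample above a
high threshold, merged across short gaps and bounded in duration. Only the
band is fixed by convention; thresholds and duration bounds are the common
defaults of this detector family and are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .core import EpochTable, EventTable, LfpRecording, interval_union

THETA_BAND = ("theta", 6.0, 12.0)
RIPPLE_BAND = ("ripple", 100.0, 250.0)
SPIKE_BAND = ("spike", 300.0, 500.0)


@dataclass
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError("need 0 < lo < hi")


THETA = BandDefinition(*THETA_BAND)
RIPPLE = BandDefinition(*RIPPLE_BAND)
SPIKE = BandDefinition(*SPIKE_BAND)


@dataclass
class AnalyticSignal:
    """Instantaneous phase (radians, [0, 2pi)) and envelope of a narrowband signal.

    Phase convention: 0 at the signal peak, pi at the trough, descending limb
    in (0, pi), ascending limb in (pi, 2pi) — i.e. the phase of the analytic
    continuation of a cosine.
    """

    phase: np.ndarray
    envelope: np.ndarray
    fs: float


def bandpass(
    x: np.ndarray, band: BandDefinition, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    if band.hi_hz >= fs / 2:
        raise ValueError(f"band {band.name} upper edge {band.hi_hz} >= Nyquist {fs/2}")
    sos = signal.butter(order, [band.lo_hz, band.hi_hz], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, float))


def analytic(filtered: np.ndarray, fs: float) -> AnalyticSignal:
    """Hilbert-transform phase and envelope of a band-passed signal."""
    z = signal.hilbert(np.asarray(filtered, float))
    return AnalyticSignal(np.mod(np.angle(z), 2 * np.pi), np.abs(z), fs)


@dataclass
class RippleDetectionParams:
    band: BandDefinition = field(default_factory=lambda: BandDefinition(*RIPPLE_BAND))
    low_thresh_sd: float = 2.0
    high_thresh_sd: float = 5.0
    smooth_sigma_s: float = 0.008
    min_duration_s: float = 0.015
    max_duration_s: float = 0.250
    merge_gap_s: float = 0.015


def _zscore_envelope(
    env: np.ndarray, fs: float, exclude: EpochTable | None
) -> np.ndarray:
    """z-score against all samples outside the excluded epochs."""
    if exclude is not None and len(exclude):
        t = np.arange(env.size) / fs
        base = env[~exclude.contains(t)]
    else:
        base = env
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd == 0:
        raise ValueError("flat signal: envelope has zero variance")
    return (env - mu) / sd


def detect_ripples(
    x: np.ndarray,
    fs: float,
    params: RippleDetectionParams | None = None,
    exclude_epochs: EpochTable | None = None,
) -> EventTable:
    """Detect ripple events on one LFP channel by envelope thresholding.

    ``exclude_epochs`` (e.g. optical stimulation) are excluded from the
    baseline used for z-scoring so stimulation-driven power does not inflate
    the reference distribution; detection itself runs on the whole trace.
    """
    p = params or RippleDetectionParams()
    filt = bandpass(x, p.band, fs)
    env = np.abs(signal.hilbert(filt))
    env = gaussian_filter1d(env, sigma=p.smooth_sigma_s * fs)
    z = _zscore_envelope(env, fs, exclude_epochs)

    above = z > p.low_thresh_sd
    if not above.any():
        return EventTable(*(np.empty(0),) * 3)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]

    # merge events separated by less than merge_gap
    gap = int(round(p.merge_gap_s * fs))
    m_starts, m_stops = [starts[0]], [stops[0]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - m_stops[-1] < gap:
            m_stops[-1] = e
        else:
            m_starts.append(s)
            m_stops.append(e)

    rows = []
    for s, e in zip(m_starts, m_stops):
        seg = z[s:e]
        if seg.max() < p.high_thresh_sd:
            continue
        dur = (e - s) / fs
        if not (p.min_duration_s <= dur <= p.max_duration_s):
            continue
        pk = s + int(np.argmax(seg))
        freq = event_frequency(x, fs, s / fs, e / fs, p.band)
        rows.append((s / fs, pk / fs, e / fs, float(seg.max()), freq))
    if not rows:
        return EventTable(*(np.empty(0),) * 3)
    arr = np.array(rows, float)
    return EventTable(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])


def event_frequency(
    x: np.ndarray,
    fs: float,
    start_s: float,
    stop_s: float,
    band: BandDefinition | None = None,
) -> float:
    """Dominant in-band frequency of one event (peak of its power spectrum).

    Returns NaN for events shorter than two cycles of the band's low edge.
    """
    band = band or RIPPLE
    if (stop_s - start_s) < 2.0 / band.lo_hz:
        return np.nan
    i0, i1 = int(round(start_s * fs)), int(round(stop_s * fs))
    seg = np.asarray(x[i0:i1], float)
    seg = seg - seg.mean()
    nfft = max(4096, int(2 ** np.ceil(np.log2(seg.size))))
    f, pxx = signal.periodogram(seg, fs=fs, window="hann", nfft=nfft)
    inband = (f >= band.lo_hz) & (f <= band.hi_hz)
    return float(f[inband][np.argmax(pxx[inband])])


def peri_stim_spectrogram(
    x: np.ndarray,
    fs: float,
    epochs: EpochTable,
    window_s: tuple[float, float] = (-0.3, 0.3),
    nperseg_s: float = 0.05,
    overlap_frac: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean short-time power spectrum around pulse onsets.

    Returns ``(freqs, times, power)`` where ``times`` are seconds relative to
    onset and ``power`` is the time x frequency matrix averaged over pulses.
    Pulses whose window falls outside the recording are skipped.
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    nperseg = int(round(nperseg_s * fs))
    noverlap = int(round(nperseg * overlap_frac))
    pre, post = window_s
    n_pre, n_post = int(round(-pre * fs)), int(round(post * fs))
    acc, count = None, 0
    for onset in epochs.start_s:
        i0 = int(round(onset * fs)) - n_pre
        i1 = int(round(onset * fs)) + n_post
        if i0 < 0 or i1 > x.size:
            continue
        f, t, sxx = signal.spectrogram(
            np.asarray(x[i0:i1], float), fs=fs, nperseg=nperseg, noverlap=noverlap,
            window="hann", mode="psd",
        )
        acc = sxx if acc is None else acc + sxx
        count += 1
    if count == 0:
        raise ValueError("no epoch window fits inside the recording")
    power = (acc / count).T  # time x frequency
    times = t + pre
    return f, times, power


def band_power_contrast(
    freqs: np.ndarray,
    times: np.ndarray,
    power: np.ndarray,
    band: BandDefinition,
    pre_window: tuple[float, float] = (-0.3, 0.0),
    post_window: tuple[float, float] = (0.0, 0.3),
) -> tuple[float, float]:
    """Mean in-band power in the pre vs post windows of a peri-stimulus spectrogram."""
    fmask = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    pre_mask = (times >= pre_window[0]) & (times < pre_window[1])
    post_mask = (times >= post_window[0]) & (times < post_window[1])
    pre = float(power[np.ix_(pre_mask, fmask)].mean())
    post = float(power[np.ix_(post_mask, fmask)].mean())
    return pre, post


def ripple_envelope(x: np.ndarray, fs: float, band: BandDefinition | None = None,
                    smooth_sigma_s: float = 0.008) -> np.ndarray:
    """Smoothed ripple-band envelope of one channel (helper for power metrics)."""
    env = np.abs(signal.hilbert(bandpass(x, band or RIPPLE, fs)))
    return gaussian_filter1d(env, sigma=smooth_sigma_s * fs)


def find_pyramidal_layer(
    lfp: LfpRecording,
    events: EventTable | None = None,
    params: RippleDetectionParams | None = None,
) -> int:
    """Channel index maximizing mean ripple-band envelope during ripple events.

    When no event table is given, ripples are detected independently on every
    channel and the union of detected intervals is used. Ties break toward
    the smaller channel index.
    """
    if lfp.n_channels == 1:
        return 0
    if events is None:
        ivs = []
        for ch in range(lfp.n_channels):
            try:
                ev = detect_ripples(lfp.channel_uv(ch), lfp.fs, params)
            except ValueError:
                continue
            if len(ev):
                ivs.append(ev.intervals)
        if not ivs:
            raise ValueError("no ripples detected on any channel")
        iv = interval_union(np.vstack(ivs))
    else:
        if len(events) == 0:
            raise ValueError("empty event table")
        iv = events.intervals
    t = np.arange(lfp.n_samples) / lfp.fs
    mask = EpochTable(iv[:, 0], iv[:, 1]).contains(t)
    means = [
        float(np.mean(ripple_envelope(lfp.channel_uv(ch), lfp.fs)[mask]))
        for ch in range(lfp.n_channels)
    ]
    return int(np.argmax(means))
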