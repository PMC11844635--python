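"""Optogenetic tagging: peri-stimulus histograms and event-responsiveness.

Responsiveness uses a ZETA-style statistic: the maximum mean-centered
deviation between the empirical cumulative distribution of pooled
peri-stimulus spike times and the uniform (linear) baseline, with the null
distribution obtained from random circular shifts of the spike times within
the window. This is timescale-free (no binning choice) and its p-value is an
empirical tail probability, add-one corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochTable, SpikeTrain

DEFAULT_ALPHA = 0.05
DEFAULT_RESAMPLES = 250
MIN_EVENTS = 10


@dataclass
class TagResult:
    unit_id: str
    p_value: float
    direction: str  # {activated, suppressed, none}
    psth_rate: np.ndarray
    psth_bins: np.ndarray
    rate_in: float
    rate_pre: float


def psth(
    train: SpikeTrain,
    onsets: np.ndarray,
    window_s: tuple[float, float] = (-0.1, 0.2),
    bin_s: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Peri-onset firing rate: (bin_centers_s, rate_hz).

    Counts are averaged over pulses and divided by the bin width.
    """
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("need at least one pulse")
    pre, post = window_s
    edges = np.arange(pre, post + bin_s / 2, bin_s)
    counts = np.zeros(edges.size - 1)
    t = train.times
    for on in onsets:
        i0 = np.searchsorted(t, on + pre)
        i1 = np.searchsorted(t, on + post)
        counts += np.histogram(t[i0:i1] - on, bins=edges)[0]
    rate = counts / (onsets.size * bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, rate


def _zeta_stat(rel: np.ndarray, window_s: float) -> float:
    """Max |mean-centered ECDF deviation from uniform| of pooled rel. times."""
    x = np.sort(rel)
    n = x.size
    ecdf = np.arange(1, n + 1) / n
    dev = ecdf - x / window_s
    return float(np.max(np.abs(dev - dev.mean())))


def zeta_test(
    train: SpikeTrain,
    event_onsets: np.ndarray,
    window_s: float,
    n_resamples: int = DEFAULT_RESAMPLES,
    rng: np.random.Generator | None = None,
) -> float:
    """ZETA-style responsiveness p-value of a unit to event onsets.

    Returns 1.0 when there are fewer than 10 events or no spikes fall in the
    pooled window (underpowered, flagged by the degenerate p).
    """
    rng = rng or np.random.default_rng()
    onsets = np.asarray(event_onsets, float)
    if onsets.size < MIN_EVENTS:
        return 1.0
    t = train.times
    rel, eidx = [], []
    for k, on in enumerate(onsets):
        i0 = np.searchsorted(t, on)
        i1 = np.searchsorted(t, on + window_s)
        rel.append(t[i0:i1] - on)
        eidx.append(np.full(i1 - i0, k))
    rel = np.concatenate(rel) if rel else np.empty(0)
    if rel.size == 0:
        return 1.0
    eidx = np.concatenate(eidx)
    stat = _zeta_stat(rel, window_s)
    # null: independent circular shift of each event's spikes within the window
    shifts = rng.uniform(0, window_s, size=(n_resamples, onsets.size))
    null = np.mod(rel[None, :] + shifts[:, eidx], window_s)
    null.sort(axis=1)
    n = rel.size
    ecdf = np.arange(1, n + 1) / n
    dev = ecdf[None, :] - null / window_s
    null_stat = np.max(np.abs(dev - dev.mean(axis=1, keepdims=True)), axis=1)
    return float((1 + np.sum(null_stat >= stat)) / (1 + n_resamples))


def classify_tag(
    train: SpikeTrain,
    pulses: EpochTable,
    alpha: float = DEFAULT_ALPHA,
    window_pad_s: float = 0.05,
    n_resamples: int = DEFAULT_RESAMPLES,
    rng: np.random.Generator | None = None,
) -> TagResult:
    """Classify a unit as opto-activated, opto-suppressed, or untagged.

    Significance comes from the ZETA-style test over a window of the pulse
    duration plus ``window_pad_s``; the direction (the test is unsigned) from
    the in-pulse firing rate against the immediately preceding equal-duration
    baseline.
    """
    onsets = pulses.start_s
    dur = float(np.median(pulses.durations))
    p = zeta_test(train, onsets, dur + window_pad_s, n_resamples, rng)
    t = train.times
    n_in = n_pre = 0
    for on in onsets:
        n_in += np.searchsorted(t, on + dur) - np.searchsorted(t, on)
        n_pre += np.searchsorted(t, on) - np.searchsorted(t, on - dur)
    total = onsets.size * dur
    rate_in, rate_pre = n_in / total, n_pre / total
    if p < alpha:
        direction = "activated" if rate_in >= rate_pre else "suppressed"
    else:
        direction = "none"
    centers, rate = psth(train, onsets, window_s=(-dur, 2 * dur), bin_s=dur / 20)
    return TagResult(train.unit_id, p, direction, rate, centers, rate_in, rate_pre)
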