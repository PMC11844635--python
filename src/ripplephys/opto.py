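"""Contrasts of network and unit activity inside vs outside opto-silencing.

Events are first classified against stimulation pulses ("peak_in": the event
peak falls inside a pulse; "fully_within": the whole event lies inside one
pulse). Events that touch a pulse (or its guard window) without meeting the
criterion are excluded from both groups so the control group stays clean.
Event-property and participation contrasts then use rank-sum (independent
groups) or signed-rank (paired, per unit) tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import EpochTable, EventTable, SpikeTrain

BASELINE, STIM, EXCLUDED = "baseline", "stim", "excluded"


def classify_events_by_stim(
    events: EventTable,
    stim: EpochTable,
    mode: str = "peak_in",
    guard_s: float = 0.1,
) -> np.ndarray:
    """Label each event {baseline, stim, excluded} against stimulation pulses.

    ``guard_s`` widens the pulses when deciding what still counts as clean
    baseline, so events abutting a pulse are excluded rather than treated as
    control.
    """
    if mode not in ("peak_in", "fully_within"):
        raise ValueError(f"unknown mode: {mode}")
    labels = np.full(len(events), BASELINE, dtype=object)
    if len(stim) == 0:
        return labels
    peak_in = stim.contains(events.peak_s)
    # overlap with guard-widened pulses
    g0, g1 = stim.start_s - guard_s, stim.stop_s + guard_s
    overlaps = np.zeros(len(events), bool)
    fully = np.zeros(len(events), bool)
    for s, e in zip(g0, g1):
        overlaps |= (events.start_s < e) & (events.stop_s > s)
    for s, e in zip(stim.start_s, stim.stop_s):
        fully |= (events.start_s >= s) & (events.stop_s <= e)
    in_stim = peak_in if mode == "peak_in" else fully
    labels[overlaps] = EXCLUDED
    labels[in_stim] = STIM
    return labels


def compare_event_properties(
    events: EventTable, labels: np.ndarray
) -> pd.DataFrame:
    """Rank-sum contrasts of duration, peak amplitude, and frequency.

    One row per property with group medians, ns, and the two-sided Wilcoxon
    rank-sum p (NaN when either group has fewer than 2 finite values).
    """
    labels = np.asarray(labels, object)
    props = {
        "duration_s": events.duration_s,
        "peak_amplitude": events.peak_amplitude,
        "frequency_hz": events.frequency_hz,
    }
    rows = []
    for name, vals in props.items():
        b = vals[(labels == BASELINE) & np.isfinite(vals)]
        s = vals[(labels == STIM) & np.isfinite(vals)]
        p = float(stats.ranksums(b, s).pvalue) if min(b.size, s.size) >= 2 else np.nan
        rows.append(
            {
                "property": name,
                "n_baseline": b.size,
                "n_stim": s.size,
                "median_baseline": float(np.median(b)) if b.size else np.nan,
                "median_stim": float(np.median(s)) if s.size else np.nan,
                "rank_sum_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("property")


def event_psd_contrast(
    x: np.ndarray,
    fs: float,
    events: EventTable,
    labels: np.ndarray,
    window_s: float = 0.064,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-group mean event power spectra around peaks and their difference.

    Returns ``(freqs, psd_baseline, psd_stim, psd_stim - psd_baseline)``.
    Spectra are Hann-windowed periodograms of ``+-window_s`` around each
    event peak.
    """
    labels = np.asarray(labels, object)
    half = int(round(window_s * fs))
    nfft = max(1024, 2 * half)

    def group_psd(mask: np.ndarray) -> np.ndarray:
        acc, cnt, f = None, 0, None
        for pk in events.peak_s[mask]:
            c = int(round(pk * fs))
            if c - half < 0 or c + half > x.size:
                continue
            seg = np.asarray(x[c - half: c + half], float)
            f, pxx = signal.periodogram(
                seg - seg.mean(), fs=fs, window="hann", nfft=nfft
            )
            acc = pxx if acc is None else acc + pxx
            cnt += 1
        if cnt == 0:
            raise ValueError("empty group for PSD contrast")
        return f, acc / cnt

    f, psd_b = group_psd(labels == BASELINE)
    _, psd_s = group_psd(labels == STIM)
    return f, psd_b, psd_s, psd_s - psd_b


@dataclass
class ParticipationContrast:
    """Per-event and per-unit contrasts between baseline and stim ripples."""

    frac_baseline: np.ndarray  # per-event fraction of units with >=1 spike
    frac_stim: np.ndarray
    participation_p: float  # rank-sum across events
    per_unit: pd.DataFrame  # count/gain/isi/fraction per group per unit
    count_p: float  # signed-rank across units
    gain_p: float
    isi_p: float
    fraction_p: float


def _per_event_counts(trains: list[SpikeTrain], ev: EventTable) -> np.ndarray:
    """units x events matrix of in-event spike counts."""
    out = np.zeros((len(trains), len(ev)), int)
    for i, tr in enumerate(trains):
        out[i] = np.searchsorted(tr.times, ev.stop_s) - np.searchsorted(
            tr.times, ev.start_s
        )
    return out


def _signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 2 or np.all(a == b):
        return np.nan if a.size < 2 else 1.0
    return float(stats.wilcoxon(a, b).pvalue)


def participation_contrast(
    pyr_trains: list[SpikeTrain],
    events: EventTable,
    labels: np.ndarray,
    total_time_s: float | None = None,
) -> ParticipationContrast:
    """Pyramidal-cell recruitment in baseline vs stim ripples.

    Per event: the fraction of units spiking at least once, compared across
    groups by rank-sum. Per unit and per group: mean in-event spike count,
    in-event rate gain over the unit's outside-event rate, mean in-event ISI
    (units silent in a group are excluded from the ISI contrast), and the
    fraction of the group's events the unit participated in; each compared
    across units by signed-rank.
    """
    labels = np.asarray(labels, object)
    groups = {}
    for name in (BASELINE, STIM):
        idx = np.flatnonzero(labels == name)
        if idx.size == 0:
            raise ValueError(f"empty group: {name}")
        groups[name] = events.take(idx)
    n_units = len(pyr_trains)

    cm = {g: _per_event_counts(pyr_trains, ev) for g, ev in groups.items()}
    frac = {g: (cm[g] >= 1).mean(axis=0) for g in cm}
    if min(frac[BASELINE].size, frac[STIM].size) >= 2:
        part_p = float(stats.ranksums(frac[BASELINE], frac[STIM]).pvalue)
    else:
        part_p = np.nan  # underpowered: single event in a group

    if total_time_s is None:
        total_time_s = float(events.stop_s[-1])
    out_time = total_time_s - float(events.duration_s.sum())

    recs = []
    for i, tr in enumerate(pyr_trains):
        in_all = int(events.as_epochs().contains(tr.times).sum())
        out_rate = (tr.n_spikes - in_all) / out_time if out_time > 0 else np.nan
        rec = {"unit_id": tr.unit_id}
        for g, ev in groups.items():
            c = cm[g][i]
            ev_time = float(ev.duration_s.sum())
            rate = c.sum() / ev_time if ev_time > 0 else np.nan
            isis = []
            for k in np.flatnonzero(c >= 2):
                i0 = np.searchsorted(tr.times, ev.start_s[k])
                i1 = np.searchsorted(tr.times, ev.stop_s[k])
                isis.append(np.diff(tr.times[i0:i1]))
            rec[f"count_{g}"] = float(c[c >= 1].mean()) if (c >= 1).any() else np.nan
            rec[f"gain_{g}"] = rate / out_rate if out_rate and out_rate > 0 else np.nan
            rec[f"isi_ms_{g}"] = (
                float(np.concatenate(isis).mean() * 1e3) if isis else np.nan
            )
            rec[f"fraction_{g}"] = float((c >= 1).mean())
        recs.append(rec)
    per_unit = pd.DataFrame(recs).set_index("unit_id")

    return ParticipationContrast(
        frac_baseline=frac[BASELINE],
        frac_stim=frac[STIM],
        participation_p=part_p,
        per_unit=per_unit,
        count_p=_signed_rank(
            per_unit[f"count_{BASELINE}"].to_numpy(), per_unit[f"count_{STIM}"].to_numpy()
        ),
        gain_p=_signed_rank(
            per_unit[f"gain_{BASELINE}"].to_numpy(), per_unit[f"gain_{STIM}"].to_numpy()
        ),
        isi_p=_signed_rank(
            per_unit[f"isi_ms_{BASELINE}"].to_numpy(),
            per_unit[f"isi_ms_{STIM}"].to_numpy(),
        ),
        fraction_p=_signed_rank(
            per_unit[f"fraction_{BASELINE}"].to_numpy(),
            per_unit[f"fraction_{STIM}"].to_numpy(),
        ),
    )


def band_power_session_test(
    pre_values: np.ndarray, post_values: np.ndarray
) -> float:
    """Paired t-test p across sessions of pre vs post mean band power."""
    return float(stats.ttest_rel(pre_values, post_values).pvalue)


def deep_superficial_split(
    depths: np.ndarray, positive_is_superficial: bool = True
) -> np.ndarray:
    """Label units deep/superficial from signed depth relative to the layer.

    With the library convention (positive = toward stratum radiatum), positive
    depths are superficial; zero is assigned deep (documented tie rule).
    Missing depths give an empty label.
    """
    depths = np.asarray(depths, float)
    labels = np.full(depths.size, "", dtype=object)
    pos = depths > 0
    neg = depths <= 0
    known = np.isfinite(depths)
    if positive_is_superficial:
        labels[known & pos] = "superficial"
        labels[known & neg] = "deep"
    else:
        labels[known & pos] = "deep"
        labels[known & neg] = "superficial"
    return labels
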