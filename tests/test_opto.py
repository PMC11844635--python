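"""Event classification against stimulation and baseline-vs-stim contrasts."""

import numpy as np
import pytest
from scipy.stats import kstest

import ripplephys as rp
from ripplephys.opto import (
    classify_events_by_stim,
    compare_event_properties,
    deep_superficial_split,
    event_psd_contrast,
    participation_contrast,
)


def events_at(peaks, half=0.03, amp=None, freq=None):
    peaks = np.asarray(peaks, float)
    return rp.EventTable(
        peaks - half, peaks, peaks + half,
        None if amp is None else np.asarray(amp, float),
        None if freq is None else np.asarray(freq, float),
    )


def pulses(onsets, width=0.3):
    onsets = np.asarray(onsets, float)
    return rp.EpochTable(onsets, onsets + width)


class TestClassify:
    def test_peak_in_vs_fully_within(self):
        # event peak inside the pulse but tail hanging out
        ev = rp.EventTable([9.95], [10.05], [10.15])
        st = pulses([10.0])
        assert classify_events_by_stim(ev, st, "peak_in")[0] == "stim"
        assert classify_events_by_stim(ev, st, "fully_within")[0] == "excluded"

    def test_no_pulses_all_baseline(self):
        ev = events_at([1, 2, 3])
        labels = classify_events_by_stim(ev, pulses([]), "peak_in")
        assert list(labels) == ["baseline"] * 3

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_events_by_stim(events_at([1.0]), pulses([0.5]), "bogus")

    def test_guard_window_excludes_near_pulse_events(self):
        ev = events_at([10.12])  # peak past pulse end but inside 100 ms guard
        labels = classify_events_by_stim(ev, pulses([9.7]), "peak_in")
        assert labels[0] == "excluded"

    def test_fully_within_subset_of_peak_in(self, rng):
        peaks = np.sort(rng.uniform(1, 99, 60))
        ev = events_at(peaks)
        st = pulses(np.arange(2, 98, 3.0))
        a = classify_events_by_stim(ev, st, "peak_in")
        b = classify_events_by_stim(ev, st, "fully_within")
        assert set(np.flatnonzero(b == "stim")) <= set(np.flatnonzero(a == "stim"))


class TestEventProperties:
    def test_identical_groups_nonsignificant(self, rng):
        peaks = np.arange(1, 201, 1.0)
        durs = rng.uniform(0.02, 0.08, peaks.size)
        ev = rp.EventTable(peaks - durs / 2, peaks, peaks + durs / 2,
                           rng.uniform(5, 9, peaks.size), rng.uniform(120, 180, peaks.size))
        labels = np.where(rng.uniform(size=peaks.size) < 0.5, "stim", "baseline")
        out = compare_event_properties(ev, labels)
        assert (out["rank_sum_p"] > 0.05).all()

    def test_planted_duration_shift_detected_frequency_unaffected(self, rng):
        peaks = np.arange(1, 301, 1.0)
        labels = np.where(np.arange(peaks.size) % 3 == 0, "stim", "baseline")
        durs = rng.uniform(0.04, 0.06, peaks.size) + np.where(labels == "stim", 0.02, 0.0)
        ev = rp.EventTable(peaks - durs / 2, peaks, peaks + durs / 2,
                           rng.uniform(5, 9, peaks.size), rng.uniform(120, 180, peaks.size))
        out = compare_event_properties(ev, labels)
        assert out.loc["duration_s", "rank_sum_p"] < 0.01
        assert out.loc["frequency_hz", "rank_sum_p"] > 0.05

    def test_label_shuffle_p_uniform(self):
        r = np.random.default_rng(8)
        peaks = np.arange(1, 121, 1.0)
        durs = r.uniform(0.02, 0.08, peaks.size)
        ev = rp.EventTable(peaks - durs / 2, peaks, peaks + durs / 2,
                           r.uniform(5, 9, peaks.size), r.uniform(120, 180, peaks.size))
        ps = []
        for _ in range(300):
            labels = np.where(r.uniform(size=peaks.size) < 0.5, "stim", "baseline")
            ps.append(compare_event_properties(ev, labels).loc["duration_s", "rank_sum_p"])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestEventPsdContrast:
    def test_identical_groups_near_zero_difference(self, rng):
        fs = 1250.0
        x = rng.standard_normal(int(120 * fs))
        peaks = np.arange(2, 118, 1.0)
        ev = events_at(peaks)
        labels = np.where(np.arange(peaks.size) % 2 == 0, "stim", "baseline")
        f, pb, ps_, diff = event_psd_contrast(x, fs, ev, labels)
        band = (f >= 100) & (f <= 250)
        assert np.abs(diff[band].mean()) < 0.2 * pb[band].mean()

    def test_amplified_stim_group_positive_in_ripple_band(self, rng):
        fs = 1250.0
        x = rng.standard_normal(int(120 * fs)) * 0.5
        peaks = np.arange(2, 118, 1.0)
        labels = np.where(np.arange(peaks.size) % 2 == 0, "stim", "baseline")
        t = np.arange(x.size) / fs
        for pk, lab in zip(peaks, labels):
            amp = 3.0 if lab == "stim" else 2.0
            i0, i1 = int((pk - 0.03) * fs), int((pk + 0.03) * fs)
            tt = t[i0:i1] - pk
            x[i0:i1] += amp * np.exp(-0.5 * (tt / 0.01) ** 2) * np.cos(2 * np.pi * 150 * tt)
        f, pb, ps_, diff = event_psd_contrast(x, fs, ev := events_at(peaks), labels)
        band = (f >= 100) & (f <= 250)
        assert diff[band].sum() > 0

    def test_distinct_carrier_frequencies_signed_difference(self, rng):
        fs = 1250.0
        x = rng.standard_normal(int(120 * fs)) * 0.2
        peaks = np.arange(2, 118, 1.0)
        labels = np.where(np.arange(peaks.size) % 2 == 0, "stim", "baseline")
        t = np.arange(x.size) / fs
        for pk, lab in zip(peaks, labels):
            freq = 200.0 if lab == "stim" else 150.0
            i0, i1 = int((pk - 0.03) * fs), int((pk + 0.03) * fs)
            tt = t[i0:i1] - pk
            x[i0:i1] += 2 * np.exp(-0.5 * (tt / 0.01) ** 2) * np.cos(2 * np.pi * freq * tt)
        f, pb, ps_, diff = event_psd_contrast(x, fs, events_at(peaks), labels)
        assert diff[(f > 180) & (f < 220)].mean() > 0
        assert diff[(f > 130) & (f < 170)].mean() < 0


class TestParticipation:
    def test_doubled_rates_in_stim_events_detected(self, rng):
        peaks = np.arange(1, 401, 1.0)
        ev = events_at(peaks)
        labels = np.where(np.arange(peaks.size) % 3 == 0, "stim", "baseline")
        trains = []
        for u in range(25):
            base = np.sort(rng.uniform(0, 402, 400))
            extra = []
            for pk, lab in zip(peaks, labels):
                lam = 0.6 if lab == "stim" else 0.3
                k = rng.poisson(lam)
                extra.extend(rng.uniform(pk - 0.03, pk + 0.03, k))
            t = np.unique(np.sort(np.r_[base, extra]))
            trains.append(rp.SpikeTrain(f"p{u}", t))
        out = participation_contrast(trains, ev, labels, total_time_s=402)
        assert out.participation_p < 0.01
        assert out.frac_stim.mean() > out.frac_baseline.mean()
        assert out.count_p < 0.05
        assert out.gain_p < 0.05
        assert out.fraction_p < 0.01

    def test_null_stim_effect_p_uniform(self):
        r = np.random.default_rng(9)
        peaks = np.arange(1, 201, 1.0)
        ev = events_at(peaks)
        trains = [
            rp.SpikeTrain(f"p{u}", np.unique(np.sort(r.uniform(0, 202, 1200))))
            for u in range(12)
        ]
        ps = []
        for _ in range(60):
            labels = np.where(r.uniform(size=peaks.size) < 0.3, "stim", "baseline")
            out = participation_contrast(trains, ev, labels, total_time_s=202)
            ps.append(out.participation_p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_event_group_flagged_underpowered(self, rng):
        peaks = np.arange(1, 31, 1.0)
        ev = events_at(peaks)
        labels = np.array(["baseline"] * 29 + ["stim"], object)
        trains = [rp.SpikeTrain("p0", np.sort(rng.uniform(0, 32, 300)))]
        out = participation_contrast(trains, ev, labels, total_time_s=32)
        assert np.isnan(out.participation_p)

    def test_empty_group_rejected(self, rng):
        ev = events_at(np.arange(1, 31, 1.0))
        labels = np.array(["baseline"] * 30, object)
        with pytest.raises(ValueError, match="stim"):
            participation_contrast(
                [rp.SpikeTrain("p0", np.sort(rng.uniform(0, 32, 100)))], ev, labels
            )


class TestDeepSuperficial:
    def test_convention_and_tie_rule(self):
        labels = deep_superficial_split(np.array([30.0, -30.0, 0.0, np.nan]))
        assert list(labels) == ["superficial", "deep", "deep", ""]

    def test_flip_consistent(self, rng):
        d = rng.normal(0, 50, 30)
        a = deep_superficial_split(d, positive_is_superficial=True)
        b = deep_superficial_split(d, positive_is_superficial=False)
        swap = {"deep": "superficial", "superficial": "deep"}
        assert all(b[i] == swap[a[i]] for i in range(30))
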