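"""Filtering, analytic signal, ripple detection, and event spectra."""

import numpy as np
import pytest

import ripplephys as rp
from ripplephys.lfp import (
    RIPPLE,
    BandDefinition,
    RippleDetectionParams,
    band_power_contrast,
    event_frequency,
    peri_stim_spectrogram,
)

FS = 1250.0


def tone(freq, dur=4.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = tone(150.0)
        y = rp.bandpass(x, RIPPLE, FS)
        mid = slice(int(FS), int(3 * FS))
        assert np.std(y[mid]) == pytest.approx(np.std(x[mid]), rel=0.01)

    def test_stopband_tone_rejected_40db(self):
        x = tone(8.0)
        y = rp.bandpass(x, RIPPLE, FS)
        mid = slice(int(FS), int(3 * FS))
        assert 20 * np.log10(np.std(y[mid]) / np.std(x[mid])) < -40

    def test_white_noise_variance_scales_with_bandwidth(self, rng):
        x = rng.standard_normal(int(200 * FS))
        y = rp.bandpass(x, RIPPLE, FS)
        frac = (RIPPLE.hi_hz - RIPPLE.lo_hz) / (FS / 2)
        assert np.var(y) / np.var(x) == pytest.approx(frac, rel=0.1)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            rp.bandpass(tone(8.0), BandDefinition("bad", 100, 700), FS)

    def test_zero_phase_time_reversal_symmetry(self, rng):
        # forward-backward filtering is time-symmetric away from edge transients
        x = rng.standard_normal(4000)
        fwd = rp.bandpass(x, RIPPLE, FS)
        rev = rp.bandpass(x[::-1], RIPPLE, FS)[::-1]
        mid = slice(250, -250)
        np.testing.assert_allclose(fwd[mid], rev[mid], atol=1e-7)


class TestAnalytic:
    def test_cosine_phase_zero_at_t0(self):
        an = rp.analytic(tone(8.0), FS)
        assert np.cos(an.phase[0]) == pytest.approx(1.0, abs=1e-6)

    def test_envelope_recovers_amplitude(self):
        an = rp.analytic(tone(8.0, amp=3.0), FS)
        mid = slice(int(FS), int(3 * FS))
        np.testing.assert_allclose(an.envelope[mid], 3.0, rtol=1e-3)

    def test_phase_unwraps_monotonically_for_tone(self):
        an = rp.analytic(tone(8.0), FS)
        un = np.unwrap(an.phase[int(FS): int(3 * FS)])
        assert np.all(np.diff(un) > 0)


def inject_burst(x, fs, t0, dur, freq, amp):
    n0, n1 = int(t0 * fs), int((t0 + dur) * fs)
    tt = np.arange(n1 - n0) / fs - dur / 2
    x[n0:n1] += amp * np.exp(-0.5 * (tt / (dur / 6)) ** 2) * np.cos(
        2 * np.pi * freq * tt
    )
    return t0 + dur / 2


class TestDetectRipples:
    def test_single_injected_burst_detected(self, rng):
        x = rng.standard_normal(int(30 * FS))
        peak = inject_burst(x, FS, 12.0, 0.06, 150.0, 8.0)
        ev = rp.detect_ripples(x, FS)
        assert len(ev) == 1
        assert ev.start_s[0] < peak < ev.stop_s[0]
        assert abs(ev.peak_s[0] - peak) < 0.01

    def test_flat_signal_errors(self):
        with pytest.raises(ValueError, match="flat"):
            rp.detect_ripples(np.zeros(10000), FS)

    def test_noise_only_low_false_positive_rate(self):
        r = np.random.default_rng(5)
        x = r.standard_normal(int(100 * FS))
        ev = rp.detect_ripples(x, FS)
        assert len(ev) / 100.0 < 0.05

    def test_nearby_bursts_merge(self, rng):
        x = rng.standard_normal(int(20 * FS))
        inject_burst(x, FS, 10.0, 0.04, 150.0, 8.0)
        inject_burst(x, FS, 10.045, 0.04, 150.0, 8.0)  # 5 ms gap
        ev = rp.detect_ripples(x, FS)
        assert len(ev) == 1

    def test_events_sorted_disjoint_within_duration_bounds(self, small_session):
        lfp = small_session.lfp
        ev = rp.detect_ripples(lfp.channel_uv(lfp.n_channels // 2), lfp.fs)
        p = RippleDetectionParams()
        assert np.all(np.diff(ev.start_s) >= 0)
        assert np.all(ev.start_s[1:] >= ev.stop_s[:-1])
        assert np.all(ev.duration_s >= p.min_duration_s - 1e-9)
        assert np.all(ev.duration_s <= p.max_duration_s + 1e-9)


class TestEventFrequency:
    @pytest.mark.parametrize("freq", [150.0, 200.0])
    def test_injected_frequency_recovered(self, freq, rng):
        x = rng.standard_normal(int(10 * FS)) * 0.1
        inject_burst(x, FS, 5.0, 0.06, freq, 8.0)
        est = event_frequency(x, FS, 4.97, 5.09)
        assert est == pytest.approx(freq, abs=10)

    def test_white_noise_event_bounded_by_band(self, rng):
        est = event_frequency(rng.standard_normal(int(FS)), FS, 0.1, 0.4)
        assert 100 <= est <= 250

    def test_too_short_event_gives_nan(self):
        assert np.isnan(event_frequency(np.zeros(10000), FS, 0.1, 0.11))


def pulse_epochs(onsets, width):
    onsets = np.asarray(onsets, float)
    return rp.EpochTable(onsets, onsets + width)


class TestPeriStimSpectrogram:
    def test_no_change_gives_balanced_contrast(self, rng):
        x = rng.standard_normal(int(60 * FS))
        ep = pulse_epochs(np.arange(2, 58, 2.0), 0.3)
        f, t, pw = peri_stim_spectrogram(x, FS, ep)
        pre, post = band_power_contrast(f, t, pw, RIPPLE)
        assert post == pytest.approx(pre, rel=0.1)

    def test_broadband_step_raises_all_bands(self, rng):
        x = rng.standard_normal(int(60 * FS))
        ep = pulse_epochs(np.arange(2, 58, 2.0), 0.3)
        for on in ep.start_s:  # triple the noise amplitude during each pulse
            i0, i1 = int(on * FS), int((on + 0.3) * FS)
            x[i0:i1] *= 3.0
        f, t, pw = peri_stim_spectrogram(x, FS, ep)
        for band in (rp.RIPPLE, rp.SPIKE):
            pre, post = band_power_contrast(f, t, pw, band)
            assert post > 2 * pre

    def test_ripple_band_only_increase_is_band_specific(self, rng):
        x = rng.standard_normal(int(60 * FS))
        ep = pulse_epochs(np.arange(2, 58, 2.0), 0.3)
        t_all = np.arange(x.size) / FS
        carrier = np.cos(2 * np.pi * 150 * t_all)
        mask = ep.contains(t_all)
        x[mask] += 2.0 * carrier[mask]
        f, t, pw = peri_stim_spectrogram(x, FS, ep)
        pre_r, post_r = band_power_contrast(f, t, pw, rp.RIPPLE)
        pre_s, post_s = band_power_contrast(f, t, pw, rp.SPIKE)
        assert post_r > 2 * pre_r
        assert post_s == pytest.approx(pre_s, rel=0.25)


class TestFindPyramidalLayer:
    def test_recovers_injection_channel(self, rng):
        n = int(40 * FS)
        samples = rng.standard_normal((8, n)) * 20
        for t0 in np.arange(3, 38, 1.5):
            prof = np.exp(-0.5 * ((np.arange(8) - 6) / 1.5) ** 2)
            for ch in range(8):
                inject_burst(samples[ch], FS, t0, 0.06, 150.0, 160.0 * prof[ch])
        lfp = rp.LfpRecording(
            samples.astype(np.int16), FS, np.arange(8) * 20.0, scale_uv=1.0
        )
        assert rp.find_pyramidal_layer(lfp) == 6

    def test_single_channel_returns_zero(self, rng):
        lfp = rp.LfpRecording(
            rng.integers(-100, 100, (1, 5000)).astype(np.int16), FS, [0.0]
        )
        assert rp.find_pyramidal_layer(lfp) == 0
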