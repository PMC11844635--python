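"""Synthetic recording sessions with known ground truth.

A session alternates run and rest blocks. During run the LFP carries a theta
sinusoid and units are von Mises phase-locked to it; during rest, transient
ripple bursts (a carrier at ``ripple_freq_hz`` under a Gaussian envelope) are
planted on top of 1/f background noise, and unit rates scale multiplicatively
inside events with optional von Mises locking to the ripple carrier phase.
Optical pulses multiplicatively scale the rates of affected units and can
additionally scale the amplitude / extend the duration of events they cover.

Spikes are drawn from the resulting inhomogeneous Poisson rate by thinning
(exact, no time discretization); planted PYR -> AAC synapses then insert a
postsynaptic spike after each presynaptic spike with probability ``p_trans``
at a jittered latency, with a 1 ms refractory dedup on the merged train.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0

from .core import EpochTable, EventTable, LfpRecording, SpikeTrain, UnitInfo

TWO_PI = 2 * np.pi


@dataclass
class Synapse:
    pre: str
    post: str
    p_trans: float
    latency_ms: float = 1.5
    jitter_ms: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.p_trans <= 1:
            raise ValueError("p_trans must be in [0, 1]")


@dataclass
class StimConfig:
    opsin: str = "arch"  # {"arch", "chr2"} -> epoch label stim_arch / stim_chr2
    pulse_width_s: float = 0.3
    period_s: float = 1.0
    start_s: float = 0.0
    stop_s: float | None = None  # default: end of session
    affected_units: tuple[str, ...] = ()
    jitter_frac: float = 0.25  # onset jitter as a fraction of the period
    gain: float = 0.2  # multiplicative rate factor inside pulses
    ripple_amp_gain: float = 1.0  # amplitude factor for events peaking in-pulse
    ripple_dur_add_ms: float = 0.0  # duration increment for events in-pulse


@dataclass
class SimConfig:
    duration_s: float = 120.0
    fs: float = 1250.0
    n_channels: int = 8
    channel_pitch_um: float = 20.0
    layer_channel: int | None = None  # default: middle channel
    n_pyr: int = 20
    n_aac: int = 3
    pyr_rate_hz: float = 2.0
    aac_rate_hz: float = 10.0
    theta_freq_hz: float = 8.0
    theta_kappa_pyr: float = 0.5
    theta_kappa_aac: float = 1.0
    ripple_rate_hz: float = 0.3  # events/s during rest
    ripple_freq_hz: float = 150.0
    ripple_dur_ms: float = 60.0
    ripple_amp: float = 8.0  # carrier amplitude in units of background SD
    pyr_ripple_gain: float = 3.0
    aac_ripple_gain: float = 2.0
    ripple_kappa: float = 1.0  # in-event phase locking concentration
    theta_amp: float = 3.0  # theta amplitude in units of background SD
    noise_amp_uv: float = 50.0  # SD of 1/f background, uV
    state_block_s: float = 30.0  # run/rest alternation block length
    run_fraction: float = 0.5
    synapses: tuple[Synapse, ...] = ()
    stim: StimConfig | None = None
    unit_overrides: dict = field(default_factory=dict)  # unit_id -> param dict
    generate_lfp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for r in (self.pyr_rate_hz, self.aac_rate_hz, self.ripple_rate_hz):
            if r < 0:
                raise ValueError("rates must be nonnegative")


@dataclass
class GroundTruth:
    events: EventTable
    state_epochs: EpochTable  # run/rest
    stim_epochs: EpochTable
    units: pd.DataFrame  # per-unit planted parameters
    synapses: tuple[Synapse, ...]


@dataclass
class Session:
    lfp: LfpRecording | None
    trains: list[SpikeTrain]
    units: list[UnitInfo]
    epochs: EpochTable  # run/rest + stim pulses, sorted
    truth: GroundTruth


def _state_epochs(cfg: SimConfig) -> EpochTable:
    """Alternating run/rest blocks covering [0, duration)."""
    starts, stops, labels = [], [], []
    t = 0.0
    while t < cfg.duration_s:
        run_len = cfg.state_block_s * cfg.run_fraction
        rest_len = cfg.state_block_s - run_len
        if run_len > 0:
            starts.append(t)
            stops.append(min(t + run_len, cfg.duration_s))
            labels.append("run")
        if rest_len > 0 and t + run_len < cfg.duration_s:
            starts.append(t + run_len)
            stops.append(min(t + cfg.state_block_s, cfg.duration_s))
            labels.append("rest")
        t += cfg.state_block_s
    return EpochTable(np.array(starts), np.array(stops), np.array(labels, object))


def _stim_epochs(cfg: SimConfig, rng: np.random.Generator) -> EpochTable:
    """Pulse train with jittered onsets (real stimulation is not periodic,
    so pulses must not lock to the theta cycle)."""
    if cfg.stim is None:
        return EpochTable(np.empty(0), np.empty(0))
    st = cfg.stim
    stop = st.stop_s if st.stop_s is not None else cfg.duration_s
    onsets = np.arange(st.start_s, stop - st.pulse_width_s, st.period_s)
    if st.jitter_frac > 0 and onsets.size:
        jmax = st.jitter_frac * st.period_s
        onsets = onsets + rng.uniform(0, jmax, size=onsets.size)
        onsets = onsets[onsets + st.pulse_width_s <= stop]
    label = f"stim_{st.opsin}"
    return EpochTable(
        onsets, onsets + st.pulse_width_s, np.array([label] * onsets.size, object)
    )


def _plant_events(
    cfg: SimConfig, rest: EpochTable, stim: EpochTable, rng: np.random.Generator
) -> EventTable:
    """Poisson-planted ripple events inside rest epochs (min 250 ms apart)."""
    base_dur = cfg.ripple_dur_ms * 1e-3
    peaks: list[float] = []
    for s, e in zip(rest.start_s, rest.stop_s):
        if e - s <= 2 * base_dur:
            continue
        n = rng.poisson(cfg.ripple_rate_hz * (e - s))
        peaks.extend(rng.uniform(s + base_dur, e - base_dur, size=n))
    peaks = np.sort(np.array(peaks))
    if peaks.size:
        keep = np.concatenate([[True], np.diff(peaks) > base_dur + 0.25])
        peaks = peaks[keep]
    durs = np.full(peaks.size, base_dur)
    amps = np.full(peaks.size, cfg.ripple_amp)
    if cfg.stim is not None and len(stim):
        in_pulse = stim.contains(peaks)
        amps[in_pulse] *= cfg.stim.ripple_amp_gain
        durs[in_pulse] += cfg.stim.ripple_dur_add_ms * 1e-3
    return EventTable(
        peaks - durs / 2, peaks, peaks + durs / 2, amps, np.full(peaks.size, cfg.ripple_freq_hz)
    )


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise with unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _build_lfp(
    cfg: SimConfig,
    run: EpochTable,
    events: EventTable,
    rng: np.random.Generator,
) -> LfpRecording:
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    layer = cfg.layer_channel if cfg.layer_channel is not None else cfg.n_channels // 2
    # channel profile of the ripple: strongest at the layer, Gaussian falloff
    prof = np.exp(-0.5 * ((np.arange(cfg.n_channels) - layer) / 1.5) ** 2)
    theta = np.zeros(n)
    run_mask = run.contains(t)
    theta[run_mask] = cfg.theta_amp * np.cos(TWO_PI * cfg.theta_freq_hz * t[run_mask])
    ripple = np.zeros(n)
    for pk, s, e, amp in zip(
        events.peak_s, events.start_s, events.stop_s, events.peak_amplitude
    ):
        i0, i1 = int(s * cfg.fs), int(e * cfg.fs)
        tt = t[i0:i1] - pk
        sigma = (e - s) / 6.0  # envelope ~ event duration at +-3 SD
        ripple[i0:i1] += amp * np.exp(-0.5 * (tt / sigma) ** 2) * np.cos(
            TWO_PI * cfg.ripple_freq_hz * tt
        )
    scale_uv = 0.195  # typical int16 ADC scale
    samples = np.empty((cfg.n_channels, n), dtype=np.int16)
    for ch in range(cfg.n_channels):
        x_uv = cfg.noise_amp_uv * (
            _pink_noise(n, rng) + theta + prof[ch] * ripple
        )
        samples[ch] = np.clip(np.round(x_uv / scale_uv), -32768, 32767).astype(np.int16)
    depths = (np.arange(cfg.n_channels) - layer) * cfg.channel_pitch_um
    return LfpRecording(samples, cfg.fs, depths, scale_uv)


def _vm_factor(phase: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """von Mises density normalized to unit mean over a uniform phase."""
    if kappa == 0:
        return np.ones_like(phase)
    return np.exp(kappa * np.cos(phase - mu)) / i0(kappa)


def _unit_rate(
    t: np.ndarray,
    p: dict,
    cfg: SimConfig,
    run: EpochTable,
    events: EventTable,
    stim: EpochTable,
) -> np.ndarray:
    rate = np.full(t.size, p["base_rate"])
    in_run = run.contains(t)
    if in_run.any() and p["theta_kappa"] > 0:
        th = TWO_PI * cfg.theta_freq_hz * t[in_run]
        rate[in_run] *= _vm_factor(th, p["theta_mu"], p["theta_kappa"])
    if len(events):
        idx = np.searchsorted(events.start_s, t, side="right") - 1
        ok = idx >= 0
        ok[ok] &= t[ok] < events.stop_s[idx[ok]]
        if ok.any():
            ph = TWO_PI * cfg.ripple_freq_hz * (t[ok] - events.peak_s[idx[ok]])
            rate[ok] *= p["ripple_gain"] * _vm_factor(
                ph, p["ripple_mu"], p["ripple_kappa"]
            )
    if len(stim) and p["stim_gain"] != 1.0:
        in_p = stim.contains(t)
        rate[in_p] *= p["stim_gain"]
    return rate


def _thin_poisson(
    rate_fn, rate_max: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    if rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0, duration, size=n_cand))
    if cand.size == 0:
        return cand
    accept = rng.uniform(0, rate_max, size=cand.size) < rate_fn(cand)
    return cand[accept]


def _waveform(rng: np.random.Generator, fs: float = 20000.0) -> np.ndarray:
    """Simple biphasic extracellular template with a known trough and late peak."""
    n = 60
    tt = np.arange(n) / fs * 1e3  # ms
    trough_ms = 1.0
    t2p_ms = rng.uniform(0.2, 0.6)
    w = -100 * np.exp(-0.5 * ((tt - trough_ms) / 0.1) ** 2)
    w += 40 * np.exp(-0.5 * ((tt - trough_ms - t2p_ms) / 0.25) ** 2)
    w += 15 * np.exp(-0.5 * ((tt - trough_ms + 0.3) / 0.12) ** 2)
    return w


def generate_session(cfg: SimConfig) -> Session:
    """Generate a full synthetic session (bit-reproducible for a fixed seed)."""
    rng = np.random.default_rng(cfg.seed)
    state = _state_epochs(cfg)
    run = state.select("run")
    rest = state.select("rest")
    stim = _stim_epochs(cfg, rng)
    events = _plant_events(cfg, rest, stim, rng)
    lfp = _build_lfp(cfg, run, events, rng) if cfg.generate_lfp else None

    unit_rows = []
    ids = [f"pyr{i:02d}" for i in range(cfg.n_pyr)] + [
        f"aac{i:02d}" for i in range(cfg.n_aac)
    ]
    for uid in ids:
        is_pyr = uid.startswith("pyr")
        p = {
            "unit_id": uid,
            "putative_type": "PYR" if is_pyr else "INT",
            "base_rate": cfg.pyr_rate_hz if is_pyr else cfg.aac_rate_hz,
            "theta_mu": float(rng.uniform(0, TWO_PI)),
            "theta_kappa": cfg.theta_kappa_pyr if is_pyr else cfg.theta_kappa_aac,
            "ripple_gain": cfg.pyr_ripple_gain if is_pyr else cfg.aac_ripple_gain,
            "ripple_mu": float(rng.uniform(0, TWO_PI)),
            "ripple_kappa": cfg.ripple_kappa,
            "stim_gain": 1.0,
            "peak_channel": int(rng.integers(0, cfg.n_channels)),
        }
        if cfg.stim is not None and uid in cfg.stim.affected_units:
            p["stim_gain"] = cfg.stim.gain
        p.update(cfg.unit_overrides.get(uid, {}))
        unit_rows.append(p)

    trains: list[SpikeTrain] = []
    for p in unit_rows:
        theta_max = float(_vm_factor(np.array([p["theta_mu"]]), p["theta_mu"], p["theta_kappa"])[0])
        ripple_max = p["ripple_gain"] * float(
            _vm_factor(np.array([p["ripple_mu"]]), p["ripple_mu"], p["ripple_kappa"])[0]
        )
        rmax = p["base_rate"] * max(theta_max, ripple_max, 1.0) * max(p["stim_gain"], 1.0)
        if rmax > cfg.fs / 2:
            import warnings

            warnings.warn(f"unit {p['unit_id']}: peak rate {rmax:.0f} Hz > fs/2")
        times = _thin_poisson(
            lambda tt: _unit_rate(tt, p, cfg, run, events, stim),
            rmax,
            cfg.duration_s,
            rng,
        )
        trains.append(SpikeTrain(p["unit_id"], times))

    # planted synapses: probabilistic postsynaptic insertion + 1 ms refractory
    by_id = {tr.unit_id: i for i, tr in enumerate(trains)}
    for syn in cfg.synapses:
        pre = trains[by_id[syn.pre]]
        post = trains[by_id[syn.post]]
        fire = rng.uniform(size=pre.n_spikes) < syn.p_trans
        extra = (
            pre.times[fire]
            + syn.latency_ms * 1e-3
            + rng.normal(0, syn.jitter_ms * 1e-3, size=int(fire.sum()))
        )
        merged = np.sort(np.concatenate([post.times, extra]))
        keep = np.concatenate([[True], np.diff(merged) >= 1e-3])
        merged = merged[keep]
        merged = merged[(merged >= 0) & (merged < cfg.duration_s)]
        trains[by_id[syn.post]] = SpikeTrain(post.unit_id, merged)

    infos = []
    layer = cfg.layer_channel if cfg.layer_channel is not None else cfg.n_channels // 2
    for p in unit_rows:
        tag = "untagged"
        if cfg.stim is not None and p["unit_id"] in cfg.stim.affected_units:
            tag = "tagged-suppressed" if cfg.stim.gain < 1 else "tagged-activated"
        infos.append(
            UnitInfo(
                unit_id=p["unit_id"],
                putative_type=p["putative_type"],
                tag_status=tag,
                peak_channel=p["peak_channel"],
                waveform=_waveform(rng),
                waveform_fs=20000.0,
                depth_um=(p["peak_channel"] - layer) * cfg.channel_pitch_um,
            )
        )

    all_epochs_df = pd.concat([state.to_frame(), stim.to_frame()]).sort_values(
        "start_s", kind="stable"
    )
    epochs = EpochTable.from_frame(all_epochs_df)
    units_df = (
        pd.DataFrame(unit_rows).set_index("unit_id")
        if unit_rows
        else pd.DataFrame(columns=["putative_type"])
    )
    truth = GroundTruth(events, state, stim, units_df, cfg.synapses)
    return Session(lfp, trains, infos, epochs, truth)
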