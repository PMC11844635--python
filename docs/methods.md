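# Methods

## Scope and data model

The package analyzes sorted extracellular recordings from hippocampal CA1:
spike trains (seconds, session starts at 0), multichannel LFP (int16 flat
binary, little-endian, sample-interleaved, with a JSON sidecar for sampling
rate, channel count, µV scale and per-channel depth), behavioral/stimulation
epochs, and ripple event tables. All intervals are half-open `[start, stop)`
so that an epoch set and its complement partition time exactly; this is
load-bearing for every baseline-vs-event rate computation. Depths are signed
with positive = below the pyramidal-layer center toward stratum radiatum;
reports can flip the convention with a flag.

## Ripple detection

Events are detected on a single channel (by default the channel maximizing
the ripple-band envelope during candidate events, a proxy for the pyramidal
layer): band-pass 100–250 Hz (4th-order Butterworth, forward–backward so
group delay is zero), Hilbert envelope, 8 ms Gaussian smoothing, z-scored
against the whole trace excluding any caller-supplied epochs (e.g. optical
stimulation, so stimulation-driven power does not inflate the reference
distribution). An event is a stretch above 2 SD containing a sample above
5 SD, with stretches closer than 15 ms merged and durations clamped to
15–250 ms. The peak is the envelope argmax; peak amplitude is its z-value;
event frequency is the argmax of a Hann-windowed, zero-padded periodogram
within the band (NaN for events shorter than two cycles of the band's low
edge). Only the band is dictated by the analysis being reproduced; the
thresholds and bounds are the common defaults of this detector family and
are all exposed in `RippleDetectionParams`.

## Circular statistics

Phase convention: 0 at the oscillation peak, π at the trough, descending
limb in (0, π) — the analytic phase of a cosine. Spike phases are
interpolated on the unit circle (sin/cos separately) to avoid wrap
artifacts. Phase preference is the circular mean, phase modulation the mean
resultant length R, and non-uniformity is tested with the Rayleigh statistic
z = nR² using Zar's finite-n p approximation. Circular–linear correlation
uses the standard sine/cosine embedding with a χ²(2) p-value. No correction
is applied for within-cycle spike-count bias. The implementation is
cross-checked in the test suite against an independent circular-statistics
library (pingouin).

## ZETA-style responsiveness test

Responsiveness of a unit to event onsets (optical pulses or ripple peaks)
avoids a binning choice: pool spike times relative to onsets into
[0, window), compare the empirical CDF to the uniform baseline, mean-center
the deviation, and take its maximum absolute value. The null distribution
comes from ≥250 resamples in which each event's spikes receive an
independent circular shift within the window (a common shift would preserve
the modulation shape and destroy power); the p-value is the add-one
empirical tail probability, so its resolution is 1/(n_resamples+1).
Fewer than 10 events or zero pooled spikes return p = 1 (underpowered,
flagged by the degenerate value). Tag classification calls the test with
window = pulse duration + 50 ms and assigns direction by the in-pulse minus
pre-pulse rate over equal-duration windows, replacing the manual PSTH
curation step of typical workflows with a deterministic rule.

## Monosynaptic inference

Cross-correlograms use 0.5 ms bins over ±50 ms, computed with a
sorted-merge sweep (no all-pairs matrix). The slow comodulation baseline is
the CCG convolved with a partially hollow Gaussian (SD 10 ms, center weight
× 0.4, renormalized, reflected edges). Because only the exact center bin is
hollowed, a strong monosynaptic peak leaks into its own baseline and biases
the excess-count estimate low by up to ~15% of the transmission
probability; the pipeline therefore uses a second, peak-corrected pass in
which the region-of-interest bins are replaced by the first-pass baseline
before re-smoothing. A connection is declared when the minimum bin-wise
Poisson upper-tail probability over the 0.5–3.0 ms region of positive lags
survives Bonferroni correction at α = 0.001; an optional lower-tail mode
covers inhibitory troughs. Spike transmission probability is the summed
observed-minus-baseline count in the region per presynaptic spike.
Partner aggregation averages each postsynaptic cell's significant
presynaptic partners' metrics arithmetically.

## SPW-R participation metrics

Per unit: baseline rate uses time outside events (and outside any excluded
epochs, e.g. stimulation — excluded by default so opsin effects do not leak
into the denominator); gain is in-event rate over baseline rate (infinite
gain is flagged, not silently dropped); spikes/event conditions on
participation (events with ≥1 spike); in-event ISI pools same-event spike
pairs; time-to-first-spike is the first in-event spike minus the event peak
(negative = before the peak); the rate–power correlation is Pearson's r
between 10 ms binned spike counts and the mean smoothed ripple-band
envelope per bin; participation fraction is the share of events with ≥1
spike. The population PETH z-scores each unit's peri-peak rate against its
own window-edge bins (outer 20% per side of a ±0.5 s window).

## Opto-silencing contrasts

Events are labeled against stimulation pulses under two rules: `peak_in`
(event peak inside a pulse) and `fully_within` (entire event inside one
pulse; a subset of the former). Events that touch a pulse or a 100 ms guard
window around it without satisfying the rule are excluded from both groups
rather than forced into baseline. Duration, peak amplitude, and frequency
are compared across groups with two-sided Wilcoxon rank-sum tests; per-event
spectra (±64 ms Hann periodograms around peaks) are averaged per group and
differenced. Pyramidal-cell recruitment uses the per-event fraction of units
spiking (rank-sum across events) and per-unit paired metrics — mean in-event
spike count, event-rate gain, in-event ISI (units silent in a group are
excluded from the ISI pair), and fraction of events participated — compared
with Wilcoxon signed-rank across units. Session-level band-power contrasts
(pre vs post pulse windows of the peri-stimulus spectrogram, Hann 50 ms
windows, 90% overlap) pair across sessions with a paired t-test.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, with
every planted parameter returned as ground truth:

- **States**: alternating run/rest blocks (30 s blocks, 50% run by
  default). Theta (8 Hz sinusoid, 3× background SD) exists only in run;
  ripples are planted only in rest.
- **LFP**: 1/f-amplitude background noise (50 µV SD) per channel, plus
  theta, plus per-event ripple bursts — a carrier at 150 Hz under a
  Gaussian envelope spanning the event (±3 SD), amplitude 8× background SD
  at the layer channel with a Gaussian falloff across channels
  (SD 1.5 channels, 20 µm pitch). Samples are quantized to int16 at
  0.195 µV/bit.
- **Spikes**: inhomogeneous Poisson by thinning (exact; no time grid).
  Rate = base rate × von Mises factor on theta phase during run (normalized
  to unit mean, so locking does not change the mean rate) × ripple gain and
  von Mises factor on the ripple carrier phase inside events × stimulation
  gain inside pulses for affected units. Defaults: pyramidal cells 2 Hz,
  κ_theta 0.5, ripple gain 3; interneurons 10 Hz, κ_theta 1.0, ripple
  gain 2, κ_ripple 1 — magnitudes in the range reported for CA1.
- **Synapses**: each presynaptic spike triggers a postsynaptic spike with
  probability p_trans at 1.5 ms latency with 0.3 ms Gaussian jitter; a 1 ms
  refractory dedup drops the later of any near-coincident pair on the
  merged train (physiologically motivated; biases planted p_trans by well
  under the recovery tolerance at realistic rates).
- **Stimulation**: pulses at a nominal period with uniform onset jitter
  (25% of the period). The jitter is essential: strictly periodic pulses
  phase-lock to theta whenever the period is commensurate with the theta
  cycle, which manufactures spurious stimulus-locked structure in untagged
  units. Pulses can also scale the amplitude and extend the duration of
  events they cover, emulating network-level disinhibition.
- Fixed seed ⇒ bit-identical sessions.

What the generator does **not** emulate: spike-sorting errors and waveform
drift, bursting/refractory structure beyond the 1 ms dedup, sharp-wave
(stratum radiatum) deflections, state transitions smoother than block
boundaries, opsin kinetics (stimulation gains are instantaneous steps), and
place-field/replay content. Passing recovery tests therefore validates the
estimators under the model's assumptions, not robustness to sorting
artifacts or nonstationarity in real data.

## Packaged cell-characteristics table

`ripplephys/data/table1_aac.csv` is a 42-row transcription of the published
per-cell AAC metrics (checksummed at load). The partner-aggregate Spearman
correlations are computed on the 25 rows with non-NaN partner columns
(average-rank ties; two-sided t-approximation p). The soma-position summary
(n = 32 cells, mean 6.0 µm, SD 215.6 µm) reproduces the published caption
exactly. The five published correlation coefficients are close to, but not
bit-identical with, the values recomputed from the printed table (e.g.
0.670 recomputed vs 0.6923 published for partner-vs-cell SPW-R modulation);
the printed table and the published figures evidently reflect slightly
different processing runs, and the published per-figure coefficients cannot
be derived from any column pairing or row subset of the printed table. The
recomputation reports what the packaged data actually yield. Whole-column
moments are likewise diagnostics, not exact targets: the printed table
carries 42 of the study's 43 cells. The table's time-to-first-spike column
contains only positive values (evidently referenced to event start); the
pipeline's own metric is referenced to the event peak and signed.

## Problem sizes and numerical choices

Recovery checks in the test suite use sizes chosen so Monte-Carlo error is
well inside the asserted tolerances: ≥3000 presynaptic spikes per planted
synapse and 20 null pairs for monosynaptic recovery (±0.02 on transmission
probability); ≥1500 events for gain recovery (±0.1 on a gain of 2); ≥500
in-event spikes for phase-preference recovery (±10°); 2000 replicates for
type-I calibration of the Rayleigh and ZETA tests (accepted band
0.03–0.07 at α = 0.05). Ties in the layer-channel search break toward the
smaller index; zero-depth units are labeled deep; empty phase samples,
infinite gains, and underpowered contrasts return flagged NaN/degenerate
values rather than raising.
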