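"""Circular statistics for spike-phase analyses.

Angles are radians in [0, 2pi) throughout the library; degrees appear only in
rendered reports. The quantities used downstream are the circular mean
(phase preference), the mean resultant length R (phase modulation depth),
the Rayleigh test of non-uniformity (z = n R^2 with the standard finite-n
p approximation), and the circular-linear correlation through the
sine/cosine embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseStats:
    n: int
    mean_angle: float  # radians in [0, 2pi); NaN when undefined
    modulation: float  # mean resultant length R in [0, 1]
    rayleigh_z: float
    p_value: float

    @property
    def defined(self) -> bool:
        return self.n > 0


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles into [0, 2pi)."""
    return np.mod(theta, TWO_PI)


def spike_phases(times, phase: np.ndarray, fs: float, valid_epochs=None) -> np.ndarray:
    """Oscillation phase at each spike time.

    Interpolates the (wrapped) instantaneous phase of an analytic signal at
    the spike times, restricted to ``valid_epochs`` when given. Interpolation
    happens on the unit circle (via sin/cos) to avoid wrap artifacts at the
    2pi -> 0 discontinuity.
    """
    times = np.asarray(times, float)
    if valid_epochs is not None:
        times = times[valid_epochs.contains(times)]
    n = phase.shape[0]
    times = times[(times >= 0) & (times <= (n - 1) / fs)]
    if times.size == 0:
        return np.empty(0)
    idx = times * fs
    s = np.interp(idx, np.arange(n), np.sin(phase))
    c = np.interp(idx, np.arange(n), np.cos(phase))
    return wrap_angle(np.arctan2(s, c))


def phase_stats(phases) -> PhaseStats:
    """Circular mean, resultant length and Rayleigh test of a phase sample."""
    phases = np.asarray(phases, float)
    n = phases.size
    if n == 0:
        return PhaseStats(0, np.nan, np.nan, np.nan, np.nan)
    z = np.exp(1j * phases).sum()
    r = np.abs(z) / n
    mean_angle = float(wrap_angle(np.angle(z)))
    rz = n * r**2
    # Zar's approximation to the Rayleigh p-value, accurate for small n too
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - rz * n)) - (1 + 2 * n))
    return PhaseStats(int(n), mean_angle, float(r), float(rz), float(min(p, 1.0)))


def rayleigh_test(phases) -> tuple[float, float]:
    """(z, p) of the Rayleigh non-uniformity test."""
    st = phase_stats(phases)
    return st.rayleigh_z, st.p_value


def circ_linear_corr(angles, values) -> tuple[float, float]:
    """Circular-linear correlation of a linear variable with an angle.

    Uses the sine/cosine embedding: with rxs = corr(x, sin a),
    rxc = corr(x, cos a), rcs = corr(sin a, cos a),

        rho^2 = (rxc^2 + rxs^2 - 2 rxc rxs rcs) / (1 - rcs^2)

    and p from the chi-square(2) approximation of n * rho^2.
    """
    a = np.asarray(angles, float)
    x = np.asarray(values, float)
    if a.size != x.size:
        raise ValueError("angles and values must have equal length")
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        return np.nan, np.nan  # constant linear variable: undefined
    sa, ca = np.sin(a), np.cos(a)
    rxs = np.corrcoef(x, sa)[0, 1]
    rxc = np.corrcoef(x, ca)[0, 1]
    rcs = np.corrcoef(sa, ca)[0, 1]
    rho2 = (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2)
    rho = float(np.sqrt(max(rho2, 0.0)))
    p = float(stats.chi2.sf(n * rho**2, df=2))
    return min(rho, 1.0), p
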