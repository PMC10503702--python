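"""Continuous wavelet machinery: Morlet CWT, global spectra, cross-spectra.

The movement features are built on the analytic Morlet wavelet with centre
frequency parameter ``omega0 = 6`` (the common choice balancing time and
frequency localisation).  The transform is evaluated in the frequency domain:
one FFT of the (zero-padded) signal, a Gaussian window per scale, one batched
inverse FFT.  Because the analytic wavelet has no response at or below zero
frequency, the transform is exactly invariant to constant offsets.

Two fixed logarithmic frequency grids are used, 16 voices per octave:

* the *GWS band* [0.25, 5] Hz for global wavelet spectra of position and
  velocity traces, anchored so the top grid point is exactly 5 Hz (the
  "power at 5 Hz" feature reads the density there);
* the *RP band* [1/15, 2] Hz for the leader-follower cross-spectrum whose
  phase measures the relative lag between the two players.

The global wavelet spectrum (GWS) is the time-average of wavelet power over
valid (non-saturated) samples, pooled across trials weighted by valid
duration, and normalised to unit integral over the band so that the mean
frequency ``integral of f * GWS(f) df`` is a proper weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .records import SampledSeries

OMEGA0 = 6.0
VOICES_PER_OCTAVE = 16
GWS_BAND = (0.25, 5.0)
RP_BAND = (1.0 / 15.0, 2.0)

#: Fourier factor for the Morlet wavelet: frequency = FOURIER_FACTOR / scale.
FOURIER_FACTOR = (OMEGA0 + np.sqrt(2.0 + OMEGA0**2)) / (4.0 * np.pi)


def log_frequency_grid(
    band: tuple[float, float], voices: int = VOICES_PER_OCTAVE
) -> np.ndarray:
    """Ascending log-spaced grid over ``band``, anchored at the upper edge.

    Frequencies are ``f_max * 2**(-k/voices)`` for k = 0, 1, ... while the
    value stays >= the band floor, returned in ascending order; the top grid
    point is exactly the band ceiling.
    """
    f_min, f_max = band
    if not 0 < f_min < f_max:
        raise InvalidArgumentError("band must satisfy 0 < low < high")
    n = int(np.floor(voices * np.log2(f_max / f_min))) + 1
    freqs = f_max * 2.0 ** (-np.arange(n) / voices)
    return freqs[::-1].copy()


def grid_step_ratio(voices: int = VOICES_PER_OCTAVE) -> float:
    """Multiplicative spacing between adjacent grid frequencies."""
    return 2.0 ** (1.0 / voices)


def cwt_morlet(values: np.ndarray, rate_hz: float, freqs: np.ndarray) -> np.ndarray:
    """Analytic Morlet CWT of a uniformly sampled signal.

    Returns the complex coefficient array of shape ``(len(freqs), len(values))``.
    The signal is zero-padded to the next power of two at least twice its
    length to suppress circular wrap-around.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DegenerateInputError("signal must be a 1-D array with >= 2 samples")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise InvalidArgumentError("frequencies must be positive")
    n = len(x)
    dt = 1.0 / rate_hz
    # Demean before padding: the analytic wavelet ignores DC, but a constant
    # offset would otherwise leak through the zero-padding edges.
    x = x - x.mean()
    n_pad = 1 << int(np.ceil(np.log2(2 * n)))
    xhat = np.fft.fft(x, n_pad)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    scales = FOURIER_FACTOR / freqs  # seconds
    # Analytic Morlet in the frequency domain, per-scale energy normalisation.
    arg = scales[:, None] * omega[None, :] - OMEGA0
    windows = (np.pi**-0.25) * np.sqrt(2.0 * np.pi * scales[:, None] / dt) * np.exp(
        -0.5 * arg**2
    )
    windows[:, omega <= 0] = 0.0  # analytic: no negative/zero-frequency response
    coeffs = np.fft.ifft(xhat[None, :] * windows, axis=1)[:, :n]
    return coeffs


@dataclass
class GWSpectrum:
    """Normalised global wavelet spectrum on the fixed GWS grid."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.frequencies.shape != self.density.shape:
            raise InvalidArgumentError("grid/density shape mismatch")
        if np.any(self.density < 0):
            raise InvalidArgumentError("density must be non-negative")

    @property
    def band_integral(self) -> float:
        return float(np.trapezoid(self.density, self.frequencies))


@dataclass
class WCSField:
    """Complex wavelet cross-spectrum restricted to the RP band.

    Orientation: ``W_follower * conj(W_leader)``, so a follower lagging the
    leader by tau has phase ``-2*pi*f*tau`` (negative for a lagging follower;
    the "phase drops below -pi/4" feature relies on this sign).
    """

    frequencies: np.ndarray
    times: np.ndarray
    values: np.ndarray  # shape (n_freq, n_time), complex
    valid_mask: np.ndarray  # shape (n_time,), bool

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.frequencies), len(self.times)):
            raise InvalidArgumentError("cross-spectrum shape mismatch")
        if len(self.valid_mask) != len(self.times):
            raise InvalidArgumentError("mask length mismatch")


def compute_gws(
    segments: Sequence[SampledSeries],
    masks: Optional[Sequence[Optional[np.ndarray]]] = None,
    band: tuple[float, float] = GWS_BAND,
    min_valid_s: float = 15.0,
) -> GWSpectrum:
    """Pooled global wavelet spectrum over one or more uniform segments.

    Per segment the Morlet scalogram power is averaged over valid times; the
    segment averages are pooled weighted by valid duration and the result is
    normalised to unit trapezoidal integral over the band.
    """
    if not segments:
        raise DegenerateInputError("no segments")
    if masks is None:
        masks = [None] * len(segments)
    freqs = log_frequency_grid(band)
    pooled = np.zeros(len(freqs))
    total_valid = 0.0
    rate = segments[0].nominal_rate
    for seg, mask in zip(segments, masks):
        if abs(seg.nominal_rate - rate) > 1e-9:
            raise InvalidArgumentError("segments must share one sampling rate")
        m = np.ones(len(seg), dtype=bool) if mask is None else np.asarray(mask, bool)
        if len(m) != len(seg):
            raise InvalidArgumentError("mask length mismatch")
        n_valid = int(m.sum())
        if n_valid == 0:
            continue
        power = np.abs(cwt_morlet(seg.values, seg.nominal_rate, freqs)) ** 2
        pooled += power[:, m].mean(axis=1) * (n_valid / seg.nominal_rate)
        total_valid += n_valid / seg.nominal_rate
    if total_valid < min_valid_s:
        raise DegenerateInputError(
            f"pooled valid duration {total_valid:.1f}s < required {min_valid_s}s"
        )
    pooled /= total_valid
    norm = np.trapezoid(pooled, freqs)
    if norm <= 0 or not np.isfinite(norm):
        raise DegenerateInputError("zero spectral power (constant trace?)")
    return GWSpectrum(freqs, pooled / norm)


def gws_summaries(spec: GWSpectrum) -> dict[str, float]:
    """Peak frequency, mean frequency and density at the 5 Hz grid point.

    Peak = argmax over the grid (ties resolved to the lowest frequency);
    mean = trapezoid of ``f * density`` over the band; the 5 Hz value is the
    density at the top grid point.
    """
    peak = float(spec.frequencies[int(np.argmax(spec.density))])
    mean = float(np.trapezoid(spec.frequencies * spec.density, spec.frequencies))
    return {
        "peak_frequency": peak,
        "mean_frequency": mean,
        "power_at_5hz": float(spec.density[-1]),
    }


def compute_wcs(
    leader: SampledSeries,
    follower: SampledSeries,
    mask: Optional[np.ndarray] = None,
    band: tuple[float, float] = RP_BAND,
    min_valid_s: float = 30.0,
) -> WCSField:
    """Wavelet cross-spectrum ``W_follower * conj(W_leader)`` on the RP grid.

    Both traces must share one uniform grid.  The band floor of 1/15 Hz means
    a 15 s oscillation period, hence the longer minimum-support requirement.
    """
    if len(leader) != len(follower) or not np.allclose(
        leader.timestamps, follower.timestamps
    ):
        raise InvalidArgumentError("leader and follower must share one time grid")
    m = np.ones(len(follower), dtype=bool) if mask is None else np.asarray(mask, bool)
    if m.sum() / follower.nominal_rate < min_valid_s:
        raise DegenerateInputError("insufficient valid duration for cross-spectrum")
    freqs = log_frequency_grid(band)
    wf = cwt_morlet(follower.values, follower.nominal_rate, freqs)
    wl = cwt_morlet(leader.values, leader.nominal_rate, freqs)
    return WCSField(freqs, follower.timestamps.copy(), wf * np.conj(wl), m)
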