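"""Goodness-of-fit and spectral analysis of dipole traces.

RMSE against recorded/target waveforms, Welch power spectral density,
complex-Morlet spectrograms, band-peak extraction, and non-negative
trial-spectrogram averaging (bursty, non-time-locked rhythms accumulate in
the averaged spectrogram instead of cancelling as they would in the
averaged waveform).

Traces are detrended (mean removed) before spectral estimation, and the
settling window at the start of a simulation should be excluded by the
caller (the simulation results carry it as ``settle_window``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "Spectrogram",
    "FitReport",
    "resample_to",
    "rmse",
    "psd",
    "band_peak",
    "morlet_spectrogram",
    "average_spectrograms",
]

#: number of cycles in the complex Morlet mother wavelet
MORLET_CYCLES = 7.0

_ALLOWED_CMAPS = ("jet", "viridis", "plasma", "inferno", "magma", "cividis")


@dataclass
class Spectrogram:
    """Time-frequency power representation of a dipole trace."""

    times: np.ndarray        # ms
    frequencies: np.ndarray  # Hz
    power: np.ndarray        # (n_freq, n_time), >= 0
    colormap: str = "viridis"
    edge_mask: np.ndarray | None = None  # True where edge effects matter

    def __post_init__(self):
        if self.power.shape != (len(self.frequencies), len(self.times)):
            raise ValueError("power matrix dimensions do not match the grids")
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be non-negative")
        if self.colormap not in _ALLOWED_CMAPS:
            raise ValueError(
                f"colormap {self.colormap!r} not in {_ALLOWED_CMAPS}"
            )


@dataclass
class FitReport:
    rmse: float       # nAm
    window: tuple[float, float]  # ms
    n_samples: int

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def resample_to(
    times_src: np.ndarray, values_src: np.ndarray, times_dst: np.ndarray
) -> np.ndarray:
    """Linear interpolation of a trace onto a destination grid."""
    return np.interp(times_dst, times_src, values_src)


def rmse(
    sim_times: np.ndarray,
    sim_values: np.ndarray,
    data_times: np.ndarray,
    data_values: np.ndarray,
    window: tuple[float, float] | None = None,
) -> FitReport:
    """Root-mean-squared error between two traces on their overlap.

    The data trace is linearly interpolated onto the simulation grid;
    the RMSE is computed over the overlapping time window (optionally
    intersected with ``window``).
    """
    sim_times = np.asarray(sim_times, dtype=float)
    lo = max(sim_times[0], np.min(data_times))
    hi = min(sim_times[-1], np.max(data_times))
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    mask = (sim_times >= lo) & (sim_times <= hi)
    if not mask.any():
        raise ValueError("traces have no overlapping samples")
    d = resample_to(np.asarray(data_times), np.asarray(data_values), sim_times[mask])
    s = np.asarray(sim_values)[mask]
    err = float(np.sqrt(np.mean((s - d) ** 2)))
    return FitReport(rmse=err, window=(float(lo), float(hi)), n_samples=int(mask.sum()))


def psd(
    times: np.ndarray,
    values: np.ndarray,
    segment_ms: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with Hann windows.

    Segments default to 1 s (or the full trace if shorter); the trace mean
    is removed first.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    dt_ms = t[1] - t[0]
    fs = 1000.0 / dt_ms  # Hz
    nper = min(len(x), int(round(segment_ms / dt_ms)))
    freqs, power = sps.welch(
        x - x.mean(), fs=fs, window="hann", nperseg=nper
    )
    return freqs, power


def band_peak(
    frequencies: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float],
) -> float:
    """Frequency (Hz) of maximum power within ``band``.

    ``power`` may be a PSD vector or a spectrogram matrix (frequencies on
    the first axis; power is then averaged over time before the argmax).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    power = np.asarray(power, dtype=float)
    if power.ndim == 2:
        power = power.mean(axis=1)
    lo, hi = band
    if lo < frequencies.min() or hi > frequencies.max():
        raise ValueError(
            f"band {band} outside the computed frequency range "
            f"[{frequencies.min():.3g}, {frequencies.max():.3g}] Hz"
        )
    mask = (frequencies >= lo) & (frequencies <= hi)
    if not mask.any():
        raise ValueError("no frequency samples inside the band")
    sub = power[mask]
    return float(frequencies[mask][np.argmax(sub)])


def morlet_spectrogram(
    times: np.ndarray,
    values: np.ndarray,
    frequencies: np.ndarray,
    colormap: str = "viridis",
) -> Spectrogram:
    """Complex-Morlet wavelet spectrogram (power per time-frequency bin).

    Uses a 7-cycle complex Morlet mother wavelet; samples within one
    wavelet half-width of either edge are flagged in ``edge_mask``.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    dt_ms = t[1] - t[0]
    fs = 1000.0 / dt_ms
    if np.any(freqs <= 0) or np.any(freqs > fs / 2):
        raise ValueError(
            f"frequency grid must lie in (0, {fs / 2:.1f}] Hz (Nyquist)"
        )
    span_ms = t[-1] - t[0]
    longest_ms = MORLET_CYCLES / freqs.min() * 1000.0
    if span_ms <= longest_ms:
        raise ValueError(
            f"trace ({span_ms:.0f} ms) shorter than the longest wavelet "
            f"({longest_ms:.0f} ms at {freqs.min():.3g} Hz)"
        )
    x = x - x.mean()
    # cmorB-C: bandwidth B chosen so the Gaussian envelope holds ~7 cycles
    bw = (MORLET_CYCLES / (2.0 * np.pi)) ** 2 * 2.0
    wavelet = f"cmor{bw}-1.0"
    fc = pywt.central_frequency(wavelet)  # = 1.0 (cycles per unit)
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    power = np.abs(coeffs) ** 2
    # flag edges: half the wavelet support per frequency
    edge = np.zeros_like(power, dtype=bool)
    for i, f in enumerate(freqs):
        half_ms = 0.5 * MORLET_CYCLES / f * 1000.0
        edge[i] = (t - t[0] < half_ms) | (t[-1] - t < half_ms)
    return Spectrogram(
        times=t, frequencies=freqs, power=power, colormap=colormap,
        edge_mask=edge,
    )


def average_spectrograms(spectrograms: list[Spectrogram]) -> Spectrogram:
    """Element-wise mean of spectrograms on identical grids.

    Power is non-negative, so bursts occurring at different times in
    different trials accumulate rather than cancel.
    """
    if not spectrograms:
        raise ValueError("no spectrograms to average")
    first = spectrograms[0]
    for s in spectrograms[1:]:
        if (
            s.power.shape != first.power.shape
            or not np.allclose(s.times, first.times)
            or not np.allclose(s.frequencies, first.frequencies)
        ):
            raise ValueError("spectrogram grids do not match")
    mean_power = np.mean([s.power for s in spectrograms], axis=0)
    return Spectrogram(
        times=first.times.copy(),
        frequencies=first.frequencies.copy(),
        power=mean_power,
        colormap=first.colormap,
        edge_mask=first.edge_mask,
    )
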