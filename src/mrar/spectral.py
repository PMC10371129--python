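"""Spectral analysis of surface-displacement traces.

Each measurement's displacement-vs-fast-time trace is mean-subtracted,
zero-padded and Fourier transformed; the magnitude-squared spectrum is
normalized to unit maximum.  Stacking the per-measurement spectra over
observation time yields the coagulation spectrogram, and the resonant
surface-wave frequency is read off as the spectral peak (parabolically
refined on log power), together with its -3 dB width — the width grows as
the oscillation becomes more heavily damped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import AnalysisOptions
from .tracking import DisplacementMatrix, DisplacementTrace

__all__ = [
    "PowerSpectrum",
    "Spectrogram",
    "FrequencyTrace",
    "power_spectrum",
    "peak_frequency",
    "build_spectrogram",
]

_LOG_FLOOR = 1e-300


@dataclass
class PowerSpectrum:
    """Normalized (max = 1) power spectrum of one displacement trace."""

    frequency: np.ndarray
    power: np.ndarray
    observation_time_T: float = 0.0
    degenerate: bool = False     # all-zero / unusable input trace


@dataclass
class Spectrogram:
    """Per-measurement normalized power spectra stacked over observation time."""

    channel_id: int
    observation_times: np.ndarray
    frequency: np.ndarray
    power: np.ndarray            # [n_T, n_freq]; each valid row has max 1
    degenerate: np.ndarray       # bool per observation time


@dataclass
class FrequencyTrace:
    """Resonant-frequency curve over observation time."""

    channel_id: int
    observation_times: np.ndarray
    peak_frequency: np.ndarray   # Hz; NaN where missing/degenerate
    peak_width: np.ndarray       # -3 dB span, Hz
    peak_power: np.ndarray       # normalized peak power


def _default_nfft(n: int, n_fft: Optional[int]) -> int:
    return int(n_fft) if n_fft else 4 * n


def power_spectrum(
    trace,
    fast_time_step: Optional[float] = None,
    n_fft: Optional[int] = None,
) -> PowerSpectrum:
    """Normalized power spectrum of a displacement trace in fast time.

    ``trace`` may be a :class:`DisplacementTrace` or a plain array (then
    ``fast_time_step`` is required).  The trace is mean-subtracted and
    zero-padded to ``n_fft`` (default 4x the trace length).  An all-zero or
    non-finite trace yields a flat zero spectrum flagged degenerate.
    """
    if isinstance(trace, DisplacementTrace):
        x = np.asarray(trace.displacement, dtype=float)
        dtau = float(trace.tau[1] - trace.tau[0])
        T = float(trace.observation_time_T)
    else:
        x = np.asarray(trace, dtype=float)
        if fast_time_step is None:
            raise ValueError("fast_time_step is required for a bare array")
        dtau = float(fast_time_step)
        T = 0.0
    if len(x) < 8:
        raise ValueError("trace must have at least 8 samples")

    nfft = _default_nfft(len(x), n_fft)
    freq = np.fft.rfftfreq(nfft, d=dtau)
    if not np.all(np.isfinite(x)) or np.allclose(x, x[0]):
        return PowerSpectrum(freq, np.zeros_like(freq), T, degenerate=True)

    spec = np.abs(np.fft.rfft(x - x.mean(), n=nfft)) ** 2
    peak = spec.max()
    return PowerSpectrum(freq, spec / peak, T, degenerate=False)


def _minus3db_width(freq: np.ndarray, power: np.ndarray, i_peak: int) -> float:
    """-3 dB (half-power) span around the peak, edges linearly interpolated."""
    half = 0.5 * power[i_peak]
    # walk left
    i = i_peak
    while i > 0 and power[i - 1] >= half:
        i -= 1
    if i == 0:
        f_lo = freq[0]
    else:
        f_lo = np.interp(half, [power[i - 1], power[i]], [freq[i - 1], freq[i]])
    # walk right
    j = i_peak
    while j < len(power) - 1 and power[j + 1] >= half:
        j += 1
    if j == len(power) - 1:
        f_hi = freq[-1]
    else:
        f_hi = np.interp(half, [power[j + 1], power[j]], [freq[j + 1], freq[j]])
    return float(max(f_hi - f_lo, 0.0))


def peak_frequency(
    spectrum: PowerSpectrum,
    band: Optional[Tuple[float, float]] = None,
    min_frequency: float = 10.0,
) -> Tuple[float, float, float]:
    """Locate the resonant peak: returns (f_peak, -3 dB width, peak power).

    The search band defaults to [min_frequency, 0.8 * f_max]; the floor
    rejects DC leakage.  The global band maximum is refined by 3-point
    parabolic interpolation on log power.  Exact power ties resolve to the
    lowest frequency.  A degenerate spectrum returns NaNs.
    """
    if spectrum.degenerate:
        return float("nan"), float("nan"), float("nan")
    freq, power = spectrum.frequency, spectrum.power
    if band is None:
        band = (min_frequency, 0.8 * freq[-1])
    mask = (freq >= band[0]) & (freq <= band[1])
    if not mask.any():
        return float("nan"), float("nan"), float("nan")
    idx = np.flatnonzero(mask)
    i_peak = idx[int(np.argmax(power[idx]))]  # argmax takes the first = lowest f on ties

    f_peak = _refine_peak(freq, power, i_peak)
    width = _minus3db_width(freq, power, i_peak)
    return float(f_peak), width, float(power[i_peak])


def _refine_peak(freq: np.ndarray, power: np.ndarray, i_peak: int) -> float:
    """Sub-bin peak location from a parabola on log power.

    A least-squares parabola is fitted over the contiguous half-power top of
    the peak, which suppresses noise-driven peak wander on broad (heavily
    damped) resonances; narrow tops fall back to the classic 3-point fit.
    """
    if not (0 < i_peak < len(freq) - 1) or power[i_peak] <= 0:
        return float(freq[i_peak])
    thr = 0.5 * power[i_peak]
    lo = i_peak
    while lo > 0 and power[lo - 1] >= thr:
        lo -= 1
    hi = i_peak
    while hi < len(power) - 1 and power[hi + 1] >= thr:
        hi += 1
    if hi - lo >= 2:
        coef = np.polyfit(freq[lo : hi + 1], np.log(np.maximum(power[lo : hi + 1], _LOG_FLOOR)), 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2.0 * coef[0])
            if freq[lo] <= vertex <= freq[hi]:
                return float(vertex)
    logp = np.log(np.maximum(power[i_peak - 1 : i_peak + 2], _LOG_FLOOR))
    denom = logp[0] - 2.0 * logp[1] + logp[2]
    if denom < 0:
        delta = float(np.clip(0.5 * (logp[0] - logp[2]) / denom, -0.5, 0.5))
        return float(freq[i_peak] + delta * (freq[1] - freq[0]))
    return float(freq[i_peak])


def build_spectrogram(
    matrix: DisplacementMatrix,
    n_fft: Optional[int] = None,
    options: Optional[AnalysisOptions] = None,
) -> Tuple[Spectrogram, FrequencyTrace]:
    """Per-measurement spectra + resonant-frequency trace for one channel.

    Gap rows of the displacement matrix propagate as degenerate spectra and
    NaN frequency-trace samples.  An empty matrix yields empty outputs.
    """
    options = options or AnalysisOptions()
    n_T = matrix.matrix.shape[0]
    if n_T == 0:
        empty = np.empty(0)
        sg = Spectrogram(matrix.channel_id, empty, empty, np.empty((0, 0)), np.empty(0, bool))
        ft = FrequencyTrace(matrix.channel_id, empty, empty.copy(), empty.copy(), empty.copy())
        return sg, ft

    dtau = float(matrix.tau[1] - matrix.tau[0])
    nfft = _default_nfft(matrix.matrix.shape[1], n_fft if n_fft else options.n_fft)
    freq = np.fft.rfftfreq(nfft, d=dtau)

    power = np.zeros((n_T, len(freq)))
    degenerate = np.zeros(n_T, dtype=bool)
    f_peak = np.full(n_T, np.nan)
    width = np.full(n_T, np.nan)
    p_peak = np.full(n_T, np.nan)
    for m in range(n_T):
        row = matrix.matrix[m]
        if matrix.gap[m] or not np.all(np.isfinite(row)):
            degenerate[m] = True
            continue
        ps = power_spectrum(row, fast_time_step=dtau, n_fft=nfft)
        power[m] = ps.power
        degenerate[m] = ps.degenerate
        if not ps.degenerate:
            f_peak[m], width[m], p_peak[m] = peak_frequency(
                ps, min_frequency=options.min_search_frequency
            )
    sg = Spectrogram(matrix.channel_id, matrix.observation_times.copy(), freq, power, degenerate)
    ft = FrequencyTrace(
        matrix.channel_id, matrix.observation_times.copy(), f_peak, width, p_peak
    )
    return sg, ft
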