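"""Pulse-echo surface-displacement tracking.

Each RAR measurement is reduced to a displacement trace by comparing every
post-push detection echo against the *equilibrium reference* — the pointwise
average of the baseline echoes recorded before the push (averaging mitigates
pulse-to-pulse transmit-amplitude variation).  The time-of-flight shift of
the sample-surface echo is estimated by normalized cross-correlation over a
lag search window, refined to sub-sample precision by 3-point parabolic
interpolation of the correlation peak, and converted to displacement via
``s = c * delay / 2`` (positive = surface moving away from the transducer).

Correlation is restricted to a gate around the equilibrium surface echo,
located as the strongest echo in the envelope of the averaged baseline; the
well-plate interface echoes are static and are excluded by the gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve, hilbert

from .config import AcquisitionConfig, AnalysisOptions
from .simulate import MeasurementRecord

__all__ = [
    "ReferenceEcho",
    "DisplacementTrace",
    "DisplacementMatrix",
    "build_reference",
    "estimate_delay",
    "delay_to_displacement",
    "track_measurement",
    "assemble_matrix",
]


@dataclass
class ReferenceEcho:
    """Gated equilibrium reference: averaged baseline restricted to the surface echo."""

    samples: np.ndarray
    gate_start: int          # index of the gate's first sample in the full A-line
    sampling_rate: float


@dataclass
class DelayEstimate:
    delay: float             # s, positive = echo arrives later
    peak: float              # normalized correlation peak in [-1, 1]
    low_confidence: bool


@dataclass
class DisplacementTrace:
    """Surface displacement vs fast time for one measurement."""

    channel_id: int
    observation_time_T: float
    tau: np.ndarray
    displacement: np.ndarray
    correlation_peak: np.ndarray
    low_confidence: np.ndarray


@dataclass
class DisplacementMatrix:
    """S(T_m, tau_n): displacement field of one channel over the whole run."""

    channel_id: int
    observation_times: np.ndarray
    tau: np.ndarray
    matrix: np.ndarray            # [n_T, n_tau]; NaN rows mark gaps
    correlation_peak: np.ndarray
    gap: np.ndarray               # bool per observation time


def _gate_half_width_samples(config: AcquisitionConfig, options: AnalysisOptions) -> int:
    # "pulse length" of a short (2-cycle) detection pulse at the center frequency
    pulse_length = 2.0 / config.center_frequency
    return max(4, int(round(options.gate_half_width_pulses * pulse_length * config.sampling_rate)))


def build_reference(
    record: MeasurementRecord,
    config: AcquisitionConfig,
    options: Optional[AnalysisOptions] = None,
) -> ReferenceEcho:
    """Average the baseline A-lines and gate them around the surface echo.

    The surface echo is located as the strongest peak of the analytic-signal
    envelope of the averaged baseline.
    """
    options = options or AnalysisOptions()
    baseline = record.baseline_alines
    if baseline.shape[0] == 0:
        raise ValueError("record contains no baseline pulses")
    mean_trace = baseline.mean(axis=0)
    envelope = np.abs(hilbert(mean_trace))
    center = int(np.argmax(envelope))
    half = _gate_half_width_samples(config, options)
    start = max(0, center - half)
    stop = min(len(mean_trace), center + half + 1)
    return ReferenceEcho(mean_trace[start:stop].copy(), start, config.sampling_rate)


def _ncc_valid(reference: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation, valid mode, batched over segment rows.

    ``segments`` has shape (P, n_ref + 2L); returns (P, 2L + 1) with lag
    index j meaning the echo window starts j - L samples late.
    """
    ref = reference - 0.0
    n_ref = len(ref)
    raw = fftconvolve(segments, ref[::-1][None, :], mode="valid", axes=1)
    energy = np.concatenate(
        [np.zeros((segments.shape[0], 1)), np.cumsum(segments**2, axis=1)], axis=1
    )
    win_energy = energy[:, n_ref:] - energy[:, : segments.shape[1] - n_ref + 1]
    denom = np.sqrt(np.maximum(win_energy, 0.0)) * np.linalg.norm(ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 0, raw / denom, 0.0)
    return np.clip(ncc, -1.0, 1.0)


def _parabolic_offset(cm1: np.ndarray, c0: np.ndarray, cp1: np.ndarray) -> np.ndarray:
    denom = cm1 - 2.0 * c0 + cp1
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(np.abs(denom) > 0, 0.5 * (cm1 - cp1) / denom, 0.0)
    return np.clip(delta, -1.0, 1.0)


def _delays_from_segments(
    reference: np.ndarray,
    segments: np.ndarray,
    max_lag: int,
    sampling_rate: float,
    correlation_floor: float,
):
    ncc = _ncc_valid(reference, segments)
    j = np.argmax(ncc, axis=1)  # first (earliest-lag) maximum on exact ties
    rows = np.arange(ncc.shape[0])
    peak = ncc[rows, j]
    # 3-point parabolic refinement, skipped at window edges
    interior = (j > 0) & (j < ncc.shape[1] - 1)
    jm = np.clip(j - 1, 0, ncc.shape[1] - 1)
    jp = np.clip(j + 1, 0, ncc.shape[1] - 1)
    delta = np.where(interior, _parabolic_offset(ncc[rows, jm], peak, ncc[rows, jp]), 0.0)
    lag = (j - max_lag) + delta
    delays = lag / sampling_rate
    flags = peak < correlation_floor
    return delays, peak, flags


def estimate_delay(
    reference: np.ndarray,
    echo: np.ndarray,
    search_window: float,
    sampling_rate: float,
    correlation_floor: float = 0.5,
) -> DelayEstimate:
    """Estimate the arrival-time shift of ``echo`` relative to ``reference``.

    Both traces must be gated to the surface echo on the same sample grid.
    ``search_window`` is the +- lag range in seconds.  If ``echo`` has the
    same length as ``reference`` it is zero-padded at both ends; a longer
    echo segment (len(reference) + 2L) is used as-is.  A peak correlation
    below ``correlation_floor`` sets the low-confidence flag (the delay is
    still returned).
    """
    reference = np.asarray(reference, dtype=float)
    echo = np.asarray(echo, dtype=float)
    max_lag = max(1, int(round(search_window * sampling_rate)))
    expected = len(reference) + 2 * max_lag
    if len(echo) == len(reference):
        echo = np.pad(echo, max_lag)
    elif len(echo) != expected:
        raise ValueError(
            f"echo length must equal reference length or reference+2*{max_lag}, got {len(echo)}"
        )
    delays, peaks, flags = _delays_from_segments(
        reference, echo[None, :], max_lag, sampling_rate, correlation_floor
    )
    return DelayEstimate(float(delays[0]), float(peaks[0]), bool(flags[0]))


def delay_to_displacement(delay, sound_speed: float):
    """Convert an echo-delay shift to surface displacement: s = c * delay / 2."""
    if sound_speed <= 0:
        raise ValueError("sound_speed must be positive")
    return sound_speed * np.asarray(delay, dtype=float) / 2.0


def track_measurement(
    record: MeasurementRecord,
    config: AcquisitionConfig,
    options: Optional[AnalysisOptions] = None,
) -> DisplacementTrace:
    """Track one measurement: reference, per-pulse delay, displacement."""
    options = options or AnalysisOptions()
    ref = build_reference(record, config, options)
    max_lag = max(1, int(round(options.search_window * config.sampling_rate)))

    detection = record.detection_alines
    n_ref = len(ref.samples)
    start = ref.gate_start - max_lag
    stop = ref.gate_start + n_ref + max_lag
    if start < 0 or stop > detection.shape[1]:
        pad_lo, pad_hi = max(0, -start), max(0, stop - detection.shape[1])
        detection = np.pad(detection, ((0, 0), (pad_lo, pad_hi)))
        start += pad_lo
        stop += pad_lo
    segments = detection[:, start:stop]

    delays, peaks, flags = _delays_from_segments(
        ref.samples, segments, max_lag, config.sampling_rate, options.correlation_floor
    )
    displacement = delay_to_displacement(delays, config.sound_speed)
    return DisplacementTrace(
        channel_id=record.channel_id,
        observation_time_T=record.observation_time_T,
        tau=record.fast_time_grid.copy(),
        displacement=np.asarray(displacement),
        correlation_peak=peaks,
        low_confidence=flags,
    )


def assemble_matrix(
    traces: Sequence[DisplacementTrace],
    expected_times: Optional[np.ndarray] = None,
) -> DisplacementMatrix:
    """Stack displacement traces of one channel into S(T_m, tau_n).

    Rows are ordered by observation time regardless of input order.  If
    ``expected_times`` is given, missing measurements become NaN gap rows —
    they are flagged, never interpolated.
    """
    if not traces:
        raise ValueError("no traces to assemble")
    channels = {t.channel_id for t in traces}
    if len(channels) > 1:
        raise ValueError(f"traces mix channels {sorted(channels)}")
    tau = traces[0].tau
    for t in traces:
        if len(t.tau) != len(tau) or not np.allclose(t.tau, tau):
            raise ValueError("traces have inconsistent fast-time grids")

    by_time = {float(t.observation_time_T): t for t in sorted(traces, key=lambda t: t.observation_time_T)}
    if expected_times is None:
        times = np.array(sorted(by_time))
    else:
        times = np.asarray(expected_times, dtype=float)

    n_tau = len(tau)
    matrix = np.full((len(times), n_tau), np.nan)
    peaks = np.full((len(times), n_tau), np.nan)
    gap = np.ones(len(times), dtype=bool)
    for i, T in enumerate(times):
        t = by_time.get(float(T))
        if t is not None:
            matrix[i] = t.displacement
            peaks[i] = t.correlation_peak
            gap[i] = False
    return DisplacementMatrix(
        channel_id=traces[0].channel_id,
        observation_times=times,
        tau=tau.copy(),
        matrix=matrix,
        correlation_peak=peaks,
        gap=gap,
    )
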