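"""Multichannel RAR acquisition simulator.

Generates synthetic RF pulse-echo archives that emulate one measurement
sequence per observation time: ``n_baseline_pulses`` detection pulses sample
the surface at equilibrium, a push tone burst perturbs the surface, and
``n_detection_pulses`` detection pulses at the PRF record the ringing
surface.  Each A-line contains two fixed well-plate interface echoes and one
sample-surface echo (a Gaussian-windowed tone at the transducer center
frequency) whose round-trip delay encodes the instantaneous surface
displacement, plus white Gaussian noise and per-pulse transmit-amplitude
jitter.

The simulator also emits the exact ground truth — noiseless displacement
waveforms, the resonant-frequency curve, and coagulation parameters obtained
by applying the extraction thresholds to the noiseless curve — so every
downstream stage can be tested against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import AcquisitionConfig
from .trajectory import CoagulationTrajectory, surface_response

__all__ = [
    "MeasurementRecord",
    "ChannelGroundTruth",
    "GroundTruth",
    "RunArchive",
    "echo_pulse",
    "synthesize_aline",
    "simulate_run",
]

#: Relative depths (fractions of surface_depth) and amplitudes of the two
#: static well-plate interface echoes; the sample-surface echo has unit
#: amplitude (air-sample interface, near-total reflection).
_PLATE_DEPTH_FRACTIONS = (0.25, 0.35)
_PLATE_AMPLITUDES = (0.5, 0.7)


def _envelope_sigma(config: AcquisitionConfig) -> float:
    """Gaussian envelope sigma (s) from the -6 dB fractional bandwidth."""
    bw = config.fractional_bandwidth * config.center_frequency
    sigma_f = 0.5 * bw / math.sqrt(2.0 * math.log(2.0))
    return 1.0 / (2.0 * math.pi * sigma_f)


def echo_pulse(config: AcquisitionConfig, t, arrival: float, amplitude: float = 1.0):
    """Gaussian-windowed tone echo centered at ``arrival`` on time grid ``t``."""
    sigma = _envelope_sigma(config)
    dt = np.asarray(t) - arrival
    return amplitude * np.exp(-0.5 * (dt / sigma) ** 2) * np.sin(
        2.0 * np.pi * config.center_frequency * dt
    )


def _time_grid(config: AcquisitionConfig) -> np.ndarray:
    return np.arange(config.n_samples) / config.sampling_rate


def _surface_delay(config: AcquisitionConfig, displacement) -> np.ndarray:
    """Round-trip delay of the surface echo for a given displacement (m)."""
    return 2.0 * (config.surface_depth + np.asarray(displacement, dtype=float)) / config.sound_speed


def _check_delay_in_trace(config: AcquisitionConfig, delay) -> None:
    margin = 4.0 * _envelope_sigma(config)
    if np.any(np.asarray(delay) + margin > config.trace_duration):
        raise ValueError(
            "surface echo delay exceeds the recorded trace length; "
            "increase trace_duration or reduce surface_depth"
        )


def _plate_trace(config: AcquisitionConfig) -> np.ndarray:
    """Static part of every A-line: the two well-plate interface echoes."""
    t = _time_grid(config)
    trace = np.zeros_like(t)
    for frac, amp in zip(_PLATE_DEPTH_FRACTIONS, _PLATE_AMPLITUDES):
        arrival = 2.0 * frac * config.surface_depth / config.sound_speed
        trace += echo_pulse(config, t, arrival, amp)
    return trace


def synthesize_aline(
    config: AcquisitionConfig,
    surface_displacement: float,
    rng: Optional[np.random.Generator] = None,
    jitter: float = 1.0,
) -> np.ndarray:
    """Synthesize one RF A-line for a given instantaneous surface displacement.

    Positive displacement moves the surface away from the transducer, so the
    round-trip delay of the surface echo grows by ``2 * displacement /
    sound_speed``.  With ``rng=None`` (or ``noise_snr_db = inf``) the trace
    is noiseless.
    """
    delay = _surface_delay(config, surface_displacement)
    _check_delay_in_trace(config, delay)
    t = _time_grid(config)
    trace = jitter * (_plate_trace(config) + echo_pulse(config, t, float(delay)))
    if rng is not None and np.isfinite(config.noise_snr_db):
        noise_rms = 10.0 ** (-config.noise_snr_db / 20.0)
        trace = trace + rng.normal(0.0, noise_rms, size=trace.shape)
    return trace


@dataclass
class MeasurementRecord:
    """One RAR measurement: the full A-line matrix of one channel at time T."""

    channel_id: int
    observation_time_T: float
    alines: np.ndarray          # [n_baseline + n_detection, n_samples]
    pulse_roles: np.ndarray     # per-row: "baseline" | "detection"
    fast_time_grid: np.ndarray  # tau_n = n / prf for the detection rows

    def __post_init__(self) -> None:
        if self.alines.ndim != 2:
            raise ValueError("alines must be a 2D matrix")
        if self.alines.shape[0] != len(self.pulse_roles):
            raise ValueError("pulse_roles length must match A-line rows")
        steps = np.diff(self.fast_time_grid)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("fast_time_grid must be strictly increasing with constant step")

    @property
    def baseline_alines(self) -> np.ndarray:
        return self.alines[self.pulse_roles == "baseline"]

    @property
    def detection_alines(self) -> np.ndarray:
        return self.alines[self.pulse_roles == "detection"]


@dataclass
class ChannelGroundTruth:
    """Noiseless truth for one channel."""

    channel_id: int
    observation_times: np.ndarray
    f_true: np.ndarray           # resonant frequency per measurement (Hz)
    amp_true: np.ndarray         # oscillation amplitude per measurement (m)
    displacement_true: np.ndarray  # S_true[T_m, tau_n] (m)
    params: "object" = None      # CoagulationParams from the noiseless curve


@dataclass
class GroundTruth:
    channels: list

    def channel(self, channel_id: int) -> ChannelGroundTruth:
        for ch in self.channels:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(channel_id)


@dataclass
class RunArchive:
    """In-memory acquisition archive: all measurements of one run."""

    config: AcquisitionConfig
    records: dict = field(default_factory=dict)  # channel_id -> [MeasurementRecord]

    @property
    def channel_ids(self) -> list:
        return sorted(self.records)

    def measurements(self, channel_id: int) -> list:
        return self.records[channel_id]


def _measurement(
    config: AcquisitionConfig,
    channel_id: int,
    T: float,
    displacements: np.ndarray,
    rng: Optional[np.random.Generator],
) -> MeasurementRecord:
    """Synthesize one full measurement (baseline + detection pulses), vectorized."""
    n_base, n_det = config.n_baseline_pulses, config.n_detection_pulses
    n_pulses = n_base + n_det
    t = _time_grid(config)

    all_disp = np.concatenate([np.zeros(n_base), displacements])
    delays = _surface_delay(config, all_disp)
    _check_delay_in_trace(config, delays)

    sigma = _envelope_sigma(config)
    dt = t[None, :] - delays[:, None]
    surface = np.exp(-0.5 * (dt / sigma) ** 2) * np.sin(2.0 * np.pi * config.center_frequency * dt)
    alines = _plate_trace(config)[None, :] + surface

    if rng is not None:
        if config.amplitude_jitter > 0:
            jitter = rng.uniform(
                1.0 - config.amplitude_jitter, 1.0 + config.amplitude_jitter, size=n_pulses
            )
            alines = alines * jitter[:, None]
        if np.isfinite(config.noise_snr_db):
            noise_rms = 10.0 ** (-config.noise_snr_db / 20.0)
            alines = alines + rng.normal(0.0, noise_rms, size=alines.shape)

    roles = np.array(["baseline"] * n_base + ["detection"] * n_det)
    fast_time = np.arange(n_det) * config.fast_time_step
    return MeasurementRecord(channel_id, float(T), alines, roles, fast_time)


def simulate_run(
    config: AcquisitionConfig,
    trajectories: Sequence[CoagulationTrajectory],
    seed: Optional[int] = None,
):
    """Simulate a full multichannel run.

    Measurements are taken at T_m = m * dT for m = 0 .. floor(total/dT), on
    identical (synchronized) grids for every channel.  Returns the archive of
    raw records and the :class:`GroundTruth` with noiseless displacement
    waveforms, frequency curves, and analytically extracted coagulation
    parameters.
    """
    from .coagulation import params_from_frequency_curve

    if len(trajectories) != config.n_channels:
        raise ValueError(
            f"need one trajectory per channel ({config.n_channels}), got {len(trajectories)}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = config.observation_times
    tau = np.arange(config.n_detection_pulses) * config.fast_time_step

    archive = RunArchive(config=config, records={c: [] for c in range(config.n_channels)})
    truth_channels = []
    for ch, traj in enumerate(trajectories):
        s_true = np.stack([surface_response(traj, T, tau) for T in times])
        for m, T in enumerate(times):
            archive.records[ch].append(_measurement(config, ch, T, s_true[m], rng))
        f_true = np.asarray(traj.frequency(times), dtype=float)
        truth_channels.append(
            ChannelGroundTruth(
                channel_id=ch,
                observation_times=times.copy(),
                f_true=f_true,
                amp_true=np.asarray(traj.amplitude(times), dtype=float),
                displacement_true=s_true,
                params=params_from_frequency_curve(times, f_true, median_filter=False),
            )
        )
    return archive, GroundTruth(channels=truth_channels)
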