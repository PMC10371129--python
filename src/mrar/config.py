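"""Run configuration: acquisition timing, geometry, and analysis options.

A :class:`RunConfig` collects everything a reproducible run needs — the
pulse-sequence timing of the acquisition, the well geometry that fixes the
resonant wavenumber, and the analysis thresholds — and serializes losslessly
to/from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .physics import FIRST_J1_ROOT, WellGeometry


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and acoustic constants of one multichannel RAR run.

    Defaults follow the reference pulse sequence: per measurement, 20
    baseline detection pulses, one 100-cycle push tone burst (20 us at
    5.0 MHz), then 500 detection pulses at a 10 kHz PRF; measurements repeat
    every 6.0 s for up to 60 min on 4 synchronized channels.
    """

    center_frequency: float = 5.0e6      # Hz, transducer center frequency
    sampling_rate: float = 100.0e6       # Hz, RF digitizer rate
    prf: float = 1.0e4                   # Hz, detection pulse repetition frequency
    n_baseline_pulses: int = 20
    n_detection_pulses: int = 500
    push_cycles: int = 100
    measurement_interval_dT: float = 6.0  # s, interval between RAR measurements
    total_duration: float = 3600.0        # s
    n_channels: int = 4
    sound_speed: float = 1480.0           # m/s, in the sample
    surface_depth: float = 2.0e-3         # m, equilibrium surface range from trace start
    trace_duration: float = 5.12e-6       # s, recorded length of each A-line
    fractional_bandwidth: float = 0.6     # -6 dB fractional bandwidth of the echo pulse
    noise_snr_db: float = 30.0            # echo-peak / noise-RMS, dB; inf disables noise
    amplitude_jitter: float = 0.05        # per-pulse multiplicative amplitude jitter (+-5%)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be positive")
        if self.sampling_rate < 4 * self.center_frequency:
            raise ValueError("sampling_rate must be at least 4x center_frequency")
        if self.n_detection_pulses < 2:
            raise ValueError("need at least 2 detection pulses")
        if self.n_baseline_pulses < 1:
            raise ValueError("need at least 1 baseline pulse")
        if self.measurement_interval_dT <= 0 or self.total_duration < 0:
            raise ValueError("invalid measurement timing")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def fast_time_step(self) -> float:
        """Fast-time step between detection pulses, dtau = 1/PRF (s)."""
        return 1.0 / self.prf

    @property
    def push_duration(self) -> float:
        """Push tone-burst duration = push_cycles / center_frequency (s)."""
        return self.push_cycles / self.center_frequency

    @property
    def n_samples(self) -> int:
        """Samples per A-line."""
        return int(round(self.trace_duration * self.sampling_rate))

    @property
    def n_measurements(self) -> int:
        """Number of measurements, at T = m * dT for m = 0 .. floor(total/dT)."""
        return int(self.total_duration // self.measurement_interval_dT) + 1

    @property
    def observation_times(self):
        import numpy as np

        return np.arange(self.n_measurements) * self.measurement_interval_dT


@dataclass(frozen=True)
class AnalysisOptions:
    """Thresholds and numerical options of the analysis chain."""

    n_fft: Optional[int] = None          # None -> 4x trace length
    rise_threshold: float = 1.05          # T_int: first rise 5% above f_int
    plateau_threshold: float = 0.95       # T_end: first reach of 95% of f_end
    median_filter: bool = True            # 3-point median pre-filter on the frequency trace
    correlation_floor: float = 0.5        # below -> low-confidence sample flag
    search_window: float = 0.5e-6         # s, +- lag window for delay estimation
    gate_half_width_pulses: float = 3.0   # echo gate half-width in pulse lengths
    min_search_frequency: float = 10.0    # Hz, spectral search-band floor

    def __post_init__(self) -> None:
        if self.rise_threshold <= 1.0 or not 0 < self.plateau_threshold <= 1.0:
            raise ValueError("invalid coagulation thresholds")
        if not 0 <= self.correlation_floor <= 1:
            raise ValueError("correlation_floor must lie in [0, 1]")
        if self.search_window <= 0:
            raise ValueError("search_window must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one run: acquisition + geometry + analysis."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    geometry: WellGeometry = field(default_factory=WellGeometry)
    density_rho: float = 1000.0
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def to_dict(self) -> dict:
        return {
            "acquisition": dataclasses.asdict(self.acquisition),
            "geometry": dataclasses.asdict(self.geometry),
            "density_rho": self.density_rho,
            "analysis": dataclasses.asdict(self.analysis),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            acquisition=AcquisitionConfig(**d.get("acquisition", {})),
            geometry=WellGeometry(**d.get("geometry", {})),
            density_rho=float(d.get("density_rho", 1000.0)),
            analysis=AnalysisOptions(**d.get("analysis", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
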