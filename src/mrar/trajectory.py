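"""Programmable coagulation trajectories for the acquisition simulator.

A trajectory prescribes how the resonant surface wave of one sample evolves
as the sample clots: the resonant frequency rises from a liquid (capillary)
plateau ``f_liquid`` to a solid (Rayleigh) plateau ``f_solid`` between
``t_start`` and ``t_end``, while the oscillation amplitude and ring-down
time drop — clots are stiffer and lossier than plasma.

Two transition shapes are supported:

``sigmoid``
    A logistic transition with midpoint ``(t_start + t_end)/2`` and width
    ``(t_end - t_start)/8``, rescaled so the plateaus are reached *exactly*
    at ``t_start`` and ``t_end``.
``piecewise_linear``
    A linear ramp between the plateaus; convenient when an analytically
    exact parameter truth is wanted.

Within one measurement the surface behaves as a damped harmonic oscillator
in fast time tau:  ``s(T, tau) = A(T) exp(-tau/tau_d(T)) sin(2 pi f(T) tau)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["CoagulationTrajectory", "surface_response", "trajectory_from_materials"]


@dataclass(frozen=True)
class CoagulationTrajectory:
    """Ground-truth evolution of one channel's resonant surface wave.

    Frequencies in Hz, times in s, amplitudes in m.  ``t_start = inf``
    describes a sample that never clots (frequency stays at ``f_liquid``).
    """

    f_liquid: float = 55.0
    f_solid: float = 300.0
    t_start: float = 90.0
    t_end: float = 150.0
    shape: Literal["sigmoid", "piecewise_linear"] = "sigmoid"
    amp_liquid: float = 20.0e-6
    amp_solid: float = 2.0e-6
    decay_liquid: float = 20.0e-3
    decay_solid: float = 5.0e-3

    def __post_init__(self) -> None:
        if not 0 < self.f_liquid < self.f_solid:
            raise ValueError("require 0 < f_liquid < f_solid")
        # t_start = inf marks a sample that never clots
        if not math.isinf(self.t_start) and not (0 <= self.t_start < self.t_end):
            raise ValueError("require 0 <= t_start < t_end")
        if min(self.amp_liquid, self.amp_solid) <= 0:
            raise ValueError("amplitudes must be positive")
        if min(self.decay_liquid, self.decay_solid) <= 0:
            raise ValueError("decay times must be positive")
        if self.shape not in ("sigmoid", "piecewise_linear"):
            raise ValueError(f"unknown shape {self.shape!r}")

    # -- transition profile -------------------------------------------------

    def progress(self, T):
        """Clotting progress g(T) in [0, 1]: 0 for T <= t_start, 1 for T >= t_end."""
        T = np.asarray(T, dtype=float)
        if math.isinf(self.t_start):
            g = np.zeros_like(T)
            return float(g) if g.ndim == 0 else g
        if self.shape == "piecewise_linear":
            g = np.clip((T - self.t_start) / (self.t_end - self.t_start), 0.0, 1.0)
        else:
            mid = 0.5 * (self.t_start + self.t_end)
            width = (self.t_end - self.t_start) / 8.0
            raw = 1.0 / (1.0 + np.exp(-np.clip((T - mid) / width, -500, 500)))
            lo = 1.0 / (1.0 + math.exp(4.0))   # logistic at t_start
            hi = 1.0 / (1.0 + math.exp(-4.0))  # logistic at t_end
            g = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
        return float(g) if g.ndim == 0 else g

    def frequency(self, T):
        """Resonant frequency f(T) in Hz; non-decreasing in T."""
        g = self.progress(T)
        return self.f_liquid + (self.f_solid - self.f_liquid) * g

    def amplitude(self, T):
        """Initial oscillation amplitude A(T) in m."""
        g = self.progress(T)
        return self.amp_liquid + (self.amp_solid - self.amp_liquid) * g

    def decay_time(self, T):
        """Ring-down (1/e envelope) time tau_d(T) in s."""
        g = self.progress(T)
        return self.decay_liquid + (self.decay_solid - self.decay_liquid) * g


def surface_response(trajectory: CoagulationTrajectory, T, tau):
    """Surface displacement (m) at observation time ``T`` and fast time ``tau``.

    Damped harmonic oscillation ``A(T) exp(-tau/tau_d(T)) sin(2 pi f(T) tau)``.
    Positive displacement means the surface moves away from the transducer.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("fast time tau must be non-negative")
    A = trajectory.amplitude(T)
    f = trajectory.frequency(T)
    td = trajectory.decay_time(T)
    s = A * np.exp(-tau / td) * np.sin(2.0 * np.pi * f * tau)
    return float(s) if np.ndim(s) == 0 else s


def trajectory_from_materials(
    surface_tension: float = 0.072,
    shear_modulus: float = 1000.0,
    density: float = 1000.0,
    geometry=None,
    **kwargs,
) -> CoagulationTrajectory:
    """Build a trajectory whose plateau frequencies follow the dispersion laws.

    The liquid plateau is the capillary-wave frequency of ``surface_tension``
    and the solid plateau the Rayleigh-wave frequency of ``shear_modulus``,
    both for the well's resonant wavenumber.  Remaining keyword arguments
    (``t_start``, ``t_end``, amplitudes, decays, ``shape``) pass through to
    :class:`CoagulationTrajectory`.
    """
    from .physics import WellGeometry, capillary_frequency, rayleigh_frequency

    geometry = geometry or WellGeometry()
    k = geometry.wavenumber_k
    return CoagulationTrajectory(
        f_liquid=capillary_frequency(surface_tension, density, k),
        f_solid=rayleigh_frequency(shear_modulus, density, k),
        **kwargs,
    )
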