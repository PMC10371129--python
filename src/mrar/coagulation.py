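"""Coagulation-parameter extraction from a resonant-frequency trace.

The clotting curve f(T) of a plasma sample is summarized by five parameters:

* ``f_int`` — mean resonant frequency over the first minute of measurements
  (liquid, capillary-wave plateau);
* ``f_end`` — mean frequency over the last five minutes (stable clot,
  Rayleigh-wave plateau);
* ``T_int`` — clotting start: first observation time at which the frequency
  has risen 5% above ``f_int``;
* ``T_end`` — clotting end: first observation time at which the frequency
  reaches 95% of ``f_end``;
* ``clotting_duration`` = ``T_end - T_int``.

Threshold crossings require persistence (the next available sample must also
satisfy the threshold) so a single noise spike does not register as a
crossing.  A trace whose final plateau does not rise at least 5% above
``f_int`` is classified ``no_clot`` rather than given a degenerate
near-zero duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisOptions
from .spectral import FrequencyTrace

__all__ = [
    "CoagulationParams",
    "initial_frequency",
    "final_frequency",
    "clotting_start",
    "clotting_end",
    "extract_params",
    "params_from_frequency_curve",
]

INITIAL_WINDOW_S = 60.0
FINAL_WINDOW_S = 300.0


@dataclass
class CoagulationParams:
    """Extracted clotting parameters for one channel; NaN where undefined."""

    channel_id: int = -1
    f_int: float = math.nan
    f_end: float = math.nan
    T_int: float = math.nan
    T_end: float = math.nan
    clotting_duration: float = math.nan
    flags: set = field(default_factory=set)  # subset of {no_clot, truncated, low_confidence}

    @property
    def no_clot(self) -> bool:
        return "no_clot" in self.flags

    def to_row(self) -> dict:
        return {
            "channel": self.channel_id,
            "f_int_Hz": self.f_int,
            "f_end_Hz": self.f_end,
            "T_int_s": self.T_int,
            "T_end_s": self.T_end,
            "duration_s": self.clotting_duration,
            "flags": "|".join(sorted(self.flags)),
        }


def _windowed_mean(times, freqs, lo, hi):
    mask = (times >= lo) & (times <= hi) & np.isfinite(freqs)
    if not mask.any():
        return math.nan
    return float(np.mean(freqs[mask]))


def initial_frequency(times: np.ndarray, freqs: np.ndarray, flags: Optional[set] = None) -> float:
    """Mean frequency over [T0, T0 + 60 s]; flags ``truncated`` on short traces."""
    valid = np.isfinite(freqs)
    if not valid.any():
        return math.nan
    t0, t_last = float(times[valid][0]), float(times[valid][-1])
    if t_last - t0 < INITIAL_WINDOW_S and flags is not None:
        flags.add("truncated")
    return _windowed_mean(times, freqs, t0, t0 + INITIAL_WINDOW_S)


def final_frequency(times: np.ndarray, freqs: np.ndarray, flags: Optional[set] = None) -> float:
    """Mean frequency over [T_last - 300 s, T_last]; flags ``truncated`` on short traces."""
    valid = np.isfinite(freqs)
    if not valid.any():
        return math.nan
    t0, t_last = float(times[valid][0]), float(times[valid][-1])
    if t_last - t0 < FINAL_WINDOW_S and flags is not None:
        flags.add("truncated")
    return _windowed_mean(times, freqs, t_last - FINAL_WINDOW_S, t_last)


def _first_persistent_crossing(times, freqs, threshold):
    """Earliest observation time with f >= threshold whose next valid sample
    (if any) also satisfies the threshold; NaN samples never count."""
    valid = np.flatnonzero(np.isfinite(freqs))
    for pos, i in enumerate(valid):
        if freqs[i] >= threshold:
            if pos + 1 < len(valid) and freqs[valid[pos + 1]] < threshold:
                continue  # lone spike, not a crossing
            return float(times[i])
    return math.nan


def clotting_start(times, freqs, f_int: float, rise_threshold: float = 1.05) -> float:
    """T_int: first persistent rise of the frequency 5% above f_int."""
    if not (f_int > 0):
        return math.nan
    return _first_persistent_crossing(times, freqs, rise_threshold * f_int)


def clotting_end(times, freqs, f_end: float, plateau_threshold: float = 0.95) -> float:
    """T_end: first persistent arrival at 95% of f_end."""
    if not (f_end > 0):
        return math.nan
    return _first_persistent_crossing(times, freqs, plateau_threshold * f_end)


def _median3(freqs: np.ndarray) -> np.ndarray:
    """Centered 3-point rolling median, NaN-tolerant, endpoints kept valid."""
    return (
        pd.Series(freqs).rolling(3, center=True, min_periods=1).median().to_numpy()
    )


def params_from_frequency_curve(
    times,
    freqs,
    channel_id: int = -1,
    rise_threshold: float = 1.05,
    plateau_threshold: float = 0.95,
    median_filter: bool = True,
    extra_flags: Optional[set] = None,
) -> CoagulationParams:
    """Extract coagulation parameters from a frequency curve f(T).

    This is the core extraction applied both to measured frequency traces
    and, as the analytic oracle, to noiseless ground-truth trajectories.
    """
    times = np.asarray(times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    flags: set = set(extra_flags or ())
    if median_filter:
        freqs = _median3(freqs)

    f_int = initial_frequency(times, freqs, flags)
    f_end = final_frequency(times, freqs, flags)
    p = CoagulationParams(channel_id=channel_id, f_int=f_int, f_end=f_end, flags=flags)
    if not (np.isfinite(f_int) and np.isfinite(f_end)):
        p.flags.add("no_clot")
        return p
    if f_end < rise_threshold * f_int:
        p.flags.add("no_clot")
        return p

    T_int = clotting_start(times, freqs, f_int, rise_threshold)
    T_end = clotting_end(times, freqs, f_end, plateau_threshold)
    if math.isnan(T_int) or math.isnan(T_end):
        p.flags.add("no_clot")
        return p
    # the 95%-of-f_end level can precede the 5% rise only in pathological
    # near-flat traces; clamp ordering by definition T_int <= T_end
    if T_end < T_int:
        T_end = T_int
    p.T_int, p.T_end = T_int, T_end
    p.clotting_duration = T_end - T_int
    return p


def extract_params(
    trace: FrequencyTrace,
    options: Optional[AnalysisOptions] = None,
) -> CoagulationParams:
    """Extract :class:`CoagulationParams` from a measured frequency trace."""
    options = options or AnalysisOptions()
    extra = set()
    if np.any(~np.isfinite(trace.peak_frequency)):
        extra.add("low_confidence")
    return params_from_frequency_curve(
        trace.observation_times,
        trace.peak_frequency,
        channel_id=trace.channel_id,
        rise_threshold=options.rise_threshold,
        plateau_threshold=options.plateau_threshold,
        median_filter=options.median_filter,
        extra_flags=extra,
    )
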