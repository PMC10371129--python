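"""Surface-wave dispersion relations and their inversions.

A sample confined in a cylindrical well supports resonant surface waves whose
restoring force depends on the material state.  In the liquid regime the wave
is a capillary wave with

    f_CW = (1/2pi) * sqrt(sigma * k^3 / rho)

where ``sigma`` is the surface tension (N/m), ``rho`` the mass density
(kg/m^3) and ``k`` the resonant wavenumber (1/m).  Once the sample gels, the
surface supports a Rayleigh wave governed by the bulk shear modulus ``G``
(Pa):

    f_RW = (1/2pi) * sqrt(G * k^2 / rho)

The resonant wavenumber is fixed by the well geometry, ``k = z / a`` with
``a`` the well radius and ``z`` a dimensionless mode constant.  The default
mode constant is the first nonzero root of the Bessel function J1
(z = 3.8317...), i.e. the fundamental axisymmetric mode with a free-slip
wall; other conventions can be supplied explicitly.

All functions are scalar- and array-aware (NumPy broadcasting) and validate
that physical quantities are strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.special import jn_zeros

__all__ = [
    "FIRST_J1_ROOT",
    "WellGeometry",
    "MaterialState",
    "capillary_frequency",
    "rayleigh_frequency",
    "invert_to_surface_tension",
    "invert_to_shear_modulus",
]

#: First nonzero root of the Bessel function J1 — fundamental axisymmetric
#: surface mode of a circular free surface with a free-slip wall.
FIRST_J1_ROOT: float = float(jn_zeros(1, 1)[0])

_TWO_PI = 2.0 * np.pi


def _require_positive(**kwargs: object) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class WellGeometry:
    """Geometry of one sample well.

    Parameters
    ----------
    radius_a : float
        Radius of the free sample surface in metres (default 3.25 mm, the
        well radius of a standard 96-well microplate).
    mode_constant_z : float
        Dimensionless resonant-mode constant; the wavenumber is
        ``k = mode_constant_z / radius_a``.
    """

    radius_a: float = 3.25e-3
    mode_constant_z: float = FIRST_J1_ROOT

    def __post_init__(self) -> None:
        _require_positive(radius_a=self.radius_a, mode_constant_z=self.mode_constant_z)

    @property
    def wavenumber_k(self) -> float:
        """Resonant wavenumber k = z / a (1/m)."""
        return self.mode_constant_z / self.radius_a


@dataclass(frozen=True)
class MaterialState:
    """Material parameters of a sample in one regime.

    Exactly one of ``surface_tension_sigma`` (liquid regime) or
    ``shear_modulus_G`` (solid regime) must be set, matching ``regime``.
    """

    density_rho: float = 1000.0
    regime: Literal["liquid", "solid"] = "liquid"
    surface_tension_sigma: Optional[float] = None
    shear_modulus_G: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive(density_rho=self.density_rho)
        if self.regime == "liquid":
            if self.surface_tension_sigma is None:
                raise ValueError("liquid regime requires surface_tension_sigma")
            _require_positive(surface_tension_sigma=self.surface_tension_sigma)
        elif self.regime == "solid":
            if self.shear_modulus_G is None:
                raise ValueError("solid regime requires shear_modulus_G")
            _require_positive(shear_modulus_G=self.shear_modulus_G)
        else:
            raise ValueError(f"unknown regime {self.regime!r}")

    def resonant_frequency(self, geometry: WellGeometry) -> float:
        """Resonant surface-wave frequency for this state in ``geometry``."""
        k = geometry.wavenumber_k
        if self.regime == "liquid":
            return float(capillary_frequency(self.surface_tension_sigma, self.density_rho, k))
        return float(rayleigh_frequency(self.shear_modulus_G, self.density_rho, k))


def capillary_frequency(sigma, rho, k):
    """Capillary-wave frequency f = (1/2pi) sqrt(sigma k^3 / rho) in Hz."""
    _require_positive(sigma=sigma, rho=rho, k=k)
    sigma, rho, k = (np.asarray(x, dtype=float) for x in (sigma, rho, k))
    f = np.sqrt(sigma * k**3 / rho) / _TWO_PI
    return float(f) if f.ndim == 0 else f


def rayleigh_frequency(G, rho, k):
    """Rayleigh-wave frequency f = (1/2pi) sqrt(G k^2 / rho) = (k/2pi) sqrt(G/rho) in Hz."""
    _require_positive(G=G, rho=rho, k=k)
    G, rho, k = (np.asarray(x, dtype=float) for x in (G, rho, k))
    f = k * np.sqrt(G / rho) / _TWO_PI
    return float(f) if f.ndim == 0 else f


def invert_to_surface_tension(f, rho, k):
    """Surface tension sigma = (2 pi f)^2 rho / k^3 (N/m) from a capillary-wave frequency."""
    _require_positive(f=f, rho=rho, k=k)
    f, rho, k = (np.asarray(x, dtype=float) for x in (f, rho, k))
    sigma = (_TWO_PI * f) ** 2 * rho / k**3
    return float(sigma) if sigma.ndim == 0 else sigma


def invert_to_shear_modulus(f, rho, k):
    """Shear modulus G = rho (2 pi f / k)^2 (Pa) from a Rayleigh-wave frequency."""
    _require_positive(f=f, rho=rho, k=k)
    f, rho, k = (np.asarray(x, dtype=float) for x in (f, rho, k))
    G = rho * (_TWO_PI * f / k) ** 2
    return float(G) if G.ndim == 0 else G
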