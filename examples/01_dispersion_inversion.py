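"""Dispersion relations: from material parameters to resonant frequency and back.

A 3.25 mm well supports a fundamental axisymmetric surface mode with
wavenumber k = 3.8317 / a.  A water-like liquid surface (sigma = 72 mN/m)
resonates as a capillary wave; a 1 kPa gel as a Rayleigh wave.  Inverting
the measured frequency recovers the material parameter.
"""

from mrar import (
    WellGeometry,
    capillary_frequency,
    invert_to_shear_modulus,
    invert_to_surface_tension,
    rayleigh_frequency,
)

geo = WellGeometry()  # radius 3.25 mm, fundamental mode
k = geo.wavenumber_k
rho = 1000.0

f_liquid = capillary_frequency(0.072, rho, k)
f_solid = rayleigh_frequency(1000.0, rho, k)
print(f"resonant wavenumber k = {k:.1f} 1/m")
print(f"capillary-wave frequency of water surface: {f_liquid:.2f} Hz")
print(f"Rayleigh-wave frequency of a 1 kPa gel:    {f_solid:.2f} Hz")

sigma = invert_to_surface_tension(f_liquid, rho, k)
G = invert_to_shear_modulus(f_solid, rho, k)
print(f"inverted surface tension: {sigma * 1e3:.2f} mN/m (expected 72)")
print(f"inverted shear modulus:   {G:.1f} Pa (expected 1000)")
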