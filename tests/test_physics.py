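"""Dispersion relations: closed-form values, inversions, scaling laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrar import (
    FIRST_J1_ROOT,
    MaterialState,
    WellGeometry,
    capillary_frequency,
    invert_to_shear_modulus,
    invert_to_surface_tension,
    rayleigh_frequency,
)

K_DEFAULT = 3.8317 / 0.00325  # fundamental mode in a 3.25 mm well


class TestClosedForms:
    def test_capillary_frequency_of_water_surface(self):
        # (1/2pi)*sqrt(0.072 * k^3 / 1000), evaluated by hand
        f = capillary_frequency(0.072, 1000.0, K_DEFAULT)
        assert f == pytest.approx(54.67, abs=0.05)

    def test_rayleigh_frequency_of_1kpa_gel(self):
        # (k/2pi)*sqrt(1000/1000), evaluated by hand
        f = rayleigh_frequency(1000.0, 1000.0, K_DEFAULT)
        assert f == pytest.approx(187.64, abs=0.05)

    def test_surface_tension_inversion_value(self):
        assert invert_to_surface_tension(54.6699, 1000.0, 3.8317 / 0.00325) == pytest.approx(
            0.072, rel=1e-4
        )

    def test_shear_modulus_inversion_value(self):
        assert invert_to_shear_modulus(187.641, 1000.0, 3.8317 / 0.00325) == pytest.approx(
            1000.0, rel=1e-4
        )


class TestScaling:
    def test_quadrupling_sigma_doubles_frequency(self):
        f1 = capillary_frequency(0.02, 1000.0, K_DEFAULT)
        assert capillary_frequency(0.08, 1000.0, K_DEFAULT) == pytest.approx(2 * f1, rel=1e-12)

    def test_k_to_three_halves_scaling(self):
        f1 = capillary_frequency(0.072, 1000.0, K_DEFAULT)
        assert capillary_frequency(0.072, 1000.0, 4 * K_DEFAULT) == pytest.approx(
            8 * f1, rel=1e-12
        )

    def test_quadrupling_g_doubles_frequency(self):
        f1 = rayleigh_frequency(500.0, 1000.0, K_DEFAULT)
        assert rayleigh_frequency(2000.0, 1000.0, K_DEFAULT) == pytest.approx(2 * f1, rel=1e-12)

    def test_doubling_frequency_quadruples_inverted_moduli(self):
        assert invert_to_shear_modulus(400.0, 1000.0, K_DEFAULT) == pytest.approx(
            4 * invert_to_shear_modulus(200.0, 1000.0, K_DEFAULT), rel=1e-12
        )
        assert invert_to_surface_tension(100.0, 1000.0, K_DEFAULT) == pytest.approx(
            4 * invert_to_surface_tension(50.0, 1000.0, K_DEFAULT), rel=1e-12
        )

    def test_dimensional_sanity_joint_density_scaling(self):
        # scaling rho and sigma (or G) by the same factor leaves f unchanged
        c = 7.3
        assert capillary_frequency(c * 0.072, c * 1000.0, K_DEFAULT) == pytest.approx(
            capillary_frequency(0.072, 1000.0, K_DEFAULT), rel=1e-12
        )
        assert rayleigh_frequency(c * 1000.0, c * 1000.0, K_DEFAULT) == pytest.approx(
            rayleigh_frequency(1000.0, 1000.0, K_DEFAULT), rel=1e-12
        )


class TestRoundTrips:
    def test_sigma_round_trip_grid(self):
        sigmas = np.logspace(-3, 0, 1000)
        rec = invert_to_surface_tension(
            capillary_frequency(sigmas, 1000.0, K_DEFAULT), 1000.0, K_DEFAULT
        )
        assert np.max(np.abs(rec / sigmas - 1)) < 1e-9

    def test_g_round_trip_grid(self):
        Gs = np.logspace(0, 5, 1000)
        rec = invert_to_shear_modulus(
            rayleigh_frequency(Gs, 1000.0, K_DEFAULT), 1000.0, K_DEFAULT
        )
        assert np.max(np.abs(rec / Gs - 1)) < 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(
        f=st.floats(1.0, 5e3),
        rho=st.floats(500.0, 2000.0),
        k=st.floats(100.0, 1e4),
    )
    def test_forward_of_inverse_is_identity(self, f, rho, k):
        assert capillary_frequency(
            invert_to_surface_tension(f, rho, k), rho, k
        ) == pytest.approx(f, rel=1e-12)
        assert rayleigh_frequency(
            invert_to_shear_modulus(f, rho, k), rho, k
        ) == pytest.approx(f, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.floats(1.001, 100.0))
    def test_forward_maps_strictly_increasing(self, scale):
        base_c = capillary_frequency(0.05, 1000.0, K_DEFAULT)
        base_r = rayleigh_frequency(500.0, 1000.0, K_DEFAULT)
        assert capillary_frequency(0.05 * scale, 1000.0, K_DEFAULT) > base_c
        assert capillary_frequency(0.05, 1000.0, K_DEFAULT * scale) > base_c
        assert rayleigh_frequency(500.0 * scale, 1000.0, K_DEFAULT) > base_r
        assert rayleigh_frequency(500.0, 1000.0, K_DEFAULT * scale) > base_r


class TestValidationAndTypes:
    @pytest.mark.parametrize("func", [capillary_frequency, rayleigh_frequency])
    @pytest.mark.parametrize("bad", [(-1.0, 1000.0, 100.0), (0.05, 0.0, 100.0), (0.05, 1000.0, -5.0)])
    def test_non_positive_arguments_rejected(self, func, bad):
        with pytest.raises(ValueError):
            func(*bad)

    def test_domain_error_names_the_argument(self):
        with pytest.raises(ValueError, match="rho"):
            capillary_frequency(0.05, -1.0, 100.0)

    def test_well_geometry_wavenumber(self):
        geo = WellGeometry(radius_a=3.25e-3)
        assert geo.wavenumber_k == pytest.approx(geo.mode_constant_z / 3.25e-3, rel=1e-15)
        assert geo.mode_constant_z == pytest.approx(FIRST_J1_ROOT)
        with pytest.raises(ValueError):
            WellGeometry(radius_a=-1.0)

    def test_material_state_requires_matching_field(self):
        with pytest.raises(ValueError):
            MaterialState(regime="liquid")  # missing surface tension
        with pytest.raises(ValueError):
            MaterialState(regime="solid", surface_tension_sigma=0.07)
        liquid = MaterialState(regime="liquid", surface_tension_sigma=0.072)
        solid = MaterialState(regime="solid", shear_modulus_G=1000.0)
        geo = WellGeometry()
        assert liquid.resonant_frequency(geo) == pytest.approx(54.67, abs=0.05)
        assert solid.resonant_frequency(geo) == pytest.approx(187.64, abs=0.05)
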