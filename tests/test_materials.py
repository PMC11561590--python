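import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from cryoskin import materials as M


@pytest.fixture(scope="module")
def mat():
    return M.preset()["solution"]


class TestPhaseFraction:
    def test_below_window_is_zero(self, mat):
        assert M.phase_fraction(mat.melt_temperature - 10 * mat.transition_half_width, mat) == 0.0

    def test_midpoint_is_half(self, mat):
        assert M.phase_fraction(mat.melt_temperature, mat) == pytest.approx(0.5, abs=1e-14)

    def test_above_window_is_one(self, mat):
        assert M.phase_fraction(mat.melt_temperature + 10 * mat.transition_half_width, mat) == 1.0

    def test_monotone_and_matches_integral_of_derivative(self, mat):
        # quadrature oracle: theta2(T) == integral of its own analytic derivative
        tm, w = mat.melt_temperature, mat.transition_half_width
        T = np.linspace(tm - 5 * w, tm + 5 * w, 401)
        theta = M.phase_fraction(T, mat)
        assert np.all(np.diff(theta) >= -1e-15)
        for t_val in np.linspace(tm - 2 * w, tm + 2 * w, 9):
            integral, _ = quad(lambda s: M.phase_fraction_derivative(s, mat),
                               tm - 5 * w, t_val, limit=200)
            assert abs(integral - M.phase_fraction(t_val, mat)) < 1e-8

    def test_theta_sum_is_one(self, mat):
        T = np.linspace(250.0, 290.0, 1001)
        theta2 = M.phase_fraction(T, mat)
        assert np.all(theta2 + (1.0 - theta2) == 1.0)


class TestMixtureProperties:
    def test_pure_phase1(self, mat):
        mix = M.mixture_properties(1.0, 0.0, mat)
        assert mix.density == mat.phase1.density
        assert mix.conductivity == mat.phase1.conductivity
        assert mix.heat_capacity == pytest.approx(mat.phase1.heat_capacity)
        assert mix.mass_fraction_function == pytest.approx(-0.5)

    def test_pure_phase2(self, mat):
        mix = M.mixture_properties(0.0, 1.0, mat)
        assert mix.density == mat.phase2.density
        assert mix.conductivity == mat.phase2.conductivity
        assert mix.heat_capacity == pytest.approx(mat.phase2.heat_capacity)
        assert mix.mass_fraction_function == pytest.approx(+0.5)

    def test_equal_densities_symmetric_cancellation(self):
        p = M.PhaseProperties(density=1000.0, heat_capacity=2000.0, conductivity=1.0)
        m = M.PhaseChangeMaterial("x", p, p, melt_temperature=273.15)
        assert M.mixture_properties(0.5, 0.5, m).mass_fraction_function == pytest.approx(0.0)

    def test_rejects_bad_theta(self, mat):
        with pytest.raises(ValueError):
            M.mixture_properties(-0.1, 1.1, mat)
        with pytest.raises(ValueError):
            M.mixture_properties(0.7, 0.7, mat)

    @given(theta2=st.floats(0.0, 1.0))
    def test_intermediate_value_property(self, theta2):
        mat = M.preset()["solution"]
        mix = M.mixture_properties(1.0 - theta2, theta2, mat)
        for attr in ("density", "conductivity", "heat_capacity"):
            lo = min(getattr(mat.phase1, attr), getattr(mat.phase2, attr))
            hi = max(getattr(mat.phase1, attr), getattr(mat.phase2, attr))
            assert lo - 1e-9 <= getattr(mix, attr) <= hi + 1e-9

    @given(t2a=st.floats(0.0, 1.0), t2b=st.floats(0.0, 1.0))
    def test_alpha_m_bounded_and_monotone(self, t2a, t2b):
        mat = M.preset()["solution"]
        ma = M.mixture_properties(1 - t2a, t2a, mat).mass_fraction_function
        mb = M.mixture_properties(1 - t2b, t2b, mat).mass_fraction_function
        assert -0.5 - 1e-12 <= ma <= 0.5 + 1e-12
        if t2a < t2b:
            assert ma <= mb + 1e-12


class TestApparentHeatCapacity:
    def test_zero_latent_heat_equals_sensible(self, mat):
        m0 = M.PhaseChangeMaterial("x", mat.phase1, mat.phase2,
                                   melt_temperature=mat.melt_temperature,
                                   transition_half_width=mat.transition_half_width,
                                   latent_heat=0.0)
        T = np.linspace(m0.melt_temperature - 2, m0.melt_temperature + 2, 101)
        theta2 = M.phase_fraction(T, m0)
        sensible = M.mixture_properties(1 - theta2, theta2, m0).heat_capacity
        assert np.allclose(M.apparent_heat_capacity(T, m0), sensible, rtol=1e-12)

    def test_far_above_melt_equals_phase2(self, mat):
        assert M.apparent_heat_capacity(mat.melt_temperature + 50, mat) == pytest.approx(
            mat.phase2.heat_capacity)

    def test_latent_heat_conservation_quadrature(self, mat):
        # independent quadrature of rho * C_P_eff over the window vs
        # sensible + latent volumetric heat (0.5 % oracle)
        tm, w = mat.melt_temperature, mat.transition_half_width
        lo, hi = tm - 10 * w, tm + 10 * w

        def rho_cp(T):
            t2 = M.phase_fraction(T, mat)
            rho = (1 - t2) * mat.phase1.density + t2 * mat.phase2.density
            return rho * M.apparent_heat_capacity(T, mat)

        total, _ = quad(rho_cp, lo, hi, limit=400)
        sensible, _ = quad(lambda T: rho_cp(T) - mat.latent_heat
                           * mat.phase1.density * mat.phase2.density
                           / ((1 - M.phase_fraction(T, mat)) * mat.phase1.density
                              + M.phase_fraction(T, mat) * mat.phase2.density)
                           * M.phase_fraction_derivative(T, mat), lo, hi, limit=400)
        latent = M.latent_volumetric_heat(mat)
        assert total == pytest.approx(sensible + latent, rel=5e-3)
        rho_lo = min(mat.phase1.density, mat.phase2.density)
        rho_hi = max(mat.phase1.density, mat.phase2.density)
        assert rho_lo * mat.latent_heat <= latent <= rho_hi * mat.latent_heat

    def test_never_below_sensible(self, mat):
        T = np.linspace(mat.melt_temperature - 3, mat.melt_temperature + 3, 601)
        theta2 = M.phase_fraction(T, mat)
        sensible = M.mixture_properties(1 - theta2, theta2, mat).heat_capacity
        assert np.all(M.apparent_heat_capacity(T, mat) >= sensible - 1e-9)

    def test_enthalpy_consistent_with_quadrature(self, mat):
        tm = mat.melt_temperature
        num, _ = quad(lambda T: ((1 - M.phase_fraction(T, mat)) * mat.phase1.density
                                 + M.phase_fraction(T, mat) * mat.phase2.density)
                      * M.apparent_heat_capacity(T, mat), tm - 5, tm + 5, limit=400)
        ana = M.volumetric_enthalpy(tm + 5, mat) - M.volumetric_enthalpy(tm - 5, mat)
        assert num == pytest.approx(ana, rel=1e-9)


class TestEigenstrain:
    def test_equal_densities_zero(self):
        p = M.PhaseProperties(density=950.0, heat_capacity=2000.0, conductivity=1.0)
        m = M.PhaseChangeMaterial("x", p, p, melt_temperature=273.15)
        assert M.phase_change_eigenstrain(0.7, m) == 0.0

    def test_zero_theta_zero(self, mat):
        assert M.phase_change_eigenstrain(0.0, mat) == 0.0

    def test_arithmetic_oracle(self):
        p1 = M.PhaseProperties(density=1000.0, heat_capacity=4186.0, conductivity=0.6)
        p2 = M.PhaseProperties(density=917.0, heat_capacity=2050.0, conductivity=2.25)
        m = M.PhaseChangeMaterial("x", p1, p2, melt_temperature=273.15)
        assert M.phase_change_eigenstrain(1.0, m) == pytest.approx(
            (1000.0 / 917.0) ** (1.0 / 3.0) - 1.0, rel=1e-14)

    def test_rejects_out_of_range(self, mat):
        with pytest.raises(ValueError):
            M.phase_change_eigenstrain(1.2, mat)


class TestValidationAndPresets:
    def test_phase_properties_invariants(self):
        with pytest.raises(ValueError):
            M.PhaseProperties(density=-1, heat_capacity=1, conductivity=1)
        with pytest.raises(ValueError):
            M.PhaseProperties(density=1, heat_capacity=1, conductivity=1, poisson=0.5)
        with pytest.raises(ValueError):
            M.PhaseProperties(density=1, heat_capacity=1, conductivity=1,
                              expansion=math.inf)

    def test_material_invariants(self):
        p = M.PhaseProperties(density=1.0, heat_capacity=1.0, conductivity=1.0)
        with pytest.raises(ValueError):
            M.PhaseChangeMaterial("x", p, p, melt_temperature=273.15,
                                  transition_half_width=0.0)
        with pytest.raises(ValueError):
            M.PhaseChangeMaterial("x", p, p, melt_temperature=273.15, latent_heat=-1.0)

    def test_presets_exist(self):
        for name in ("none", "betaine", "tre", "bt-1", "bt-2", "bt-3", "gly", "dmso"):
            mats = M.preset(name)
            assert set(mats) == {"solution", "skin"}

    def test_bt_reduces_skin_expansion_about_40_percent(self):
        base = M.preset("none")["skin"].phase1.expansion
        bt = M.preset("bt-2")["skin"].phase1.expansion
        assert bt == pytest.approx(0.6 * base)

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            M.preset("nope")

    def test_materials_from_config_override(self):
        cfg = {"preset": "none", "materials": {"solution": {
            "melt_temperature_C": -5.0,
            "latent_heat": 3.0e5,
            "phase1": {"density": 917, "heat_capacity": 2050, "conductivity": 2.2},
            "phase2": {"density": 1000, "heat_capacity": 4186, "conductivity": 0.6},
        }}}
        mats = M.materials_from_config(cfg)
        assert mats["solution"].melt_temperature == pytest.approx(268.15)
        assert mats["skin"].name == "skin"

    def test_mechanical_blend_handles_infinite_viscosity(self):
        p1 = M.PhaseProperties(density=900, heat_capacity=2000, conductivity=2,
                               young_modulus=9e9, maxwell_viscosity=math.inf)
        p2 = M.PhaseProperties(density=1000, heat_capacity=4000, conductivity=0.6,
                               young_modulus=1e6, maxwell_viscosity=1e4)
        m = M.PhaseChangeMaterial("x", p1, p2, melt_temperature=273.15)
        _, _, _, mu0 = M.mechanical_properties(0.0, m)
        _, _, _, mu_half = M.mechanical_properties(0.5, m)
        assert math.isinf(mu0)
        assert mu_half == pytest.approx(2e4)

    def test_celsius_kelvin_round_trip(self):
        assert M.kelvin_to_celsius(M.celsius_to_kelvin(-80.0)) == pytest.approx(-80.0)
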