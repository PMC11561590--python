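import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erf, erfc

from cryoskin import materials as M
from cryoskin.thermal_solver import build_grid


@pytest.fixture(scope="session")
def default_materials():
    return M.preset()


@pytest.fixture(scope="session")
def solution_material(default_materials):
    return default_materials["solution"]


@pytest.fixture
def small_grid():
    return build_grid(16, 16)


# ---------------------------------------------------------------------------
# Neumann two-phase Stefan closed form (independent oracle)
# ---------------------------------------------------------------------------

def neumann_lambda(k_s, c_s, k_l, c_l, rho, latent, t_melt, t_wall, t_init):
    """Root lambda of the two-phase Stefan transcendental equation for a
    half-space initially liquid at t_init, wall held at t_wall < t_melt.

    Front position is x_f(t) = 2 lambda sqrt(alpha_s t).
    """
    alpha_s = k_s / (rho * c_s)
    alpha_l = k_l / (rho * c_l)
    nu = math.sqrt(alpha_s / alpha_l)
    stefan_rhs = latent * math.sqrt(math.pi) / (c_s * (t_melt - t_wall))

    def f(lam):
        solid = math.exp(-lam ** 2) / erf(lam)
        liquid = ((k_l / k_s) * nu * (t_init - t_melt) / (t_melt - t_wall)
                  * math.exp(-(lam * nu) ** 2) / erfc(lam * nu))
        return solid - liquid - lam * stefan_rhs

    return brentq(f, 1e-9, 8.0)


def stefan_material():
    """Equal-density two-phase material for the Stefan benchmark."""
    rho = 1000.0
    solid = M.PhaseProperties(density=rho, heat_capacity=2050.0, conductivity=2.22)
    liquid = M.PhaseProperties(density=rho, heat_capacity=4226.0, conductivity=0.556)
    return M.PhaseChangeMaterial(
        "stefan", solid, liquid, melt_temperature=273.15,
        transition_half_width=0.25, latent_heat=338000.0)


def simulate_stefan_front(nx, t_checks, dt=0.5, lx=0.06,
                          t_wall=263.15, t_init=275.15):
    """Freeze a 1D column from the left wall; return {t: front position}."""
    from cryoskin.thermal_solver import (MaterialField, ThermalBC, ThermalState,
                                         step_temperature, _StencilCache)
    mat = stefan_material()
    ny = 8
    grid = build_grid(nx, ny, lx=lx, ly=lx * ny / nx,
                      skin_lx=lx / nx, skin_ly=lx * ny / nx / ny)
    mats = {"solution": mat, "skin": mat}
    mf = MaterialField(grid, mats)
    bc = ThermalBC(kind="dirichlet_hold", start_temperature=t_wall,
                   applies_to=("left",))
    T0 = np.full((ny, nx), t_init)
    state = ThermalState(0.0, T0, mf.ice_fraction(T0.ravel()).reshape(T0.shape))
    cache = _StencilCache(grid)
    out = {}
    t_end = max(t_checks)
    x = grid.x_centers
    while state.time < t_end - 1e-9:
        state = step_temperature(state, grid, mf, [bc], dt, state.time, _cache=cache)
        for tc in t_checks:
            if tc not in out and state.time >= tc - 1e-9:
                theta = state.theta_ice[0]
                i = int(np.argmax(theta < 0.5))
                out[tc] = float(np.interp(0.5, [theta[i], theta[i - 1]],
                                          [x[i], x[i - 1]]))
    return out, mat, grid
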