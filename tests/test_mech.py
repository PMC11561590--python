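import math

import numpy as np
import pytest

from cryoskin import materials as M
from cryoskin.mech_solver import (MechBC, MechSolver, StressState, cell_scalar,
                                  max_principal, peak_stress, stress_profile,
                                  update_stress, von_mises)
from cryoskin.thermal_solver import build_grid


def elastic_material(E=9e9, nu=0.33, alpha=5e-5, mu=math.inf):
    p = M.PhaseProperties(density=917.0, heat_capacity=2050.0, conductivity=2.25,
                          young_modulus=E, poisson=nu, expansion=alpha,
                          maxwell_viscosity=mu)
    return M.PhaseChangeMaterial("uniform", p, p, melt_temperature=273.15)


def uniform_setup(E=9e9, nu=0.33, alpha=5e-5, mu=math.inf, n=8,
                  bc=None):
    mat = elastic_material(E, nu, alpha, mu)
    grid = build_grid(n, n)
    mats = {"solution": mat, "skin": mat}
    solver = MechSolver(grid, mats, bc or MechBC(left="fixed", right="fixed",
                                                 bottom="fixed", top="fixed"))
    return grid, solver


ALL_ZERO = dict()


class TestScalars:
    def test_hydrostatic_von_mises_zero(self):
        sigma = np.array([3e6, 3e6, 3e6, 0.0])
        assert von_mises(sigma) == pytest.approx(0.0, abs=1e-6)

    def test_uniaxial_identity(self):
        sigma = np.array([-5e6, 0.0, 0.0, 0.0])
        assert von_mises(sigma) == pytest.approx(5e6)
        assert max_principal(np.array([5e6, 0.0, 0.0, 0.0])) == pytest.approx(5e6)

    def test_random_tensor_eigenvalue_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            sxx, syy, szz, sxy = rng.normal(0, 1e6, 4)
            full = np.array([[sxx, sxy, 0.0], [sxy, syy, 0.0], [0.0, 0.0, szz]])
            ev = np.linalg.eigvalsh(full)
            vm_oracle = math.sqrt(0.5 * ((ev[0] - ev[1]) ** 2 + (ev[1] - ev[2]) ** 2
                                         + (ev[2] - ev[0]) ** 2))
            sig = np.array([sxx, syy, szz, sxy])
            assert von_mises(sig) == pytest.approx(vm_oracle, rel=1e-12)
            assert max_principal(sig) == pytest.approx(ev[-1], rel=1e-12, abs=1e-3)


class TestUpdateStress:
    def test_no_input_no_stress(self):
        grid, solver = uniform_setup()
        st = solver.new_state()
        z = np.zeros(grid.n_cells)
        out = solver.step(st, z, z, z, 1.0)
        assert np.allclose(out.sigma, 0.0)
        assert np.allclose(out.u_disp, 0.0)

    def test_constrained_thermoelastic_closed_form(self):
        # fully constrained, elastic limit, uniform cooling: plane-strain
        # closed form sigma_xx = sigma_yy = sigma_zz = -E alpha dT / (1 - 2 nu)
        E, nu, alpha, dT = 9e9, 0.33, 5e-5, -10.0
        grid, solver = uniform_setup(E=E, nu=nu, alpha=alpha)
        st = solver.new_state()
        z = np.zeros(grid.n_cells)
        out = solver.step(st, np.full(grid.n_cells, dT), z, z, 1.0)
        expected = -E * alpha * dT / (1.0 - 2.0 * nu)
        sig = out.cell_sigma()
        assert np.allclose(sig[:, :3], expected, rtol=1e-9)
        assert np.allclose(sig[:, 3], 0.0, atol=abs(expected) * 1e-9)

    def test_maxwell_relaxation_closed_form(self):
        # fixed total strain, injected deviatoric stress: S(t) = S0 exp(-t/tau),
        # tau = 2 mu (1 + nu) / E, within 1% over 3 tau
        E, nu, mu = 9e9, 0.33, 1e10
        grid, solver = uniform_setup(E=E, nu=nu, alpha=0.0, mu=mu)
        st = solver.new_state()
        s0 = 1e6
        st.sigma[:, :, 0] = +s0
        st.sigma[:, :, 1] = -s0
        tau = 2.0 * mu * (1.0 + nu) / E
        dt = tau / 1000.0
        z = np.zeros(grid.n_cells)
        state = st
        for _ in range(3000):
            state = solver.step(state, z, z, z, dt)
        ratio = state.sigma[0, 0, 0] / s0
        assert ratio == pytest.approx(math.exp(-3.0), rel=0.01)

    def test_elastic_limit_no_relaxation(self):
        grid, solver = uniform_setup(mu=math.inf)
        st = solver.new_state()
        st.sigma[:, :, 0] = 1e6
        st.sigma[:, :, 1] = -1e6
        z = np.zeros(grid.n_cells)
        out = solver.step(st, z, z, z, 1e6)
        assert np.allclose(out.sigma, st.sigma, rtol=1e-12, atol=1.0)

    def test_equilibrium_residual_small(self, default_materials):
        grid = build_grid(16, 16)
        solver = MechSolver(grid, default_materials, MechBC())
        st = solver.new_state()
        rng = np.random.default_rng(0)
        theta2 = np.clip(rng.uniform(0, 1, grid.n_cells), 0, 1)
        out = solver.step(st, rng.normal(0, 1, grid.n_cells),
                          rng.normal(0, 0.05, grid.n_cells), theta2, 1.0)
        assert out.residual <= 1e-6

    def test_trace_consistency_isotropic_compliance(self):
        # volumetric elastic strain equals tr(sigma) / (3 K) for a purely
        # mechanical load (closed-form identity of the isotropic compliance)
        E, nu, dT = 9e9, 0.33, -7.0
        alpha = 5e-5
        grid, solver = uniform_setup(E=E, nu=nu, alpha=alpha)
        st = solver.new_state()
        z = np.zeros(grid.n_cells)
        out = solver.step(st, np.full(grid.n_cells, dT), z, z, 1.0)
        K = E / (3.0 * (1.0 - 2.0 * nu))
        sig = out.cell_sigma()
        tr = sig[:, :3].sum(axis=1)
        # total strain is zero (fully constrained), so elastic vol strain
        # must cancel the thermal part: tr(sigma)/(3K) == -3 alpha dT
        assert np.allclose(tr / (3.0 * K), -3.0 * alpha * dT, rtol=1e-9)

    def test_phase_eigenstrain_direction(self, default_materials):
        # freezing (theta2 liquid decreasing) of a constrained solution cell
        # must generate compression (expansion eigenstrain)
        grid = build_grid(8, 8, skin_lx=1e-3, skin_ly=1e-3)
        solver = MechSolver(grid, default_materials,
                            MechBC(left="fixed", right="fixed", bottom="fixed",
                                   top="fixed"))
        st = solver.new_state()
        dth = np.full(grid.n_cells, -1.0)   # liquid -> frozen
        th2 = np.zeros(grid.n_cells)
        out = solver.step(st, np.zeros(grid.n_cells), dth, th2, 1.0)
        sol_cells = grid.region_mask("solution").ravel()
        assert np.all(out.cell_sigma()[sol_cells, 0] < 0.0)

    def test_all_free_supports_rejected(self):
        with pytest.raises(ValueError):
            MechBC(left="free", right="free", bottom="free", top="free")

    def test_update_stress_wrapper(self, default_materials):
        grid = build_grid(8, 8)
        st = MechSolver(grid, default_materials, MechBC()).new_state()
        out = update_stress(st, np.zeros(grid.n_cells), np.zeros(grid.n_cells),
                            1.0, grid, default_materials, MechBC(),
                            theta2_field=np.zeros(grid.n_cells))
        assert np.allclose(out.sigma, 0.0)


def _state_with(grid, fills, time=0.0):
    n = grid.n_cells
    st = StressState(time=time, sigma=np.zeros((n, 4, 4)),
                     creep_strain=np.zeros((n, 4)), thermal_strain=np.zeros(n),
                     u_disp=np.zeros(2 * (grid.nx + 1) * (grid.ny + 1)))
    for cell, comp, val in fills:
        st.sigma[cell, :, comp] = val
    return st


class TestPeakStress:
    def test_constant_zero_history(self):
        grid = build_grid(16, 16)
        s0 = _state_with(grid, [], time=1.0)
        val, t, cell = peak_stress([s0], "skin", grid)
        assert val == 0.0 and t == 1.0
        first_skin = int(np.flatnonzero(grid.region_mask("skin").ravel())[0])
        assert cell == (first_skin // grid.nx, first_skin % grid.nx)

    def test_single_spike_recovered(self):
        grid = build_grid(16, 16)
        skin_cells = np.flatnonzero(grid.region_mask("skin").ravel())
        target = int(skin_cells[1])
        s0 = _state_with(grid, [], time=0.0)
        s1 = _state_with(grid, [(target, 0, 7e6)], time=5.0)
        val, t, cell = peak_stress([s0, s1], "skin", grid)
        assert val == pytest.approx(7e6)
        assert t == 5.0
        assert cell == (target // grid.nx, target % grid.nx)

    def test_tie_breaks_to_earlier_time(self):
        grid = build_grid(16, 16)
        c = int(np.flatnonzero(grid.region_mask("skin").ravel())[0])
        s0 = _state_with(grid, [(c, 0, 7e6)], time=2.0)
        s1 = _state_with(grid, [(c, 0, 7e6)], time=9.0)
        _, t, _ = peak_stress([s0, s1], "skin", grid)
        assert t == 2.0

    def test_unknown_region(self):
        grid = build_grid(8, 8)
        with pytest.raises(KeyError):
            peak_stress([_state_with(grid, [])], "elsewhere", grid)


class TestStressProfile:
    def test_zero_state_zero_profile(self):
        grid = build_grid(16, 16)
        pos, vals = stress_profile(_state_with(grid, []), grid, "x")
        assert len(pos) == grid.nx
        assert np.allclose(vals, 0.0)

    def test_manufactured_linear_field(self):
        grid = build_grid(16, 16)
        st = _state_with(grid, [])
        xline = np.tile(grid.x_centers, grid.ny)
        st.sigma[:, :, 0] = (2e6 * xline / grid.lx)[:, None]
        pos, vals = stress_profile(st, grid, "x")
        assert np.allclose(vals, 2e6 * pos / grid.lx, rtol=1e-12)

    def test_symmetric_loading_symmetric_profile(self, default_materials):
        grid = build_grid(16, 16)
        solver = MechSolver(grid, default_materials,
                            MechBC(left="roller", right="roller",
                                   bottom="roller", top="roller"))
        st = solver.new_state()
        out = solver.step(st, np.full(grid.n_cells, -5.0),
                          np.zeros(grid.n_cells), np.zeros(grid.n_cells), 1.0)
        _, vals = stress_profile(out, grid, "x")
        assert np.allclose(vals, vals[::-1], rtol=1e-6)

    def test_bad_axis(self):
        grid = build_grid(8, 8)
        with pytest.raises(ValueError):
            stress_profile(_state_with(grid, []), grid, "z")
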