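"""Quasi-static 2D Maxwell thermo-viscoelastic stress solver.

Plane strain on the same structured grid as the thermal solver, bilinear
(Q4) displacement elements with 2x2 Gauss quadrature and a direct sparse
factorization.  Each step inverts the Maxwell strain-rate decomposition

    d(eps)/dt = d(eps)_elastic + d(eps)_creep + d(eps)_thermal (+ phase)

with backward Euler: given the total strain increment from the displacement
solve, the creep increment ``dt * S_new / (2 mu)`` is taken implicitly,
which amounts to relaxing the old deviatoric stress by ``1/(1 + G dt/mu)``
and using the effective shear modulus ``G_eff = G/(1 + G dt/mu)`` in the
tangent.  The volumetric response is elastic with bulk modulus K.

Thermal strain ``alpha dT`` and the phase-change density eigenstrain enter
as isotropic stress-free strain increments.  Stress is stored per Gauss
point with components (xx, yy, zz, xy); sigma_zz is carried explicitly by
the plane-strain kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import PhaseChangeMaterial, mechanical_properties
from .thermal_solver import Grid

_SQ3 = 1.0 / np.sqrt(3.0)
#: Gauss points on the reference square, matching node order
#: (-,-), (+,-), (+,+), (-,+).
_GAUSS = [(-_SQ3, -_SQ3), (_SQ3, -_SQ3), (_SQ3, _SQ3), (-_SQ3, _SQ3)]

#: Voigt (xx, yy, xy-engineering) projectors of the isotropic tangent:
#: D = K * _M_VOL + G * _M_DEV.
_M_VOL = np.array([[1.0, 1.0, 0.0],
                   [1.0, 1.0, 0.0],
                   [0.0, 0.0, 0.0]])
_M_DEV = 2.0 * np.array([[2.0 / 3.0, -1.0 / 3.0, 0.0],
                         [-1.0 / 3.0, 2.0 / 3.0, 0.0],
                         [0.0, 0.0, 0.5]])

_SUPPORTS = ("roller", "fixed", "free")


@dataclass(frozen=True)
class MechBC:
    """Support condition of each outer edge: roller (zero normal
    displacement), fixed (zero displacement) or free (traction-free)."""

    left: str = "roller"
    right: str = "roller"
    bottom: str = "fixed"
    top: str = "free"

    def __post_init__(self) -> None:
        for e in ("left", "right", "bottom", "top"):
            if getattr(self, e) not in _SUPPORTS:
                raise ValueError(f"unknown support {getattr(self, e)!r} on edge {e}")
        if all(getattr(self, e) == "free" for e in ("left", "right", "bottom", "top")):
            raise ValueError("all-free supports leave the equilibrium system singular")


@dataclass
class StressState:
    """Per-Gauss-point stress and accumulated strain histories.

    sigma has shape (n_cells, 4 gauss points, 4 components xx/yy/zz/xy).
    creep_strain and thermal_strain are cell-averaged accumulations; u_disp
    is the nodal displacement vector (2 dofs per node).
    """

    time: float
    sigma: np.ndarray
    creep_strain: np.ndarray      # (n_cells, 4 components)
    thermal_strain: np.ndarray    # (n_cells,) accumulated isotropic eigenstrain
    u_disp: np.ndarray            # (n_dofs,)
    residual: float = 0.0

    def cell_sigma(self) -> np.ndarray:
        """Gauss-point average stress per cell, shape (n_cells, 4)."""
        return self.sigma.mean(axis=1)

    def copy(self) -> "StressState":
        return StressState(self.time, self.sigma.copy(), self.creep_strain.copy(),
                           self.thermal_strain.copy(), self.u_disp.copy(), self.residual)


def _nested_dissection_nodes(nxn: int, nyn: int) -> np.ndarray:
    """Elimination order of an nxn-by-nyn structured node grid by recursive
    bisection (children first, middle-line separator last)."""
    order: List[int] = []

    def rec(x0: int, x1: int, y0: int, y1: int) -> None:  # half-open ranges
        w, h = x1 - x0, y1 - y0
        if w <= 0 or h <= 0:
            return
        if w * h <= 16:
            for j in range(y0, y1):
                order.extend(j * nxn + i for i in range(x0, x1))
            return
        if w >= h:
            m = x0 + w // 2
            rec(x0, m, y0, y1)
            rec(m + 1, x1, y0, y1)
            order.extend(j * nxn + m for j in range(y0, y1))
        else:
            m = y0 + h // 2
            rec(x0, x1, y0, m)
            rec(x0, x1, m + 1, y1)
            order.extend(m * nxn + i for i in range(x0, x1))

    rec(0, nxn, 0, nyn)
    return np.asarray(order, dtype=np.int64)


def _element_b_matrices(dx: float, dy: float) -> Tuple[np.ndarray, float]:
    """B matrices (4 gauss points, 3 strain comps, 8 dofs) and w*|J|."""
    B = np.zeros((4, 3, 8))
    detj_w = dx * dy / 4.0  # weight 1 at each Gauss point
    for g, (xi, eta) in enumerate(_GAUSS):
        # dN/dxi, dN/deta for nodes (-,-), (+,-), (+,+), (-,+)
        dn_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
        dn_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
        dn_dx = dn_dxi * 2.0 / dx
        dn_dy = dn_deta * 2.0 / dy
        for a in range(4):
            B[g, 0, 2 * a] = dn_dx[a]
            B[g, 1, 2 * a + 1] = dn_dy[a]
            B[g, 2, 2 * a] = dn_dy[a]
            B[g, 2, 2 * a + 1] = dn_dx[a]
    return B, detj_w


class MechSolver:
    """Precomputed assembly structures for one grid + materials + supports."""

    def __init__(self, grid: Grid, materials: Dict[str, PhaseChangeMaterial],
                 bc: MechBC):
        self.grid = grid
        self.materials = dict(materials)
        self.bc = bc
        nx, ny = grid.nx, grid.ny
        self.n_nodes = (nx + 1) * (ny + 1)
        self.n_dofs = 2 * self.n_nodes

        self.B, self.detj_w = _element_b_matrices(grid.dx, grid.dy)
        # element stiffness templates: Ke = K_bulk * KV + G_eff * KG
        self.KV = sum(self.detj_w * self.B[g].T @ _M_VOL @ self.B[g] for g in range(4))
        self.KG = sum(self.detj_w * self.B[g].T @ _M_DEV @ self.B[g] for g in range(4))

        jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        n1 = jj * (nx + 1) + ii
        n2 = n1 + 1
        n3 = n2 + (nx + 1)
        n4 = n1 + (nx + 1)
        nodes = np.stack([n1, n2, n3, n4], axis=-1).reshape(-1, 4)
        dofs = np.empty((grid.n_cells, 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * nodes
        dofs[:, 1::2] = 2 * nodes + 1
        self.edofs = dofs
        rows = np.repeat(dofs, 8, axis=1).ravel()
        cols = np.tile(dofs, (1, 8)).ravel()

        fixed = np.zeros(self.n_dofs, dtype=bool)
        xi = np.arange(nx + 1)
        yj = np.arange(ny + 1)
        edge_nodes = {
            "left": yj * (nx + 1),
            "right": yj * (nx + 1) + nx,
            "bottom": xi,
            "top": ny * (nx + 1) + xi,
        }
        normal_dof = {"left": 0, "right": 0, "bottom": 1, "top": 1}
        for e, nds in edge_nodes.items():
            support = getattr(bc, e)
            if support == "fixed":
                fixed[2 * nds] = True
                fixed[2 * nds + 1] = True
            elif support == "roller":
                fixed[2 * nds + normal_dof[e]] = True
        if not fixed.any():
            raise ValueError("no constrained dofs; equilibrium system singular")
        self.free = np.flatnonzero(~fixed)

        # Reduced system in a nested-dissection ordering (structured grid, so
        # the separator tree is known exactly); SuperLU then factors with
        # NATURAL ordering in symmetric mode, which is ~2-3x faster than its
        # generic fill-reducing orderings here.
        nodeperm = _nested_dissection_nodes(nx + 1, ny + 1)
        dofperm = np.empty(self.n_dofs, dtype=np.int64)
        dofperm[0::2] = 2 * nodeperm
        dofperm[1::2] = 2 * nodeperm + 1
        pos = -np.ones(self.n_dofs, dtype=np.int64)
        pos[self.free] = 0  # mark free
        ordered_free = dofperm[pos[dofperm] == 0]
        self.n_free = ordered_free.size
        red = -np.ones(self.n_dofs, dtype=np.int64)
        red[ordered_free] = np.arange(self.n_free)
        self._free_perm = ordered_free  # global dof id per reduced index

        rr, cc = red[rows], red[cols]
        keep = (rr >= 0) & (cc >= 0)
        self._keep = keep
        rk, ck = rr[keep], cc[keep]
        order = np.lexsort((rk, ck))  # CSC: sort by column, then row
        self._entry_pos = np.empty(order.size, dtype=np.int64)
        # collapse duplicate (row, col) pairs to canonical CSC slots
        sr, sc = rk[order], ck[order]
        newslot = np.ones(order.size, dtype=bool)
        newslot[1:] = (sr[1:] != sr[:-1]) | (sc[1:] != sc[:-1])
        slot_of_sorted = np.cumsum(newslot) - 1
        self._entry_pos[order] = slot_of_sorted
        self._nnz = int(slot_of_sorted[-1]) + 1
        self._csc_indices = sr[newslot].astype(np.int32)
        counts = np.bincount(sc[newslot], minlength=self.n_free)
        self._csc_indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)

        # per-cell material index and eigenstrain density-contrast coefficient
        self.cell_mat = [
            (grid.region.ravel() == idx, self.materials[name])
            for idx, name in enumerate(Grid.REGIONS)
        ]
        self.eig_coef = np.zeros(grid.n_cells)
        for mask, mat in self.cell_mat:
            self.eig_coef[mask] = (mat.phase1.density / mat.phase2.density) ** (1.0 / 3.0) - 1.0

    # -- helpers -----------------------------------------------------------

    def new_state(self) -> StressState:
        n = self.grid.n_cells
        return StressState(time=0.0, sigma=np.zeros((n, 4, 4)),
                           creep_strain=np.zeros((n, 4)),
                           thermal_strain=np.zeros(n),
                           u_disp=np.zeros(self.n_dofs))

    def cell_properties(self, theta2: np.ndarray):
        """(E, nu, alpha, mu) per cell at liquid fraction theta2."""
        n = self.grid.n_cells
        E = np.empty(n); nu = np.empty(n); al = np.empty(n); mu = np.empty(n)
        for mask, mat in self.cell_mat:
            e, v, a, m = mechanical_properties(theta2[mask], mat)
            E[mask], nu[mask], al[mask], mu[mask] = e, v, a, m
        return E, nu, al, mu

    def _internal_force(self, sigma: np.ndarray) -> np.ndarray:
        """Assembled nodal force of a (n_cells, 4 gp, 4 comp) stress field."""
        f = np.zeros(self.n_dofs)
        sig_ip = sigma[:, :, [0, 1, 3]]  # in-plane Voigt (xx, yy, xy)
        fe = self.detj_w * np.einsum("gij,ngi->nj", self.B, sig_ip)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        return f

    # -- the step ----------------------------------------------------------

    def step(self, state: StressState, dT: np.ndarray, dtheta2: np.ndarray,
             theta2: np.ndarray, dt: float) -> StressState:
        """Advance stress by one quasi-static increment.

        dT, dtheta2 and theta2 are flat per-cell arrays: the temperature
        change, the liquid-fraction change over the step and the new liquid
        fraction (used for property blending).
        """
        if not dt > 0:
            raise ValueError("dt must be > 0")
        E, nu, alpha, mu = self.cell_properties(theta2)
        Kb = E / (3.0 * (1.0 - 2.0 * nu))
        G = E / (2.0 * (1.0 + nu))
        with np.errstate(over="ignore"):
            relax = 1.0 / (1.0 + G * dt / mu)
        relax = np.where(np.isinf(mu), 1.0, relax)
        G_eff = G * relax

        e0 = alpha * dT + self.eig_coef * dtheta2  # isotropic eigenstrain increment

        # Stress memory release on melting: the fraction of the remaining
        # solid that liquefied this step carries no stress into the liquid
        # (melt water flows / equilibrates; only the surviving solid skeleton
        # keeps its load).  Freezing direction is unaffected.
        th2_old = np.clip(theta2 - dtheta2, 0.0, 1.0)
        melted = np.clip(dtheta2, 0.0, None) / np.maximum(1.0 - th2_old, 1e-12)
        keep_mem = np.clip(1.0 - melted, 0.0, 1.0)

        sig = state.sigma * keep_mem[:, None, None]
        p_old = sig[:, :, :3].mean(axis=2)
        S_old = sig.copy()
        S_old[:, :, :3] -= p_old[:, :, None]
        S_rel = S_old * relax[:, None, None]
        p_trial = p_old - (3.0 * Kb * e0)[:, None]
        sig_trial = S_rel.copy()
        sig_trial[:, :, :3] += p_trial[:, :, None]

        # tangent stiffness (straight into the canonical reduced CSC slots)
        data = (Kb[:, None] * self.KV.ravel()[None, :]
                + G_eff[:, None] * self.KG.ravel()[None, :]).ravel()
        f = self._internal_force(sig_trial)

        csc_data = np.bincount(self._entry_pos, weights=data[self._keep],
                               minlength=self._nnz)
        Kff = sp.csc_matrix((csc_data, self._csc_indices, self._csc_indptr),
                            shape=(self.n_free, self.n_free))
        du = np.zeros(self.n_dofs)
        try:
            lu = spla.splu(Kff, permc_spec="NATURAL",
                           options={"SymmetricMode": True}, diag_pivot_thresh=0.0)
            sol = lu.solve(-f[self._free_perm])
        except RuntimeError as exc:
            raise RuntimeError("singular equilibrium system (check supports)") from exc
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("singular equilibrium system (check supports)")
        du[self._free_perm] = sol

        # strain increments at Gauss points and stress update
        ue = du[self.edofs]                                   # (n, 8)
        eps = np.einsum("gij,nj->ngi", self.B, ue)            # (n, 4gp, 3): xx, yy, gamma
        tr = eps[:, :, 0] + eps[:, :, 1]
        dev = np.empty_like(sig)
        dev[:, :, 0] = eps[:, :, 0] - tr / 3.0
        dev[:, :, 1] = eps[:, :, 1] - tr / 3.0
        dev[:, :, 2] = -tr / 3.0
        dev[:, :, 3] = 0.5 * eps[:, :, 2]

        S_new = S_rel + 2.0 * G_eff[:, None, None] * dev
        p_new = p_trial + Kb[:, None] * tr
        sig_new = S_new.copy()
        sig_new[:, :, :3] += p_new[:, :, None]

        res = self._internal_force(sig_new)
        res_norm = float(np.max(np.abs(res[self.free]))) if self.free.size else 0.0
        # nodal-force scale of a uniform stress field of magnitude max|sigma|
        scale = max(float(np.max(np.abs(sig_new))), 1.0) * max(
            self.grid.dx, self.grid.dy) * self.grid.thickness
        # creep strain increment dt * S_new / (2 mu), cell-averaged
        with np.errstate(over="ignore", invalid="ignore"):
            creep_inc = np.where(np.isinf(mu)[:, None, None], 0.0,
                                 dt * S_new / (2.0 * mu[:, None, None]))
        return StressState(
            time=state.time + dt,
            sigma=sig_new,
            creep_strain=state.creep_strain + creep_inc.mean(axis=1),
            thermal_strain=state.thermal_strain + e0,
            u_disp=state.u_disp + du,
            residual=res_norm / scale,
        )


def update_stress(state: StressState, dT_field: np.ndarray, dtheta2_field: np.ndarray,
                  dt: float, grid: Grid, materials: Dict[str, PhaseChangeMaterial],
                  bc: MechBC, theta2_field: Optional[np.ndarray] = None,
                  solver: Optional[MechSolver] = None) -> StressState:
    """One-shot stress update (constructs a solver unless one is passed).

    ``theta2_field`` is the post-step liquid fraction; if omitted the blend
    is evaluated at the fully frozen state plus the given increment.
    """
    s = solver or MechSolver(grid, materials, bc)
    dT = np.asarray(dT_field, dtype=float).ravel()
    dth = np.asarray(dtheta2_field, dtype=float).ravel()
    th = (np.asarray(theta2_field, dtype=float).ravel()
          if theta2_field is not None else np.clip(dth, 0.0, 1.0))
    return s.step(state, dT, dth, th, dt)


# ---------------------------------------------------------------------------
# Scalar measures and reductions
# ---------------------------------------------------------------------------

def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von Mises scalar of (..., 4) stress tensors (xx, yy, zz, xy), Pa."""
    sig = np.asarray(sigma, dtype=float)
    p = sig[..., :3].mean(axis=-1)
    sxx = sig[..., 0] - p
    syy = sig[..., 1] - p
    szz = sig[..., 2] - p
    sxy = sig[..., 3]
    out = np.sqrt(1.5 * (sxx ** 2 + syy ** 2 + szz ** 2 + 2.0 * sxy ** 2))
    return float(out) if out.ndim == 0 else out


def max_principal(sigma: np.ndarray) -> np.ndarray:
    """Largest principal stress (positive = tension) of (..., 4) tensors."""
    sig = np.asarray(sigma, dtype=float)
    mean_ip = 0.5 * (sig[..., 0] + sig[..., 1])
    rad = np.sqrt((0.5 * (sig[..., 0] - sig[..., 1])) ** 2 + sig[..., 3] ** 2)
    out = np.maximum(mean_ip + rad, sig[..., 2])
    return float(out) if out.ndim == 0 else out


_MEASURES = {"von_mises": von_mises, "principal": max_principal}


def cell_scalar(state: StressState, measure: str = "von_mises") -> np.ndarray:
    """Per-cell scalar stress (Gauss-point average tensor), flat array."""
    try:
        fn = _MEASURES[measure]
    except KeyError:
        raise KeyError(f"unknown measure {measure!r}") from None
    return fn(state.cell_sigma())


def peak_stress(history: Iterable[StressState], region: str, grid: Grid,
                measure: str = "von_mises") -> Tuple[float, float, Tuple[int, int]]:
    """Max of the scalar stress over time and the cells of a region.

    region: 'skin' | 'solution' | 'skin_boundary' (within 2 cells of the
    interface).  Ties break toward the earliest time, then the lowest flat
    cell index.  Returns (value, time, (j, i) cell index).
    """
    mask = grid.region_mask(region).ravel()
    if not mask.any():
        raise ValueError(f"region {region!r} has no cells")
    best_val, best_t, best_cell = -np.inf, None, None
    cells = np.flatnonzero(mask)
    for st in history:
        vals = cell_scalar(st, measure)[cells]
        k = int(np.argmax(vals))
        if vals[k] > best_val:
            best_val = float(vals[k])
            best_t = st.time
            best_cell = int(cells[k])
    if best_t is None:
        raise ValueError("empty history")
    return best_val, best_t, (best_cell // grid.nx, best_cell % grid.nx)


def stress_profile(state: StressState, grid: Grid, axis: str,
                   measure: str = "von_mises") -> Tuple[np.ndarray, np.ndarray]:
    """Scalar stress along the skin midline: positions (m) and values (Pa).

    axis 'x' samples the full row of cells through the skin center,
    axis 'y' the full column.
    """
    vals = cell_scalar(state, measure).reshape(grid.ny, grid.nx)
    jc, ic = grid.nearest_cell(grid.lx / 2.0, grid.ly / 2.0)
    if axis == "x":
        return grid.x_centers, vals[jc, :]
    if axis == "y":
        return grid.y_centers, vals[:, ic]
    raise ValueError("axis must be 'x' or 'y'")
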