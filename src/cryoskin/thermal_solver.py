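"""Transient 2D heat conduction with phase change on a structured grid.

Cell-centered finite volumes, harmonic-mean face conductivities, implicit
(backward Euler) stepping.  The latent heat is handled with an
enthalpy-consistent Picard iteration: the effective capacity of each cell is
the secant slope ``(H(T_k) - H(T_n)) / (T_k - T_n)`` of the analytic
volumetric enthalpy, so the converged step satisfies a discrete enthalpy
balance and the boundary-heat ledger closes to the Picard tolerance.

The convective term of the governing equation is dropped (u = 0): no flow
model or parameters are available, and conduction plus latent heat dominates
at these scales.  Internal sources Q and q0 are accepted as config hooks but
default to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import PhaseChangeMaterial, celsius_to_kelvin
from . import materials as mats

EDGES = ("left", "right", "bottom", "top")


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Structured cell grid over the solution domain with an embedded skin
    rectangle (both centered; lengths in meters)."""

    nx: int
    ny: int
    lx: float = 0.020
    ly: float = 0.020
    skin_lx: float = 0.010
    skin_ly: float = 0.002
    thickness: float = 1.0
    region: np.ndarray = field(repr=False, default=None)  # (ny, nx) int8: 0 solution, 1 skin

    REGIONS = ("solution", "skin")

    @property
    def dx(self) -> float:
        return self.lx / self.nx

    @property
    def dy(self) -> float:
        return self.ly / self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dy * self.thickness

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def region_mask(self, name: str) -> np.ndarray:
        if name == "skin":
            return self.region == 1
        if name == "solution":
            return self.region == 0
        if name == "skin_boundary":
            return interface_band(self, width=2)
        raise KeyError(f"unknown region {name!r}")

    def boundary_mask(self) -> np.ndarray:
        m = np.zeros((self.ny, self.nx), dtype=bool)
        m[0, :] = m[-1, :] = True
        m[:, 0] = m[:, -1] = True
        return m

    def nearest_cell(self, x: float, y: float) -> Tuple[int, int]:
        i = int(np.clip(np.round(x / self.dx - 0.5), 0, self.nx - 1))
        j = int(np.clip(np.round(y / self.dy - 0.5), 0, self.ny - 1))
        return j, i


def build_grid(nx: int = 100, ny: int = 100, lx: float = 0.020, ly: float = 0.020,
               skin_lx: float = 0.010, skin_ly: float = 0.002,
               thickness: float = 1.0) -> Grid:
    """Label cells whose center lies in the centered skin rectangle as skin.

    Membership is half-open on the max edges ([x0, x1) x [y0, y1)) so a
    refinement never double-counts centers sitting exactly on an edge.
    """
    if min(nx, ny) < 8:
        raise ValueError("nx and ny must be >= 8")
    if not (0 < skin_lx <= lx and 0 < skin_ly <= ly):
        raise ValueError("skin rectangle must be positive and fit inside the domain")
    xc = (np.arange(nx) + 0.5) * (lx / nx)
    yc = (np.arange(ny) + 0.5) * (ly / ny)
    x0, x1 = (lx - skin_lx) / 2.0, (lx + skin_lx) / 2.0
    y0, y1 = (ly - skin_ly) / 2.0, (ly + skin_ly) / 2.0
    in_x = (xc >= x0) & (xc < x1)
    in_y = (yc >= y0) & (yc < y1)
    region = (in_y[:, None] & in_x[None, :]).astype(np.int8)
    return Grid(nx=nx, ny=ny, lx=lx, ly=ly, skin_lx=skin_lx, skin_ly=skin_ly,
                thickness=thickness, region=region)


def interface_band(grid: Grid, width: int = 2) -> np.ndarray:
    """Cells within `width` cells (Chebyshev distance) of the skin/solution
    interface, on either side."""
    from scipy.ndimage import binary_dilation
    skin = grid.region == 1
    struct = np.ones((3, 3), dtype=bool)
    grown = binary_dilation(skin, structure=struct, iterations=width)
    shrunk = ~binary_dilation(~skin, structure=struct, iterations=width)
    return grown & ~shrunk


# ---------------------------------------------------------------------------
# Boundary conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalBC:
    """One boundary condition applied to a set of outer edges.

    kind:
      * ``dirichlet_ramp``  -- edge temperature start + rate * t, clipped at target
      * ``dirichlet_hold``  -- fixed edge temperature (``start_temperature``)
      * ``convective_bath`` -- Robin condition with film coefficient h toward
        ``bath_temperature``
    Temperatures kelvin, times seconds (stage-relative).
    """

    kind: str
    start_temperature: float = float("nan")
    target_temperature: float = float("nan")
    ramp_rate: float = 0.0  # K/s, signed
    bath_temperature: float = float("nan")
    film_coefficient: float = float("nan")
    applies_to: Tuple[str, ...] = EDGES

    def __post_init__(self) -> None:
        if self.kind not in ("dirichlet_ramp", "dirichlet_hold", "convective_bath"):
            raise ValueError(f"unknown BC kind {self.kind!r}")
        if self.kind == "dirichlet_ramp":
            span = self.target_temperature - self.start_temperature
            if span * self.ramp_rate <= 0:
                raise ValueError("ramp_rate sign inconsistent with start -> target")
        if self.kind == "convective_bath" and not self.film_coefficient > 0:
            raise ValueError("film coefficient h must be > 0 for convective BC")
        bad = set(self.applies_to) - set(EDGES)
        if bad:
            raise ValueError(f"unknown edges {sorted(bad)}")

    def edge_temperature(self, t_stage: float) -> float:
        """Imposed edge (or bath) temperature at stage-relative time t."""
        if self.kind == "dirichlet_hold":
            return self.start_temperature
        if self.kind == "convective_bath":
            return self.bath_temperature
        t_end = (self.target_temperature - self.start_temperature) / self.ramp_rate
        return self.start_temperature + self.ramp_rate * min(max(t_stage, 0.0), t_end)


# ---------------------------------------------------------------------------
# State and material field
# ---------------------------------------------------------------------------

@dataclass
class ThermalState:
    """Temperature / phase fields at one time point.

    ``theta_ice`` is the frozen-phase fraction (1 - theta2 of the material's
    liquid indicator).  ``boundary_heat`` is the cumulative heat that entered
    the domain through the boundary (J, signed), updated every step.
    """

    time: float
    T: np.ndarray            # (ny, nx) kelvin
    theta_ice: np.ndarray    # (ny, nx) in [0, 1]
    boundary_heat: float = 0.0

    def copy(self) -> "ThermalState":
        return ThermalState(self.time, self.T.copy(), self.theta_ice.copy(),
                            self.boundary_heat)


class MaterialField:
    """Vectorized per-cell evaluation of region-dependent material laws."""

    def __init__(self, grid: Grid, materials: Dict[str, PhaseChangeMaterial]):
        self.grid = grid
        self.materials = dict(materials)
        self._masks = [
            (grid.region.ravel() == idx, self.materials[name])
            for idx, name in enumerate(Grid.REGIONS)
        ]

    def _apply(self, fn, T: np.ndarray) -> np.ndarray:
        out = np.empty_like(T, dtype=float)
        for mask, mat in self._masks:
            out[mask] = fn(T[mask], mat)
        return out

    def conductivity(self, T: np.ndarray) -> np.ndarray:
        def fn(t, m):
            th2 = mats.phase_fraction(t, m)
            return (1.0 - th2) * m.phase1.conductivity + th2 * m.phase2.conductivity
        return self._apply(fn, T)

    def enthalpy(self, T: np.ndarray) -> np.ndarray:
        return self._apply(mats.volumetric_enthalpy, T)

    def apparent_rho_cp(self, T: np.ndarray) -> np.ndarray:
        def fn(t, m):
            th2 = np.asarray(mats.phase_fraction(t, m))
            rho = (1.0 - th2) * m.phase1.density + th2 * m.phase2.density
            return rho * np.asarray(mats.apparent_heat_capacity(t, m))
        return self._apply(fn, T)

    def liquid_fraction(self, T: np.ndarray) -> np.ndarray:
        return self._apply(lambda t, m: np.asarray(mats.phase_fraction(t, m)), T)

    def ice_fraction(self, T: np.ndarray) -> np.ndarray:
        return 1.0 - self.liquid_fraction(T)


# ---------------------------------------------------------------------------
# Implicit step
# ---------------------------------------------------------------------------

def _edge_cells(grid: Grid, edge: str) -> np.ndarray:
    """Flat indices of the cells adjacent to an outer edge."""
    nx, ny = grid.nx, grid.ny
    idx = np.arange(grid.n_cells).reshape(ny, nx)
    return {"left": idx[:, 0], "right": idx[:, -1],
            "bottom": idx[0, :], "top": idx[-1, :]}[edge]


def _edge_geometry(grid: Grid, edge: str) -> Tuple[float, float]:
    """(face area, half cell width normal to the edge)."""
    if edge in ("left", "right"):
        return grid.dy * grid.thickness, grid.dx / 2.0
    return grid.dx * grid.thickness, grid.dy / 2.0


class _StencilCache:
    """Precomputed COO index structure of the 5-point stencil for one grid."""

    def __init__(self, grid: Grid):
        nx, ny, n = grid.nx, grid.ny, grid.n_cells
        idx = np.arange(n).reshape(ny, nx)
        ax, bx = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        ay, by = idx[:-1, :].ravel(), idx[1:, :].ravel()
        self.face_a = np.concatenate([ax, ay])
        self.face_b = np.concatenate([bx, by])
        self.rows = np.concatenate([self.face_a, self.face_b, self.face_a, self.face_b,
                                    np.arange(n)])
        self.cols = np.concatenate([self.face_a, self.face_b, self.face_b, self.face_a,
                                    np.arange(n)])
        self.n = n
        self.nxf = ax.size  # number of x faces


def step_temperature(state: ThermalState, grid: Grid, matfield: MaterialField,
                     bcs: Sequence[ThermalBC], dt: float, stage_time: float,
                     tol: float = 1e-6, max_iter: int = 50,
                     _cache: Optional[_StencilCache] = None) -> ThermalState:
    """Advance temperature by one implicit step with Picard iteration.

    Boundary values are evaluated at the end-of-step stage time (implicit).
    Edges not covered by any BC are insulated.  Returns a new state; the
    boundary ledger is incremented by the discrete flux through all edges.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    cache = _cache or _StencilCache(grid)
    nx, ny, n = grid.nx, grid.ny, grid.n_cells
    V = grid.cell_volume
    t_bc = stage_time + dt

    Tn = state.T.ravel()
    Hn = matfield.enthalpy(Tn)

    # resolve per-edge BCs
    edge_bc: Dict[str, ThermalBC] = {}
    for bc in bcs:
        for e in bc.applies_to:
            edge_bc[e] = bc

    Tk = Tn.copy()
    Tnew = Tk
    for _ in range(max_iter):
        kc = matfield.conductivity(Tk)
        k2 = kc.reshape(ny, nx)
        gx = (2.0 * k2[:, :-1] * k2[:, 1:] / (k2[:, :-1] + k2[:, 1:])
              ) * grid.dy * grid.thickness / grid.dx
        gy = (2.0 * k2[:-1, :] * k2[1:, :] / (k2[:-1, :] + k2[1:, :])
              ) * grid.dx * grid.thickness / grid.dy
        g = np.concatenate([gx.ravel(), gy.ravel()])

        dT = Tk - Tn
        small = np.abs(dT) < 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            cbar = np.where(small, 1.0, (matfield.enthalpy(Tk) - Hn) / np.where(small, 1.0, dT))
        if np.any(small):
            rcp = matfield.apparent_rho_cp(Tk)
            cbar[small] = rcp[small]

        diag = V * cbar / dt
        b = diag * Tn

        # boundary contributions
        bflux_g: List[Tuple[np.ndarray, np.ndarray, float]] = []
        diag_extra = np.zeros(n)
        for e, bc in edge_bc.items():
            cells = _edge_cells(grid, e)
            area, half = _edge_geometry(grid, e)
            t_edge = bc.edge_temperature(t_bc)
            if bc.kind == "convective_bath":
                gb = area / (1.0 / bc.film_coefficient + half / kc[cells])
            else:
                gb = area * kc[cells] / half
            diag_extra[cells] += gb
            b[cells] += gb * t_edge
            bflux_g.append((cells, gb, t_edge))

        data = np.concatenate([g, g, -g, -g, diag + diag_extra])
        A = sp.coo_matrix((data, (cache.rows, cache.cols)), shape=(n, n)).tocsr()
        # SPD system: warm-started Jacobi-CG is ~15x faster than the direct
        # solve here; fall back to SuperLU if it ever stalls.
        Tnew, info = spla.cg(A, b, x0=Tk, rtol=1e-13, atol=0.0,
                             M=sp.diags(1.0 / A.diagonal()), maxiter=1000)
        if info != 0:
            Tnew = spla.spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(Tnew)):
            raise RuntimeError(
                f"non-finite temperature at t={state.time + dt:.3f} s "
                f"(stage time {t_bc:.3f} s); min/max of previous iterate: "
                f"{Tk.min():.2f}/{Tk.max():.2f} K")
        if np.max(np.abs(Tnew - Tk)) < tol:
            Tk = Tnew
            break
        Tk = Tnew

    q_boundary = 0.0
    for cells, gb, t_edge in bflux_g:
        q_boundary += float(np.sum(gb * (t_edge - Tk[cells]))) * dt

    T2 = Tk.reshape(ny, nx)
    theta_ice = matfield.ice_fraction(Tk).reshape(ny, nx)
    return ThermalState(time=state.time + dt, T=T2, theta_ice=theta_ice,
                        boundary_heat=state.boundary_heat + q_boundary)


# ---------------------------------------------------------------------------
# Protocol runner
# ---------------------------------------------------------------------------

@dataclass
class ThermalRunResult:
    """Outputs of a thermal protocol run."""

    times: np.ndarray                 # per-step times
    mean_ice: np.ndarray              # per-step domain-mean ice fraction
    trace_times: np.ndarray           # output-cadence times
    probe_traces: Dict[str, Dict[str, np.ndarray]]  # name -> {"T_K", "theta_ice"}
    probe_cells: Dict[str, Tuple[int, int]]
    onset_times: Dict[str, Optional[float]]  # 'boundary', 'skin', 'solution', 'skin_interface'
    energy_ledger: List[Dict[str, float]]    # per stage
    snapshots: List[ThermalState]
    final_state: ThermalState


def run_thermal(protocol, grid: Grid, materials: Dict[str, PhaseChangeMaterial],
                initial_temperature: Optional[float] = None,
                snapshot_interval: Optional[float] = None,
                onset_threshold: float = 0.01,
                step_callback: Optional[Callable] = None) -> ThermalRunResult:
    """Run an ordered sequence of boundary-condition stages.

    ``protocol`` needs ``.stages`` (each with name, bcs, duration, dt,
    output_interval and optionally dt_frozen) and ``.probes`` (name -> (x, y)
    in meters).  ``step_callback(state, prev_state, stage, dt)`` is invoked
    after every accepted step (used for one-way mechanical coupling).
    """
    stages = list(protocol.stages)
    if not stages:
        raise ValueError("protocol has no stages")
    for st in stages:
        if not st.duration > 0:
            raise ValueError(f"stage {st.name!r} has non-positive duration")

    matfield = MaterialField(grid, materials)
    cache = _StencilCache(grid)
    T0 = initial_temperature
    if T0 is None:
        T0 = getattr(protocol, "initial_temperature", None)
    if T0 is None:
        raise ValueError("initial temperature not given")
    T = np.full((grid.ny, grid.nx), float(T0))
    state = ThermalState(time=0.0, T=T, theta_ice=matfield.ice_fraction(T.ravel()).reshape(T.shape))

    probes = dict(getattr(protocol, "probes", {}) or {})
    probe_cells = {name: grid.nearest_cell(x, y) for name, (x, y) in probes.items()}
    probe_traces = {name: {"T_K": [], "theta_ice": []} for name in probes}
    trace_times: List[float] = []

    times: List[float] = [0.0]
    mean_ice: List[float] = [float(state.theta_ice.mean())]

    boundary = grid.boundary_mask()
    skin = grid.region_mask("skin")
    interface = interface_band(grid, width=1)
    onset: Dict[str, Optional[float]] = {"boundary": None, "skin": None,
                                         "solution": None, "skin_interface": None}

    def record_traces(s: ThermalState) -> None:
        trace_times.append(s.time)
        for name, (j, i) in probe_cells.items():
            probe_traces[name]["T_K"].append(s.T[j, i])
            probe_traces[name]["theta_ice"].append(s.theta_ice[j, i])

    def check_onsets(s: ThermalState) -> None:
        if all(v is not None for v in onset.values()):
            return
        frozen = s.theta_ice > onset_threshold
        if onset["boundary"] is None and np.any(frozen & boundary):
            onset["boundary"] = s.time
        if onset["solution"] is None and np.any(frozen & ~skin):
            onset["solution"] = s.time
        if onset["skin"] is None and np.any(frozen & skin):
            onset["skin"] = s.time
        if onset["skin_interface"] is None and np.any(frozen & interface):
            onset["skin_interface"] = s.time

    record_traces(state)
    check_onsets(state)
    snapshots: List[ThermalState] = [state.copy()] if snapshot_interval else []

    ledger: List[Dict[str, float]] = []
    t_global = 0.0
    next_trace = 0.0
    next_snap = 0.0
    for stage in stages:
        stage_start = t_global
        stage_end = t_global + stage.duration
        q0 = state.boundary_heat
        h0 = float(np.sum(matfield.enthalpy(state.T.ravel()))) * grid.cell_volume
        dt_base = stage.dt
        dt_frozen = getattr(stage, "dt_frozen", None)
        while state.time < stage_end - 1e-9:
            dt = dt_base
            if dt_frozen and np.all(state.theta_ice > 0.999):
                dt = dt_frozen
            dt = min(dt, stage_end - state.time)
            prev = state
            state = step_temperature(prev, grid, matfield, stage.bcs, dt,
                                     stage_time=prev.time - stage_start, _cache=cache)
            times.append(state.time)
            mean_ice.append(float(state.theta_ice.mean()))
            check_onsets(state)
            if state.time >= next_trace - 1e-9 + stage.output_interval:
                next_trace = state.time
                record_traces(state)
            if snapshot_interval and state.time >= next_snap - 1e-9 + snapshot_interval:
                next_snap = state.time
                snapshots.append(state.copy())
            if step_callback is not None:
                step_callback(state, prev, stage, dt)
        h1 = float(np.sum(matfield.enthalpy(state.T.ravel()))) * grid.cell_volume
        q1 = state.boundary_heat
        ledger.append({
            "stage": stage.name,
            "t_start": stage_start, "t_end": stage_end,
            "boundary_heat_J": q1 - q0,
            "enthalpy_change_J": h1 - h0,
            "drift_J": (h1 - h0) - (q1 - q0),
        })
        t_global = stage_end

    return ThermalRunResult(
        times=np.asarray(times), mean_ice=np.asarray(mean_ice),
        trace_times=np.asarray(trace_times),
        probe_traces={k: {kk: np.asarray(vv) for kk, vv in v.items()}
                      for k, v in probe_traces.items()},
        probe_cells=probe_cells, onset_times=onset, energy_ledger=ledger,
        snapshots=snapshots, final_state=state)


def phase_completion_time(times: np.ndarray, values: np.ndarray,
                          threshold: float = 0.999,
                          direction: str = "up") -> Optional[float]:
    """First time a trace crosses `threshold`, linearly interpolated.

    direction 'up' detects an upward crossing (freezing completion of a mean
    ice-fraction trace), 'down' a downward one (melt completion).  Returns
    None if never crossed.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0 or t.size != v.size:
        raise ValueError("times and values must be equal-length, nonempty")
    if direction == "up":
        hit = v >= threshold
    elif direction == "down":
        hit = v <= threshold
    else:
        raise ValueError("direction must be 'up' or 'down'")
    if not hit.any():
        return None
    i = int(np.argmax(hit))
    if i == 0:
        return float(t[0])
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t[i])
    frac = (threshold - v0) / (v1 - v0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
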