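"""Protocol composition and coupled cooling/rewarming simulation driver.

A :class:`Protocol` is an ordered list of boundary-condition stages plus
probe locations.  :func:`run_cycle` advances the thermal solution stage by
stage and, at a configurable coupling cadence, feeds temperature and
phase-fraction increments to the quasi-static Maxwell stress solver
(one-way, staggered coupling).  Milestones (per-region ice onset,
freeze/melt completion, peak stresses) are extracted on the fly so full
stress histories never need to be stored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import __version__
from .materials import PhaseChangeMaterial, celsius_to_kelvin
from .thermal_solver import (Grid, ThermalBC, ThermalRunResult,
                             phase_completion_time, run_thermal)
from .mech_solver import MechBC, MechSolver, StressState, cell_scalar

REGIONS_TRACKED = ("skin", "solution", "skin_boundary")
MEASURES_TRACKED = ("von_mises", "principal")


@dataclass(frozen=True)
class Stage:
    """One boundary-condition stage of a protocol."""

    name: str
    bcs: Tuple[ThermalBC, ...]
    duration: float
    dt: float = 0.5
    output_interval: float = 1.0
    dt_frozen: Optional[float] = None   # accelerated step once fully frozen
    mech_interval: float = 1.0          # mechanical coupling cadence

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"stage {self.name!r} must have positive duration")
        if not (self.dt > 0 and self.output_interval > 0 and self.mech_interval > 0):
            raise ValueError("dt, output_interval and mech_interval must be > 0")


@dataclass(frozen=True)
class Protocol:
    """Ordered stages plus initial temperature and named probe points.

    Probes may be None, in which case :func:`default_probes` places
    'point1' at the skin/solution interface and 'point2' in the solution on
    the same concentric circle about the domain center.
    """

    name: str
    stages: Tuple[Stage, ...]
    initial_temperature: float
    probes: Optional[Dict[str, Tuple[float, float]]] = None

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.stages)


def default_probes(grid: Grid) -> Dict[str, Tuple[float, float]]:
    """Point 1: solution cell touching the skin short edge; Point 2: solution
    cell at the same distance from the domain center, rotated 90 degrees."""
    r = grid.skin_lx / 2.0 + 0.75 * grid.dx
    cx, cy = grid.lx / 2.0, grid.ly / 2.0
    return {"point1": (cx + r, cy), "point2": (cx, cy + r)}


LN2_TEMPERATURE = celsius_to_kelvin(-196.0)
BATH_TEMPERATURE = celsius_to_kelvin(37.0)


def standard_cooling_protocol(initial_temperature: float = celsius_to_kelvin(4.0),
                              ramp_rate: float = -1.0 / 60.0,
                              ramp_target: float = celsius_to_kelvin(-80.0),
                              total_duration: float = 6000.0,
                              ln2_film_coefficient: float = 200.0,
                              dt: float = 1.0,
                              dt_frozen: float = 5.0,
                              output_interval: float = 1.0,
                              mech_interval: float = 10.0) -> Protocol:
    """Controlled -1 C/min ramp to -80 C on all outer edges, then an LN2
    convective bath stage until ``total_duration`` (snapshot horizon)."""
    if initial_temperature <= ramp_target:
        raise ValueError("initial temperature must exceed the ramp target "
                         "(zero-length ramp stage)")
    ramp_duration = (ramp_target - initial_temperature) / ramp_rate
    stages = [Stage(
        name="ramp",
        bcs=(ThermalBC(kind="dirichlet_ramp", start_temperature=initial_temperature,
                       target_temperature=ramp_target, ramp_rate=ramp_rate),),
        duration=ramp_duration, dt=dt, dt_frozen=dt_frozen,
        output_interval=output_interval, mech_interval=mech_interval)]
    if total_duration > ramp_duration:
        stages.append(Stage(
            name="ln2",
            bcs=(ThermalBC(kind="convective_bath", bath_temperature=LN2_TEMPERATURE,
                           film_coefficient=ln2_film_coefficient),),
            duration=total_duration - ramp_duration, dt=dt, dt_frozen=dt_frozen,
            output_interval=output_interval, mech_interval=4.0 * mech_interval))
    return Protocol(name="standard_cooling", stages=tuple(stages),
                    initial_temperature=initial_temperature)


def standard_rewarming_protocol(duration: float = 450.0,
                                bath_temperature: float = BATH_TEMPERATURE,
                                film_coefficient: float = 800.0,
                                initial_temperature: float = LN2_TEMPERATURE,
                                dt: float = 0.25,
                                output_interval: float = 1.0,
                                mech_interval: float = 2.0) -> Protocol:
    """37 C water-bath rewarming of a uniformly frozen -196 C domain."""
    stage = Stage(
        name="bath",
        bcs=(ThermalBC(kind="convective_bath", bath_temperature=bath_temperature,
                       film_coefficient=film_coefficient),),
        duration=duration, dt=dt, output_interval=output_interval,
        mech_interval=mech_interval)
    return Protocol(name="standard_rewarming", stages=(stage,),
                    initial_temperature=initial_temperature)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class PeakRecord:
    value: float
    time: float
    cell: Tuple[int, int]


@dataclass
class SimulationResult:
    """Everything one coupled run produces."""

    protocol_name: str
    config_echo: Dict
    thermal: ThermalRunResult
    milestones: Dict
    stress_times: np.ndarray
    stress_traces: Dict[str, np.ndarray]      # "<region>/<measure>" -> regional max trace
    stress_peaks: Dict[str, PeakRecord]       # "<region>/<measure>"
    final_stress: Optional[StressState]
    stress_snapshots: List[StressState]
    code_version: str = __version__
    seed: Optional[int] = None

    def milestones_json(self) -> str:
        def default(o):
            if isinstance(o, PeakRecord):
                return {"value": o.value, "time": o.time, "cell": list(o.cell)}
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        payload = {"protocol": self.protocol_name, "code_version": self.code_version,
                   "milestones": self.milestones, "config": self.config_echo}
        return json.dumps(payload, sort_keys=True, indent=2, default=default)

    def probe_trace_frame(self):
        """Probe traces as a tidy pandas DataFrame (time_s, probe_id, T_C, theta_ice)."""
        import pandas as pd
        rows = []
        for name, tr in self.thermal.probe_traces.items():
            t = self.thermal.trace_times
            for k in range(len(t)):
                rows.append((t[k], name, tr["T_K"][k] - 273.15, tr["theta_ice"][k]))
        return pd.DataFrame(rows, columns=["time_s", "probe_id", "T_C", "theta_ice"])


def _protocol_echo(protocol: Protocol, grid: Grid,
                   materials: Dict[str, PhaseChangeMaterial],
                   mech_bc: Optional[MechBC]) -> Dict:
    echo = {
        "protocol": {
            "name": protocol.name,
            "initial_temperature_K": protocol.initial_temperature,
            "stages": [
                {"name": s.name, "duration_s": s.duration, "dt_s": s.dt,
                 "dt_frozen_s": s.dt_frozen, "output_interval_s": s.output_interval,
                 "mech_interval_s": s.mech_interval,
                 "bcs": [asdict(bc) for bc in s.bcs]}
                for s in protocol.stages],
        },
        "grid": {"nx": grid.nx, "ny": grid.ny, "lx_m": grid.lx, "ly_m": grid.ly,
                 "skin_lx_m": grid.skin_lx, "skin_ly_m": grid.skin_ly,
                 "thickness_m": grid.thickness},
        "materials": {name: asdict(m) for name, m in materials.items()},
        "mech_bc": asdict(mech_bc) if mech_bc is not None else None,
    }
    return echo


def run_cycle(protocol: Protocol, grid: Grid,
              materials: Dict[str, PhaseChangeMaterial],
              mech_bc: Optional[MechBC] = None,
              with_mech: bool = True,
              snapshot_interval: Optional[float] = None,
              stress_snapshot_interval: Optional[float] = None,
              onset_threshold: float = 0.01) -> SimulationResult:
    """Run one protocol with one-way coupled thermal + stress physics.

    Deterministic given its configuration (no randomness anywhere).
    """
    probes = protocol.probes or default_probes(grid)
    for name, (x, y) in probes.items():
        if not (0 <= x <= grid.lx and 0 <= y <= grid.ly):
            raise ValueError(f"probe {name!r} outside domain")
    proto = Protocol(name=protocol.name, stages=protocol.stages,
                     initial_temperature=protocol.initial_temperature, probes=probes)

    mech_bc = mech_bc or MechBC()
    solver = MechSolver(grid, materials, mech_bc) if with_mech else None

    region_cells = {r: np.flatnonzero(grid.region_mask(r).ravel())
                    for r in REGIONS_TRACKED}
    stress_times: List[float] = []
    traces: Dict[str, List[float]] = {f"{r}/{m}": []
                                      for r in REGIONS_TRACKED for m in MEASURES_TRACKED}
    peaks: Dict[str, PeakRecord] = {}
    stress_snapshots: List[StressState] = []

    coupler = {"state": solver.new_state() if solver else None,
               "last_T": None, "last_th2": None, "next_t": 0.0, "next_snap": 0.0}

    def record_stress(st: StressState, t: float) -> None:
        stress_times.append(t)
        for m in MEASURES_TRACKED:
            vals = cell_scalar(st, m)
            for r, cells in region_cells.items():
                key = f"{r}/{m}"
                v = vals[cells]
                k = int(np.argmax(v))
                traces[key].append(float(v[k]))
                if key not in peaks or v[k] > peaks[key].value:
                    cidx = int(cells[k])
                    peaks[key] = PeakRecord(float(v[k]), t,
                                            (cidx // grid.nx, cidx % grid.nx))

    def callback(state, prev, stage, dt) -> None:
        if solver is None:
            return
        c = coupler
        if c["last_T"] is None:
            # reference fields at t=0 (stress-free initial state)
            th20 = 1.0 - prev.theta_ice.ravel()
            c["last_T"] = prev.T.ravel().copy()
            c["last_th2"] = th20.copy()
            c["next_t"] = stage.mech_interval
            record_stress(c["state"], prev.time)
        if state.time + 1e-9 < c["next_t"]:
            return
        th2 = 1.0 - state.theta_ice.ravel()
        dT = state.T.ravel() - c["last_T"]
        dth = th2 - c["last_th2"]
        dt_mech = state.time - (stress_times[-1] if stress_times else 0.0)
        st = solver.step(c["state"], dT, dth, th2, dt_mech)
        st.time = state.time
        c["state"] = st
        c["last_T"] = state.T.ravel().copy()
        c["last_th2"] = th2.copy()
        c["next_t"] = state.time + stage.mech_interval
        record_stress(st, state.time)
        if stress_snapshot_interval and state.time >= c["next_snap"]:
            c["next_snap"] = state.time + stress_snapshot_interval
            stress_snapshots.append(st.copy())

    thermal = run_thermal(proto, grid, materials,
                          snapshot_interval=snapshot_interval,
                          onset_threshold=onset_threshold,
                          step_callback=callback if with_mech else None)

    milestones: Dict = {
        "onset_times_s": dict(thermal.onset_times),
        "freeze_completion_s": phase_completion_time(
            thermal.times, thermal.mean_ice, 0.999, "up"),
        "melt_completion_s": phase_completion_time(
            thermal.times, thermal.mean_ice, 0.001, "down"),
        "probe_cells": {k: list(v) for k, v in thermal.probe_cells.items()},
        "probe_coords_m": {k: list(v) for k, v in probes.items()},
        "energy_ledger": thermal.energy_ledger,
    }
    if peaks:
        milestones["peak_stress"] = {k: {"value_Pa": p.value, "time_s": p.time,
                                         "cell": list(p.cell)}
                                     for k, p in peaks.items()}

    return SimulationResult(
        protocol_name=proto.name,
        config_echo=_protocol_echo(proto, grid, materials, mech_bc if with_mech else None),
        thermal=thermal,
        milestones=milestones,
        stress_times=np.asarray(stress_times),
        stress_traces={k: np.asarray(v) for k, v in traces.items()},
        stress_peaks=peaks,
        final_stress=coupler["state"],
        stress_snapshots=stress_snapshots,
    )


def probe_completion_time(result: SimulationResult, probe: str) -> Optional[float]:
    """Phase-transition completion time of one probe's ice-fraction trace.

    Direction is inferred from the run: freezing if the domain-mean ice
    fraction rises overall, melting otherwise.
    """
    tr = result.thermal.probe_traces.get(probe)
    if tr is None:
        raise KeyError(f"probe {probe!r} has no trace")
    t = result.thermal.trace_times
    freezing = result.thermal.mean_ice[-1] >= result.thermal.mean_ice[0]
    if freezing:
        return phase_completion_time(t, tr["theta_ice"], 0.999, "up")
    return phase_completion_time(t, tr["theta_ice"], 0.001, "down")


def interface_lag(result: SimulationResult, probe1: str = "point1",
                  probe2: str = "point2") -> float:
    """Difference of per-probe phase-completion times (probe1 - probe2, s).

    Positive means the skin-interface probe completes later.
    """
    t1 = probe_completion_time(result, probe1)
    t2 = probe_completion_time(result, probe2)
    if t1 is None or t2 is None:
        raise ValueError("a probe never completed its phase transition")
    return t1 - t2
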