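"""Writers for run artifacts: CSV traces, JSON milestone reports, ASCII VTK
rectilinear snapshots and HDF5 field dumps."""

from __future__ import annotations

import json
import os
from typing import Dict

import numpy as np

from .thermal_solver import Grid, ThermalState
from .scenario import SimulationResult


def write_probe_traces_csv(result: SimulationResult, path: str) -> None:
    """Tidy CSV: time_s, probe_id, T_C, theta_ice."""
    df = result.probe_trace_frame()
    df.to_csv(path, index=False)


def write_stress_traces_csv(result: SimulationResult, path: str) -> None:
    """Regional-max stress traces: time_s plus one column per region/measure."""
    import pandas as pd
    data = {"time_s": result.stress_times}
    for key, vals in result.stress_traces.items():
        data[key.replace("/", "_") + "_Pa"] = vals
    pd.DataFrame(data).to_csv(path, index=False)


def write_milestones_json(result: SimulationResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(result.milestones_json())
        fh.write("\n")


def write_energy_log(result: SimulationResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(result.thermal.energy_ledger, fh, indent=2)
        fh.write("\n")


def write_vtk_rectilinear(grid: Grid, fields: Dict[str, np.ndarray], path: str,
                          title: str = "cryoskin snapshot") -> None:
    """Legacy ASCII VTK rectilinear file with cell-centered scalar fields."""
    nx, ny = grid.nx, grid.ny
    xs = np.linspace(0.0, grid.lx, nx + 1)
    ys = np.linspace(0.0, grid.ly, ny + 1)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write(f"X_COORDINATES {nx + 1} double\n")
        fh.write(" ".join(f"{v:.9g}" for v in xs) + "\n")
        fh.write(f"Y_COORDINATES {ny + 1} double\n")
        fh.write(" ".join(f"{v:.9g}" for v in ys) + "\n")
        fh.write("Z_COORDINATES 1 double\n0\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr, dtype=float).ravel()
            fh.write("\n".join(f"{v:.9g}" for v in flat) + "\n")


def write_thermal_snapshot_vtk(grid: Grid, state: ThermalState, path: str) -> None:
    write_vtk_rectilinear(grid, {"T_K": state.T, "theta_ice": state.theta_ice},
                          path, title=f"t={state.time:.3f}s")


def write_snapshots_h5(result: SimulationResult, grid: Grid, path: str) -> None:
    """All retained thermal/stress snapshots in one HDF5 file."""
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["code_version"] = result.code_version
        f.attrs["protocol"] = result.protocol_name
        g = f.create_group("thermal")
        for k, st in enumerate(result.thermal.snapshots):
            sg = g.create_group(f"{k:05d}")
            sg.attrs["time_s"] = st.time
            sg.create_dataset("T_K", data=st.T)
            sg.create_dataset("theta_ice", data=st.theta_ice)
        g = f.create_group("stress")
        for k, st in enumerate(result.stress_snapshots):
            sg = g.create_group(f"{k:05d}")
            sg.attrs["time_s"] = st.time
            sg.create_dataset("sigma", data=st.sigma)


def write_run_outputs(result: SimulationResult, grid: Grid, out_dir: str,
                      basename: str = "run", write_h5: bool = True) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_probe_traces_csv(result, os.path.join(out_dir, f"{basename}_probes.csv"))
    if len(result.stress_times):
        write_stress_traces_csv(result, os.path.join(out_dir, f"{basename}_stress.csv"))
    write_milestones_json(result, os.path.join(out_dir, f"{basename}_milestones.json"))
    write_energy_log(result, os.path.join(out_dir, f"{basename}_energy.json"))
    for k, st in enumerate(result.thermal.snapshots):
        write_thermal_snapshot_vtk(
            grid, st, os.path.join(out_dir, f"{basename}_thermal_{k:05d}.vtk"))
    if write_h5 and (result.thermal.snapshots or result.stress_snapshots):
        write_snapshots_h5(result, grid, os.path.join(out_dir, f"{basename}.h5"))
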