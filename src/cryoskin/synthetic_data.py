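"""Seeded synthetic-data generators with exact ground truth.

Every generator returns (data, truth) so analysis round-trips can be tested
without any external data.  Reproducibility contract: one global seed is
expanded into independent per-generator streams with
``np.random.SeedSequence(seed, spawn_key=(STREAM,))`` where STREAM is a fixed
small integer per generator (trace=1, dsc=2, permeation=3).  Adding a new
generator therefore never perturbs existing streams.  Noise is additive
Gaussian only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .assays import CPAProperties, OsmometryRecord, Thermogram

_STREAMS = {"trace": 1, "dsc": 2, "permeation": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Thermocouple traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Piecewise cooling trace: ramp -> nucleation -> recalescence ->
    plateau -> resumed cooling.  Rates are cooling magnitudes in K/min."""

    cooling_rate: float = 1.0            # K/min, > 0
    initial_temperature: float = 4.0     # C
    freezing_point: float = 0.0          # C (equilibrium)
    nucleation_temperature: float = -5.0  # C, below the freezing point
    recalescence_rise_time: float = 4.0  # s (exponential time constant)
    recalescence_cap: float = 30.0       # K, upper bound on the rise
    plateau_duration: float = 120.0      # s
    post_plateau_rate: float = 1.0       # K/min, > 0
    post_duration: float = 120.0         # s of resumed cooling
    noise_sd: float = 0.0                # K
    sampling_interval: float = 1.0       # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nucleation_temperature < self.freezing_point:
            raise ValueError("nucleation temperature must be below the freezing point")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (self.cooling_rate > 0 and self.post_plateau_rate > 0):
            raise ValueError("cooling rates must be positive magnitudes")
        if not (self.sampling_interval > 0 and self.recalescence_rise_time > 0):
            raise ValueError("sampling interval and rise time must be positive")
        if self.initial_temperature <= self.nucleation_temperature:
            raise ValueError("trace must start above the nucleation temperature")


@dataclass(frozen=True)
class TraceTruth:
    nucleation_time: float
    nucleation_temperature: float
    supercooling_depth: float
    recalescence_amplitude: float
    plateau_start: float
    plateau_end: float
    plateau_temperature: float


def trace_model(spec: TraceSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free piecewise trace evaluated at times t (s)."""
    rate = spec.cooling_rate / 60.0
    t_nuc = (spec.initial_temperature - spec.nucleation_temperature) / rate
    plateau_T = min(spec.freezing_point,
                    spec.nucleation_temperature + spec.recalescence_cap)
    tau = spec.recalescence_rise_time
    t_plat_start = t_nuc + 5.0 * tau
    t_plat_end = t_plat_start + spec.plateau_duration
    post_rate = spec.post_plateau_rate / 60.0
    T_end = plateau_T - (plateau_T - spec.nucleation_temperature) * np.exp(-5.0)

    T = np.empty_like(t, dtype=float)
    seg1 = t < t_nuc
    T[seg1] = spec.initial_temperature - rate * t[seg1]
    seg2 = (t >= t_nuc) & (t < t_plat_end)
    T[seg2] = plateau_T - (plateau_T - spec.nucleation_temperature) * np.exp(
        -(t[seg2] - t_nuc) / tau)
    seg3 = t >= t_plat_end
    T[seg3] = T_end - post_rate * (t[seg3] - t_plat_end)
    return T


def gen_trace(spec: TraceSpec) -> Tuple[np.ndarray, np.ndarray, TraceTruth]:
    """Generate (times s, temperatures C, truth) for one cooling trace."""
    rate = spec.cooling_rate / 60.0
    t_nuc = (spec.initial_temperature - spec.nucleation_temperature) / rate
    tau = spec.recalescence_rise_time
    t_plat_start = t_nuc + 5.0 * tau
    t_plat_end = t_plat_start + spec.plateau_duration
    total = t_plat_end + spec.post_duration
    n = int(np.floor(total / spec.sampling_interval)) + 1
    t = np.arange(n) * spec.sampling_interval
    T = trace_model(spec, t)
    if spec.noise_sd > 0:
        T = T + _rng(spec.seed, "trace").normal(0.0, spec.noise_sd, size=T.shape)
    plateau_T = min(spec.freezing_point,
                    spec.nucleation_temperature + spec.recalescence_cap)
    truth = TraceTruth(
        nucleation_time=t_nuc,
        nucleation_temperature=spec.nucleation_temperature,
        supercooling_depth=spec.freezing_point - spec.nucleation_temperature,
        recalescence_amplitude=plateau_T - spec.nucleation_temperature,
        plateau_start=t_plat_start,
        plateau_end=t_plat_end,
        plateau_temperature=plateau_T,
    )
    return t, T, truth


# ---------------------------------------------------------------------------
# DSC thermograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSCSpec:
    """Gaussian melting endotherm on a linear baseline.

    The peak area over temperature equals
    ``(1 - nonfreezing_fraction) * water_mass_fraction * latent_heat * rate``
    so the analyzed enthalpy recovers the frozen-water latent heat exactly.
    The peak center sits two widths above the freezing point, which puts the
    leading-edge tangent onset at the freezing point itself.
    """

    freezing_point: float = 0.0       # C
    water_mass_fraction: float = 0.8
    nonfreezing_fraction: float = 0.1
    latent_heat: float = 334.0        # J/g water
    peak_width: float = 1.5           # K (Gaussian sigma)
    baseline_slope: float = 0.0       # (W/g)/K
    baseline_intercept: float = 0.0   # W/g
    scan_rate: float = 5.0            # K/min
    noise_sd: float = 0.0             # W/g
    temperature_span: float = 20.0    # K on each side of the peak center
    samples: int = 2001
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.water_mass_fraction <= 1.0
                and 0.0 <= self.nonfreezing_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if not self.peak_width > 0:
            raise ValueError("peak width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class DSCTruth:
    melting_enthalpy: float           # J/g sample
    nonfreezing_fraction: float
    freezing_point: float             # C (intended tangent onset)
    peak_center: float                # C
    water_mass_fraction: float


def gen_dsc(spec: DSCSpec) -> Tuple[Thermogram, DSCTruth]:
    """Generate (Thermogram, truth) for one melting scan."""
    center = spec.freezing_point + 2.0 * spec.peak_width
    T = np.linspace(center - spec.temperature_span, center + spec.temperature_span,
                    spec.samples)
    enthalpy = (1.0 - spec.nonfreezing_fraction) * spec.water_mass_fraction * spec.latent_heat
    rate_K_s = spec.scan_rate / 60.0
    area_WgK = enthalpy * rate_K_s  # integral of the peak over temperature
    gauss = np.exp(-0.5 * ((T - center) / spec.peak_width) ** 2) / (
        spec.peak_width * np.sqrt(2.0 * np.pi))
    q = spec.baseline_intercept + spec.baseline_slope * T + area_WgK * gauss
    if spec.noise_sd > 0:
        q = q + _rng(spec.seed, "dsc").normal(0.0, spec.noise_sd, size=q.shape)
    tg = Thermogram(temperature=T, heat_flow=q, scan_rate=spec.scan_rate,
                    water_mass_fraction=spec.water_mass_fraction)
    truth = DSCTruth(melting_enthalpy=enthalpy,
                     nonfreezing_fraction=spec.nonfreezing_fraction,
                     freezing_point=spec.freezing_point,
                     peak_center=center,
                     water_mass_fraction=spec.water_mass_fraction)
    return tg, truth


# ---------------------------------------------------------------------------
# Osmometry / permeation series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermeationSpec:
    """First-order CPA uptake C(t) = C_inf (1 - exp(-t/tau)), inverted
    exactly through the permeation chain into osmolality readings."""

    c_equilibrium: float = 0.8           # mol/L intratissue solution
    tau: float = 20.0                    # min
    times: Tuple[float, ...] = (1, 2, 5, 10, 20, 30, 45, 60, 90, 120, 150, 180)
    pi_pbs: float = 0.30                 # osmol/kg
    v_pbs: float = 0.010                 # L
    w_dry: float = 0.20                  # g
    w_moist: float = 1.00                # g
    cpa: CPAProperties = field(default_factory=lambda: CPAProperties(
        molar_mass=117.15, density=1.25))  # betaine-like
    water_density: float = 1.0           # g/mL at 4 C
    solution_density: float = 1.0        # g/mL
    noise_sd: float = 0.0                # osmol/kg on pi_cpa
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if np.any(np.diff(np.asarray(self.times, dtype=float)) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class PermeationTruth:
    c_equilibrium: float
    tau: float
    concentrations: Tuple[float, ...]    # true C(t), mol/L


def _pi_from_concentration(c: float, spec: PermeationSpec) -> float:
    """Exact inversion of the permeation chain: osmolality for a target C."""
    a = spec.cpa.molar_mass / spec.cpa.density - spec.cpa.molar_mass / spec.solution_density
    b = (spec.w_moist - spec.w_dry) / spec.solution_density
    n = c * b / (1000.0 - c * a)
    return spec.pi_pbs + n / (spec.v_pbs * spec.water_density)


def gen_permeation(spec: PermeationSpec) -> Tuple[List[OsmometryRecord], PermeationTruth]:
    """Generate (records, truth) for one uptake kinetics series."""
    rng = _rng(spec.seed, "permeation")
    t = np.asarray(spec.times, dtype=float)
    c_true = spec.c_equilibrium * (1.0 - np.exp(-t / spec.tau))
    records = []
    for ti, ci in zip(t, c_true):
        pi = _pi_from_concentration(float(ci), spec)
        if spec.noise_sd > 0:
            pi = max(pi + float(rng.normal(0.0, spec.noise_sd)), spec.pi_pbs)
        records.append(OsmometryRecord(
            immersion_time=float(ti), pi_cpa=pi, pi_pbs=spec.pi_pbs,
            v_pbs=spec.v_pbs, w_dry=spec.w_dry, w_moist=spec.w_moist,
            cpa=spec.cpa, water_density=spec.water_density,
            solution_density=spec.solution_density))
    truth = PermeationTruth(c_equilibrium=spec.c_equilibrium, tau=spec.tau,
                            concentrations=tuple(float(c) for c in c_true))
    return records, truth
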