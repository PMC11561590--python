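"""Bench-data computations: CPA permeation kinetics, DSC thermogram
quantities, and thermocouple-trace nucleation analysis.

Unit conventions (normalized in one place, see :class:`OsmometryRecord`):
osmolality in osmol/kg, volumes in liters, masses in grams, densities in
g/mL, molar mass in g/mol.  Concentrations come out in mol per liter of
intratissue solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter


# ---------------------------------------------------------------------------
# CPA permeation kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPAProperties:
    """Molar mass (g/mol) and density (g/mL) of a cryoprotective agent."""

    molar_mass: float
    density: float

    def __post_init__(self) -> None:
        if not (self.molar_mass > 0 and self.density > 0):
            raise ValueError("molar mass and density must be positive")


@dataclass(frozen=True)
class OsmometryRecord:
    """One equilibrated osmometry measurement of CPA that left the skin.

    Attributes
    ----------
    immersion_time : float
        Loading duration in minutes (metadata, not used by the chain).
    pi_cpa, pi_pbs : float
        Equilibrated and blank osmolality, osmol/kg.
    v_pbs : float
        Equilibration bath volume, liters.
    w_dry, w_moist : float
        Skin dry and moist weight, grams.
    cpa : CPAProperties
    water_density : float
        g/mL at the working temperature (4 C).
    solution_density : float
        Density of the intratissue aqueous solution used in the
        concentration denominator, g/mL.
    """

    immersion_time: float
    pi_cpa: float
    pi_pbs: float
    v_pbs: float
    w_dry: float
    w_moist: float
    cpa: CPAProperties
    water_density: float = 1.0
    solution_density: float = 1.0

    def __post_init__(self) -> None:
        if not (self.pi_cpa >= self.pi_pbs >= 0.0):
            raise ValueError("require pi_cpa >= pi_pbs >= 0")
        if not (self.w_moist >= self.w_dry > 0.0):
            raise ValueError("require w_moist >= w_dry > 0")
        if not (self.v_pbs > 0 and self.water_density > 0 and self.solution_density > 0):
            raise ValueError("volumes and densities must be positive")


@dataclass(frozen=True)
class PermeationResult:
    """Outputs of the permeation chain."""

    n_cpa: float        # mol permeated
    wt_cpa: float       # g
    v_cpa: float        # mL
    c_cpa: float        # mol / L of intratissue solution


def permeated_amount(rec: OsmometryRecord) -> PermeationResult:
    """Apply the four-step permeation chain to one osmometry record.

    n = (pi_cpa - pi_pbs) * V_pbs * rho_w   [osmol/kg * L * kg/L = mol]
    Wt = n * MW                              [g]
    V = Wt / rho_cpa                         [mL]
    C = n / (V + (W2 - W1 - Wt)/rho)         [denominator mL -> reported mol/L]

    Raises ValueError if the inferred intratissue water mass
    ``W2 - W1 - Wt`` is negative (inconsistent measurement).
    """
    n = (rec.pi_cpa - rec.pi_pbs) * rec.v_pbs * rec.water_density
    wt = n * rec.cpa.molar_mass
    v = wt / rec.cpa.density
    residual_water = rec.w_moist - rec.w_dry - wt
    if residual_water < -1e-12:
        raise ValueError(
            f"negative intratissue water mass ({residual_water:.4g} g): "
            "measurement inconsistency")
    volume_ml = v + residual_water / rec.solution_density
    c = 0.0 if n == 0.0 else n / (volume_ml / 1000.0)
    return PermeationResult(n_cpa=n, wt_cpa=wt, v_cpa=v, c_cpa=c)


def equilibration_time(times: Sequence[float], concentrations: Sequence[float],
                       fraction: float = 0.95,
                       tail_points: int = 3,
                       tail_tolerance: float = 0.05) -> float:
    """First time the uptake curve reaches `fraction` of its plateau (min).

    The plateau is the mean of the final `tail_points` samples; crossing is
    linearly interpolated.  A non-monotone tail beyond ``tail_tolerance``
    (relative) triggers a warning but the plateau is still estimated.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0 or t.size != c.size:
        raise ValueError("times and concentrations must be equal-length, nonempty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    tail = c[-tail_points:]
    plateau = float(tail.mean())
    if plateau > 0 and (tail.max() - tail.min()) > tail_tolerance * abs(plateau):
        warnings.warn("uptake tail is non-monotone beyond tolerance; "
                      "plateau estimate may be poor", stacklevel=2)
    target = fraction * plateau
    if c[0] >= target:
        return float(t[0])
    above = c >= target
    if not above.any():
        return float(t[-1])
    i = int(np.argmax(above))
    frac = (target - c[i - 1]) / (c[i] - c[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


# ---------------------------------------------------------------------------
# DSC thermogram analysis
# ---------------------------------------------------------------------------

#: Latent heat of fusion of pure water, J/g.
WATER_LATENT_HEAT = 334.0


@dataclass(frozen=True)
class Thermogram:
    """A melting scan: temperature (C, strictly increasing), heat flow (W/g,
    endotherm positive), scan rate (K/min), and the sample's total water
    mass fraction."""

    temperature: np.ndarray
    heat_flow: np.ndarray
    scan_rate: float
    water_mass_fraction: float

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        q = np.asarray(self.heat_flow, dtype=float)
        if T.size != q.size or T.size < 8:
            raise ValueError("temperature and heat_flow must be equal-length (>= 8)")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature must be strictly monotone within a scan")
        if not self.scan_rate > 0:
            raise ValueError("scan rate must be positive")
        if not (0.0 <= self.water_mass_fraction <= 1.0):
            raise ValueError("water mass fraction must lie in [0, 1]")
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "heat_flow", q)


@dataclass(frozen=True)
class DSCResult:
    onset_freezing_point: float       # C
    melting_enthalpy: float           # J/g of sample
    nonfreezing_water_fraction: float  # of total water
    peak_temperature: float           # C


def dsc_quantities(tg: Thermogram, baseline_window: float = 5.0,
                   latent_heat: float = WATER_LATENT_HEAT) -> DSCResult:
    """Onset, enthalpy and nonfreezing water content of a melting endotherm.

    A linear baseline is fitted over the flanking `baseline_window` kelvin at
    each end of the scan; the onset is the intersection of that baseline with
    the steepest leading-edge tangent; the enthalpy is the baseline-subtracted
    peak integral over temperature divided by the scan rate; the nonfreezing
    fraction is ``(m_water - dH/L_f) / m_water`` clipped to [0, 1].
    """
    T, q = tg.temperature, tg.heat_flow
    lo = T <= T[0] + baseline_window
    hi = T >= T[-1] - baseline_window
    flank = lo | hi
    if flank.sum() < 4:
        raise ValueError("baseline windows contain too few samples")
    slope, intercept = np.polyfit(T[flank], q[flank], 1)
    resid = q - (slope * T + intercept)

    noise = float(np.std(resid[flank]))
    peak_idx = int(np.argmax(resid))
    if resid[peak_idx] <= max(5.0 * noise, 1e-12):
        raise ValueError("no detectable endothermic peak")

    dh_per_K = np.trapezoid(np.clip(resid, 0.0, None), T)  # (W/g) * K
    rate_K_per_s = tg.scan_rate / 60.0
    enthalpy = dh_per_K / rate_K_per_s
    if enthalpy < 0:
        raise ValueError("negative melting enthalpy")

    # steepest point on the leading edge, tangent down to the baseline
    lead = slice(0, peak_idx + 1)
    dq = np.gradient(resid[lead], T[lead])
    k = int(np.argmax(dq))
    if dq[k] <= 0:
        raise ValueError("no rising leading edge found")
    onset = T[lead][k] - resid[lead][k] / dq[k]

    m_water = tg.water_mass_fraction
    if m_water > 0:
        frozen = enthalpy / latent_heat  # g water per g sample
        nonfreezing = float(np.clip((m_water - frozen) / m_water, 0.0, 1.0))
    else:
        nonfreezing = 0.0
    return DSCResult(onset_freezing_point=float(onset),
                     melting_enthalpy=float(enthalpy),
                     nonfreezing_water_fraction=nonfreezing,
                     peak_temperature=float(T[peak_idx]))


# ---------------------------------------------------------------------------
# Thermocouple-trace nucleation detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleationEvent:
    """Detected supercooling/recalescence event on a cooling trace."""

    nucleation_time: float        # s
    nucleation_temperature: float  # C
    supercooling_depth: float     # K, relative to the equilibrium freezing point
    recalescence_amplitude: float  # K
    plateau_start: float          # s
    plateau_end: float            # s

    def __post_init__(self) -> None:
        if self.supercooling_depth < 0:
            raise ValueError("supercooling depth must be >= 0")
        if self.plateau_start < self.nucleation_time:
            raise ValueError("plateau cannot start before nucleation")


def detect_nucleation(times: Sequence[float], temperatures: Sequence[float],
                      equilibrium_freezing_point: float,
                      smoothing_window: int = 11,
                      noise_factor: float = 5.0) -> Optional[NucleationEvent]:
    """Find the nucleation event on a uniformly sampled cooling trace.

    Nucleation is the first local minimum of the (lightly smoothed) trace
    followed by a rise exceeding ``noise_factor`` times the MAD-based noise
    level of the derivative; the recalescence amplitude is the rise to the
    following local maximum; the plateau is the longest interval after that
    maximum where |dT/dt| stays below 10 % of the imposed cooling rate
    (estimated from the pre-nucleation ramp).  Returns None when no event is
    found (a valid outcome for ice-free traces).
    """
    t = np.asarray(times, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if t.size != T.size or t.size < 8:
        raise ValueError("need equal-length series with >= 8 samples")
    dt_s = np.diff(t)
    if np.any(dt_s <= 0) or (dt_s.max() - dt_s.min()) > 1e-6 * dt_s.mean():
        raise ValueError("sampling must be uniform and increasing")
    dt0 = float(dt_s.mean())

    win = max(5, int(smoothing_window) | 1)  # odd, >= 5
    win = min(win, (T.size - 1) | 1)
    Ts = savgol_filter(T, window_length=win, polyorder=2) if T.size > win else T.copy()
    dTdt = savgol_filter(T, window_length=win, polyorder=2, deriv=1, delta=dt0) \
        if T.size > win else np.gradient(T, t)

    resid = T - Ts
    mad = float(np.median(np.abs(resid - np.median(resid))))
    noise = 1.4826 * mad
    thresh = max(noise_factor * noise, 1e-9)

    # candidate local minima: smoothed derivative crosses - -> +
    sign = np.sign(dTdt)
    crossings = np.flatnonzero((sign[:-1] < 0) & (sign[1:] >= 0))
    event_idx = None
    for i in crossings:
        j_end = min(T.size, i + max(3, int(round(60.0 / dt0))))
        rise = float(np.max(Ts[i:j_end]) - Ts[i])
        if rise > thresh:
            event_idx = int(i + 1)
            break
    if event_idx is None:
        return None

    # refine: the recalescence jump is far sharper than the minimum itself,
    # so take the sample at the foot of the first above-noise upward jump in
    # the window; fall back to the raw minimum for slow rises
    lo = max(0, event_idx - win)
    hi = min(T.size, event_idx + win + 1)
    jumps = np.diff(T[lo:hi])
    cand = np.flatnonzero(jumps > max(7.0 * noise, 1e-12))
    if cand.size:
        event_idx = int(lo + cand[0])
    else:
        event_idx = int(lo + np.argmin(T[lo:hi]))

    t_nuc = float(t[event_idx])
    T_nuc = float(T[event_idx])

    # imposed cooling rate from the pre-nucleation ramp
    pre = slice(0, max(2, int(0.8 * event_idx)))
    ramp_rate = float(np.polyfit(t[pre], T[pre], 1)[0]) if event_idx >= 4 else float(
        np.median(dTdt[:max(2, event_idx)]))
    rate_floor = 0.10 * max(abs(ramp_rate), 1e-12)

    # recalescence: highest raw sample between the event and the resumption
    # of clear cooling (the plateau is included since the rise is asymptotic)
    start = min(event_idx + win, T.size)  # skip the smoothing kink at the event
    after = np.flatnonzero(dTdt[start:] < -rate_floor)
    rise_end = int(start + after[0]) if after.size else T.size
    recal_peak = int(event_idx + np.argmax(T[event_idx:rise_end]))
    recal_amp = float(T[recal_peak] - T[event_idx])

    # the rise has settled once the smoothed slope falls below the floor
    settled = np.flatnonzero(dTdt[start:] < rate_floor)
    settle = int(start + settled[0]) if settled.size else T.size
    flat = np.abs(dTdt) < rate_floor
    flat[:settle] = False
    # longest run of flat samples
    best_len, best_start = 0, None
    run_start = None
    for i in range(settle, T.size + 1):
        on = i < T.size and flat[i]
        if on and run_start is None:
            run_start = i
        if not on and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_start is None:
        plateau_start = plateau_end = float(t[min(recal_peak, T.size - 1)])
    else:
        plateau_start = float(t[best_start])
        plateau_end = float(t[best_start + best_len - 1])

    return NucleationEvent(
        nucleation_time=t_nuc,
        nucleation_temperature=T_nuc,
        supercooling_depth=max(equilibrium_freezing_point - T_nuc, 0.0),
        recalescence_amplitude=recal_amp,
        plateau_start=max(plateau_start, t_nuc),
        plateau_end=plateau_end,
    )
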