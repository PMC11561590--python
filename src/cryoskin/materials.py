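"""Phase-change material models: indicator functions and mixture rules.

A :class:`PhaseChangeMaterial` bundles the thermophysical and mechanical
constants of the two phases of a freezable medium.  Phase 1 is the
low-temperature (frozen) phase and phase 2 the high-temperature (liquid /
thawed) phase, i.e. the "transition" is crossed in the melting direction as
temperature increases.  The smoothed phase indicator ``theta2(T)`` rises from
0 to 1 over a compact window ``[T_m - dT_tr, T_m + dT_tr]``; the latent heat
of the transition is folded into an apparent heat capacity through the
analytic derivative of the bounded mass-fraction function ``alpha_m``.

All temperatures are kelvin internally.  Use :func:`celsius_to_kelvin` /
:func:`kelvin_to_celsius` at interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

KELVIN_OFFSET = 273.15


def celsius_to_kelvin(t_c: ArrayLike) -> ArrayLike:
    return np.asarray(t_c, dtype=float) + KELVIN_OFFSET if np.ndim(t_c) else float(t_c) + KELVIN_OFFSET


def kelvin_to_celsius(t_k: ArrayLike) -> ArrayLike:
    return np.asarray(t_k, dtype=float) - KELVIN_OFFSET if np.ndim(t_k) else float(t_k) - KELVIN_OFFSET


@dataclass(frozen=True)
class PhaseProperties:
    """Constant properties of one phase.

    Parameters
    ----------
    density : float
        kg/m^3.
    heat_capacity : float
        J/(kg K).
    conductivity : float
        W/(m K).
    young_modulus : float
        Pa.
    poisson : float
        Dimensionless, in [0, 0.5).
    expansion : float
        Linear thermal expansion coefficient, 1/K.
    maxwell_viscosity : float
        Pa s; ``math.inf`` marks a purely elastic phase.
    """

    density: float
    heat_capacity: float
    conductivity: float
    young_modulus: float = 1e6
    poisson: float = 0.3
    expansion: float = 0.0
    maxwell_viscosity: float = math.inf

    def __post_init__(self) -> None:
        for name in ("density", "heat_capacity", "conductivity", "young_modulus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not (0.0 <= self.poisson < 0.5):
            raise ValueError(f"poisson must be in [0, 0.5), got {self.poisson!r}")
        if not math.isfinite(self.expansion):
            raise ValueError("expansion must be finite")
        if not self.maxwell_viscosity > 0:
            raise ValueError("maxwell_viscosity must be positive (may be inf)")

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson))

    @property
    def bulk_modulus(self) -> float:
        return self.young_modulus / (3.0 * (1.0 - 2.0 * self.poisson))


@dataclass(frozen=True)
class PhaseChangeMaterial:
    """Two-phase material with a smoothed melting transition.

    ``phase1`` is the pre-transition (frozen, low-T) phase, ``phase2`` the
    post-transition (liquid, high-T) phase.  ``latent_heat`` is the heat
    absorbed per kg converting phase 1 into phase 2.
    """

    name: str
    phase1: PhaseProperties
    phase2: PhaseProperties
    melt_temperature: float
    transition_half_width: float = 0.5
    latent_heat: float = 0.0

    def __post_init__(self) -> None:
        if not self.transition_half_width > 0:
            raise ValueError("transition_half_width must be > 0")
        if self.latent_heat < 0:
            raise ValueError("latent_heat must be >= 0")

    def with_melt_temperature(self, t_m: float) -> "PhaseChangeMaterial":
        return replace(self, melt_temperature=t_m)


@dataclass(frozen=True)
class MixtureState:
    """Effective properties at given phase fractions (latent term excluded)."""

    theta1: ArrayLike
    theta2: ArrayLike
    density: ArrayLike
    heat_capacity: ArrayLike
    conductivity: ArrayLike
    mass_fraction_function: ArrayLike  # alpha_m in [-1/2, +1/2]


def phase_fraction(T: ArrayLike, mat: PhaseChangeMaterial) -> ArrayLike:
    """Smoothed post-transition (liquid) fraction theta2 as a function of T.

    C^1 cubic smoothstep over ``[T_m - dT_tr, T_m + dT_tr]``: 0 below the
    window, 1 above it, 0.5 at ``T_m``, monotone nondecreasing in T.
    """
    T = np.asarray(T, dtype=float)
    s = (T - (mat.melt_temperature - mat.transition_half_width)) / (2.0 * mat.transition_half_width)
    s = np.clip(s, 0.0, 1.0)
    out = s * s * (3.0 - 2.0 * s)
    return float(out) if out.ndim == 0 else out


def phase_fraction_derivative(T: ArrayLike, mat: PhaseChangeMaterial) -> ArrayLike:
    """Analytic d(theta2)/dT of the smoothstep indicator (compact support)."""
    T = np.asarray(T, dtype=float)
    w = 2.0 * mat.transition_half_width
    s = (T - (mat.melt_temperature - mat.transition_half_width)) / w
    inside = (s > 0.0) & (s < 1.0)
    sc = np.clip(s, 0.0, 1.0)
    out = np.where(inside, 6.0 * sc * (1.0 - sc) / w, 0.0)
    return float(out) if out.ndim == 0 else out


def _check_thetas(theta1: ArrayLike, theta2: ArrayLike) -> None:
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    if np.any(t1 < -1e-12) or np.any(t1 > 1 + 1e-12) or np.any(t2 < -1e-12) or np.any(t2 > 1 + 1e-12):
        raise ValueError("phase fractions must lie in [0, 1]")
    if np.any(np.abs(t1 + t2 - 1.0) > 1e-9):
        raise ValueError("theta1 + theta2 must equal 1")


def mixture_properties(theta1: ArrayLike, theta2: ArrayLike, mat: PhaseChangeMaterial) -> MixtureState:
    """Theta-weighted mixture rules for density, conductivity and sensible C_P.

    ``rho = theta1 rho1 + theta2 rho2``, ``k = theta1 k1 + theta2 k2``,
    sensible ``C_P = (theta1 rho1 C1 + theta2 rho2 C2) / rho`` and the bounded
    mass-fraction function ``alpha_m = (theta2 rho2 - theta1 rho1) / (2 rho)``.
    """
    _check_thetas(theta1, theta2)
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    p1, p2 = mat.phase1, mat.phase2
    rho = t1 * p1.density + t2 * p2.density
    k = t1 * p1.conductivity + t2 * p2.conductivity
    cp = (t1 * p1.density * p1.heat_capacity + t2 * p2.density * p2.heat_capacity) / rho
    alpha_m = 0.5 * (t2 * p2.density - t1 * p1.density) / rho
    return MixtureState(theta1=t1, theta2=t2, density=rho, heat_capacity=cp,
                        conductivity=k, mass_fraction_function=alpha_m)


def apparent_heat_capacity(T: ArrayLike, mat: PhaseChangeMaterial) -> ArrayLike:
    """Effective C_P(T) including the latent-heat spike, J/(kg K).

    ``C_P = (theta1 rho1 C1 + theta2 rho2 C2 + L d(rho alpha_m)/dT) / rho``
    with the latent term evaluated from the analytic smoothstep derivative:
    ``rho d(alpha_m)/dT = (rho1 rho2 / rho) d(theta2)/dT``.
    """
    T = np.asarray(T, dtype=float)
    t2 = np.asarray(phase_fraction(T, mat))
    t1 = 1.0 - t2
    p1, p2 = mat.phase1, mat.phase2
    rho = t1 * p1.density + t2 * p2.density
    sensible = t1 * p1.density * p1.heat_capacity + t2 * p2.density * p2.heat_capacity
    latent = mat.latent_heat * (p1.density * p2.density / rho) * np.asarray(
        phase_fraction_derivative(T, mat))
    out = (sensible + latent) / rho
    return float(out) if out.ndim == 0 else out


def volumetric_enthalpy(T: ArrayLike, mat: PhaseChangeMaterial) -> ArrayLike:
    """Exact volumetric enthalpy H(T) = int rho(T') C_P_eff(T') dT', J/m^3.

    Reference H = 0 at the lower transition edge ``T_m - dT_tr``.  Closed
    form: outside the window the integrand is the constant pure-phase
    ``rho_i C_i``; across the window the sensible part integrates the
    smoothstep and the latent part is
    ``L rho1 rho2 ln(rho/rho1) / (rho2 - rho1)`` (``L rho theta2`` when the
    densities are equal).  This is the conserved quantity of the apparent
    heat capacity formulation and is used by the thermal solver's
    enthalpy-consistent Picard iteration and energy ledger.
    """
    T = np.asarray(T, dtype=float)
    p1, p2 = mat.phase1, mat.phase2
    tlo = mat.melt_temperature - mat.transition_half_width
    thi = mat.melt_temperature + mat.transition_half_width
    w = 2.0 * mat.transition_half_width

    s = np.clip((T - tlo) / w, 0.0, 1.0)
    theta2 = s * s * (3.0 - 2.0 * s)
    # int theta2 dT from tlo: w * (s^3 - s^4/2)
    int_theta2 = w * (s ** 3 - 0.5 * s ** 4)
    rc1 = p1.density * p1.heat_capacity
    rc2 = p2.density * p2.heat_capacity
    t_in = np.clip(T, tlo, thi) - tlo
    sensible = rc1 * t_in + (rc2 - rc1) * int_theta2

    if abs(p2.density - p1.density) > 1e-12 * p1.density:
        rho = p1.density + theta2 * (p2.density - p1.density)
        latent = mat.latent_heat * p1.density * p2.density * (
            np.log(rho / p1.density) / (p2.density - p1.density))
    else:
        latent = mat.latent_heat * p1.density * theta2

    below = rc1 * np.minimum(T - tlo, 0.0)
    above = rc2 * np.maximum(T - thi, 0.0)
    out = sensible + latent + below + above
    return float(out) if out.ndim == 0 else out


def latent_volumetric_heat(mat: PhaseChangeMaterial) -> float:
    """Total latent heat per unit volume absorbed across the window, J/m^3."""
    p1, p2 = mat.phase1, mat.phase2
    if abs(p2.density - p1.density) > 1e-12 * p1.density:
        return mat.latent_heat * p1.density * p2.density * math.log(
            p2.density / p1.density) / (p2.density - p1.density)
    return mat.latent_heat * p1.density


def phase_change_eigenstrain(theta2: ArrayLike, mat: PhaseChangeMaterial) -> ArrayLike:
    """Linear eigenstrain of converting a theta2 fraction of phase 1 into phase 2.

    ``theta2 * ((rho1/rho2)^(1/3) - 1)``; zero when the densities match.
    The reference (zero-strain) state is pure phase 1, so for an ice->water
    material this is negative (melting contracts relative to the frozen
    state).  The mechanical solver consumes increments of this quantity, so
    the choice of reference drops out.
    """
    t2 = np.asarray(theta2, dtype=float)
    if np.any(t2 < -1e-12) or np.any(t2 > 1 + 1e-12):
        raise ValueError("theta2 must lie in [0, 1]")
    coef = (mat.phase1.density / mat.phase2.density) ** (1.0 / 3.0) - 1.0
    out = t2 * coef
    return float(out) if out.ndim == 0 else out


def mechanical_properties(theta2: ArrayLike, mat: PhaseChangeMaterial):
    """Blend (E, nu, alpha, mu) between the phases at liquid fraction theta2.

    E, nu and alpha interpolate linearly in theta2.  The Maxwell viscosity
    blends harmonically (linear fluidity 1/mu), which degrades gracefully
    when one phase is purely elastic (mu = inf) and lets a small liquid
    fraction relax deviatoric stress quickly.
    """
    t2 = np.asarray(theta2, dtype=float)
    p1, p2 = mat.phase1, mat.phase2
    E = p1.young_modulus + t2 * (p2.young_modulus - p1.young_modulus)
    nu = p1.poisson + t2 * (p2.poisson - p1.poisson)
    alpha = p1.expansion + t2 * (p2.expansion - p1.expansion)
    inv1 = 0.0 if math.isinf(p1.maxwell_viscosity) else 1.0 / p1.maxwell_viscosity
    inv2 = 0.0 if math.isinf(p2.maxwell_viscosity) else 1.0 / p2.maxwell_viscosity
    inv = (1.0 - t2) * inv1 + t2 * inv2
    with np.errstate(divide="ignore"):
        mu = np.where(inv > 0.0, 1.0 / np.maximum(inv, 1e-300), math.inf)
    if np.ndim(theta2) == 0:
        return float(E), float(nu), float(alpha), float(mu)
    return E, nu, alpha, mu


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Literature defaults for an aqueous (PBS-like) solution: phase 1 = ice,
#: phase 2 = liquid water.  The liquid phase is given a soft elastic surrogate
#: (small E, small mu) so fluid cells carry negligible deviatoric stress while
#: staying inside the linear-elastic constitutive family.
#: Ice near its melting point creeps readily; the Maxwell viscosity below
#: gives a deviatoric relaxation time 2*mu*(1+nu)/E of roughly a minute, so
#: slow (cooling-rate) loading relaxes while fast rewarming transients do not.
_ICE = PhaseProperties(density=917.0, heat_capacity=2050.0, conductivity=2.25,
                       young_modulus=9.0e9, poisson=0.33, expansion=51e-6,
                       maxwell_viscosity=1e12)
#: The liquid conductivity is an effective value including natural
#: convection in the bath-warmed solution (the conduction-only solver needs
#: the enhancement; Nu ~ 3 on these gap sizes).
_WATER = PhaseProperties(density=1000.0, heat_capacity=4186.0, conductivity=1.4,
                         young_modulus=2.0e6, poisson=0.49, expansion=70e-6,
                         maxwell_viscosity=1e4)
_SKIN_FROZEN = PhaseProperties(density=1050.0, heat_capacity=2100.0, conductivity=1.2,
                               young_modulus=4.0e9, poisson=0.30, expansion=1.7e-4,
                               maxwell_viscosity=1e12)
_SKIN_FRESH = PhaseProperties(density=1100.0, heat_capacity=3500.0, conductivity=0.37,
                              young_modulus=1.0e6, poisson=0.45, expansion=2.5e-4,
                              maxwell_viscosity=1e7)

#: Melting points reflect the 15 wt% CPA formulations the tissue is immersed
#: in (freezing-point depression ~2 K); intratissue solution slightly lower.
_BASE_SOLUTION = PhaseChangeMaterial(
    name="solution", phase1=_ICE, phase2=_WATER,
    melt_temperature=KELVIN_OFFSET - 2.0, transition_half_width=0.5,
    latent_heat=3.34e5)
_BASE_SKIN = PhaseChangeMaterial(
    name="skin", phase1=_SKIN_FROZEN, phase2=_SKIN_FRESH,
    melt_temperature=KELVIN_OFFSET - 2.5, transition_half_width=0.5,
    latent_heat=0.70 * 3.34e5)  # ~70 % water content

#: CPA-formulation modifiers: (solution melt-point depression K,
#: skin melt-point depression K, skin expansion scale).  These stand in for
#: the measured formulation effects (e.g. the betaine/trehalose mix lowers
#: the freezing point and cuts the skin expansion coefficient by ~40 %);
#: they alter parameters only -- no solute transport is simulated.
_CPA_MODIFIERS = {
    "none": (0.0, 0.0, 1.0),
    "betaine": (1.03, 0.6, 0.75),
    "tre": (0.45, 0.3, 0.9),
    "bt-1": (0.8, 0.5, 0.65),
    "bt-2": (0.9, 0.55, 0.60),
    "bt-3": (0.95, 0.55, 0.65),
    "gly": (1.9, 1.0, 0.95),
    "dmso": (2.3, 1.2, 0.95),
}


def preset(name: str = "none") -> dict:
    """Return {'solution': ..., 'skin': ...} materials for a named CPA preset."""
    key = name.lower()
    if key not in _CPA_MODIFIERS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_CPA_MODIFIERS)}")
    d_sol, d_skin, a_scale = _CPA_MODIFIERS[key]
    sol = replace(_BASE_SOLUTION, melt_temperature=_BASE_SOLUTION.melt_temperature - d_sol)
    skin_frozen = replace(_BASE_SKIN.phase1, expansion=_BASE_SKIN.phase1.expansion * a_scale)
    skin_fresh = replace(_BASE_SKIN.phase2, expansion=_BASE_SKIN.phase2.expansion * a_scale)
    skin = replace(_BASE_SKIN, phase1=skin_frozen, phase2=skin_fresh,
                   melt_temperature=_BASE_SKIN.melt_temperature - d_skin)
    return {"solution": sol, "skin": skin}


def _phase_from_dict(d: dict) -> PhaseProperties:
    return PhaseProperties(
        density=float(d["density"]),
        heat_capacity=float(d["heat_capacity"]),
        conductivity=float(d["conductivity"]),
        young_modulus=float(d.get("young_modulus", 1e6)),
        poisson=float(d.get("poisson", 0.3)),
        expansion=float(d.get("expansion", 0.0)),
        maxwell_viscosity=float(d.get("maxwell_viscosity", math.inf)),
    )


def material_from_dict(name: str, d: dict) -> PhaseChangeMaterial:
    """Build a material from a config mapping (temperatures in kelvin unless
    a key ends in ``_C``)."""
    t_m = d.get("melt_temperature")
    if t_m is None:
        t_m = celsius_to_kelvin(float(d["melt_temperature_C"]))
    return PhaseChangeMaterial(
        name=name,
        phase1=_phase_from_dict(d["phase1"]),
        phase2=_phase_from_dict(d["phase2"]),
        melt_temperature=float(t_m),
        transition_half_width=float(d.get("transition_half_width", 0.5)),
        latent_heat=float(d.get("latent_heat", 0.0)),
    )


def materials_from_config(cfg: dict) -> dict:
    """Materials from a config: a named ``preset`` plus per-material overrides."""
    mats = preset(cfg.get("preset", "none"))
    for name, sub in cfg.get("materials", {}).items():
        mats[name] = material_from_dict(name, sub)
    return mats
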