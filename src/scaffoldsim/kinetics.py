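"""Pointwise biological rate laws for perfused chondrocyte culture.

Everything in this module is local (per voxel, per instant): Michaelis-Menten
glucose uptake, stoichiometric lactate release, the affine lactate->pH map,
the pH viability gate, and the piecewise shear-stress modulation of the
proliferation rate.  All quantities are SI unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = [
    "KineticParams",
    "PLATEAU_FACTOR",
    "glucose_uptake_rate",
    "lactate_rate",
    "ph_from_lactate",
    "viability_step",
    "shear_growth_factor",
    "growth_rate",
]

ArrayLike = Union[float, np.ndarray]

#: Growth-rate multiplier on the stimulatory shear plateau (dimensionless).
#: Equals the linear low-shear branch evaluated at its upper boundary,
#: alpha + beta * 0.1 Pa = 0.8761 + 104.5 * 0.1 = 11.3261 ~ 11.326.
PLATEAU_FACTOR = 11.326


@dataclass
class KineticParams:
    """Kinetic and material parameters of the culture model (SI units).

    Defaults are the literature values used throughout: glucose uptake
    saturates at ``Vm`` with half-saturation ``Km``; growth under static
    (zero-shear) conditions proceeds at most at ``Kg0 * alpha_c``; the
    shear law is parameterised by ``alpha_c`` (intercept) and ``beta_c``
    (slope, 1/Pa).  ``Keq`` is the linear partition coefficient between
    fluid-phase and cell-phase glucose at the biomass interface.

    ``Kc`` closes the growth half-saturation term ``Kc * rho_cell * eps_c``
    (a concentration, kg/m^3).  No literature value exists for it; the
    default places half-saturation at half the default inlet glucose
    concentration (2.25 kg/m^3) for a fully packed cell phase (eps_c = 1).

    ``rd`` (death rate) and ``Dc`` (cell migration diffusivity) default to
    zero: cell loss occurs only through the pH viability gate, and migration
    is quantitatively negligible at monolayer scale.
    """

    Vm: float = 3.9e-5          # max glucose uptake rate [kg/m^3/s]
    Km: float = 6.3e-3          # glucose half-saturation [kg/m^3]
    Kg0: float = 5.8e-6         # max static growth rate [1/s]
    alpha_c: float = 0.8761     # shear-law intercept [-]
    beta_c: float = 104.5       # shear-law slope [1/Pa] (0.1045e3)
    Keq: float = 0.1            # interfacial equilibrium coefficient [-]
    Dgf: float = 1.0e-9         # glucose diffusivity, fluid phase [m^2/s]
    Dgc: float = 1.0e-10        # glucose diffusivity, cell phase [m^2/s]
    Dlf: float = 1.4e-9         # lactate diffusivity, fluid phase [m^2/s]
    rho_cell: float = 182.0     # cellular mass density [kg/m^3] (0.182 g/cm^3)
    dc: float = 13.0e-6         # chondrocyte monolayer thickness [m]
    Kc: float = 2.25 / 182.0    # growth saturation coefficient [-]; see docstring
    rd: float = 0.0             # death rate [1/s]
    Dc: float = 0.0             # cell migration diffusivity [m^2/s]
    ph_threshold: float = 6.8   # viability cutoff [pH]

    def __post_init__(self) -> None:
        for name in ("Vm", "Km", "Kg0", "alpha_c", "beta_c", "Keq", "Dgf",
                     "Dgc", "Dlf", "rho_cell", "dc", "Kc", "rd", "Dc"):
            if getattr(self, name) < 0:
                raise ValueError(f"KineticParams.{name} must be nonnegative")

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)


def glucose_uptake_rate(c_gc: ArrayLike, eps_b: ArrayLike,
                        p: KineticParams) -> ArrayLike:
    """Volumetric glucose consumption rate Rg [kg/m^3/s].

    Michaelis-Menten in the cell-phase glucose concentration, weighted by
    the local cell volume fraction:

        Rg = Vm * eps_b * c_gc / (Km + eps_b * c_gc)

    Saturates at ``Vm``; zero when either the substrate or the cells are
    absent.
    """
    c = np.asarray(c_gc, dtype=float)
    eb = np.asarray(eps_b, dtype=float)
    if np.any(c < 0):
        raise ValueError("glucose concentration must be nonnegative")
    if np.any((eb < 0) | (eb > 1)):
        raise ValueError("cell volume fraction must lie in [0, 1]")
    x = eb * c
    out = p.Vm * x / (p.Km + x)
    if np.isscalar(c_gc) and np.isscalar(eps_b):
        return float(out)
    return out


def lactate_rate(Rg: ArrayLike) -> ArrayLike:
    """Lactate production rate Rl = 2 * Rg [kg/m^3/s].

    Anaerobic glycolysis yields two lactate per glucose; the mass-based
    factor of two is the modelling convention adopted for chondrocytes.
    """
    Rg_a = np.asarray(Rg, dtype=float)
    if np.any(Rg_a < 0):
        raise ValueError("glucose uptake rate must be nonnegative")
    out = 2.0 * Rg_a
    return float(out) if np.isscalar(Rg) else out


def ph_from_lactate(c_l: ArrayLike) -> ArrayLike:
    """Culture pH as an affine function of lactate concentration [kg/m^3].

        pH = 7.4 - 0.0406 * c_l

    The intercept is the physiological set point of fresh medium.
    """
    c = np.asarray(c_l, dtype=float)
    if np.any(c < 0):
        raise ValueError("lactate concentration must be nonnegative")
    out = 7.4 - 0.0406 * c
    return float(out) if np.isscalar(c_l) else out


def viability_step(ph: ArrayLike, threshold: float = 6.8) -> ArrayLike:
    """Step viability indicator S{pH}: 1 where pH >= threshold, else 0.

    Chondrocytes tolerate mildly acidic media down to pH 6.8; below that
    the local cell population is considered lost.  The boundary is
    inclusive (alive at exactly the threshold).
    """
    ph_a = np.asarray(ph, dtype=float)
    out = (ph_a >= threshold).astype(float)
    return float(out) if np.isscalar(ph) else out


def shear_growth_factor(tau: ArrayLike, p: KineticParams) -> ArrayLike:
    """Shear-modulated maximum growth rate Kg(tau) [1/s].

    Piecewise response of chondrocyte proliferation to fluid shear stress
    tau [Pa]:

        Kg = Kg0 * (alpha + beta*tau)          tau in [0, 0.1)   stimulation
        Kg = Kg0 * 11.326                      tau in [0.1, 0.6) plateau
        Kg = Kg0 * 2.5*(1 - tau)*11.326        tau in [0.6, 1)   inhibition
        Kg = 0                                 tau >= 1          lethal

    The branch constants make the factor continuous (to the printed
    precision) at 0.1 and exactly at 0.6 and 1 Pa.
    """
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("shear stress must be nonnegative")
    out = np.zeros_like(t)
    low = t < 0.1
    mid = (t >= 0.1) & (t < 0.6)
    high = (t >= 0.6) & (t < 1.0)
    out[low] = p.Kg0 * (p.alpha_c + p.beta_c * t[low])
    out[mid] = p.Kg0 * PLATEAU_FACTOR
    out[high] = p.Kg0 * 2.5 * (1.0 - t[high]) * PLATEAU_FACTOR
    return float(out) if np.isscalar(tau) else out


def growth_rate(c_gc: ArrayLike, eps_c: ArrayLike, tau: ArrayLike,
                p: KineticParams) -> ArrayLike:
    """Specific proliferation rate rg [1/s].

    Substrate-limited, crowding-saturated growth at the shear-dependent
    ceiling Kg(tau):

        rg = Kg(tau) * c_gc / (Kc * rho_cell * eps_c + c_gc)

    The denominator term ``Kc * rho_cell * eps_c`` is a concentration
    (kg/m^3): denser cell packing raises the glucose level needed to
    sustain a given fraction of the maximal rate.  Returns 0 where both
    substrate and cells vanish.
    """
    c = np.asarray(c_gc, dtype=float)
    ec = np.asarray(eps_c, dtype=float)
    if np.any(c < 0):
        raise ValueError("glucose concentration must be nonnegative")
    if np.any((ec < 0) | (ec > 1)):
        raise ValueError("cell volume fraction must lie in [0, 1]")
    Kg = shear_growth_factor(tau, p)
    denom = p.Kc * p.rho_cell * ec + c
    out = np.where(denom > 0, np.asarray(Kg) * np.divide(
        c, denom, out=np.zeros_like(c + denom), where=denom > 0), 0.0)
    if np.isscalar(c_gc) and np.isscalar(eps_c) and np.isscalar(tau):
        return float(out)
    return out
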