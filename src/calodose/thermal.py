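"""Thermal constants of the polystyrene core and scalar dose conversions.

The calorimeter converts a radiation-induced temperature rise into absorbed
dose through the specific heat capacity of the polystyrene (PS) core,

    Cp(T) = (1000 / M) * (a * T**-2 + b * T + c)    [J/(kg K)],

an empirical fit valid near room temperature, with M the molar mass of the
styrene repeat unit in g/mol and T the absolute temperature in K.  Because
dose [Gy] = Cp * dT [K], the same numerical relation holds between mGy and
mK, which are the working units everywhere else in this package.

This module also provides the excess-heat diagnostic (the ratio of an
observed temperature-per-dose slope to the slope expected from PS heating
alone) and the diffusive length scale sqrt(delta * tau) that links a fitted
thermal time constant to the physical size of the conducting component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HeatCapacityModel",
    "DEFAULT_HEAT_CAPACITY",
    "heat_capacity",
    "dose_from_delta_T",
    "delta_T_from_dose",
    "ideal_slope_mK_per_mGy",
    "excess_heat_factor",
    "effective_thermal_length",
]


@dataclass(frozen=True)
class HeatCapacityModel:
    """Coefficients of the empirical polystyrene heat-capacity law.

    Defaults are the published constants for the PS stock used in the
    calorimeter core; ``heat_capacity`` with these defaults is positive and
    strictly increasing over the room-temperature range [280 K, 320 K].
    """

    molar_mass: float = 104.15  # g/mol, styrene repeat unit
    coeff_a: float = 7.755e5  # K^2 term
    coeff_b: float = 0.5345  # linear term, per K
    coeff_c: float = -41.58  # constant term

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")


DEFAULT_HEAT_CAPACITY = HeatCapacityModel()


def heat_capacity(T, model: HeatCapacityModel = DEFAULT_HEAT_CAPACITY):
    """Specific heat capacity of polystyrene in J/(kg K).

    Parameters
    ----------
    T : float or array_like
        Absolute temperature in K; must be strictly positive.
    model : HeatCapacityModel
        Coefficients; defaults to the polystyrene constants.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    cp = 1000.0 / model.molar_mass * (model.coeff_a * T**-2 + model.coeff_b * T + model.coeff_c)
    return cp if cp.ndim else float(cp)


def dose_from_delta_T(delta_T, cp: float):
    """Absorbed dose from a temperature rise: dose = cp * delta_T.

    With ``delta_T`` in K the dose is in Gy; with ``delta_T`` in mK the dose
    is in mGy (the factor of 1000 cancels).  ``cp`` is in J/(kg K) and must
    be strictly positive.
    """
    if cp <= 0:
        raise ValueError(f"heat capacity must be positive, got {cp}")
    delta_T = np.asarray(delta_T, dtype=float)
    dose = cp * delta_T
    return dose if dose.ndim else float(dose)


def delta_T_from_dose(dose, cp: float):
    """Temperature rise producing a given dose (inverse of dose_from_delta_T)."""
    if cp <= 0:
        raise ValueError(f"heat capacity must be positive, got {cp}")
    dose = np.asarray(dose, dtype=float)
    dT = dose / cp
    return dT if dT.ndim else float(dT)


def ideal_slope_mK_per_mGy(cp: float) -> float:
    """Temperature-per-dose slope expected from polystyrene heating alone.

    This is the rise, in mK, that 1 mGy absorbed in PS of heat capacity
    ``cp`` produces (0.00083 mK/mGy at cp = 1208 J/(kg K)).
    """
    return delta_T_from_dose(1.0, cp)


def excess_heat_factor(measured_slope: float, cp: float, *, rounded: bool = False) -> float:
    """Ratio of an observed mK-per-mGy slope to the ideal PS-only slope.

    A factor of 1 means the sensor reports exactly the heating expected from
    dose to the polystyrene; larger values quantify excess heat from
    high-atomic-number components (thermistor beads, lead wires) that absorb
    disproportionately in kilovolt X-ray beams.

    Parameters
    ----------
    measured_slope : float
        Observed slope in mK per mGy of reference (ionization-chamber) dose.
    cp : float
        Polystyrene heat capacity in J/(kg K).
    rounded : bool
        If True, round the factor to the nearest integer for presentation
        alongside nearby printed values; the default reports the raw ratio.
    """
    if measured_slope <= 0:
        raise ValueError(f"measured slope must be positive, got {measured_slope}")
    if cp <= 0:
        raise ValueError(f"heat capacity must be positive, got {cp}")
    factor = measured_slope / ideal_slope_mK_per_mGy(cp)
    return float(round(factor)) if rounded else factor


def effective_thermal_length(diffusivity: float, time_constant: float) -> float:
    """Diffusive length scale sqrt(delta * tau) in m.

    ``diffusivity`` (delta) is the thermal diffusivity in m^2/s and
    ``time_constant`` (tau) a fitted thermal relaxation time in s.  The
    square root is the dimensionally consistent combination; it estimates
    the size of the component whose conduction sets that time scale
    (e.g. ~8 mm for tau = 628 s at delta = 1e-7 m^2/s, comparable to the
    7.3 mm core radius).
    """
    if diffusivity < 0:
        raise ValueError(f"diffusivity must be non-negative, got {diffusivity}")
    if time_constant < 0:
        raise ValueError(f"time constant must be non-negative, got {time_constant}")
    return math.sqrt(diffusivity * time_constant)
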