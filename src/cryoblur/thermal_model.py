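"""Lumped heat-flow model of one-sided sample cooling.

A thin aqueous sample on a highly conducting heat exchanger is cooled from
one surface.  Heat flows at rate dQ/dt = -kappa*A*dT/L through the water
column of depth L; with heat capacity c*m this yields the first-order
kinetics

    dT/dt = -kappa*A*(T - T_coolant) / (c*m*L)
    T(t)  = delta_T * (exp(-k t) - 1) + T0,   k = kappa*A / (c*m*L)

so the cooling rate is maximal at t=0 (k*delta_T) and decays exponentially.
The heat capacity of water is given volumetrically (4 J cm^-3 K^-1); with
the default mass convention m = rho*A*L the rate constant reduces to the
density-free k = kappa / (c_vol * L^2), i.e. initial rates scale as 1/L^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WATER_CONDUCTIVITY",
    "WATER_VOLUMETRIC_HEAT_CAPACITY",
    "WATER_DENSITY",
    "CoolingModel",
    "temperature_course",
    "cooling_rate",
    "time_to_temperature",
    "interval_mean_rate",
]

#: Thermal conductivity of water (W m^-1 K^-1) as used throughout.
WATER_CONDUCTIVITY = 0.5562

#: Volumetric heat capacity of water, J cm^-3 K^-1.
WATER_VOLUMETRIC_HEAT_CAPACITY = 4.0

#: Density of water, kg/m^3 (used only for the default mass convention).
WATER_DENSITY = 1000.0


@dataclass(frozen=True)
class CoolingModel:
    """One-sided cooling of a water column of depth ``thickness_L``.

    Parameters
    ----------
    kappa : float
        Thermal conductivity (W m^-1 K^-1).
    area : float
        Cooled surface area (m^2); default is the 4-mm cover slide (2e-5 m^2).
    thickness_L : float
        Effective depth of the probed layer (m).
    c_vol : float
        Volumetric heat capacity in J cm^-3 K^-1 (converted internally).
    t0 : float
        Initial sample temperature (degC).
    delta_T : float
        Initial temperature difference to the coolant (degC); 233 between
        37 degC and liquid nitrogen at -196 degC.
    mass : float or None
        Sample mass (kg).  ``None`` (default) uses m = rho*A*L, which makes
        the model density-free and reproduces the printed rates; a literal
        mass can be supplied to override.
    """

    thickness_L: float
    kappa: float = WATER_CONDUCTIVITY
    area: float = 2e-5
    c_vol: float = WATER_VOLUMETRIC_HEAT_CAPACITY
    t0: float = 37.0
    delta_T: float = 233.0
    mass: float | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("thickness_L", "kappa", "area", "c_vol", "delta_T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mass is not None and self.mass <= 0:
            raise ValueError("mass must be positive when given")

    @property
    def heat_capacity(self) -> float:
        """Total heat capacity c*m in J/K (volumetric c times sample volume)."""
        c_vol_si = self.c_vol * 1e6  # J cm^-3 K^-1 -> J m^-3 K^-1
        volume = (
            self.area * self.thickness_L if self.mass is None else self.mass / WATER_DENSITY
        )
        return c_vol_si * volume

    @property
    def rate_constant(self) -> float:
        """k = kappa*A/(c*m*L) in s^-1."""
        return self.kappa * self.area / (self.heat_capacity * self.thickness_L)

    @property
    def coolant_temperature(self) -> float:
        return self.t0 - self.delta_T


def temperature_course(model: CoolingModel, t):
    """Temperature (degC) at time(s) ``t`` (s): delta_T*(exp(-k t)-1)+T0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = model.delta_T * (np.exp(-model.rate_constant * t) - 1.0) + model.t0
    return float(out) if out.ndim == 0 else out


def cooling_rate(model: CoolingModel, t):
    """Magnitude of dT/dt (degC/s) at time(s) ``t``; maximal k*delta_T at t=0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = model.rate_constant * model.delta_T * np.exp(-model.rate_constant * t)
    return float(out) if out.ndim == 0 else out


def time_to_temperature(model: CoolingModel, temp: float) -> float:
    """Closed-form inverse of the temperature course: time (s) to reach ``temp``."""
    lo = model.coolant_temperature
    if not lo < temp <= model.t0:
        raise ValueError(f"temperature {temp} outside reachable range ({lo}, {model.t0}]")
    return -math.log((temp - model.t0 + model.delta_T) / model.delta_T) / model.rate_constant


def interval_mean_rate(model: CoolingModel, t_hi: float, t_lo: float) -> float:
    """Mean cooling rate (degC/s) while traversing ``t_hi`` -> ``t_lo`` (degC).

    The traversal time follows from the closed-form inverse of the
    temperature course; typical use is the critical 0 to -130 degC band in
    which ice crystallization can occur.
    """
    if not t_lo < t_hi:
        raise ValueError("t_hi must exceed t_lo")
    dt = time_to_temperature(model, t_lo) - time_to_temperature(model, t_hi)
    return (t_hi - t_lo) / dt
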