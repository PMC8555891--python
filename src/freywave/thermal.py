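"""Pulse heating: SAR* to temperature rise under the adiabatic assumption.

For a single microwave pulse much shorter than thermal-diffusion time
scales (< 1 ms), conduction is negligible and the local temperature rise is

    dT = PIN * SAR* * tau_d / c_p            (degC)

with PIN the incident power density (mW/cm^2), tau_d the pulse duration (s)
and c_p the tissue specific heat capacity.  The temperature follows a
linear ramp up to dT at t = tau_d and is held constant afterwards, since
conduction is far too slow to relax it on acoustic time scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import PhantomGrid
from .em_solver import SARMap

__all__ = [
    "TemperatureLoad",
    "temperature_rise",
    "ramp_schedule",
    "diffusion_negligibility",
    "BRAIN_THERMAL_DIFFUSIVITY",
    "ADIABATIC_LIMIT_S",
]

#: Brain tissue thermal diffusivity (m^2/s) used for the adiabatic check.
BRAIN_THERMAL_DIFFUSIVITY = 2e-7

#: Pulse durations at or above this violate the no-conduction assumption.
ADIABATIC_LIMIT_S = 1e-3


@dataclass
class TemperatureLoad:
    """Per-voxel temperature rise dT (degC) reached at the end of a pulse
    of duration tau_d (s) at incident power density pin (mW/cm^2)."""

    delta_T: np.ndarray
    tau_d: float
    pin: float

    def __post_init__(self):
        if np.any(self.delta_T < 0):
            raise ValueError("temperature rise must be non-negative")


def temperature_rise(
    sar_map: SARMap, phantom: PhantomGrid, pin: float, tau_d: float
) -> TemperatureLoad:
    """End-of-pulse temperature rise, dT = pin * SAR* * tau_d / c_p.

    ``pin`` is in mW/cm^2 and ``tau_d`` in seconds.  A ``tau_d`` at or above
    1 ms only warns (the adiabatic assumption degrades); ``pin <= 0`` is an
    error.  Voxels with zero SAR* (vacuum, zero conductivity) stay at zero.
    """
    if pin <= 0:
        raise ValueError("incident power density must be positive")
    if tau_d <= 0:
        raise ValueError("pulse duration must be positive")
    if tau_d >= ADIABATIC_LIMIT_S:
        warnings.warn(
            f"tau_d = {tau_d:.3g} s >= 1 ms: thermal diffusion is no longer "
            f"negligible and the adiabatic temperature rise is an upper bound",
            stacklevel=2,
        )
    if sar_map.sar_star is None:
        raise ValueError("sar_star not filled; call normalize_sar first")
    cp = phantom.property_volume("cp", default=np.inf)
    delta_T = pin * sar_map.sar_star * tau_d / cp
    return TemperatureLoad(delta_T=delta_T, tau_d=tau_d, pin=pin)


def ramp_schedule(load: TemperatureLoad, t: float | np.ndarray) -> np.ndarray:
    """Temperature at time t: linear ramp to delta_T at tau_d, then constant."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    frac = np.minimum(t / load.tau_d, 1.0)
    if frac.ndim == 0:
        return load.delta_T * float(frac)
    return load.delta_T[..., None] * frac


def diffusion_negligibility(
    tau_d: float, length_scale: float,
    diffusivity: float = BRAIN_THERMAL_DIFFUSIVITY,
) -> float:
    """Thermal diffusion length over the feature size: sqrt(4 D tau_d)/L.

    Values much below 1 mean heat stays where it was deposited for the
    duration of the pulse.
    """
    if tau_d < 0 or length_scale <= 0:
        raise ValueError("tau_d must be >= 0 and length_scale > 0")
    return float(np.sqrt(4.0 * diffusivity * tau_d) / length_scale)
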