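"""Thermodynamic links between water potential, relative humidity and VPD.

The Kelvin equation ties the equilibrium relative humidity of air in contact
with water held at potential :math:`\\Psi` (Pa, <= 0) to temperature:

.. math:: RH = e / e_0(T) = \\exp\\left(\\frac{M_w \\Psi}{\\rho_w R T}\\right)

so that 100 % RH corresponds to 0 MPa and drier soil (more negative potential)
to lower pore-air humidity.  Atmospheric relative humidity is recovered from
vapor pressure deficit with a Magnus-form saturation curve (Sonntag
coefficients over a water surface).

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "DEFAULT_CONSTANTS",
    "rh_from_psi",
    "psi_from_rh",
    "esat",
    "rha_from_vpd",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used by the Kelvin and Magnus relations.

    Attributes
    ----------
    mw : float
        Molecular weight of water, kg mol^-1.
    r : float
        Universal gas constant, J K^-1 mol^-1.
    rho_w : float
        Density of liquid water, kg m^-3.
    magnus_a, magnus_b, magnus_c : float
        Saturation vapor pressure coefficients (Sonntag, water surface):
        esat(Ta) = magnus_a * exp(magnus_b * Ta / (magnus_c + Ta)), with
        magnus_a in hPa and Ta in deg C.
    """

    mw: float = 0.018
    r: float = 8.31
    rho_w: float = 1000.0
    magnus_a: float = 6.112
    magnus_b: float = 17.62
    magnus_c: float = 243.12

    def __post_init__(self) -> None:
        for name in ("mw", "r", "rho_w", "magnus_a", "magnus_b", "magnus_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name!r} must be strictly positive")


DEFAULT_CONSTANTS = PhysicalConstants()


def rh_from_psi(psi, t_k, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Equilibrium relative humidity (fraction in (0, 1]) at water potential ``psi``.

    Parameters
    ----------
    psi : array_like
        Water potential in Pa; must be <= 0 (suction is negative).
    t_k : array_like
        Absolute temperature in K; must be > 0.
    """
    psi = np.asarray(psi, dtype=float)
    t_k = np.asarray(t_k, dtype=float)
    if np.any(psi > 0):
        raise ValueError("water potential must be <= 0 Pa")
    if np.any(t_k <= 0):
        raise ValueError("temperature must be > 0 K")
    out = np.exp(c.mw * psi / (c.rho_w * c.r * t_k))
    return out if out.ndim else float(out)


def psi_from_rh(rh, t_k, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Water potential in Pa (<= 0) in equilibrium with relative humidity ``rh``.

    Exact inverse of :func:`rh_from_psi`: psi = (rho_w R T / Mw) * ln(rh).
    ``rh`` is a fraction in (0, 1].
    """
    rh = np.asarray(rh, dtype=float)
    t_k = np.asarray(t_k, dtype=float)
    if np.any((rh <= 0) | (rh > 1)):
        raise ValueError("relative humidity must be a fraction in (0, 1]")
    if np.any(t_k <= 0):
        raise ValueError("temperature must be > 0 K")
    out = (c.rho_w * c.r * t_k / c.mw) * np.log(rh)
    return out if out.ndim else float(out)


def esat(ta_c, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Saturation vapor pressure over water in kPa at air temperature ``ta_c`` (deg C)."""
    ta_c = np.asarray(ta_c, dtype=float)
    if np.any(ta_c <= -c.magnus_c):
        raise ValueError(f"air temperature must exceed {-c.magnus_c} degC")
    out = c.magnus_a * np.exp(c.magnus_b * ta_c / (c.magnus_c + ta_c)) / 10.0
    return out if out.ndim else float(out)


def rha_from_vpd(vpd, ta_c, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Atmospheric relative humidity in % from VPD (kPa) and air temperature (deg C).

    RHa = 100 * (1 - VPD / esat(Ta)), clipped to [0, 100] to absorb small
    sensor-level excursions of VPD beyond saturation.
    """
    vpd = np.asarray(vpd, dtype=float)
    if np.any(vpd < 0):
        raise ValueError("VPD must be >= 0 kPa")
    out = np.clip(100.0 * (1.0 - vpd / esat(ta_c, c)), 0.0, 100.0)
    return out if out.ndim else float(out)
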