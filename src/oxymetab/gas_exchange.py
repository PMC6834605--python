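"""Air-water O2 exchange: Schmidt numbers, transfer velocities, flux.

The transfer velocity follows the quadratic wind-speed law for CO2
(0.31 * u10^2, cm/h) rescaled to O2 through the Schmidt-number ratio
(ScO2/660)^n, with the exponent n switching from -2/3 to -1/2 at
u10 = 2 m/s.  Flux is F = -k * (DO - DOsat), positive into the water.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import constants as c
from .seawater import density_eos, o2_solubility_umol_kg


def schmidt_co2_fresh(temp_c):
    """Freshwater CO2 Schmidt number as a cubic in temperature (degC).

    Valid 0-40 degC; outside that range a warning is raised and the
    polynomial is still evaluated.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any((t < 0) | (t > 40)):
        warnings.warn("temperature outside 0-40 degC: Schmidt polynomial "
                      "extrapolated", stacklevel=2)
    c0, c1, c2, c3 = c.SC0_CO2_FRESH_COEFFS
    out = c0 + c1 * t + c2 * t**2 + c3 * t**3
    return out if out.ndim else float(out)


def schmidt_o2(temp_c, salinity):
    """O2 Schmidt number: freshwater CO2 value scaled linearly in salinity."""
    s = np.asarray(salinity, dtype=float)
    if np.any(s < 0):
        raise ValueError("salinity must be non-negative")
    out = np.asarray(schmidt_co2_fresh(temp_c)) * (1.0 + c.SC_O2_SALINITY_COEF * s)
    return out if out.ndim else float(out)


def k_co2(u10):
    """CO2 transfer velocity (cm/h) from 10-m wind speed (m/s)."""
    u = np.asarray(u10, dtype=float)
    if np.any(u < 0):
        raise ValueError("u10 must be non-negative")
    out = c.K_CO2_WIND_COEF * u**2
    return out if out.ndim else float(out)


def schmidt_exponent(u10):
    """Schmidt-number exponent: -2/3 below 2 m/s, -1/2 at or above."""
    u = np.asarray(u10, dtype=float)
    out = np.where(u >= c.WIND_EXPONENT_THRESHOLD_MS, -0.5, -2.0 / 3.0)
    return out if out.ndim else float(out)


def k_o2(temp_c, salinity, u10):
    """O2 transfer velocity (cm/h): kCO2 * (ScO2/660)^n.

    At ScO2 = 660 the ratio is exactly 1 on either exponent branch.
    """
    kc = np.asarray(k_co2(u10))
    sc = np.asarray(schmidt_o2(temp_c, salinity))
    n = np.asarray(schmidt_exponent(u10))
    out = kc * (sc / c.SC_CO2_SALTWATER) ** n
    return out if out.ndim else float(out)


def k_cm_h_to_m_d(k_cm_h):
    """Convert a transfer velocity from cm/h to m/d (x 0.24)."""
    out = np.asarray(k_cm_h, dtype=float) * c.CM_PER_H_TO_M_PER_D
    return out if out.ndim else float(out)


def do_saturation(temp_c, salinity, elevation_m=0.0):
    """Air-equilibrium DO concentration (uM).

    Garcia-Gordon solubility (umol/kg) converted to volumetric units with
    the surface density, then scaled by a barometric altitude factor
    exp(-elevation / 8000 m).  Elevation defaults to sea level.
    """
    sol = o2_solubility_umol_kg(temp_c, salinity)
    rho = density_eos(temp_c, salinity)
    press = np.exp(-np.asarray(elevation_m, dtype=float)
                   / c.BAROMETRIC_SCALE_HEIGHT_M)
    out = sol * (rho / 1000.0) * press
    return out if out.ndim else float(out)


def o2_flux(k_o2_m_d, do_um, do_sat_um):
    """Air-water O2 flux (mmol m^-2 d^-1), positive into the water.

    F = -k * (DO - DOsat) with k in m/d and concentrations in uM
    (= mmol m^-3), so undersaturated water takes up oxygen.
    """
    k = np.asarray(k_o2_m_d, dtype=float)
    if np.any(k < 0):
        raise ValueError("transfer velocity must be non-negative")
    out = -k * (np.asarray(do_um, dtype=float) - np.asarray(do_sat_um, dtype=float))
    return out if out.ndim else float(out)


def wind_to_10m(u_z, z_m, z0_m=c.ROUGHNESS_LENGTH_M):
    """Scale a wind speed measured at height z (m) to 10 m.

    Neutral logarithmic profile u10 = u_z * ln(10/z0) / ln(z/z0) with a
    configurable roughness length (default 2e-4 m, typical of small
    sheltered water bodies).
    """
    if z_m <= 0:
        raise ValueError("measurement height must be positive")
    u = np.asarray(u_z, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be non-negative")
    out = u * (np.log(10.0 / z0_m) / np.log(z_m / z0_m))
    return out if out.ndim else float(out)
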