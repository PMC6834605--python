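"""Seawater property formulae: O2 solubility, salinity correction, density.

Oxygen solubility follows the Garcia & Gordon (1992) combined fit to the
Benson & Krause data (umol/kg coefficient set); density is the UNESCO
(1983) one-atmosphere equation of state (EOS-80).  Both are plain
polynomial evaluations and are vectorised over numpy arrays.
"""

from __future__ import annotations

import numpy as np

# Garcia & Gordon (1992) combined-fit coefficients, umol/kg set.
GG_UMOL_KG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
GG_UMOL_KG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
GG_UMOL_KG_C0 = -2.75915e-7

# Salinity-compensation coefficient set (the Garcia-Gordon mL/L fit's
# salinity terms), as documented by optode vendors for correcting
# freshwater-calibrated DO readings.
GG_SALFAC_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
GG_SALFAC_C0 = -4.88682e-7


def scaled_temperature(temp_c):
    """Logarithmic temperature scale Ts = ln((298.15 - T)/(273.15 + T))."""
    temp_c = np.asarray(temp_c, dtype=float)
    return np.log((298.15 - temp_c) / (273.15 + temp_c))


def o2_solubility_umol_kg(temp_c, salinity):
    """Equilibrium O2 concentration (umol/kg) at 1 atm moist air.

    Parameters
    ----------
    temp_c : water temperature, degC (validity 0-40).
    salinity : practical salinity (validity 0-42).
    """
    ts = scaled_temperature(temp_c)
    s = np.asarray(salinity, dtype=float)
    a0, a1, a2, a3, a4, a5 = GG_UMOL_KG_A
    b0, b1, b2, b3 = GG_UMOL_KG_B
    ln_c = (
        a0 + a1 * ts + a2 * ts**2 + a3 * ts**3 + a4 * ts**4 + a5 * ts**5
        + s * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
        + GG_UMOL_KG_C0 * s**2
    )
    return np.exp(ln_c)


def salinity_correction_factor(temp_c, salinity):
    """Multiplicative factor converting a freshwater-calibrated DO reading
    to its value in water of the given salinity.

    exp(S*(B0 + B1*Ts + B2*Ts^2 + B3*Ts^3) + C0*S^2): the salinity part of
    the Garcia-Gordon solubility fit, equal to 1 at S = 0 and strictly
    decreasing in S over the oceanographic range.
    """
    ts = scaled_temperature(temp_c)
    s = np.asarray(salinity, dtype=float)
    b0, b1, b2, b3 = GG_SALFAC_B
    out = np.exp(s * (b0 + b1 * ts + b2 * ts**2 + b3 * ts**3)
                 + GG_SALFAC_C0 * s**2)
    return out if out.ndim else float(out)


# UNESCO (1983) one-atmosphere equation of state (Millero & Poisson 1981).
_EOS_RHOW = (999.842594, 6.793952e-2, -9.095290e-3, 1.001685e-4,
             -1.120083e-6, 6.536332e-9)
_EOS_A = (8.24493e-1, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9)
_EOS_B = (-5.72466e-3, 1.0227e-4, -1.6546e-6)
_EOS_C = 4.8314e-4


def density_eos(temp_c, salinity):
    """In-situ density (kg/m^3) at surface pressure from T (degC) and S.

    UNESCO 1983 one-atmosphere EOS.  Check values: rho(S=0, T=5) =
    999.96675, rho(35, 5) = 1027.67547, rho(35, 25) = 1023.34306.
    """
    t = np.asarray(temp_c, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = sum(c * t**i for i, c in enumerate(_EOS_RHOW))
    a = sum(c * t**i for i, c in enumerate(_EOS_A))
    b = sum(c * t**i for i, c in enumerate(_EOS_B))
    out = rho_w + a * s + b * s**1.5 + _EOS_C * s**2
    return out if out.ndim else float(out)
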