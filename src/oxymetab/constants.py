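"""Named physical constants and method defaults.

Every tunable that the estimators depend on lives here so that a single
import site documents the conventions: the diel windows, the gas-exchange
coefficients, the suboxic threshold, and the boosted-tree hyperparameters.
"""

# ---------------------------------------------------------------------------
# Diel windows (local hours).  The metabolic day runs 05:00 -> 05:00; the
# dark (respiration-only) window runs 19:00 -> 05:00 the following morning.
DAY_START_HOUR = 5.0
DARK_START_HOUR = 19.0
DARK_HOURS = 10.0
LIGHT_WINDOW_H = (5.0, 19.0)

#: minimum fraction of expected records a daily window must contain
COVERAGE_MIN = 0.80

#: DO below this level is treated as analytically undetectable (uM)
DETECTION_LIMIT_UM = 2.0

# ---------------------------------------------------------------------------
# Gas exchange.
#: freshwater CO2 Schmidt-number polynomial in T (degC): c0 + c1*T + c2*T^2 + c3*T^3
SC0_CO2_FRESH_COEFFS = (1800.6, -120.10, 3.7818, -0.047608)
#: linear salinity scaling of the O2 Schmidt number
SC_O2_SALINITY_COEF = 3.14e-3
#: quadratic wind-speed law for the CO2 transfer velocity (cm/h per (m/s)^2)
K_CO2_WIND_COEF = 0.31
#: reference Schmidt number for CO2 in seawater
SC_CO2_SALTWATER = 660.0
#: u10 threshold (m/s) switching the Schmidt exponent from -2/3 to -1/2
WIND_EXPONENT_THRESHOLD_MS = 2.0
#: cm/h -> m/d
CM_PER_H_TO_M_PER_D = 0.24
#: e-folding scale height for the barometric pressure correction (m)
BAROMETRIC_SCALE_HEIGHT_M = 8000.0
#: aerodynamic roughness length used by the neutral log wind profile (m)
ROUGHNESS_LENGTH_M = 2.0e-4
#: mg/L -> umol/L for O2 (molar mass 31.998 g/mol)
MG_L_TO_UM_O2 = 1000.0 / 31.998

# ---------------------------------------------------------------------------
# Water-column structure.
#: DO level defining the top of the suboxic zone (uM)
SUBOXIC_THRESHOLD_UM = 20.0
#: extrapolation guard rails for the suboxic-depth crossing (m)
SUBOXIC_DEPTH_CAP_M = 20.0
SUBOXIC_DEPTH_FLOOR_M = 0.0

# ---------------------------------------------------------------------------
# Statistics.
GRANGER_ALPHA = 0.05
EWS_WINDOW_FRACTION = 0.15
EWS_WINDOW_MIN = 5

#: gradient-boosting defaults: trees, shrinkage, interaction depth, bag fraction
BRT_N_TREES = 363
BRT_SHRINKAGE = 0.05
BRT_INTERACTION_DEPTH = 3
BRT_BAG_FRACTION = 0.7

# ---------------------------------------------------------------------------
# Singular spectrum analysis.
#: embedding window: 3 days at 10-min cadence
SSA_WINDOW_SAMPLES = 432
#: dominant-period band (hours) treated as the daily cycle
SSA_DIEL_BAND_H = (20.0, 28.0)
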