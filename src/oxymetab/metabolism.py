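"""Daily metabolic rates from diel oxygen curves.

Three estimators of community respiration (CR), net community production
(NCP) and gross primary production (GPP) per sensor depth:

``bdo``
    Sum of per-step "biological DO" increments: over the dark window
    (19:00 -> 05:00, scaled x 24/10 to a daily rate) for CR and over the
    full 05:00 -> 05:00 metabolic day for NCP.  In integrated mode the
    air-water flux term is removed from each increment first.
``slope``
    Least-squares slope of DO versus time (days) over the dark window
    (CR) and the metabolic day (NCP); the preceding day is paired with
    the following night for GPP.
``ssa_slope``
    Singular-spectrum analysis reconstruction of the daily cycle (tide
    and small-scale variability removed) followed by the slope method.

GPP = NCP + |CR| wherever CR <= 0; GPP is undefined when DO rose over
night (CR > 0).  Days on which DO sits below the detection limit are
reported as missing, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as c
from .env_io import _metabolic_date
from .structure import integrate_profile
from .types import SensorSeries

__all__ = [
    "bdo_rates", "slope_rates", "ssa_reconstruct_diel", "ssa_slope_rates",
    "integrate_rates", "flux_contribution", "rates_all_methods",
]


# ---------------------------------------------------------------------------
# window bookkeeping


def _night_date(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Calendar date of the night a dark-window record belongs to (a night
    starting 19:00 on day d carries date d)."""
    return (index - pd.Timedelta(hours=c.DARK_START_HOUR)).normalize()


def _is_dark(index: pd.DatetimeIndex) -> np.ndarray:
    h = index.hour + index.minute / 60.0
    return (h >= c.DARK_START_HOUR) | (h < c.DAY_START_HOUR)


def _anoxic_dates(series: SensorSeries,
                  limit_um: float = c.DETECTION_LIMIT_UM) -> pd.DatetimeIndex:
    """Metabolic dates on which DO sat below the detection limit
    essentially all day (>= 95% of records)."""
    below = (series.data["do_um"] < limit_um)
    frac = below.groupby(_metabolic_date(series.data.index)).mean()
    return pd.DatetimeIndex(frac.index[frac >= 0.95])


def _finalize(table: pd.DataFrame, series: SensorSeries, method: str,
              anoxic_limit_um: float) -> pd.DataFrame:
    """Attach GPP, mask anoxic days, and tidy columns."""
    table = table.copy()
    gpp = table["ncp_um_d"] + table["cr_um_d"].abs()
    gpp[table["cr_um_d"] > 0] = np.nan
    table["gpp_um_d"] = gpp
    anoxic = _anoxic_dates(series, anoxic_limit_um)
    table.loc[table.index.isin(anoxic),
              ["cr_um_d", "ncp_um_d", "gpp_um_d"]] = np.nan
    table.insert(0, "depth_m", series.depth_m)
    table.insert(1, "method", method)
    table.index.name = "date"
    return table.reset_index()


# ---------------------------------------------------------------------------
# BDO estimator


def _increments(series: SensorSeries) -> pd.Series:
    """Per-step DO change, indexed by interval *start*; steps spanning a
    gap (dt != cadence) are discarded."""
    do = series.data["do_um"]
    dt = do.index.to_series().diff()
    inc = do.diff()
    good = dt == pd.Timedelta(minutes=series.cadence_min)
    inc = inc[good.to_numpy()]
    inc.index = inc.index - pd.Timedelta(minutes=series.cadence_min)
    return inc


def _window_sum(inc: pd.Series, dates: pd.DatetimeIndex, window_h: float,
                cadence_min: int, coverage_min: float):
    expected = window_h * 60 / cadence_min
    sums = inc.groupby(dates).sum()
    counts = inc.groupby(dates).size()
    coverage = counts / expected
    sums[coverage < coverage_min] = np.nan
    return sums, coverage


def bdo_rates(series: SensorSeries, flux_um_d: pd.Series | None = None,
              coverage_min: float = c.COVERAGE_MIN,
              dark_hours: float = c.DARK_HOURS,
              anoxic_limit_um: float = c.DETECTION_LIMIT_UM) -> pd.DataFrame:
    """Daily CR/NCP/GPP from summed per-step biological DO changes.

    Parameters
    ----------
    series : sensor record (cadence must be <= 60 min).
    flux_um_d : optional air-water flux expressed as a concentration rate
        (uM/d, i.e. areal flux divided by the column depth), indexed by
        timestamp; when given, each increment has flux * dt removed so the
        sums are biological ("integrated mode").  Omit it for single-depth
        rates.
    """
    if series.cadence_min > 60:
        raise ValueError("BDO needs cadence <= 60 min")
    inc = _increments(series)
    if flux_um_d is not None:
        dt_days = series.cadence_min / (24.0 * 60.0)
        aligned = flux_um_d.reindex(inc.index)
        inc = inc - aligned * dt_days
    dark = _is_dark(inc.index)
    cr_sum, cr_cov = _window_sum(inc[dark], _night_date(inc.index[dark]),
                                 dark_hours, series.cadence_min, coverage_min)
    ncp_sum, ncp_cov = _window_sum(inc, _metabolic_date(inc.index),
                                   24.0, series.cadence_min, coverage_min)
    table = pd.DataFrame({
        "cr_um_d": cr_sum * (24.0 / dark_hours),
        "ncp_um_d": ncp_sum,
        "cr_coverage": cr_cov,
        "ncp_coverage": ncp_cov,
    })
    return _finalize(table, series, "bdo", anoxic_limit_um)


# ---------------------------------------------------------------------------
# slope estimator


def _window_slope(do: pd.Series, dates: pd.DatetimeIndex, window_h: float,
                  cadence_min: int, coverage_min: float):
    """OLS slope of DO vs time (uM per day) within each window."""
    expected = window_h * 60 / cadence_min + 1
    slopes, coverage = {}, {}
    t_days = do.index.asi8 / (1e9 * 86400.0)
    frame = pd.DataFrame({"t": t_days, "y": do.to_numpy()})
    for d, grp in frame.groupby(dates):
        coverage[d] = len(grp) / expected
        if coverage[d] < coverage_min or len(grp) < 2:
            slopes[d] = np.nan
            continue
        t = grp["t"].to_numpy()
        y = grp["y"].to_numpy()
        tc = t - t.mean()
        slopes[d] = float(tc @ (y - y.mean()) / (tc @ tc))
    idx = pd.DatetimeIndex(sorted(slopes))
    return (pd.Series([slopes[d] for d in idx], index=idx),
            pd.Series([coverage[d] for d in idx], index=idx))


def slope_rates(series: SensorSeries,
                coverage_min: float = c.COVERAGE_MIN,
                anoxic_limit_um: float = c.DETECTION_LIMIT_UM,
                method_tag: str = "slope") -> pd.DataFrame:
    """Daily CR/NCP/GPP from least-squares slopes of DO versus time.

    CR(d) is the slope over the night [19:00 d, 05:00 d+1); NCP(d) the
    slope over [05:00 d, 05:00 d+1); GPP(d) = NCP(d) + |CR(d)| pairs the
    preceding day with the following night.
    """
    do = series.data["do_um"]
    dark = _is_dark(do.index)
    cr, cr_cov = _window_slope(do[dark], _night_date(do.index[dark]),
                               c.DARK_HOURS, series.cadence_min, coverage_min)
    ncp, ncp_cov = _window_slope(do, _metabolic_date(do.index),
                                 24.0, series.cadence_min, coverage_min)
    table = pd.DataFrame({
        "cr_um_d": cr, "ncp_um_d": ncp,
        "cr_coverage": cr_cov, "ncp_coverage": ncp_cov,
    })
    return _finalize(table, series, method_tag, anoxic_limit_um)


# ---------------------------------------------------------------------------
# singular spectrum analysis


@dataclass
class SSAResult:
    series: SensorSeries          #: DO replaced by the diel reconstruction
    interpolated_fraction: float  #: fraction of grid points gap-filled
    periods_h: np.ndarray         #: dominant period of each eigentriple
    kept: np.ndarray              #: indices of grouped eigentriples


def _frequency_rotation(basis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an orthonormal basis so each column is frequency-pure.

    Near-equal eigenvalues (e.g. a tidal and a diel pair of similar
    amplitude) make raw SSA eigenvectors arbitrary mixtures of the two
    oscillations.  Diagonalising the Parseval-weighted mean-frequency
    operator A_ij = sum_k w_k * k * Re(F*_ki F_kj) within the retained
    subspace separates them; the eigenvalues are each rotated component's
    mean Fourier bin, giving a continuous period estimate as a bonus.
    """
    length = basis.shape[0]
    spec = np.fft.rfft(basis, axis=0)
    w = np.full(spec.shape[0], 2.0 / length)
    w[0] = 1.0 / length
    if length % 2 == 0:
        w[-1] = 1.0 / length
    operator = ((spec.conj().T * (w * np.arange(spec.shape[0]))) @ spec).real
    mean_bin, rot = np.linalg.eigh(operator)
    return basis @ rot, mean_bin


def ssa_reconstruct_diel(series: SensorSeries,
                         window_len: int = c.SSA_WINDOW_SAMPLES,
                         band_h: tuple[float, float] = c.SSA_DIEL_BAND_H,
                         max_components: int = 30) -> SSAResult:
    """Reconstruct the trend + daily cycle of a DO record by SSA.

    The record is placed on a complete grid (interior gaps linearly
    interpolated, fraction reported), embedded in a trajectory matrix of
    ``window_len`` lags (default 3 days at 10-min cadence), and decomposed
    through the eigenvectors of the lag-covariance matrix.  The retained
    leading subspace is rotated into frequency-pure components (see
    :func:`_frequency_rotation`; otherwise a tide of similar amplitude to
    the diel cycle mixes into its eigenvectors), and components whose
    period is at least the lower edge of ``band_h`` — the slow trend plus
    the diel pair — are kept; the tidal band (~12.4 h) and high-frequency
    variability fall outside and are discarded.  The kept components are
    diagonal-averaged back into a series.

    Note the sub-diel harmonics of a non-sinusoidal daily cycle (12 h,
    8 h, ...) also fall outside the default band — the 12-h harmonic is
    spectrally inseparable from the semidiurnal tide at this window
    length — so the reconstruction is a deliberately smoothed daily
    cycle.  Widen ``band_h`` on tide-free records if the sharp diel shape
    matters.
    """
    grid = pd.date_range(series.data.index[0], series.data.index[-1],
                         freq=f"{series.cadence_min}min")
    do = series.data["do_um"].reindex(grid)
    n_missing = int(do.isna().sum())
    x = do.interpolate(method="linear", limit_direction="both").to_numpy()
    n = len(x)
    if n < 2 * window_len:
        raise ValueError(
            f"segment of {n} samples shorter than 2 x window ({2 * window_len})")

    traj = np.lib.stride_tricks.sliding_window_view(x, window_len).T  # L x K
    lagcov = traj @ traj.T
    evals, evecs = np.linalg.eigh(lagcov)
    order = np.argsort(evals)[::-1][:max_components]
    evecs, mean_bin = _frequency_rotation(evecs[:, order])

    span_h = window_len * series.cadence_min / 60.0
    with np.errstate(divide="ignore"):
        periods = np.where(mean_bin > 1e-9, span_h / np.maximum(mean_bin, 1e-9),
                           np.inf)
    kept = np.flatnonzero(periods >= band_h[0])

    counts = np.convolve(np.ones(window_len), np.ones(traj.shape[1]))
    recon = np.zeros(n)
    for j in kept:
        u = evecs[:, j]
        w = traj.T @ u
        recon += np.convolve(u, w)
    recon /= counts

    frame = pd.DataFrame(
        {"do_um": recon,
         "temp_c": series.data["temp_c"].reindex(grid).interpolate(
             method="linear", limit_direction="both").to_numpy()},
        index=grid)
    frame.index.name = "timestamp"
    out = SensorSeries(series.depth_m, frame, series.cadence_min,
                       series.provenance + "|ssa")
    return SSAResult(out, n_missing / n, periods, kept)


def ssa_slope_rates(series: SensorSeries,
                    window_len: int = c.SSA_WINDOW_SAMPLES,
                    band_h: tuple[float, float] = c.SSA_DIEL_BAND_H,
                    coverage_min: float = c.COVERAGE_MIN,
                    anoxic_limit_um: float = c.DETECTION_LIMIT_UM) -> pd.DataFrame:
    """Slope rates on the SSA diel reconstruction (method tag
    ``ssa_slope``).

    Coverage is judged on the *original* record: windows that were mostly
    gap in the raw data stay missing even though SSA interpolates them.
    """
    ssa = ssa_reconstruct_diel(series, window_len, band_h)
    rates = slope_rates(ssa.series, coverage_min=0.0,
                        anoxic_limit_um=anoxic_limit_um,
                        method_tag="ssa_slope")
    raw = slope_rates(series, coverage_min=coverage_min,
                      anoxic_limit_um=anoxic_limit_um)
    raw = raw.set_index("date")
    rates = rates.set_index("date")
    for col, cov in (("cr_um_d", "cr_coverage"), ("ncp_um_d", "ncp_coverage")):
        bad = raw.index[raw[cov].isna() | (raw[cov] < coverage_min)]
        rates.loc[rates.index.isin(bad), col] = np.nan
        rates[cov] = raw[cov].reindex(rates.index)
    rates["gpp_um_d"] = rates["ncp_um_d"] + rates["cr_um_d"].abs()
    rates.loc[rates["cr_um_d"] > 0, "gpp_um_d"] = np.nan
    return rates.reset_index()


# ---------------------------------------------------------------------------
# depth integration and flux bookkeeping


def integrate_rates(per_depth_rates: pd.DataFrame,
                    min_depths: int = 2) -> pd.DataFrame:
    """Trapezoidal depth integration of per-depth daily rates.

    Input is long-format (columns ``date``, ``depth_m``, ``cr_um_d``,
    ``ncp_um_d``, ``gpp_um_d``, ``method``); output has one row per
    (date, method) with integrated rates in mmol O2 m^-2 d^-1 (uM d^-1
    across metres), the 0-1 m layer held at the shallowest value, and an
    ``n_depths`` coverage column.  Dates with fewer than ``min_depths``
    rates available are reported missing.
    """
    out_rows = []
    for (date, method), grp in per_depth_rates.groupby(["date", "method"]):
        row = {"date": date, "method": method, "scope": "integrated"}
        for col in ("cr_um_d", "ncp_um_d", "gpp_um_d"):
            sub = grp[["depth_m", col]].dropna().sort_values("depth_m")
            if len(sub) < min_depths:
                row[col.replace("_um_d", "_mmol_m2_d")] = np.nan
                continue
            row[col.replace("_um_d", "_mmol_m2_d")] = integrate_profile(
                sub["depth_m"].to_numpy(), sub[col].to_numpy())
        row["n_depths"] = int(grp[["cr_um_d", "ncp_um_d"]]
                              .notna().any(axis=1).sum())
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def flux_contribution(integrated_ncp_mmol_m2_d: pd.Series,
                      flux_mmol_m2_d: pd.Series):
    """Percent contribution of air-water flux to the daily rate signal.

    100 * |F| / (|F| + |integrated biological rate|) per date, plus the
    mean/median summary across dates.  Inputs are aligned on their date
    index; dates missing either series are dropped.
    """
    frame = pd.DataFrame({"bdo": integrated_ncp_mmol_m2_d,
                          "flux": flux_mmol_m2_d}).dropna()
    denom = frame["flux"].abs() + frame["bdo"].abs()
    pct = 100.0 * frame["flux"].abs() / denom
    pct.name = "flux_pct"
    summary = {"mean_pct": float(pct.mean()), "median_pct": float(pct.median())}
    return pct, summary


def rates_all_methods(series: SensorSeries,
                      flux_um_d: pd.Series | None = None,
                      methods=("bdo", "slope", "ssa_slope")) -> pd.DataFrame:
    """Convenience wrapper stacking every requested estimator for one
    depth into a single long table."""
    parts = []
    for m in methods:
        if m == "bdo":
            parts.append(bdo_rates(series, flux_um_d))
        elif m == "slope":
            parts.append(slope_rates(series))
        elif m == "ssa_slope":
            parts.append(ssa_slope_rates(series))
        else:
            raise ValueError(f"unknown method {m!r}")
    return pd.concat(parts, ignore_index=True)
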