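"""Water-column oxygen structure: depth integrals, day-to-day change,
suboxic-zone depth and percent saturation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as c
from .gas_exchange import do_saturation
from .types import SensorSeries

__all__ = ["integrate_profile", "delta_do", "suboxic_depth",
           "percent_saturation", "structure_table", "SuboxicDepth"]


def integrate_profile(depths_m, values) -> float:
    """Trapezoidal depth integral of a profile, per m^2 of lake surface.

    The 0 m -> shallowest-sensor layer is held constant at the shallowest
    value, so a profile in uM (mmol m^-3) integrates to mmol m^-2.  Exact
    for any piecewise-linear profile by construction.
    """
    d = np.asarray(depths_m, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least two depths")
    if np.any(np.diff(d) <= 0):
        order = np.argsort(d)
        d, v = d[order], v[order]
    return float(v[0] * d[0] + np.trapezoid(v, d))


def delta_do(daily: pd.DataFrame) -> pd.DataFrame:
    """Day-to-day change in daily-mean DO, per depth.

    ``daily`` is long-format (date, depth_m, do_um).  ddo(d) =
    do(d) - do(d-1); missing whenever either day is missing or the dates
    are not consecutive.
    """
    out = []
    for depth, grp in daily.groupby("depth_m"):
        grp = grp.sort_values("date")
        step = grp["date"].diff().dt.days
        ddo = grp["do_um"].diff().where(step == 1)
        out.append(pd.DataFrame({"date": grp["date"], "depth_m": depth,
                                 "ddo_um_d": ddo}))
    return pd.concat(out, ignore_index=True)


@dataclass
class SuboxicDepth:
    depth_m: float
    extrapolated: bool


def suboxic_depth(depths_m, do_um,
                  threshold_um: float = c.SUBOXIC_THRESHOLD_UM,
                  cap_m: float = c.SUBOXIC_DEPTH_CAP_M,
                  floor_m: float = c.SUBOXIC_DEPTH_FLOOR_M) -> SuboxicDepth:
    """Depth at which DO first falls to the suboxic threshold (20 uM).

    A linear spline through the (depth, DO) points is solved for its
    shallowest downward crossing of the threshold.  If the whole profile
    sits above the threshold, the deepest segment is extrapolated downward
    (flagged, capped); if the whole profile sits below it, the shallowest
    segment is extrapolated upward (flagged, floored at the surface).
    Extrapolation beyond the sensor span can overestimate the true depth
    and is therefore always flagged.
    """
    d = np.asarray(depths_m, dtype=float)
    v = np.asarray(do_um, dtype=float)
    keep = ~np.isnan(v)
    d, v = d[keep], v[keep]
    if len(d) < 2:
        raise ValueError("need at least two depths with DO values")
    order = np.argsort(d)
    d, v = d[order], v[order]

    # interior downward crossings, shallowest first
    for i in range(len(d) - 1):
        hi, lo = v[i], v[i + 1]
        if hi >= threshold_um >= lo and hi != lo:
            z = d[i] + (hi - threshold_um) / (hi - lo) * (d[i + 1] - d[i])
            return SuboxicDepth(float(z), False)
        if hi == threshold_um == lo:
            return SuboxicDepth(float(d[i]), False)
    # on-node hit not bracketed by a descending segment
    at = np.flatnonzero(v == threshold_um)
    if at.size:
        return SuboxicDepth(float(d[at[0]]), False)

    if v[-1] > threshold_um:          # oxygenated to the deepest sensor
        slope = (v[-1] - v[-2]) / (d[-1] - d[-2])
        if slope >= 0:
            return SuboxicDepth(float(cap_m), True)
        z = d[-1] + (threshold_um - v[-1]) / slope
        return SuboxicDepth(float(min(z, cap_m)), True)
    # suboxic above the shallowest sensor
    slope = (v[1] - v[0]) / (d[1] - d[0])
    if slope >= 0:
        return SuboxicDepth(float(floor_m), True)
    z = d[0] + (threshold_um - v[0]) / slope
    return SuboxicDepth(float(max(z, floor_m)), True)


def percent_saturation(series: SensorSeries, salinity: float,
                       elevation_m: float = 0.0) -> pd.Series:
    """Percent DO saturation per record: 100 * DO / DOsat(T, S,
    elevation)."""
    sat = do_saturation(series.data["temp_c"].to_numpy(), salinity,
                        elevation_m)
    pct = 100.0 * series.data["do_um"].to_numpy() / sat
    return pd.Series(pct, index=series.data.index, name="pct_saturation")


def structure_table(daily: pd.DataFrame,
                    threshold_um: float = c.SUBOXIC_THRESHOLD_UM) -> pd.DataFrame:
    """Per-date water-column descriptors from long-format daily means.

    Returns one row per date with integrated DO (mmol m^-2), integrated
    temperature (degC m), integrated ddo (mmol m^-2 d^-1), suboxic depth
    (m) and its extrapolation flag.
    """
    ddo = delta_do(daily)
    daily = daily.merge(ddo, on=["date", "depth_m"], how="left")
    rows = []
    for date, grp in daily.groupby("date"):
        grp = grp.sort_values("depth_m")
        row = {"date": date}
        prof = grp.dropna(subset=["do_um"])
        if len(prof) >= 2:
            row["do_mmol_m2"] = integrate_profile(prof["depth_m"], prof["do_um"])
            sub = suboxic_depth(prof["depth_m"], prof["do_um"], threshold_um)
            row["suboxic_depth_m"] = sub.depth_m
            row["suboxic_extrapolated"] = sub.extrapolated
        temp = grp.dropna(subset=["temp_c"])
        if len(temp) >= 2:
            row["temp_c_m"] = integrate_profile(temp["depth_m"], temp["temp_c"])
        dprof = grp.dropna(subset=["ddo_um_d"])
        if len(dprof) >= 2:
            row["ddo_mmol_m2_d"] = integrate_profile(dprof["depth_m"],
                                                     dprof["ddo_um_d"])
        rows.append(row)
    out = pd.DataFrame(rows)
    return out
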