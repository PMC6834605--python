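"""Reading, quality screening and daily averaging of input series.

Two sensor-file dialects are understood: ``canonical`` (ISO timestamps,
DO already in uM) and ``minidot`` (logger-style export with Unix time,
battery voltage and DO in mg/L).  All downstream code consumes
:class:`~oxymetab.types.SensorSeries`; daily statistics use the
05:00 -> 05:00 metabolic day with an 80% coverage requirement.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import constants as c
from .seawater import salinity_correction_factor
from .types import SalinityProfile, SensorSeries

log = logging.getLogger(__name__)

WIND_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

_CANONICAL_COLS = ["timestamp", "do_um", "temp_c"]
_MINIDOT_COLS = ["unix_timestamp", "utc_datetime", "battery_v",
                 "temperature_c", "do_mg_l", "quality"]


# ---------------------------------------------------------------------------
# sensor files


def read_sensor(path, dialect: str = "canonical",
                depth_m: float = np.nan, cadence_min: int = 10) -> SensorSeries:
    """Parse one sensor export into a :class:`SensorSeries`.

    Malformed rows are logged and dropped; duplicated timestamps keep the
    first occurrence with a warning.  DO in a ``minidot`` file is converted
    from mg/L to uM (x 1000/31.998).
    """
    if dialect not in ("canonical", "minidot"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"unparseable sensor file {path}: {exc}") from exc
    raw.columns = [str(col).strip().lower() for col in raw.columns]

    if dialect == "canonical":
        missing = set(_CANONICAL_COLS) - set(raw.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        ts = pd.to_datetime(raw["timestamp"], errors="coerce")
        do = pd.to_numeric(raw["do_um"], errors="coerce")
        temp = pd.to_numeric(raw["temp_c"], errors="coerce")
    else:
        missing = {"utc_datetime", "temperature_c", "do_mg_l"} - set(raw.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        ts = pd.to_datetime(raw["utc_datetime"], errors="coerce")
        do = pd.to_numeric(raw["do_mg_l"], errors="coerce") * c.MG_L_TO_UM_O2
        temp = pd.to_numeric(raw["temperature_c"], errors="coerce")

    frame = pd.DataFrame({"do_um": do.values, "temp_c": temp.values},
                         index=pd.DatetimeIndex(ts, name="timestamp"))
    bad = frame.index.isna() | frame["do_um"].isna() | (frame["do_um"] < 0)
    if bad.any():
        log.warning("%s: dropping %d malformed rows", path, int(bad.sum()))
        frame = frame[~bad]
    dup = frame.index.duplicated(keep="first")
    if dup.any():
        log.warning("%s: dropping %d duplicated timestamps", path, int(dup.sum()))
        frame = frame[~dup]
    frame = frame.sort_index()
    if len(frame) < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows")
    return SensorSeries(depth_m=depth_m, data=frame, cadence_min=cadence_min,
                        provenance=f"{path}|{dialect}")


def write_sensor(series: SensorSeries, path) -> None:
    """Write a series in the canonical dialect (lossless round-trip to
    6 significant digits)."""
    out = series.data.reset_index()
    out.columns = _CANONICAL_COLS
    out.to_csv(path, index=False, float_format="%.6g",
               date_format="%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------------------
# salinity


def read_salinity_profiles(path) -> list[SalinityProfile]:
    """Read ``date,depth_m,salinity`` rows (one file, many dates); rows
    sharing (date, depth) — e.g. two sampling sites — are averaged."""
    raw = pd.read_csv(path, parse_dates=["date"])
    mean = raw.groupby(["date", "depth_m"])["salinity"].mean().reset_index()
    profiles = []
    for date, grp in mean.groupby("date"):
        profiles.append(SalinityProfile(
            date=date,
            salinity_by_depth=dict(zip(grp["depth_m"], grp["salinity"]))))
    return sorted(profiles, key=lambda p: p.date)


def salinity_correct(series: SensorSeries,
                     profiles: list[SalinityProfile]) -> SensorSeries:
    """Apply the Garcia-Gordon salinity compensation to each DO record.

    Each record uses the salinity from the most recent profile dated on or
    before it; records before the first profile fall back to the earliest
    profile (with a warning).
    """
    profiles = sorted(profiles, key=lambda p: p.date)
    sal_values = []
    for p in profiles:
        if series.depth_m in p.salinity_by_depth:
            sal_values.append((p.date, p.salinity_by_depth[series.depth_m]))
    if not sal_values:
        raise ValueError(f"no profile covers depth {series.depth_m} m")
    dates = pd.DatetimeIndex([d for d, _ in sal_values])
    sals = np.array([s for _, s in sal_values])
    idx = dates.searchsorted(series.data.index, side="right") - 1
    if (idx < 0).any():
        log.warning("records precede the first salinity profile; using the "
                    "earliest profile for them")
        idx = np.clip(idx, 0, None)
    s_per_record = sals[idx]
    factor = salinity_correction_factor(series.data["temp_c"].to_numpy(),
                                        s_per_record)
    return series.replace_do(series.data["do_um"].to_numpy() * factor)


# ---------------------------------------------------------------------------
# daily statistics


def _metabolic_date(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Calendar date of the 05:00 -> 05:00 window each record falls in."""
    return (index - pd.Timedelta(hours=c.DAY_START_HOUR)).normalize()


def daily_average(series: SensorSeries,
                  coverage_min: float = c.COVERAGE_MIN) -> pd.DataFrame:
    """Daily mean DO and temperature over 05:00 -> 05:00 windows.

    Windows covering less than ``coverage_min`` of the expected record
    count are reported as missing (NaN).  Returns a DataFrame indexed by
    date with columns ``do_um``, ``temp_c``, ``coverage``.
    """
    expected = 24 * 60 / series.cadence_min
    grouper = _metabolic_date(series.data.index)
    agg = series.data.groupby(grouper).agg(
        do_um=("do_um", "mean"), temp_c=("temp_c", "mean"),
        n=("do_um", "size"))
    agg["coverage"] = agg.pop("n") / expected
    low = agg["coverage"] < coverage_min
    agg.loc[low, ["do_um", "temp_c"]] = np.nan
    # dates whose whole window fell in a gap appear as missing rows
    full = pd.date_range(agg.index.min(), agg.index.max(), freq="D")
    agg = agg.reindex(full)
    agg["coverage"] = agg["coverage"].fillna(0.0)
    agg.index.name = "date"
    return agg


def daily_series(series_list: list[SensorSeries],
                 coverage_min: float = c.COVERAGE_MIN) -> pd.DataFrame:
    """Long-format daily means for several depths: one row per
    (date, depth_m)."""
    frames = []
    for s in series_list:
        f = daily_average(s, coverage_min).reset_index()
        f.insert(1, "depth_m", s.depth_m)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def bin_wind_direction(directions_deg) -> np.ndarray:
    """Bin compass directions into 8 sectors of 45 deg centred on
    N, NE, ..., NW.

    Each sector is the half-open interval (centre - 22.5, centre + 22.5]
    so a shared boundary belongs to the sector it closes (337.5 -> NW,
    22.5 -> N).
    """
    d = np.asarray(directions_deg, dtype=float)
    if np.any((d < 0) | (d >= 360)):
        raise ValueError("directions must lie in [0, 360)")
    idx = np.ceil((d - 22.5) / 45.0).astype(int) % 8
    return np.array(WIND_SECTORS, dtype=object)[idx]


# ---------------------------------------------------------------------------
# driver files


def read_weather(path) -> pd.DataFrame:
    """GHCN-Daily-style extract: ``date,prcp_mm,tavg_c``."""
    raw = pd.read_csv(path, parse_dates=["date"]).set_index("date")
    out = raw.rename(columns={"prcp_mm": "precip_mm", "tavg_c": "air_temp_c"})
    if (out["precip_mm"].dropna() < 0).any():
        raise ValueError("negative precipitation")
    return out[["precip_mm", "air_temp_c"]]


def read_ssh(path) -> pd.DataFrame:
    """Daily sea-level text: ``date,ssh_m``."""
    return pd.read_csv(path, parse_dates=["date"]).set_index("date")[["ssh_m"]]


def read_mei(path) -> pd.Series:
    """MEI table, one row per year with 12 monthly columns; returned as a
    monthly series."""
    raw = pd.read_csv(path)
    year_col = raw.columns[0]
    long = raw.melt(id_vars=[year_col], var_name="month", value_name="mei")
    long["month"] = long["month"].astype(int)
    idx = pd.PeriodIndex.from_fields(year=long[year_col],
                                     month=long["month"], freq="M")
    return pd.Series(long["mei"].to_numpy(), index=idx).sort_index().dropna()


def read_wind(path, anemometer_height_m: float = 3.0) -> pd.DataFrame:
    """15-minute wind records ``timestamp,wind_ms,wind_dir_deg``; speeds are
    converted to 10 m and averaged over the metabolic day."""
    from .gas_exchange import wind_to_10m

    raw = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    raw["u10_ms"] = wind_to_10m(raw["wind_ms"].to_numpy(), anemometer_height_m)
    grouper = _metabolic_date(raw.index)
    daily = raw.groupby(grouper).agg(
        u10_ms=("u10_ms", "mean"), wind_dir_deg=("wind_dir_deg", "mean"))
    daily.index.name = "date"
    return daily


def build_env_table(weather: pd.DataFrame | None = None,
                    ssh: pd.DataFrame | None = None,
                    mei: pd.Series | None = None,
                    wind: pd.DataFrame | None = None) -> pd.DataFrame:
    """Outer-join daily driver inputs into one table (monthly MEI repeated
    per day)."""
    parts = [p for p in (weather, ssh, wind) if p is not None]
    if not parts:
        raise ValueError("no driver inputs")
    table = parts[0]
    for p in parts[1:]:
        table = table.join(p, how="outer")
    if mei is not None:
        table["mei"] = mei.reindex(table.index.to_period("M")).to_numpy()
    table.index.name = "date"
    return table
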