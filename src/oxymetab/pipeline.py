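"""End-to-end orchestration: simulate -> ingest -> flux -> rates ->
structure -> drivers, with a manifest and a static report.

A run is driven by a :class:`RunConfig` (YAML-serialisable).  Outputs are
delimited text; the manifest records the package version, seed, config
hash and per-stage row counts so a rerun with the same config reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, constants as c
from . import driver_stats as ds
from . import env_io, metabolism as mb, structure as st
from .gas_exchange import do_saturation, k_cm_h_to_m_d, k_o2
from .synthetic import LakeScenario, demo_scenario, simulate_drivers, simulate_lake

log = logging.getLogger(__name__)

VALID_METHODS = ("bdo", "slope", "ssa_slope")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, with study defaults."""

    scenario: LakeScenario = field(default_factory=demo_scenario)
    methods: tuple[str, ...] = VALID_METHODS
    suboxic_threshold_um: float = c.SUBOXIC_THRESHOLD_UM
    coverage_min: float = c.COVERAGE_MIN
    granger_alpha: float = c.GRANGER_ALPHA
    ews_window_fraction: float = c.EWS_WINDOW_FRACTION
    brt_predictors: tuple[str, ...] = ("mei", "ssh_m", "precip_mm", "u10_ms",
                                       "air_temp_c")
    brt_response: str = "do_mmol_m2"
    run_brt: bool = True
    seed: int = 0
    out_dir: str = "oxymetab_run"

    def validate(self) -> None:
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from "
                                 f"{VALID_METHODS}")
        self.scenario.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"] = self.scenario.to_dict()
        d["methods"] = list(self.methods)
        d["brt_predictors"] = list(self.brt_predictors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scenario" in d:
            d["scenario"] = LakeScenario.from_dict(d["scenario"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "brt_predictors" in d:
            d["brt_predictors"] = tuple(d["brt_predictors"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path, manifest: dict, stage: str,
           index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format="%.8g")
    manifest["stages"][stage] = {"path": path.name, "rows": int(len(frame))}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on the configured scenario; returns the
    manifest (also written to ``manifest.json`` in the output directory).
    """
    config.validate()
    config.scenario.seed = config.seed
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(), "stages": {}}
    config.to_yaml(out / "config.yaml")

    # -- simulate -----------------------------------------------------------
    series_list, truth = simulate_lake(config.scenario)
    drivers = simulate_drivers(config.scenario)
    for s in series_list:
        env_io.write_sensor(s, out / f"sensor_{s.depth_m:g}m.csv")
    _write(truth, out / "truth.csv", manifest, "simulate")
    _write(drivers.reset_index(), out / "drivers.csv", manifest, "drivers_in")

    # -- ingest: daily means ------------------------------------------------
    daily = env_io.daily_series(series_list, config.coverage_min)
    pct = []
    for s in series_list:
        sat = st.percent_saturation(s, config.scenario.salinity,
                                    config.scenario.elevation_m)
        day = sat.groupby(env_io._metabolic_date(sat.index)).mean()
        pct.append(pd.DataFrame({"date": day.index, "depth_m": s.depth_m,
                                 "pct_saturation": day.to_numpy()}))
    daily = daily.merge(pd.concat(pct, ignore_index=True),
                        on=["date", "depth_m"], how="left")
    _write(daily, out / "daily.csv", manifest, "ingest")

    # -- flux ---------------------------------------------------------------
    top = series_list[0]
    u10_daily = drivers["u10_ms"]
    u10 = u10_daily.reindex(top.data.index.normalize()).to_numpy()
    k_md = k_cm_h_to_m_d(k_o2(top.data["temp_c"].to_numpy(),
                              config.scenario.salinity, u10))
    sat = do_saturation(top.data["temp_c"].to_numpy(),
                        config.scenario.salinity,
                        config.scenario.elevation_m)
    flux = pd.DataFrame({
        "flux_mmol_m2_d": -k_md * (top.data["do_um"].to_numpy() - sat),
        "k_o2_m_d": k_md, "do_sat_um": sat}, index=top.data.index)
    _write(flux.reset_index(), out / "flux.csv", manifest, "flux")

    # -- rates --------------------------------------------------------------
    column_depth = max(s.depth_m for s in series_list)
    flux_um_d = flux["flux_mmol_m2_d"] / column_depth
    per_depth = []
    for s in series_list:
        f = flux_um_d if (config.scenario.flux_coupling
                          and "bdo" in config.methods) else None
        per_depth.append(mb.rates_all_methods(s, f, config.methods))
    rates = pd.concat(per_depth, ignore_index=True)
    integrated = mb.integrate_rates(rates)
    _write(rates, out / "rates.csv", manifest, "rates")
    _write(integrated, out / "rates_integrated.csv", manifest,
           "rates_integrated")
    if config.scenario.flux_coupling and "bdo" in config.methods:
        bdo_int = integrated[integrated["method"] == "bdo"].set_index("date")
        daily_flux = (flux["flux_mmol_m2_d"]
                      .groupby(env_io._metabolic_date(flux.index)).mean())
        pct_flux, summary = mb.flux_contribution(bdo_int["ncp_mmol_m2_d"],
                                                 daily_flux)
        table = pct_flux.reset_index().rename(columns={"index": "date"})
        table.attrs.update(summary)
        _write(table.assign(**summary), out / "flux_contribution.csv",
               manifest, "flux_contribution")

    # -- structure ----------------------------------------------------------
    struct = st.structure_table(daily, config.suboxic_threshold_um)
    _write(struct, out / "structure.csv", manifest, "structure")

    # -- driver statistics --------------------------------------------------
    merged = _merge_daily(struct, integrated, drivers, config.methods[0])
    merged.to_csv(out / "merged_daily.csv", index=False, float_format="%.8g")
    stats_out = _driver_stage(merged, config)
    _write(stats_out["screen"], out / "regression_screen.csv", manifest,
           "screen")
    _write(stats_out["granger"], out / "granger.csv", manifest, "granger")
    _write(stats_out["ews"], out / "ews.csv", manifest, "ews")
    if stats_out.get("brt") is not None:
        _write(stats_out["brt"], out / "brt_influence.csv", manifest, "brt")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _merge_daily(struct: pd.DataFrame, integrated: pd.DataFrame,
                 drivers: pd.DataFrame, method: str) -> pd.DataFrame:
    rates = integrated[integrated["method"] == method]
    merged = struct.merge(
        rates[["date", "cr_mmol_m2_d", "ncp_mmol_m2_d", "gpp_mmol_m2_d"]],
        on="date", how="left")
    return merged.merge(drivers.reset_index(), on="date", how="left")


def _driver_stage(merged: pd.DataFrame, config: RunConfig) -> dict:
    out: dict = {}
    predictors = [p for p in ("mei", "ssh_m", "precip_mm", "u10_ms",
                              "air_temp_c")
                  if merged[p].notna().any()]
    out["screen"] = ds.ols_screen(merged, "do_mmol_m2", predictors,
                                  config.granger_alpha)
    granger_rows = []
    for cause in ("u10_ms", "ncp_mmol_m2_d"):
        for effect in ("do_mmol_m2", "suboxic_depth_m"):
            try:
                g = ds.granger_lag1(merged.set_index("date")[cause],
                                    merged.set_index("date")[effect],
                                    config.granger_alpha)
                granger_rows.append(g.__dict__ | {"cause": cause,
                                                  "effect": effect})
            except ValueError as exc:
                log.warning("granger %s->%s skipped: %s", cause, effect, exc)
    out["granger"] = pd.DataFrame(granger_rows)
    ews = ds.rolling_ews(merged.set_index("date")["do_mmol_m2"],
                         config.ews_window_fraction)
    out["ews"] = ews.table.reset_index()

    out["brt"] = None
    if config.run_brt:
        try:
            brt = ds.brt_fit(merged, config.brt_response,
                             list(config.brt_predictors),
                             seed=config.seed)
            out["brt"] = (brt.relative_influence.rename_axis("predictor")
                          .reset_index()
                          .assign(pct_variation=brt.pct_variation))
        except ValueError as exc:
            log.warning("BRT stage skipped: %s", exc)
    return out


# ---------------------------------------------------------------------------
# report


def make_report(run_dir, out_name: str = "report") -> list[str]:
    """Render static summary panels for a completed run.

    One PNG per available stage output: DO/temperature depth-time fields,
    integrated DO and suboxic depth, daily rates (with truth overlay when
    the run is synthetic), driver series, and rolling early-warning
    statistics.  Stages absent from the run directory are skipped without
    error.  Returns the list of files written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    written: list[str] = []

    def _save(fig, name):
        path = run_dir / f"{out_name}_{name}.png"
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(str(path))

    daily_p = run_dir / "daily.csv"
    if daily_p.exists():
        daily = pd.read_csv(daily_p, parse_dates=["date"])
        for col, label in (("do_um", "DO (uM)"), ("temp_c", "T (degC)")):
            wide = daily.pivot(index="depth_m", columns="date", values=col)
            fig, ax = plt.subplots(figsize=(8, 2.6))
            mesh = ax.pcolormesh(wide.columns, wide.index, wide.values,
                                 shading="nearest")
            ax.invert_yaxis()
            ax.set_ylabel("depth (m)")
            fig.colorbar(mesh, ax=ax, label=label)
            _save(fig, col)

    struct_p = run_dir / "structure.csv"
    if struct_p.exists():
        struct = pd.read_csv(struct_p, parse_dates=["date"])
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
        axes[0].plot(struct["date"], struct["do_mmol_m2"])
        axes[0].set_ylabel("integrated DO\n(mmol m$^{-2}$)")
        axes[1].plot(struct["date"], struct["suboxic_depth_m"])
        axes[1].invert_yaxis()
        axes[1].set_ylabel("suboxic depth (m)")
        _save(fig, "structure")

    rates_p = run_dir / "rates.csv"
    if rates_p.exists():
        rates = pd.read_csv(rates_p, parse_dates=["date"])
        truth_p = run_dir / "truth.csv"
        truth = (pd.read_csv(truth_p, parse_dates=["date"])
                 if truth_p.exists() else None)
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
        for ax, col, tcol in zip(axes, ("ncp_um_d", "gpp_um_d", "cr_um_d"),
                                 ("ncp_true", "gpp_true", "cr_true")):
            for (depth, method), grp in rates.groupby(["depth_m", "method"]):
                ax.plot(grp["date"], grp[col], lw=0.8,
                        label=f"{depth:g} m {method}")
            if truth is not None:
                for depth, grp in truth.groupby("depth_m"):
                    ax.plot(grp["date"], grp[tcol], "k--", lw=1.0)
            ax.set_ylabel(col.replace("_um_d", " (uM/d)"))
        axes[0].legend(fontsize=6, ncol=3)
        _save(fig, "rates")

    drv_p = run_dir / "drivers.csv"
    if drv_p.exists():
        drv = pd.read_csv(drv_p, parse_dates=["date"])
        cols = [x for x in ("ssh_m", "u10_ms", "precip_mm", "mei")
                if x in drv.columns]
        fig, axes = plt.subplots(len(cols), 1, sharex=True,
                                 figsize=(8, 1.8 * len(cols)))
        for ax, col in zip(np.atleast_1d(axes), cols):
            ax.plot(drv["date"], drv[col], lw=0.8)
            ax.set_ylabel(col)
        _save(fig, "drivers")

    ews_p = run_dir / "ews.csv"
    if ews_p.exists():
        ews = pd.read_csv(ews_p, parse_dates=["date"])
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 4))
        axes[0].plot(ews["date"], ews["variance"])
        axes[0].set_ylabel("rolling variance")
        axes[1].plot(ews["date"], ews["autocorr_lag1"])
        axes[1].set_ylabel("rolling AC(1)")
        _save(fig, "ews")

    brt_p = run_dir / "brt_influence.csv"
    if brt_p.exists():
        brt = pd.read_csv(brt_p)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.barh(brt["predictor"], brt["relative_influence"])
        ax.set_xlabel("relative influence (%)")
        _save(fig, "brt")

    return written
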