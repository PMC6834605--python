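"""Rate estimators: BDO sums, dark-window slopes, SSA detiding,
depth integration and flux bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from conftest import clean_scenario, make_series
from oxymetab import metabolism as mb
from oxymetab.synthetic import DepthSpec, simulate_lake


def _day_index(start="2016-03-01 05:00", days=1, cadence=10):
    n = int(days * 24 * 60 / cadence) + 1
    return pd.date_range(start, periods=n, freq=f"{cadence}min")


class TestBDO:
    def test_constant_night_decline(self):
        """0.5 uM lost per 10-min step all night: dark sum -30 uM scales
        to CR = -72 uM/d (oracle: -30 * 24/10)."""
        idx = pd.date_range("2016-03-01 19:00", periods=61, freq="10min")
        do = 200.0 - 0.5 * np.arange(61)
        rates = mb.bdo_rates(make_series(idx, do)).set_index("date")
        assert rates.loc["2016-03-01", "cr_um_d"] == pytest.approx(-72.0)

    def test_ncp_telescopes_to_zero(self):
        idx = _day_index(days=2)
        do = 150.0 + 10 * np.sin(2 * np.pi * np.arange(len(idx)) / 144.0)
        rates = mb.bdo_rates(make_series(idx, do)).set_index("date")
        assert rates.loc["2016-03-01", "ncp_um_d"] == pytest.approx(0.0,
                                                                    abs=1e-9)

    def test_gpp_missing_when_do_rose_overnight(self):
        idx = _day_index(days=2)
        do = 150.0 + 0.1 * np.arange(len(idx))      # monotone rise
        rates = mb.bdo_rates(make_series(idx, do)).set_index("date")
        row = rates.loc["2016-03-01"]
        assert row["cr_um_d"] > 0
        assert np.isnan(row["gpp_um_d"])
        assert row["ncp_um_d"] > 0

    def test_increment_across_gap_discarded(self):
        idx = _day_index(days=1)
        do = np.full(len(idx), 150.0)
        keep = (idx < "2016-03-01 20:00") | (idx >= "2016-03-02 00:00")
        do2 = do[keep].copy()
        do2[idx[keep] >= "2016-03-02 00:00"] += 500.0   # jump across the gap
        rates = mb.bdo_rates(make_series(idx[keep], do2)).set_index("date")
        # the 500-uM jump spans the gap and must not enter the sums;
        # the night itself is below coverage, so CR is missing not wild
        assert np.isnan(rates.loc["2016-03-01", "cr_um_d"])

    def test_flux_removal_recovers_biology(self):
        """Adding a constant artificial flux to the DO record and handing
        the same flux series back yields the original rates."""
        sc = clean_scenario(days=6, depths=[DepthSpec(1.0, 100.0, -80.0,
                                                      200.0)])
        series, truth = simulate_lake(sc)
        s = series[0]
        flux_um_d = pd.Series(24.0, index=s.data.index)  # 1 uM per hour
        contaminated = s.replace_do(
            s.data["do_um"].to_numpy()
            + np.arange(len(s)) * (24.0 * 10 / (60 * 24)))
        rates = mb.bdo_rates(contaminated, flux_um_d).set_index("date")
        good = rates.dropna(subset=["cr_um_d", "ncp_um_d"])
        assert np.allclose(good["ncp_um_d"], 20.0, atol=1e-8)
        assert np.allclose(good["cr_um_d"], -80.0, atol=1e-8)

    def test_cadence_guard(self):
        idx = pd.date_range("2016-03-01", periods=48, freq="90min")
        with pytest.raises(ValueError, match="cadence"):
            mb.bdo_rates(make_series(idx, np.full(48, 150.0), cadence=90))


class TestSlope:
    def test_linear_night_slope(self):
        """DO falling at exactly 2 uM/h all night gives CR = -48 uM/d
        (oracle: closed-form OLS on a noiseless line)."""
        idx = pd.date_range("2016-03-01 19:00", periods=61, freq="10min")
        hours = np.arange(61) / 6.0
        rates = mb.slope_rates(make_series(idx, 200.0 - 2.0 * hours))
        rates = rates.set_index("date")
        assert rates.loc["2016-03-01", "cr_um_d"] == pytest.approx(-48.0)

    def test_constant_day_all_zero(self):
        idx = _day_index(days=2)
        rates = mb.slope_rates(make_series(idx, np.full(len(idx), 150.0)))
        row = rates.set_index("date").loc["2016-03-01"]
        assert row["cr_um_d"] == pytest.approx(0.0, abs=1e-9)
        assert row["ncp_um_d"] == pytest.approx(0.0, abs=1e-9)
        assert row["gpp_um_d"] == pytest.approx(0.0, abs=1e-9)

    def test_gpp_is_definitional_sum(self, clean_bundle):
        _, series, _ = clean_bundle
        rates = mb.slope_rates(series[0]).dropna(
            subset=["cr_um_d", "ncp_um_d", "gpp_um_d"])
        assert np.allclose(rates["gpp_um_d"],
                           rates["ncp_um_d"] + rates["cr_um_d"].abs())

    def test_low_coverage_night_missing(self):
        idx = pd.date_range("2016-03-01 19:00", periods=30, freq="10min")
        rates = mb.slope_rates(make_series(idx, np.linspace(200, 190, 30)))
        assert np.isnan(rates.set_index("date").loc["2016-03-01", "cr_um_d"])


class TestNoiselessRecovery:
    """On tide- and noise-free input the estimators recover the truth
    exactly where their assumptions hold (BDO CR/NCP, slope CR); the
    24-h OLS slope for NCP carries the analytically known diel-shape
    bias cov(t, diel)/var(t)."""

    def test_bdo_and_slope_cr_exact(self, clean_bundle):
        _, series, truth = clean_bundle
        for s in series:
            t = truth[truth.depth_m == s.depth_m].iloc[0]
            bdo = mb.bdo_rates(s).dropna(subset=["cr_um_d", "ncp_um_d"])
            slp = mb.slope_rates(s).dropna(subset=["cr_um_d"])
            assert np.allclose(bdo["cr_um_d"], t["cr_true"], atol=1e-8)
            assert np.allclose(bdo["ncp_um_d"], t["ncp_true"], atol=1e-8)
            assert np.allclose(slp["cr_um_d"], t["cr_true"], atol=1e-6)

    def test_slope_ncp_carries_known_diel_bias(self, clean_bundle):
        """The one-period OLS slope equals NCP_true plus the covariance
        of time with the diel cycle (oracle: direct OLS on the noiseless
        signal), an inherent property of the 24-h slope estimator."""
        _, series, truth = clean_bundle
        s = series[0]
        t = truth[truth.depth_m == s.depth_m].iloc[0]
        slp = mb.slope_rates(s).dropna(subset=["ncp_um_d"])
        do = s.data["do_um"]
        win = do[(do.index >= "2016-03-03 05:00")
                 & (do.index < "2016-03-04 05:00")]
        tt = (win.index.asi8 / (1e9 * 86400.0))
        oracle = np.polyfit(tt - tt.mean(), win.to_numpy(), 1)[0]
        assert np.allclose(slp["ncp_um_d"], oracle, atol=1e-6)
        assert oracle > t["ncp_true"]        # bias is upward for this shape

    def test_method_disagreement_grows_with_noise(self):
        """CR disagreement between slope and BDO is zero on noiseless
        input and increases along a seeded noise ladder."""
        gaps = []
        for sd in (0.0, 2.0, 5.0):
            sc = clean_scenario(days=10,
                                depths=[DepthSpec(1.0, 100.0, -80.0, 200.0)],
                                noise_sd_um=sd, seed=7)
            series, _ = simulate_lake(sc)
            bdo = mb.bdo_rates(series[0]).set_index("date")["cr_um_d"]
            slp = mb.slope_rates(series[0]).set_index("date")["cr_um_d"]
            gaps.append((bdo - slp).abs().mean())
        assert gaps[0] == pytest.approx(0.0, abs=1e-8)
        assert gaps[0] < gaps[1] < gaps[2]


class TestSSA:
    def _sine_series(self, periods_h, amps, days=9, base=150.0):
        idx = pd.date_range("2016-03-01", periods=days * 144, freq="10min")
        t_h = np.arange(len(idx)) / 6.0
        do = base + sum(a * np.sin(2 * np.pi * t_h / p)
                        for p, a in zip(periods_h, amps))
        return make_series(idx, do), t_h

    def test_pure_diel_sinusoid_preserved(self):
        s, t_h = self._sine_series([24.0], [20.0])
        res = mb.ssa_reconstruct_diel(s)
        target = s.data["do_um"].to_numpy()
        r = np.corrcoef(res.series.data["do_um"], target)[0, 1]
        assert r > 0.99

    def test_tide_removed_diel_kept(self):
        s, t_h = self._sine_series([24.0, 12.42], [20.0, 20.0])
        res = mb.ssa_reconstruct_diel(s)
        recon = res.series.data["do_um"].to_numpy()
        diel = np.sin(2 * np.pi * t_h / 24.0)
        tide = np.sin(2 * np.pi * t_h / 12.42)
        assert abs(np.corrcoef(recon, diel)[0, 1]) > 0.95
        assert abs(np.corrcoef(recon, tide)[0, 1]) < 0.2

    def test_constant_input_constant_output(self):
        idx = pd.date_range("2016-03-01", periods=1000, freq="10min")
        s = make_series(idx, np.full(1000, 150.0))
        res = mb.ssa_reconstruct_diel(s)
        assert np.allclose(res.series.data["do_um"], 150.0, atol=1e-6)
        assert res.interpolated_fraction == 0.0

    def test_short_segment_rejected(self):
        idx = pd.date_range("2016-03-01", periods=500, freq="10min")
        with pytest.raises(ValueError, match="shorter"):
            mb.ssa_reconstruct_diel(make_series(idx, np.full(500, 1.0)))

    def test_interpolated_fraction_reported(self):
        sc = clean_scenario(days=9, noise_sd_um=1.0, tidal_amplitude_um=5.0,
                            gaps=[("2016-03-04 00:00", "2016-03-04 12:00")])
        series, _ = simulate_lake(sc)
        res = mb.ssa_reconstruct_diel(series[0])
        assert res.interpolated_fraction == pytest.approx(72 / (9 * 144),
                                                          rel=0.05)


class TestSSASlope:
    def test_tide_free_agrees_with_plain_slope(self):
        """With the passband widened to admit the diel harmonics, the SSA
        reconstruction preserves the night slope to within 10% of the
        plain slope estimate on tide-free input.  The default diel-only
        band (20-28 h) necessarily sheds the sub-diel harmonics of the
        non-sinusoidal daily cycle (they share the tidal band), so there
        it yields a deliberately smoothed CR instead."""
        sc = clean_scenario(days=9, depths=[DepthSpec(1.0, 120.0, -100.0,
                                                      200.0)],
                            noise_sd_um=0.5, seed=5)
        series, _ = simulate_lake(sc)
        slp = mb.slope_rates(series[0]).set_index("date")["cr_um_d"].dropna()

        def rel_diff(band):
            ssa = mb.ssa_slope_rates(series[0], band_h=band)
            ssa = ssa.set_index("date")["cr_um_d"]
            both = pd.concat([slp, ssa], axis=1, join="inner").dropna()
            return ((both.iloc[:, 0] - both.iloc[:, 1]).abs()
                    / both.iloc[:, 0].abs())

        assert (rel_diff((4.0, 28.0)) < 0.10).all()
        assert rel_diff((20.0, 28.0)).mean() < 0.35   # smoothed, not wild

    def test_all_missing_night_stays_missing(self):
        sc = clean_scenario(days=9, noise_sd_um=0.5,
                            gaps=[("2016-03-04 18:50", "2016-03-05 05:10")])
        series, _ = simulate_lake(sc)
        ssa = mb.ssa_slope_rates(series[0]).set_index("date")
        assert np.isnan(ssa.loc["2016-03-04", "cr_um_d"])
        assert np.isfinite(ssa.loc["2016-03-02", "cr_um_d"])


class TestIntegration:
    def _rates(self, values):
        return pd.DataFrame({
            "date": pd.Timestamp("2016-03-01"), "method": "bdo",
            "depth_m": [1.0, 6.0, 12.0],
            "cr_um_d": values, "ncp_um_d": values, "gpp_um_d": values})

    def test_constant_profile_is_column_depth_times_rate(self):
        out = mb.integrate_rates(self._rates([10.0, 10.0, 10.0]))
        assert out["ncp_mmol_m2_d"].iloc[0] == pytest.approx(120.0)

    def test_hand_trapezoid(self):
        # oracle: 0-1 m: 10, 1-6 m: 50, 6-12 m: 30 -> 90
        out = mb.integrate_rates(self._rates([10.0, 10.0, 0.0]))
        assert out["ncp_mmol_m2_d"].iloc[0] == pytest.approx(90.0)

    def test_missing_depth_degrades_with_flag(self):
        out = mb.integrate_rates(self._rates([10.0, np.nan, 0.0]))
        # remaining trapezoids: 0-1: 10, 1-12: 55 -> 65
        assert out["ncp_mmol_m2_d"].iloc[0] == pytest.approx(65.0)
        assert out["n_depths"].iloc[0] == 2

    def test_single_depth_is_missing(self):
        out = mb.integrate_rates(self._rates([10.0, np.nan, np.nan]))
        assert np.isnan(out["ncp_mmol_m2_d"].iloc[0])


class TestFluxContribution:
    def test_trivial_shares(self):
        dates = pd.date_range("2016-03-01", periods=3, freq="D")
        bdo = pd.Series([100.0, 100.0, -80.0], index=dates)
        flux = pd.Series([0.0, 100.0, 80.0], index=dates)
        pct, summary = mb.flux_contribution(bdo, flux)
        assert pct.iloc[0] == 0.0
        assert pct.iloc[1] == pytest.approx(50.0)
        assert pct.iloc[2] == pytest.approx(50.0)

    def test_summary_matches_brute_force_recomputation(self):
        """On a flux-coupled synthetic run the summary equals an
        independent re-summation of the daily series."""
        sc = clean_scenario(
            days=30, flux_coupling=True, noise_sd_um=0.5,
            tidal_amplitude_um=4.0,
            depths=[DepthSpec(1.0, 120.0, -119.0, 200.0),
                    DepthSpec(6.0, 100.0, -101.0, 160.0),
                    DepthSpec(12.0, 40.0, -40.0, 80.0)])
        series, truth = simulate_lake(sc)
        flux_daily = (truth.drop_duplicates("date")
                      .set_index("date")["flux_true_mmol_m2_d"])
        flux_um_d = flux_daily.reindex(
            series[0].data.index.normalize()).set_axis(series[0].data.index)
        per_depth = pd.concat(
            [mb.bdo_rates(s, flux_um_d.set_axis(s.data.index)
                          if len(s.data) == len(series[0].data) else
                          flux_daily.reindex(s.data.index.normalize())
                          .set_axis(s.data.index)) for s in series],
            ignore_index=True)
        integ = mb.integrate_rates(per_depth).set_index("date")
        pct, summary = mb.flux_contribution(integ["ncp_mmol_m2_d"],
                                            flux_daily)
        manual = 100 * flux_daily.abs() / (flux_daily.abs()
                                           + integ["ncp_mmol_m2_d"].abs())
        manual = manual.dropna()
        assert summary["mean_pct"] == pytest.approx(manual.mean(), rel=1e-9)
        assert summary["median_pct"] == pytest.approx(manual.median(),
                                                      rel=1e-9)


def test_anoxic_days_reported_missing_not_zero():
    sc = clean_scenario(days=8, depths=[DepthSpec(12.0, 0.0, 0.0, 0.5)],
                        noise_sd_um=0.0)
    series, _ = simulate_lake(sc)
    for fn in (mb.bdo_rates, mb.slope_rates):
        rates = fn(series[0]).set_index("date")
        mid = rates.loc["2016-03-04"]
        assert np.isnan(mid["cr_um_d"]) and np.isnan(mid["ncp_um_d"])
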