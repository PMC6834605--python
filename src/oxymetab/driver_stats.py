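"""Driver attribution: regression screen, Granger causality, rolling
early-warning statistics, and boosted regression trees.

The Granger test is the lag-1 nested-model F-test: y_t ~ y_{t-1} versus
y_t ~ y_{t-1} + x_{t-1}.  Boosted trees use squared-error gradient
boosting with the study defaults (363 trees, shrinkage 0.05, interaction
depth 3, bag fraction 0.7); relative influence is the normalised sum of
split improvements, and sensitivity curves sweep one predictor over its
range with the others fixed at their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from . import constants as c
from .seawater import density_eos  # noqa: F401  (public surface)

__all__ = ["ols_screen", "density_eos", "granger_lag1", "rolling_ews",
           "brt_fit", "RegressionResult", "GrangerResult", "EWSResult",
           "BRTResult"]


# ---------------------------------------------------------------------------
# regression screen


@dataclass
class RegressionResult:
    response: str
    predictor: str
    n: int
    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    significant: bool


def ols_screen(table: pd.DataFrame, response: str, predictors,
               alpha: float = c.GRANGER_ALPHA,
               bh_adjust: bool = False) -> pd.DataFrame:
    """Simple linear regression of the response on each predictor.

    Pairwise-complete observations; the sign of r is preserved.  Raw
    two-sided P-values are reported; an optional Benjamini-Hochberg
    column can be added (off by default, matching the raw-P reporting
    convention of the regression screen).
    """
    rows = []
    for pred in predictors:
        sub = table[[response, pred]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {pred!r}")
        x = sub[pred].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero-variance predictor {pred!r}")
        fit = stats.linregress(x, y)
        rows.append(RegressionResult(
            response, pred, len(sub), fit.slope, fit.intercept, fit.rvalue,
            fit.rvalue**2, fit.pvalue, fit.pvalue < alpha))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Granger causality (lag 1)


@dataclass
class GrangerResult:
    cause: str
    effect: str
    lag: int
    n: int
    f_stat: float
    p_value: float
    causal: bool


def granger_lag1(x: pd.Series, y: pd.Series,
                 alpha: float = c.GRANGER_ALPHA,
                 min_n: int = 30) -> GrangerResult:
    """Does x forecast y one day ahead?

    Nested-model F-test of ``y_t ~ y_{t-1} + x_{t-1}`` against
    ``y_t ~ y_{t-1}`` with (1, n-3) degrees of freedom, after listwise
    deletion across gaps.  The test is direction-specific.  Degenerate
    designs (x collinear with y, constant series) are rejected with an
    explanatory error.
    """
    frame = pd.DataFrame({"y": y, "yl": y.shift(1), "xl": x.shift(1)}).dropna()
    n = len(frame)
    if n < min_n:
        raise ValueError(f"only {n} complete triples; need >= {min_n}")
    yv = frame["y"].to_numpy(dtype=float)
    base = np.column_stack([np.ones(n), frame["yl"].to_numpy(dtype=float)])
    full = np.column_stack([base, frame["xl"].to_numpy(dtype=float)])
    if np.linalg.matrix_rank(full) < 3:
        raise ValueError(
            "degenerate design: lagged predictor is collinear with the "
            "lagged response (identical or constant series?)")
    rss_r = _rss(base, yv)
    rss_u = _rss(full, yv)
    df_resid = n - 3
    if rss_u <= 0:
        raise ValueError("perfect fit: F statistic undefined")
    f = (rss_r - rss_u) / (rss_u / df_resid)
    p = float(stats.f.sf(f, 1, df_resid))
    return GrangerResult(getattr(x, "name", "x") or "x",
                         getattr(y, "name", "y") or "y",
                         1, n, float(f), p, p < alpha)


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# rolling early-warning statistics


@dataclass
class EWSResult:
    name: str
    window: int
    window_fraction: float
    table: pd.DataFrame = field(repr=False)


def rolling_ews(series: pd.Series,
                window_fraction: float = c.EWS_WINDOW_FRACTION,
                detrend_sd: float | None = None) -> EWSResult:
    """Trailing-window variance and lag-1 autocorrelation of a daily
    series.

    The window is ``round(window_fraction * n)`` observations (minimum
    5).  Optional Gaussian detrending (bandwidth ``detrend_sd`` in
    observations) subtracts a smoothed trend before computing the
    statistics; off by default.  Constant windows yield variance 0 and
    undefined (NaN) autocorrelation.
    """
    x = series.dropna()
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 observations")
    if detrend_sd is not None:
        from scipy.ndimage import gaussian_filter1d
        x = x - gaussian_filter1d(x.to_numpy(dtype=float), detrend_sd)
    window = max(c.EWS_WINDOW_MIN, round(window_fraction * n))
    var = x.rolling(window).var()

    def _ac1(w: np.ndarray) -> float:
        a, b = w[:-1], w[1:]
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    ac = x.rolling(window).apply(_ac1, raw=True)
    table = pd.DataFrame({"variance": var, "autocorr_lag1": ac})
    return EWSResult(getattr(series, "name", "series") or "series",
                     window, window_fraction, table)


# ---------------------------------------------------------------------------
# boosted regression trees


@dataclass
class BRTResult:
    response: str
    predictors: list[str]
    params: dict
    pct_variation: float                 #: 100 * (1 - SSE/SST), in-sample
    relative_influence: pd.Series = field(repr=False)
    sensitivity: dict = field(repr=False)
    model: GradientBoostingRegressor = field(repr=False)


def brt_fit(table: pd.DataFrame, response: str, predictors,
            n_trees: int = c.BRT_N_TREES,
            shrinkage: float = c.BRT_SHRINKAGE,
            interaction_depth: int = c.BRT_INTERACTION_DEPTH,
            bag_fraction: float = c.BRT_BAG_FRACTION,
            seed: int = 0,
            sensitivity_points: int = 50,
            min_n: int = 50) -> BRTResult:
    """Gradient-boosted regression of a response on many drivers.

    Trees are limited to ``interaction_depth + 1`` leaves, mirroring the
    classic gbm interaction-depth parameterisation (a depth-k tree has k
    splits).  Relative influence per predictor is the normalised total
    squared-error improvement over all splits, summing to 100.  ``pct
    variation`` is computed in-sample.
    """
    frame = table[[response, *predictors]].dropna()
    if len(frame) < min_n:
        raise ValueError(f"only {len(frame)} complete rows; need >= {min_n}")
    x = frame[list(predictors)].to_numpy(dtype=float)
    y = frame[response].to_numpy(dtype=float)
    model = GradientBoostingRegressor(
        n_estimators=n_trees, learning_rate=shrinkage,
        max_leaf_nodes=interaction_depth + 1, max_depth=None,
        subsample=bag_fraction, random_state=seed, loss="squared_error")
    model.fit(x, y)
    pred = model.predict(x)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    pct = 100.0 * (1.0 - sse / sst)
    influence = pd.Series(100.0 * model.feature_importances_,
                          index=list(predictors), name="relative_influence")

    sens = {}
    means = x.mean(axis=0)
    for j, name in enumerate(predictors):
        grid = np.linspace(x[:, j].min(), x[:, j].max(), sensitivity_points)
        probe = np.tile(means, (sensitivity_points, 1))
        probe[:, j] = grid
        sens[name] = pd.DataFrame({name: grid,
                                   "response": model.predict(probe)})
    params = {"n_trees": n_trees, "shrinkage": shrinkage,
              "interaction_depth": interaction_depth,
              "bag_fraction": bag_fraction, "seed": seed}
    return BRTResult(response, list(predictors), params, pct, influence,
                     sens, model)
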