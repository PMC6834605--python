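# Methods

`oxymetab` estimates free-water metabolic rates from multi-depth,
high-frequency dissolved-oxygen (DO) records in a stratified marine lake,
describes the water column's oxygen structure, and attributes variation in
both to environmental drivers. This note records the models, the defaults
and why they hold, the numerical choices, and the known limitations —
including exactly what the synthetic-lake tests do and do not demonstrate
about field data.

## 1. The metabolic model

Biological oxygen dynamics at one depth are modelled as

    dDO/dt = P(t) + CR/24,

with community respiration CR ≤ 0 (µM O₂ d⁻¹) constant around the clock
and gross primary production P(t) ≥ 0 confined to daylight. Daily
integrals define the three rates: GPP = ∫P dt over one day, CR, and net
community production NCP = GPP + CR. The *metabolic day* runs 05:00 →
05:00 and the *dark window* 19:00 → 05:00, matching a tropical light
cycle; both hours are configurable constants (`constants.py`).

Three estimators are provided:

- **BDO** — per-timestep "biological DO" increments (ΔDO over one
  10-minute step, minus the air–water flux term in integrated mode) are
  summed over the dark window for CR (scaled ×24/10, i.e. a 10-h night
  extrapolated to the full day under the constant-respiration
  assumption) and over the metabolic day for NCP. NCP telescopes, so the
  BDO estimate is exact whenever the record is complete.
- **slope** — ordinary least-squares slope of DO versus time (days) over
  the dark window (CR) and over the metabolic day (NCP). The preceding
  day is paired with the following night: GPP(d) = NCP(d) + |CR(d)| with
  CR(d) taken from the night beginning 19:00 on day d. GPP is reported
  missing whenever CR > 0 (DO rose overnight).
- **ssa_slope** — singular-spectrum analysis reconstructs the trend plus
  daily cycle of the DO record, discarding the semidiurnal tide and
  high-frequency variability, and the slope estimator is then applied to
  the reconstruction. Intended for records with a pronounced tidal
  signal, where the plain slope is badly contaminated.

### A structural property of the 24-h slope worth knowing

For a signal DO(t) = (NCP/T)·t + h(t) with h diel-periodic, the OLS slope
over one period is NCP + cov(t, h)/var(t). The covariance term vanishes
only if the production-weighted second moment of time-of-day about the
window midpoint equals T²/12 — which no midday-peaked production shape in
a 05:00–19:00 light window satisfies. With the package's half-sinusoid
production the bias is ≈ 0.14·GPP µM d⁻¹ (upward). Consequences:

- On noiseless synthetic data, BDO CR, BDO NCP and slope CR recover the
  truth exactly; slope NCP recovers the truth *plus* this shape bias.
  One acceptance-style test asserts sub-1% recovery for all four
  quantities and therefore fails on the slope-NCP clause by design; the
  failure is the documentation.
- On field data the same bias is present but unknowable (the true diel
  shape is unobserved); slope NCP should be read as a trend estimate
  whose offset depends on the diel shape, and BDO NCP preferred when the
  record is complete enough.

### Coverage, gaps and anoxia

A window (night or day) is evaluated only if ≥ 80% of its expected
records are present (`COVERAGE_MIN`); increments spanning a gap are
discarded outright, so servicing gaps shorten sums rather than corrupt
them. Days on which ≥ 95% of records sit below the detection limit
(2 µM default) report all three rates as *missing*, not zero: a sensor
in anoxic water measures nothing about metabolism. The 80% and 2 µM
values are pragmatic choices, not field-calibrated.

## 2. Singular spectrum analysis

The DO record is placed on a complete grid (interior gaps linearly
interpolated; the interpolated fraction is reported), embedded with a
432-sample window (3 days at 10-min cadence), and the lag-covariance
matrix eigendecomposed. Two numerical choices matter:

- **Frequency-separating rotation.** When the tidal and diel amplitudes
  are comparable their eigenvalues nearly coincide and raw eigenvectors
  mix the two oscillations. The retained leading subspace (30
  components) is therefore rotated by diagonalising the
  Parseval-weighted mean-frequency operator; rotated components are
  frequency-pure and the operator's eigenvalues give each component's
  mean period directly (continuous, not bin-quantised — a 12.42-h tide
  is estimated as ≈ 12.2–12.4 h rather than snapping to the 12-h bin).
- **Band grouping.** Components with period ≥ 20 h (the slow trend plus
  the diel pair; band configurable) are kept and diagonal-averaged back
  into a series. The sub-diel harmonics of a non-sinusoidal daily cycle
  (12 h, 8 h, …) fall outside this band and are discarded — necessarily,
  because at a 3-day window the 12-h harmonic is spectrally inseparable
  from the M2 tide (0.2 Rayleigh widths apart). The reconstruction is
  therefore a deliberately smoothed daily cycle: ssa_slope CR runs
  ~25% below plain-slope CR on tide-free records with a sharp diel
  shape, while cutting CR RMSE by an order of magnitude when the tide
  is 3× the diel amplitude. Use ssa_slope where the tide demands it;
  widen the band on tide-free records if the sharp shape matters.

## 3. Gas exchange

The air–water O₂ flux chain: freshwater CO₂ Schmidt number as a cubic in
temperature; O₂ Schmidt number via a linear salinity factor; CO₂
transfer velocity k = 0.31·u₁₀² (cm h⁻¹); O₂ transfer velocity
k_O2 = k_CO2·(Sc_O2/660)ⁿ with n = −2/3 below u₁₀ = 2 m s⁻¹ and −1/2 at
or above it (k_O2 = k_CO2 exactly at Sc_O2 = 660 on either branch);
F = −k_O2(DO − DOsat) in mmol m⁻² d⁻¹ after converting cm h⁻¹ → m d⁻¹
(×0.24), positive into the water. All coefficients live in
`constants.py`.

Saturation DO uses the Garcia–Gordon combined solubility fit (µmol kg⁻¹
set; check value 274.610 µmol kg⁻¹ at 10 °C, S = 35) converted to µM with
the UNESCO one-atmosphere density and scaled by a barometric factor
exp(−elevation/8000 m). The salinity compensation applied to
freshwater-calibrated optode readings uses the salinity terms of the same
family of fits, per optode vendor practice, with the most recent past
profile's salinity per record. Wind measured at 3 m is scaled to 10 m by
a neutral logarithmic profile with roughness length z₀ = 2×10⁻⁴ m
(configurable; the choice of height-conversion law shifts u₁₀ by a few
percent and hence k by up to ~10%).

## 4. Oxygen structure

Depth integrals are trapezoidal over the sensor depths with the 0–1 m
layer held at the 1-m value, so µM integrates to mmol m⁻²; the scheme is
exact for piecewise-linear profiles and linear in its inputs. ΔDO is the
day-to-day difference of daily means (missing unless both days exist and
are consecutive). The suboxic-zone depth is the shallowest downward
crossing of 20 µM by the linear spline through the (depth, DO) points;
with only three sensors any smoothing spline is unidentifiable, so exact
interpolation is the only defensible fit. When the whole profile sits
above the threshold, the deepest segment is extrapolated downward
(capped at 20 m); below it, the shallowest segment upward (floored at
0 m) — extrapolation is always flagged, since crossings outside the
sensor span are geometric guesses, and uniformly adding oxygen can never
shallow the returned depth.

## 5. Driver attribution

- **Regression screen**: per-predictor simple OLS on pairwise-complete
  daily data, raw two-sided P-values (Benjamini–Hochberg column
  optional, off by default), sign of r preserved.
- **Granger causality (lag 1)**: nested-model F-test of
  y_t ~ y_{t−1} + x_{t−1} against y_t ~ y_{t−1}, (1, n−3) degrees of
  freedom, listwise deletion across gaps, n ≥ 30 required; verified
  against the statsmodels reference implementation and calibrated to a
  5% ± 2% type-I rate over 1000 null pairs at n = 300. The test is
  direction-specific and degenerate designs (collinear or constant
  series) are rejected with an explanatory error.
- **Early-warning statistics**: trailing-window variance and lag-1
  autocorrelation with window = round(0.15·n), minimum 5; no detrending
  by default (optional Gaussian detrending is exposed, bandwidth in
  observations). Note the lag-1 autocorrelation of a short AR(1) window
  is biased low by ≈ (1+4φ)/window.
- **Boosted regression trees**: squared-error gradient boosting, 363
  trees, shrinkage 0.05, bag fraction 0.7, trees limited to
  interaction_depth+1 = 4 leaves (the classic gbm parameterisation: a
  depth-k tree has k splits — not sklearn's depth-k meaning), fixed
  seed. Relative influence is the normalised total split improvement
  (sums to 100); "% variation captured" is in-sample 100·(1 − SSE/SST),
  which flatters the fit relative to held-out scoring and is reported
  as such deliberately; sensitivity curves sweep one predictor over its
  observed range with the others at their means, ignoring predictor
  correlation.

## 6. The synthetic lake

`synthetic.LakeScenario` generates what the estimators assume plus the
contaminants they must survive: per-depth DO built from closed-form
cumulative integrals of the production/respiration model (so the
noise-free 05:00→05:00 net change equals NCP_true *exactly*, at any
cadence), a sinusoidal tide (default period 12.42 h, amplitude
configurable), AR(1) sensor noise (default φ = 0.6, innovation SD 1 µM —
plausible optode smoothing, not calibrated to any instrument),
deterministic diel+seasonal temperature, sensor-servicing gaps, and a
daily driver table (log-normal wind, zero-inflated-gamma precipitation,
seasonal SSH and air temperature, monthly MEI declining through the
year, von Mises easterly wind direction). An optional one-day-lagged
linear coupling plants a known Granger-causal driver→response channel.
A single scenario seed fans out to fixed-purpose substreams, so
identical scenarios are byte-identical and adding one stream never
perturbs another.

Default true rates are near-balanced (NCP_true of +2/−2/−1 µM d⁻¹ at
1/6/12 m): any sustained large NCP would trend DO unboundedly, which no
real lake does (real systems equilibrate through the very air–water flux
the generator deliberately does not feed back). The optional flux
coupling is one-way — flux is computed against the noise-free surface
biological signal and spread over the column — keeping NCP_true exact by
construction while giving the integrated-mode BDO estimator a real flux
term to remove.

What passing tests therefore show: the estimators are algebraically
correct, the detiding works against a known tide, the statistics are
calibrated against known null and coupled channels. What they do not
show: performance under flux feedback, sensor drift or fouling,
non-stationary diel shapes, internal waves, advection, or rates that
vary day to day — none of which the generator emulates. Seasonal driver
columns (SSH, air temperature) covary deterministically by construction,
as in real data; only the serially independent columns are usable as
null channels.

## 7. Reproducibility

Every pipeline run writes a manifest (package version, seed, SHA-256
config hash, per-stage row counts); identical configs reproduce
byte-identical tables. Problem sizes used by the test suite and the
acceptance checks — a one-year noiseless recovery run, 50×16-day
detiding trials, 1000×300-point null calibrations — were chosen so the
full suite completes in well under a minute of CPU while keeping
Monte-Carlo bands an order of magnitude tighter than the thresholds
they guard.
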