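# Methods

Model assumptions, parameter choices and numerical decisions behind
`wheatn`. The README covers usage; this note explains *why* the package
computes what it computes.

## Nitrogen indicators

* **PNA** (kg N/ha) sums organ dry biomass × N concentration over leaf,
  stem and ear. Biomass is stored in g/m² and converted with the exact
  factor 10 (1 g/m² = 10 kg/ha); concentrations in % DM enter as fractions.
* **PNC** (% DM) is PNA divided by total aboveground biomass, i.e. the
  biomass-weighted mean of the organ concentrations — the package tests
  this algebraic identity directly.
* **Critical N curve** `Nc(W) = 4.15 · W^−0.38` (W in Mg DM/ha, Nc in
  % DM) is the standard winter-wheat dilution power law; it is strictly
  decreasing and equals its coefficient exactly at W = 1.
* **NNI = Nact / Nc(W)**. The package takes the *actual* concentration
  Nact to be PNC, the whole-plant concentration at the same sampling date
  as the biomass measurement. This is the common operational reading of
  the index; any other concentration can be passed to `nni` explicitly.

## Sensor models

* **Reflectance spectra** live on a gapless 1-nm integer grid (350–2500 nm
  for the full-range instrument); off-grid band requests use linear
  interpolation. All narrow-band index formulas consume interpolated band
  values, so they are well-defined for any grid covering their bands.
* **Empirical-line calibration** is the affine map sending the black-panel
  DN to 0 and the white-panel DN to 255. Calibrated values are clamped to
  [0, 255] by default (out-of-range field pixels do occur); clamping can be
  disabled, and the number of clamped values can be reported. Calibration
  is affine, so it commutes with mask-mean aggregation — the package
  aggregates AOI pixels first and calibrates the mean.
* **Index registry.** 28 narrow-band, 9 fluorescence, 14 RGB-camera
  indices plus 3 leaf-clip pass-through features. Two deliberate
  deviations from printed sources, chosen once and recorded in the code:
  * `TBI2` as printed is the ratio of a quantity to itself (identically 1);
    the registry evaluates the normalized difference of the same two bands
    instead. `compute_asd_vis(strict=True)` reproduces the degenerate
    printed form.
  * `MCARI2` uses the standard published radicand; a misprinted variant
    with an undefined square root is not implemented.
  Two historical aliases (`SR_(418,405)`, `SR_(740,720)`) resolve to the
  registry entries with the same band math.
* **Undefined values** (zero denominators, logarithms of non-positive
  ratios, a red-edge position outside the grid) are returned as NaN and
  counted, never raised: one degenerate plot must not abort a campaign
  analysis. All-NaN feature columns are dropped with a warning.
* **Red edge.** REP uses the 4-point linear interpolation
  `700 + 40·((R670+R780)/2 − R700)/(R740 − R700)`; REV is the interpolated
  reflectance at REP; REFD is the maximum per-nm first difference over
  680–760 nm.

## Regression models

* **Parametric (PR).** Five forms: linear, quadratic (OLS), logarithmic
  (OLS on ln x), power and exponential (OLS in log space, which assumes
  multiplicative errors — a deliberate, classical simplification). The
  best single index is chosen by absolute Pearson correlation on a
  stratified 70/30 holdout (73/31 plots at the default size), then the
  form with the best validation R² is refit on all rows.
* **Stepwise MLR.** Forward entry at p < 0.05, backward removal at
  p > 0.10, using OLS partial t-test p-values. A perfect-fit guard stops
  selection once the residual sum of squares falls below 1e-10 × SS_tot,
  where p-values are numerically meaningless.
* **GPR.** Anisotropic squared-exponential (ARD) kernel
  `K = γ·exp(−Σ_b (x_ib−x_jb)²/(2σ_b²))` plus a fitted white-noise term,
  implemented on top of scikit-learn's `GaussianProcessRegressor`
  (constant × RBF + white kernel, `normalize_y=True`). Features are
  standardized internally (zero-variance features are centred and left at
  scale 1), and length scales are bounded in [1e-2, 1e3] so "irrelevant"
  saturates at a finite, comparable value. Hyperparameters are fitted by
  marginal-likelihood maximization with seeded restarts.
* **SBBR.** From the full feature set, iteratively refit the GP and drop
  the feature with the largest fitted length scale (least relevant under
  ARD), recording the 10-fold cross-validated RMSE of every visited
  subset; the selected subset minimizes CV RMSE, ties broken toward fewer
  features. CV fold assignment is seeded per subset size so the procedure
  is reproducible yet not tied to a single partition.

## Evaluation

RMSE, MAE and NSE follow their textbook definitions; R² is the squared
Pearson correlation between observed values and *pooled out-of-fold*
predictions — every sample is predicted exactly once by a model that never
saw it, and one statistic is computed on the pooled vector. Fold
assignment is a seeded shuffled k-fold (k = 10 by default). NSE and R²
require non-constant observations and raise otherwise.

## Synthetic experiment generator

The generator exists because the reference field data are private. It is
built for *structural* realism — the qualitative relationships a method
comparison needs — not for spectral fidelity.

Latent chain per plot and stage, driven by N fertilization rate
(0–225 kg N/ha):

1. A saturating response `sat(f) = 1.6·f/(f + 0.6)`, `f = rate/225`,
   maps rate to biomass W and to a target NNI; multiplicative lognormal
   noise (`noise_sd_latent`) represents plot-to-plot variability.
2. PNC follows from the dilution curve: `PNC = NNI · Nc(W)`; LNC is a
   stage-specific multiple of PNC (leaves are N-richer than the whole
   plant, more so after heading).
3. Physiology: chlorophyll saturates in LNC (Michaelis form), flavonols
   decline exponentially in LNC (the well-known inverse N response).
4. Observations: canopy reflectance is a linear soil/vegetation mixture
   whose red-edge midpoint shifts with chlorophyll; fluorescence channels
   implement UV screening by flavonols (`exp(−0.9·flav)`); RGB DNs are
   band-window means re-expressed against in-scene panels; the leaf-clip
   sensor reports Chl, Flav and their ratio. Organ samples are constructed
   to reproduce the latent PNC and LNC *exactly*, so derived indicators
   equal latent ones to rounding.

Stage parameters (biomass levels, NNI ranges, soil fractions, organ
partitioning, leaf-to-plant N ratios) were set once, from agronomic
reasoning, so that per-stage indicator means and coefficients of variation
fall within ±50 % of published field statistics and the rate–LNC rank
correlation is strong; they were not tuned against test outcomes. Feekes 5
plots are N-richer with high soil exposure; Feekes 11 plots are diluted
(low PNC, ear present) with mostly closed canopy, and canopy closure is
enforced to increase between stages within a plot.

Known limits: no radiative-transfer model (no BRDF, no water-band
fine structure beyond fixed endmember dips), no spatial correlation
between plots, no weather or site effects, lognormal noise only, and a
deterministic stage sequence. Conclusions about absolute accuracy do not
transfer to field data; method *rankings* under a saturating index–N link
are the intended use.

## Problem sizes and runtime

All simulation sizes are the package's own choice, set for a single-CPU
budget: the default experiment is 104 plots × 2 stages; the acceptance
check of the qualitative model ranking uses the fluorescence family
(9 features), 52 plots, two stage groupings, three targets and five seeds
with restart-free GP fits (~4 min); GP-based unit tests use 20–40 rows.
Larger grids scale linearly in cells and roughly cubically in rows (GP
solves).

## Numerical choices

* Exact closed-form constants (4.15, −0.38, the 255 DN scale) are bound to
  named module constants and asserted exactly in tests.
* GP numerics: internal feature standardization, `normalize_y`, bounded
  length scales, and scikit-learn's 1e-10 diagonal jitter; the acceptance
  oracle includes that jitter in the nugget.
* Stepwise selection guards against zero residual variance (above).
* Randomness is exclusively `numpy.random.default_rng` seeded from
  user-visible configuration; repeated runs are bitwise identical.
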