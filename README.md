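# wheatn

Estimation of winter-wheat nitrogen status from multi-sensor vegetation
indices: agronomic nitrogen indicators, an index registry for four proximal-
and remote-sensing instruments, and regression models — including Gaussian
process regression with sequential backward band removal (SBBR) — compared
under seeded cross-validation on a synthetic but agronomically structured
experiment generator.

## The scientific problem

Crop nitrogen (N) management needs a fast, non-destructive readout of plant N
status. The reference indicators come from destructive organ sampling:

* **LNC / PNC** — leaf and whole-plant N concentration (% of dry matter);
  PNC is the biomass-weighted mean of the organ concentrations.
* **PNA** — plant N accumulation (kg N/ha), organ biomass × concentration.
* **NNI** — nitrogen nutrition index, the actual plant N concentration
  divided by the *critical* concentration `Nc(W) = 4.15 · W^−0.38` (% DM, W
  in Mg DM/ha), the minimum concentration supporting maximal growth at that
  biomass. NNI = 1 is optimal, < 1 deficient, > 1 luxury uptake.

Proximal and remote sensors offer non-destructive proxies. This package
implements four instrument families and the algebra connecting them to the
indicators:

| family      | instrument                        | features                                  |
| ----------- | --------------------------------- | ----------------------------------------- |
| `asd`       | full-range spectroradiometer      | 28 narrow-band indices (NDVI, REP, MCARI…) |
| `multiplex` | multi-excitation fluorimeter      | 9 fluorescence ratios (SFR, FER, FLAV, NBI…) |
| `rgb`       | UAV digital camera                | 14 colour indices from calibrated DNs      |
| `dualex`    | leaf-clip optical sensor          | NBI, Chl, Flav readouts                    |

RGB digital numbers are radiometrically calibrated with the empirical line
method from in-scene white/black panels:
`DN_cal = (DN − DN_black)/(DN_white − DN_black) · 255`.

Index–indicator links are fitted with:

* **PR** — best single index under parametric forms (linear, quadratic,
  logarithmic, power, exponential), chosen on a 70/30 holdout;
* **MLR** — stepwise multiple linear regression (entry p < 0.05, removal
  p > 0.10);
* **GPR** — Gaussian process regression with an anisotropic (ARD)
  squared-exponential kernel, one length scale per feature;
* **GPR + SBBR** — sequential backward band removal: iteratively drop the
  feature with the largest fitted length scale (least relevant), retrain,
  and keep the subset with the lowest 10-fold cross-validated RMSE.

Field campaigns are expensive, so the package ships a seeded synthetic
generator that reproduces the qualitative structure of a two-stage
(Feekes 5 and Feekes 11) N-fertilization experiment: a saturating N-rate
response, biomass-driven N dilution, chlorophyll/flavonol physiology, linear
soil–vegetation spectral mixing with a chlorophyll-controlled red edge, and
consistent observations for all four sensors. See
[docs/methods.md](docs/methods.md) for assumptions and limits.

## Worked example

```python
import numpy as np
from wheatn import (
    ExperimentConfig, generate_experiment, indicators_table, build_feature_table,
    critical_n, nni, kfold_cv, BestIndexRegressor, GPRegressor, sbbr,
)

# 1. Nitrogen indicators from the dilution curve
print(f"Nc(1 Mg/ha)  = {critical_n(1.0):.2f} % DM")
print(f"Nc(8 Mg/ha)  = {critical_n(8.0):.2f} % DM")
print(f"NNI at 3.0 % and 2 Mg/ha = {nni(3.0, 2.0):.3f}")

# 2. Simulate a two-stage fertilization experiment
cfg = ExperimentConfig(n_plots=60, seed=42)
dataset = generate_experiment(cfg)
ind = indicators_table(dataset.plant_samples)
print("\nindicator means by stage:")
print(ind.groupby("stage")[["LNC", "PNC", "NNI"]].mean().round(2))

# 3. Fluorescence indices -> leaf N, best single index vs GPR with SBBR
feats = build_feature_table(dataset, families=("multiplex",))
early = feats[feats["stage"] == "Feekes5"]
cols = [c for c in early.columns if c not in ("plot_id", "stage", "LNC", "PNC", "NNI")]
X, y = early[cols], early["LNC"].to_numpy()

pr = kfold_cv(BestIndexRegressor(seed=0), X, y, k=10, seed=0)
trace = sbbr(X, y, k_folds=10, seed=0, n_restarts=1)
gpr = kfold_cv(GPRegressor(n_restarts=1, random_state=0), X[trace.selected], y, k=10, seed=0)

print(f"\nbest single index (10-fold CV):  R2={pr.r2:.3f}  RMSE={pr.rmse:.3f} % DM")
print(f"SBBR kept {len(trace.selected)}/{len(cols)} indices: {trace.selected}")
print(f"GPR on selected (10-fold CV):    R2={gpr.r2:.3f}  RMSE={gpr.rmse:.3f} % DM")
```

Output:

```text
Nc(1 Mg/ha)  = 4.15 % DM
Nc(8 Mg/ha)  = 1.88 % DM
NNI at 3.0 % and 2 Mg/ha = 0.941

indicator means by stage:
           LNC   PNC   NNI
stage
Feekes11  2.82  1.61  0.88
Feekes5   4.95  4.30  1.15

best single index (10-fold CV):  R2=0.614  RMSE=0.331 % DM
SBBR kept 2/9 indices: ['FLAV', 'NBI_R']
GPR on selected (10-fold CV):    R2=0.701  RMSE=0.291 % DM
```

The nonlinear multi-feature model with relevance-driven feature selection
outperforms the best single index, and the selected indices (flavonol
content and fluorescence nitrogen balance) are the physiologically expected
N proxies.

## Command-line interface

```sh
wheatn synth --seed 42 --out runs/data            # generate a dataset
wheatn indices --family multiplex --in runs/data --out runs/vis.csv
wheatn fit --method gpr --select --target lnc --family multiplex \
       --stage feekes5 --in runs/data --out runs/fit.json
wheatn run --seed 0 --out runs/grid               # full family x target x stage x method grid
```

`wheatn run` writes `results.csv` (one row per grid cell and method, with
pooled cross-validated R², RMSE, MAE, NSE), a rendered `report.md`, the
generated dataset and a `manifest.json` with the configuration hash.

## Reproduction

Everything is seeded and deterministic on one CPU:

```sh
pip install --no-build-isolation --no-deps -e .

# full test suite, including the acceptance criteria (~5 min)
python -m pytest -o addopts= -p no:cacheprovider -q tests/

# analytic acceptance targets
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion: the
critical-N curve value at unit biomass, empirical-line panel endpoints,
metric identities, a dense closed-form GP posterior oracle, SBBR noise
recovery, a hand-coded oracle for all 51 index formulas, the qualitative
model ranking (GPR + SBBR ≥ PR and MLR in a majority of synthetic grid
cells over 5 seeds), and the nitrogen-indicator identities.
`scripts/acceptance.py` writes the analytic target
(`t1`: Nc at W = 1 Mg DM/ha = 4.15 % DM) as JSON.

## Layout

```
src/wheatn/
  indicators.py   organ sampling -> PNA, PNC, Nc, NNI
  spectra.py      spectra, empirical-line DN calibration, AOI aggregation
  indices.py      54-entry vegetation-index registry, feature tables
  synthetic.py    seeded multi-sensor experiment generator
  models.py       parametric / stepwise MLR / GPR estimators, SBBR
  evaluation.py   RMSE, MAE, NSE, R2, seeded k-fold CV, comparison reports
  pipeline.py     grid orchestration with per-cell crash isolation
  cli.py          wheatn command-line interface
```

All estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`/`set_params`, trailing-underscore fitted attributes) and work
inside scikit-learn tooling such as `clone` and cross-validation loops.
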