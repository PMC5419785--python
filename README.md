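# rndvi — thermal-time-normalized canopy NDVI dynamics for rice

`rndvi` models the seasonal trajectory of rice canopy NDVI measured by
active-optical proximal sensors (e.g. a handheld GreenSeeker). It is
aimed at crop-phenotyping and precision-nitrogen researchers who want a
simple, transferable dynamic model of canopy greenness: one that needs
no destructive sampling and no per-site recalibration of the time axis.

## The model

Raw NDVI trajectories differ across cultivars, nitrogen rates, sites
and years, but collapse onto a common shape after two normalizations:

- **Thermal time.** Daily growing degree days
  GDD = max(0, (T_min + T_max)/2 − T_base), T_base = 10 °C for rice,
  are accumulated from transplanting (AGDD) and divided by the
  transplant-to-harvest total: RAGDD = AGDD_i / AGDD_h, a dimensionless
  [0, 1] season clock.
- **Amplitude.** Each NDVI reading is divided by its treatment or yield
  group's seasonal maximum: RNDVI = NDVI_i / NDVI_max.

The pooled (RAGDD, RNDVI) cloud is then fitted by candidate curve
families, headlined by the **double logistic**

    RNDVI(x) = [1 + e^(−a (x − b))]⁻¹ − [1 + e^(−c (x − d))]⁻¹,

a green-up limb (steepness *a*, inflection timing *b*) minus a
senescence limb (*c*, *d*): rise after tillering, plateau around
booting, decline after heading. Separate models are fitted per cultivar
type (Japonica / Indica) and yield level (low ≤ 8.25, middle, high
≥ 10.5 t·ha⁻¹), and parameters are compared across groups with Wald
z-tests. Predicted NDVI is reconstructed as
NDVI_s = NDVI_max × RNDVI_s and scored stage-wise against observations
with the accuracy slope k (through-origin regression of simulated on
observed), R² and RMSE.

No field dataset is distributed, so the package includes a synthetic
experiment generator that emulates the original factorial design
(2 cultivars × 6 N rates × 3 replicates, ~25–30 sampling dates over a
133–156-day season) from published per-group parameter sets, letting
every stage run and be tested offline.

## Worked example

```python
import warnings
import numpy as np
from rndvi import fit_candidates, eval_curve
from rndvi.reference import HIGH_YIELD_POOLED

rng = np.random.default_rng(42)
x = np.linspace(0.0, 1.1, 60)
y = eval_curve(HIGH_YIELD_POOLED, x) + rng.normal(0, 0.05, x.size)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for fit in fit_candidates((x, y)):
        print(f"{fit.spec.family:24s} r2={fit.r2:.4f} rmse={fit.rmse:.4f}")
```

prints

```
double_logistic          r2=0.9847 rmse=0.0385
cubic                    r2=0.9614 rmse=0.0611
rational_quad            r2=0.9136 rmse=0.0914
logistic3                r2=0.6911 rmse=0.1728
rational_power           r2=0.6883 rmse=0.1736
```

— the double logistic wins the ranking on data it generated (noise
σ = 0.05), with the cubic and rational forms trailing, mirroring the
selection outcome on real canopies. The fitted parameters
(16.21, 0.194, 11.95, 1.026) sit within noise of the generating truth.

More narrative walk-throughs live in `examples/` (thermal clock, curve
families, model selection, per-group models with parameter comparison,
and the full simulate → fit → validate pipeline). The same pipeline is
scriptable from the shell:

```sh
rndvi simulate --config run.yaml
rndvi fit      --config run.yaml
rndvi validate --config run.yaml --models out/fits.json
```

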