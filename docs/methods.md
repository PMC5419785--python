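# Methods

## Model and assumptions

The package treats a rice canopy's NDVI trajectory as a deterministic
function of thermal time plus sensor noise. Three assumptions carry the
whole construction:

1. **Development follows heat, not calendar.** Daily growing degree
   days use the simple-average method, GDD = max(0, (Tmin+Tmax)/2 −
   Tbase). Accumulated GDD (AGDD) is an exact cumulative sum from
   transplanting; a missing weather day inside the season is a hard
   error rather than an interpolation, because a silently patched sum
   would shift the clock of every later observation. Dividing by the
   transplant-to-harvest total AGDD_h gives RAGDD ∈ [0, 1], which is
   exactly 1 at harvest by construction.
2. **Amplitude is a group property.** Cultivar, N rate and yield level
   move the height of the NDVI curve much more than its shape. Dividing
   by the group's seasonal maximum NDVI_max removes the amplitude, so
   pooled groups share one relative curve. NDVI_max is computed from
   the pooled group observations by default; an override accepts an
   externally supplied (e.g. historical) value per group.
3. **The relative curve is a double logistic.** A rising logistic limb
   (steepness a, inflection timing b, in RAGDD units) minus a
   senescence limb (c, d) reproduces rise–plateau–decline. a and c are
   sometimes loosely called "inflection points" in the agronomy
   literature; mathematically they are rate parameters — the inflection
   locations are b and d — and the package names them accordingly.

Four alternative families from the original model-selection exercise
ship alongside it (cubic polynomial, two rational forms, 3-parameter
logistic), ranked by R² with RMSE and parameter count as tie-breaks.
No information criterion is used: the families have 3–4 parameters on
hundreds of points, so R² ordering is the published and adequate rule.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `tbase_c` | °C | 10.0 | dominant base temperature for rice thermal time; configurable because the convention is not universal |
| `include_transplant_day` | – | true | AGDD on DAT i sums days 0..i so every observed day carries thermal time; flippable for the 1..i convention |
| double-logistic start | – | a=c=10, b=0.2, d=1.0 | mid-range steepness, green-up near 1/5 of the season, senescence near harvest |
| double-logistic bounds | – | a,c ∈ (0, 100], b ∈ [−0.5, 1], d ∈ [0.5, 1.6] | encode the physical rise-then-fall reading of the curve on the [0, 1.1] clock |
| yield-level thresholds | t·ha⁻¹ | 8.25, 10.5 | the published production-level grouping for Jiangsu rice; boundary cases: 8.25 → low, 10.5 → high |
| stage bins (RAGDD) | – | tillering 0.10–0.30, jointing 0.30–0.45, booting 0.45–0.60, heading 0.60–0.70, flowering 0.70–0.80 | stages are named in sources only by calendar date; RAGDD bins transfer across seasons and are recorded in output |
| `noise_sd` | NDVI | 0.015 | synthetic sensor noise; see below |

## Fitting and numerics

Nonlinear families are fitted by scipy's trust-region reflective least
squares (`xtol=ftol=gtol=1e-12`); the cubic and linear families are
solved exactly by ordinary least squares. If the default start fails to
converge, eight scattered starts are tried and the best solution kept;
fits are deterministic given identical inputs. The rational-quadratic
family is initialized by its exact linearization (y·(1+cx+dx²) = a+bx
is linear in the coefficients) before polishing. Parameter standard
errors come from the linearized covariance s²(JᵀJ)⁻¹ at the solution
and feed the Wald z-test used to compare group models; the z-test
replaces an ambiguously described t-procedure in the source material
and is the standard large-sample choice when fits come from different
datasets.

R² is the coefficient of determination about the observed mean, not
squared Pearson correlation — for nonlinear fits the two differ. When
the observations have zero variance R² is undefined: it is reported as
0.0 when the fit is also exact (the model explains nothing beyond the
mean) and NaN with a warning otherwise. Sums of squares below ~1e-24
relative to scale are treated as zero so constant inputs are not
dominated by float rounding.

The accuracy slope k is the through-origin regression of simulated on
observed values, Σ(obs·sim)/Σ(obs²) — the slope a 1:1 scatter plot
reader compares with the 45° line; an ordinary-intercept slope is
available as an option. RMSE is computed as simulated minus observed.
Curve peaks are located by a 2201-point grid scan refined by bounded
scalar minimization; rational-family denominators within 1e-12 of zero
raise a domain error. Ties in the seasonal-maximum search break to the
earliest day after transplanting (then plot id) for determinism.

## What the synthetic generator emulates — and what it does not

`gen_experiment` reproduces the *statistical design* of the original
factorial field experiments: 2 cultivars (one Japonica with a 156-day
season, one Indica with 133) × 6 N rates (0–375 kg·ha⁻¹) × 3 replicate
plots, sampled every 5 days from DAT 6, with per-cultivar-by-N seasonal
NDVI maxima and grain yields taken from the published tables, and
generating curves per (cultivar type × yield level) from the published
parameter sets. Weather is a half-sine season (mean 25 °C, amplitude
4 °C, diurnal range 10 °C, daily jitter σ 1.5 °C) typical of a Yangtze
rice season. Noise is additive Gaussian on NDVI (σ = 0.015, truncated
to [0, 1]); replicate yields are jittered (σ = 0.1 t·ha⁻¹) but clipped
inside their design yield level's band, since two published yields sit
within 0.04 t·ha⁻¹ of the 10.5 boundary and unconstrained jitter would
scramble the grouping. Each plot draws from its own seed stream (master
seed hashed with the plot id), so adding plots never perturbs existing
ones.

The generator does **not** simulate soil/water background reflectance
before canopy closure, NDVI saturation artifacts over dense canopies,
weather-responsive curve shape (the truth curve depends on thermal time
only through the clock), or within-plot replicate-reading variance
(readings arrive already averaged). Passing tests therefore demonstrate
that the pipeline is *self-consistent* — it recovers known generating
structure at realistic noise — not that the fitted parameter values
would match any particular new field campaign.

## Design choices that were genuinely open

- **DAT convention:** the transplanting day is DAT 0, so thermal time
  and observation indexing share an origin.
- **Pooling order:** yield-level groups normalize by the pooled group
  maximum by default; `per_cultivar_norm` instead normalizes each
  cultivar by its own maximum before pooling, for mixed-type groups
  with very different amplitudes. Because a pooled group mixes N
  treatments with different NDVI_max, even noiseless synthetic pooled
  clouds are not exactly one curve — fits on them show R² ≈ 0.98–0.999
  rather than 1, which is a property of the method, not an artifact.
- **Candidate registry:** extensible; only the five published families
  are shipped because only their coefficients are public.
- **Validation NDVI_max:** the validate stage recomputes NDVI_max from
  the validation dataset's own groups (falling back to the model file's
  stored value), matching the "same treatment or yield level" reading
  of the back-transform.

## Problem sizes

The test suite and the acceptance script run everything at the scale of
the emulated design: 36 plots × ~25–30 dates (~1000 observations),
50-point noiseless recovery grids, 200 replicates for noisy-recovery
medians and 100 for ranking win rates. The full suite completes in
seconds on one CPU.

## Known limitations

- The GDD convention behind the published AGDD values is unstated in
  the source; with the default simple-average/base-10 convention the
  published AGDD column is not expected to reproduce exactly, and the
  package does not claim it.
- Steepness parameters a and c are weakly identified from noisy data
  (median relative errors of a few percent at σ = 0.03, far wider in
  the tails); timing parameters b and d are robust. Conclusions that
  hinge on steepness differences need parameter-comparison tests, not
  point estimates.
- Stage bins in RAGDD are a modeling convenience; real stage boundaries
  drift with cultivar and management, and the defaults should be
  adjusted when phenology observations are available.
- The model is descriptive: it carries no nitrogen-response or stress
  mechanism, and transfers only as far as the normalizations hold.
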