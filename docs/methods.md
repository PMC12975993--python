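# Methods

This note documents the models, numerical choices and limitations of
the canalbedo toolkit, in the spirit of a model-documentation page.

## Radiance to broadband albedo

A field spectroradiometer records radiance `L(λ)` on a fixed 1-nm grid
from 350 to 2500 nm (2151 bands). Files on any other grid are rejected
rather than resampled: resampling would silently change the broadband
integral. The chain is:

1. **Dark current.** If the session contains dark captures, the
   (averaged) dark spectrum is subtracted from every capture; if not,
   processing continues with a logged notice, since instruments of this
   class usually dark-correct internally.
2. **Panel interpolation.** White-reference captures are taken roughly
   every 15 minutes; panel radiance at a canopy-capture instant is
   linearly interpolated per band between the bracketing captures.
   Outside the first/last capture the nearest capture is used up to a
   `max_gap` of 20 minutes (slightly above the nominal cadence); beyond
   that the capture fails with a coverage error rather than
   extrapolating. Linear interpolation is exact for linear irradiance
   drift, which bounds the interpolation error below the device noise
   floor for slowly varying illumination.
3. **Reflectance.** `r(λ) = ρ_panel · L_canopy(λ) / L_panel(λ)`, with
   `ρ_panel = 1.0` by default (pure ratio). A scalar or per-band factor
   can be supplied for a calibrated ~99 % panel. Bands with
   non-positive panel radiance are invalid; a capture fails QC if more
   than 5 % (configurable) of bands are invalid. Reflectance values
   below 0 or above 1 are **flagged, never clipped** — clipping would
   bias the broadband mean.
4. **Water-band mask.** The intervals 1350–1420, 1800–1950 and
   2400–2500 nm are excluded (closed endpoints), leaving exactly
   1828 = 2151 − (71 + 151 + 101) bands. The long-wave interval ends at
   the grid maximum of 2500 nm. Closed endpoints are a convention
   fixed here so the retained-band count is reproducible.
5. **Broadband albedo.** The unweighted arithmetic mean of reflectance
   over retained, valid bands. Under the Lambertian assumption the
   nadir reflectance stands in for hemispherical albedo. A
   solar-spectrum weighting hook exists but is off by default: the
   quantity of record is the plain full-range average.
6. **Plot aggregation.** The captures of a plot/period (nominally four)
   give mean and SEM (sample sd / √n; 0 for a single capture).

No BRDF or zenith-angle normalisation is applied: both instruments face
the canopy perpendicularly, which is also why device agreement is best
near solar noon.

Day periods are assigned by local clock time with closed-open windows:
morning [08:00, 10:00), noon [11:00, 13:00), afternoon [14:00, 16:00).

## Albedometer series

Albedo is the ratio of the down-facing to up-facing pyranometer.
Ratios are unstable at low irradiance, so records are dropped when
incoming irradiance is below 20 W m⁻² (below 1 W m⁻² the reason is
recorded as `night`), and ratios above 1.5 are dropped as sensor
faults. Every dropped record carries exactly one reason code. No
irradiance threshold is prescribed by the upstream protocol; these are
package defaults surfaced in configuration.

## Device validation

Each spectroradiometer observation is matched to the mean of kept
albedometer points within ±10 minutes (configurable); unmatched
observations are reported, not raised. Agreement is OLS with Pearson's
r and a two-sided t-test on n−2 df; a Deming option is provided because
both devices carry error, but Pearson/OLS is the quantity of record.

## Trial genetics

Per environment, the randomised complete block model
`y_ij = μ + block_j + genotype_i + e_ij` is fitted with genotype and
block random. Balanced data use ANOVA method-of-moments
(σ̂²_e = MSE, σ̂²_g = (MSG − MSE)/r truncated at 0), which coincides
with REML; unbalanced data use Fisher-scoring REML with step-halving,
started from the method-of-moments values and stopped when successive
REML log-likelihoods change by less than 1e−8. Components at the
boundary are truncated to 0 and flagged; truncation keeps H² in [0, 1].
With missing plots the replicate count entering H² is the harmonic mean
of per-genotype replicate counts.

Heritability is reported on the **line-mean basis**
`H² = σ²_g / (σ²_g + σ²_e / r)`. A Cullis-style generalised
heritability (1 − PEV/σ²_g) is available behind a flag; the two
coincide for balanced designs. Genotype BLUPs shrink raw mean
deviations toward the grand mean by `σ²_g / (σ²_g + σ²_e / r)`; for a
balanced single environment this equals H², and the result matches a
direct Henderson mixed-model-equations solve.

The multi-environment model fits fixed terms **sequentially** in the
order Year, Environment (time of sowing), Year:Environment, Genotype,
Genotype:Environment, with replicate-within-environment as a random
intercept. The block-variance ratio γ is estimated by profiled REML
(the compound-symmetry structure admits a closed-form whitening, so the
optimisation is one-dimensional); columns that do not increase the
design rank after earlier terms are dropped with the term's df reduced
(with three (year, tos) cells the Year:Environment interaction has
0 df, as expected). Each term's incremental Wald statistic W is the
drop in whitened residual sum of squares over the estimated residual
variance, χ²-scaled with df = rank gained. **p-values use the Wald-F
reference** F(df_term, n − p): the raw χ² reference ignores
residual-variance estimation error and is anticonservative at trial
sizes (the χ² p is still exposed as `p_chi2`). With γ = 0 and balanced
data W/df reproduces the classical sequential ANOVA F exactly.
Significance codes: *** p < 0.001, ** p < 0.01, * p < 0.05, else NS.

Spatial AR1×AR1 residual models are out of scope; row/range trends can
only enter as iid random intercepts.

## GGE biplots

The genotype × environment table (means or BLUPs) is centred by
environment means — removing E and leaving G + G×E — and decomposed by
SVD. Scores are `U·S^f` and loadings `V·S^(1−f)` with the symmetric
partition f = 0.5 by default, under which environment-vector angles
reflect between-environment correlation and vector length the G + G×E
discrimination. No scaling is applied by default (environments share
albedo units); sd-scaling is behind a flag and rejects constant
columns. Missing cells are mean-imputed (logged). Component signs are
fixed so the first environment's loading is non-negative, making runs
byte-identical; angle and length diagnostics are invariant to this
convention.

## Micrometeorology

ΔT is **spike-height minus below-flag-leaf** air temperature (upper
minus lower; positive when the canopy top is warmer). The sign
convention is fixed here and carried in output metadata. Logger series
are never resampled: records are paired nearest-in-time within a
10-minute tolerance, and ΔT is the mean paired difference within a
stage window (heading/flowering) and optional day period. Infrared
canopy temperature is aligned to spike-height air temperature the same
way and summarised by OLS. Trait tables give pairwise-complete Pearson
correlations with per-cell n and two-sided p; no multiplicity
correction by default (Holm available behind a flag).

## Synthetic campaigns

The generator defines the study conditions; defaults are fixed once:

* **Trials:** 30 genotypes × 3 replicates × 3 environments
  ((2018, TOS 1), (2018, TOS 2), (2019, TOS 1)); genotypic variance
  0.0043, residual 0.0021 (line-mean H² = 0.86 at r = 3), G×E variance
  0.001, block variance 0.0005, grand mean 0.20. Environment main
  effects are deterministic offsets (+0.015, −0.02, 0), mirroring a
  fixed-effect trial structure.
* **Diurnal model:** solar elevation follows a half-sine day of 12 h
  peaking at 60°, solar noon at 12:03 local; true albedo is
  `α(t) = α_noon + c·(sec z(t) − sec z_noon)` with α_noon = 0.20 and
  c = 0.03, clipped to [0, 0.95] — a U-shape with its minimum exactly
  at solar noon and daytime values in the 0.15–0.25 range typical of
  cereal canopies. Incoming irradiance peaks at 1000 W m⁻².
* **Spectra:** canopy radiance is irradiance × a vegetation/soil
  mixture (green peak, red-edge, NIR plateau, water-band dips; soil
  monotone increasing) rescaled so its masked-band mean equals the
  target albedo. Capture noise is a multiplicative log-normal factor
  (1 % by default, mean-corrected so plot means are unbiased); radiance
  is positive, so noise is never additive-Gaussian on the spectral
  scale. A per-band noise channel exists (0 by default). Dark current
  is a constant offset added to every capture.
* **Loggers:** additive Gaussian noise (pyranometers 2 W m⁻²,
  temperature loggers 0.2 °C). Plot-level ΔT is drawn so its
  across-plot correlation with albedo is ρ = 0.48; canopy temperature
  tracks spike air temperature with noise calibrated to a within-plot
  correlation of 0.99.

All randomness flows from one seed through named substreams, so adding
a fixture never perturbs existing ones; identical seeds give
byte-identical fixture files.

What the generator does **not** emulate: radiative-transfer realism
(no PROSAIL-class canopy model), weather fronts and clouds, spatial
field trends, phenology-dependent canopy change, or instrument
calibration drift. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not field
validity of the measurements.

## Verification strategy and problem sizes

Every estimator is checked against an independent oracle: hand ANOVA
and Henderson solves, closed-form normal equations, full-SVD
reconstructions, explicit summation for window means, and statsmodels
MixedLM for the unbalanced REML path. Monte-Carlo suites use 500
balanced trials for component recovery, 1000 null trials for Wald
type-I calibration (empirical rate checked against binomial 95 %
bounds), and 1000 seeded plots for pipeline inversion — sizes chosen to
make Monte-Carlo error small relative to the asserted tolerances.

Two statistical subtleties are worth recording. The plot-mean coverage
check uses the noise-model SEM (σ_noise/√n): with four captures, three
*sample*-SEM intervals have only t₃ ≈ 94 % coverage no matter how small
the noise, so sample-SEM behaviour is tested separately. And the mean
of Ĥ² over simulations sits ≈ 0.01 below the true 0.86 at 30 genotypes
— Ĥ² is a concave transform of the unbiased σ̂²_g (delta-method bias
O(1/n)) — so the simulation suite asserts strict mean recovery of
σ̂²_g and mean Ĥ² within 0.02. The diurnal U-curve has a flat bottom:
the raw argmin under default pyranometer noise wanders by tens of
minutes, so the time-of-minimum contract is asserted on the noiseless
curve while noon-mean recovery uses the noisy stream.

## Known limitations

* The REML fit covers genotype + block random effects; arbitrary
  variance structures (spatial correlation, heterogeneous G×E) are not
  implemented.
* Wald denominator df is n − p rather than a Kenward–Roger or
  Satterthwaite approximation; at trial sizes (≥ 180 residual df) the
  difference is negligible, as the calibration suite confirms.
* The albedometer QC thresholds are heuristics, not calibrated to any
  particular sensor.
* Proprietary binary spectroradiometer formats are not decoded; the
  long-format text dialect is the interchange format.
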