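# Methods

This note records the models behind `digiwell`, the parameter choices that
matter, and what the simulator does and does not claim about real chips.

## Chip geometry and mask registration

The chip is modelled logically: `n_modules` identical modules, each a
row-major `grid_rows x grid_cols` grid holding `wells_per_module` wells
(grid slots beyond that count carry no well). The production default is
4 x 10 040 wells of 1 nL. The grid factorization is not physically
documented anywhere we could anchor it, so the default uses the exact
factorization 40 x 251 = 10 040 — exactness avoids a partial final row and
makes enumeration unambiguous. Well pitch (120 µm) and diameter (90 µm) are
rendering defaults only; they set the simulated image scale and never enter
any counting or quantification logic.

Registration takes "four geometric user inputs" to be the four module
corner pixels in TL, TR, BR, BL order. Four correspondences determine a
projective homography exactly (direct linear transform); we fit projective
rather than affine because flatbed scans of a mounted chip can show mild
keystone. The fitted map must hit all four corners to 1e-6 px, and any
three collinear inputs are rejected. Pixel coordinates are 0-based
(x = column, y = row) with continuous coordinates at pixel centers.
Automatic corner detection and lens-distortion models are out of scope.

## Partitioning and amplification model

Loading a nominal `c` copies draws the realized molecule number
`M ~ Poisson(c)` — dilution of a synthetic stock is physically Poisson,
which is also what gives fractional nominals such as 6.25 their meaning.
Each molecule is retained in a well with probability `retention_fraction`
(default 0.5: about half the master mix ends up in wells, the rest stays in
the feed channels) and retained molecules land uniformly at random across
the module's 10 040 wells. Each molecule amplifies independently with
probability `amplification_probability` (default 1.0 — the chemistry is
designed to detect essentially every template); a well is positive when at
least one of its molecules amplifies. Methylation-specific primers do not
amplify the unmethylated background, so background copies are carried in
the ground truth but generate no signal; a `false_amplification_rate`
switch can inject spurious positives for robustness testing.

`partition_molecules(..., exact=True)` loads exactly the nominal (integer)
molecule count instead of a Poisson draw. This deterministic-input mode
exists because limit-of-quantification claims are statements about
detecting *loaded* molecules ("every loaded molecule yields a positive
well"), not about the Poisson statistics of preparing the dilution: at a
nominal 1 copy a Poisson draw is empty 37% of the time, which would measure
the input preparation rather than the assay. The standard-curve workflow
keeps the Poisson draw; the LOQ workflow uses exact loading.

## Image rendering

Each well is rendered as a flat disk (well diameter) at its mapped center;
the disk amplitude is one draw per well per channel from the negative
population N(800, 50) ADU or the positive population N(12000, 800) ADU.
A Gaussian PSF (sigma 1 px) blurs the scene, spectral crosstalk mixes
channels linearly (identity by default — the four dyes were chosen for
minimal overlap; off-diagonals are capped at 5%), then a constant
background (200 ADU) and per-pixel Gaussian read noise (sd 25 ADU) are
added and the image is clipped to the 16-bit range. Disks are stamped at
the nearest-pixel center; sub-pixel placement is deliberately not modelled
(the extraction aperture is strictly inside the disk, so a half-pixel
offset never leaks background into the aperture at the default scale of
0.1 px/µm). The default intensity populations are separated by more than
200 negative SDs, as endpoint digital PCR produces; the simulator enforces
at least 10 SDs of separation. Scanner optics, flat-field structure and
fluid dynamics are not modelled.

Images are written as multi-page 16-bit grayscale TIFF with the channel
name in each page's description tag.

## Intensity extraction

Per well and channel, the mean of the pixels whose centers fall within a
circular aperture of radius 0.35 x pitch around the mapped center. The
averaging footprint of the original acquisition software is not documented;
a disk at 0.35 pitch stays inside the well under moderate registration
error. Pixel inclusion is a strict center-in-disk test with no
partial-pixel weighting, which makes extraction deterministic, exactly
linear in the image, and exactly equivariant under integer translations.
No background subtraction is performed — the constant background simply
shifts the negative population, which the mixture model absorbs.

## Mixture model and five-sigma threshold

Each channel's 10 040 per-well intensities are fitted with a two-component
location-scale (Gaussian) mixture by EM. The acquisition literature calls
this a "Poisson mixture model" without writing down a likelihood for
continuous fluorescence; we use the Gaussian mixture as the working model
and report the Poisson-loading reparameterization of the weight
(`lambda = -ln(1 - w)`, since the occupied-well fraction under Poisson
loading is `1 - exp(-lambda)`) — tying the weight to lambda adds no
identifiability, so it is a report, not a constraint.

Numerical choices:

- Initialization is deterministic from data quantiles (negative component
  at the 10th percentile with 1.4826 x MAD spread, positive at the 99.9th
  percentile, initial positive weight 0.02); no random restarts, so the
  same data always give the same fit.
- Convergence: relative change of the log-likelihood below 1e-8, cap 500
  iterations. SDs are floored at 1e-6 ADU.
- Very large inputs (above 200 000 values) run the EM iterations on a
  deterministic stride subsample and then refine on the full data; on a
  10^7-value fit this changes component estimates by well under the
  sampling noise (~0.2% on SDs) and cuts runtime ~20-fold.
- Identifiability guard: if the fitted "positive" mean lies below the
  negative five-sigma threshold, the two components describe one
  population; the fit collapses to a single population whose statistics are
  the plain sample mean/SD (weight 0). Without the guard, EM on
  negative-only data converges to an arbitrary split of the single Gaussian
  and the threshold would measure a local optimum rather than the 5σ tail.

The positivity threshold is `negative_mean + 5 * negative_sd`. For a
Gaussian negative population the 5σ upper-tail mass is 2.87e-7 — roughly
one false positive per million well measurements, i.e. fewer than one
spurious count per four-module chip. Calls use strict inequality (ties at
the threshold stay negative), channels are fitted independently, and a
sub-1/n positive weight still leaves the threshold anchored on the dominant
component. Multi-population "rain" modelling and crosstalk unmixing are out
of scope (the simulator can generate crosstalk; the caller does not undo it).

## Quantification

`lambda = -ln(1 - k/N)` converts `k` positive of `N` wells into mean
occupancy; `corrected_copies = lambda * N` is the molecule estimate
(undefined at saturation `k = N`). Copies per mL divide by the
plasma-equivalent volume (default 0.1 mL) and the retention fraction. The
pipeline reports raw counts, corrected copies and retention-adjusted copies
per mL side by side, because published detected-vs-expected plots do not
state which convention they use; the headline value is the corrected,
retention-adjusted one. Confidence intervals on lambda are not implemented
(point estimator only).

Standard-curve metrics: OLS of detected on expected over the nonzero ladder
points on linear axes; the 0-copy point is a negative control excluded from
the regression. LOD is the smallest nominal detected in at least one
replicate, LOQ the smallest detected in all replicates, and analytical
specificity is LOQ / background copies x 100 (with 200 000 background
copies and LOQ 1 this is 0.0005%).

## MethyLight comparator

`mean_2dct = (2^-dCt_1 + 2^-dCt_2 + 2^-dCt_3) / 3` with
`dCt_i = Ct_i - Ct_ref`; undetected replicates enter at Ct = 100, giving a
near-zero rather than missing contribution. The reference-gene (LINE-1)
mean Ct is consumed as an input; reference quantification itself is wet
chemistry outside this package. The result is exactly multiplied by `2^c`
when the reference shifts by `c`, and is monotone decreasing in each target
Ct — both are tested properties.

## Clinical statistics

- Univariate thresholds maximize Youden's J = TPR - FPR over midpoints
  between adjacent distinct values (plus ±inf), ties broken toward the
  higher threshold (higher specificity). The source description of the
  objective ("true positive rate minus false negative rate") is internally
  inconsistent — TPR - FNR = 2·TPR - 1 is maximized by calling everything
  positive — so the implemented objective is the standard Youden index,
  which matches the described sensitivity/specificity trade-off.
- Panel models are logistic regressions fitted by IRLS with a 1e-6 ridge
  jitter on the Hessian; the jitter keeps the Newton step defined on
  separable leave-one-out folds, which warn and return the last iterate.
  Evaluation is leave-one-out: each sample's case probability comes from a
  model that never saw it, and those held-out probabilities are swept as
  thresholds to build the ROC (tied probabilities collapse to one vertex,
  so the trapezoidal AUC equals the Mann-Whitney statistic with ties
  counted one half).
- Bootstrap CIs resample cases and controls within class (stratified), so
  every resample contains both classes; percentile interval, seed recorded.
  Stratification is a package choice — unstratified resampling can produce
  single-class resamples at this cohort size.
- Printed clinical percentages use round-half-away-from-zero to integer
  percent, the convention of clinical tables.
- `panel_search` evaluates all nonempty subsets (capped at 8 markers) by
  LOOCV AUC, ties broken toward smaller panels.

## Cohort generator and calibration

`simulate_cohort` draws each sample's per-marker copies-per-mL as
`Poisson(rate x 0.1 mL) / 0.1 mL` — pure counting noise on a
100 µL plasma equivalent, with class-specific rates per marker:

| marker | case rate (copies/mL) | control rate |
|--------|----------------------|--------------|
| SOX17  | 13                   | 4            |
| CDO1   | 10                   | 5            |
| TAC1   | 8                    | 2            |
| HOXA7  | 9                    | 5            |

The rates were calibrated once, by large-sample Monte Carlo, so the
four-marker logistic panel has a **population AUC of 0.86** (measured
0.861), the discrimination level the pipeline's recovery test targets;
controls carry low but nonzero rates, reflecting background methylation in
cancer-free individuals. Optional covariates: age N(67, 8) years for cases
vs N(64, 8) for controls, pack-years N(45, 25) vs N(35, 25) clipped at 0.

What the generator does **not** model: inter-patient heterogeneity of
methylation burden (every case shares one rate per marker, so real cohorts
are more dispersed than simulated ones), marker correlations within a
patient, pre-analytical losses, and assay failures. Passing the recovery
test therefore shows the estimation machinery is unbiased at the study's
sample size under the stated model — it does not certify clinical
performance on real plasma, which requires patient data this package does
not ship.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run at the platform's native
scales: 10 040 wells per module for all calling and quantification checks,
the seven-point ladder (0–200 copies) in duplicate with 200 000 background
copies for the standard curve, 10^7 wells for the false-positive-rate
check, 10 000 replicates for the occupancy-estimator bias check, and 200
synthetic cohorts of 39 cases + 33 controls for the LOOCV recovery check.
Full-chip image rendering at 0.1 px/µm keeps a four-channel module image
near 3000 x 500 px, which makes the complete simulated standard curve run
in seconds.

## Known limitations

- The mixture likelihood is Gaussian; heavy-tailed negative populations
  (dust, debris) would widen the fitted SD and raise thresholds
  conservatively rather than being modelled explicitly.
- The occupancy estimator assumes uniform loading across wells; systematic
  loading gradients would bias lambda.
- LOOCV AUC at n = 39 + 33 is slightly pessimistic relative to the
  population AUC (measured mean 0.823 vs 0.861 over 200 cohorts) — the
  small-sample cost of honest cross-validation, visible in the recovery
  test's tolerance.
- The CLI covers the common single-module workflows; multi-module batch
  orchestration is left to scripting the library.
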