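# Methods

## Scope and model

`optoquant` implements the measurement and modeling chain used to
characterize blue-light (LOV-domain) optogenetic activators of FGF, BMP
and Nodal signaling in zebrafish embryos. The inputs are multi-channel
confocal z-stacks (nuclear stain, co-injected GFP reporter, and a
phospho-effector immunofluorescence readout: ppERK, pSmad1 or pSmad2),
a manifest CSV describing each sample's condition, and a YAML run
configuration. The outputs are per-sample region-median statistics with
QC decisions, group-level statistics, and fitted response models with
derived kinetic/dose parameters.

### Quantification

Per sample, the pipeline builds three boolean 3D masks by thresholding:
the nuclear ("DAPI") region, the reporter-positive ("GFP") region, and
their intersection ("DAPI+GFP"). Mask membership uses a strict
inequality (intensity > threshold), so a threshold at the global maximum
yields an empty mask. Thresholds default to Otsu's between-class-variance
split, with a manual override mirroring interactive workflows; the Otsu
cut is reported mid-gap between the two separated populations, which
leaves the induced mask unchanged while keeping the threshold strictly
between well-separated modes.

The effector channel is divided voxelwise by the GFP channel to correct
for heterogeneous mRNA distribution (the reporter and the activator mRNA
disperse together, so GFP is a proxy for activator dose). Voxels with
zero reporter intensity are marked undefined and excluded from all
medians — an epsilon-clamp would silently distort the ratio statistics.
Six medians are computed over the imaged 3D volume: raw and normalized
effector within each of the three regions. Empty regions produce NaN
plus a QC reason, never a silent zero. Downstream analysis consumes the
normalized GFP-region median for FGF and BMP and the normalized
DAPI+GFP-region median for Nodal, whose effector is nuclear.

### QC gates

Automatable gates: (1) reporter coverage — samples whose GFP mask covers
less than 5% of the embryo extent are excluded as under-injected; the
embryo extent is the largest connected component of the DAPI channel
above a low background threshold (default 10% of the DAPI Otsu cut),
since raw stacks do not delineate the embryo; (2) saturation streaking —
a per-channel saturated-voxel fraction above 1% flags the sample; this
is a deliberately simple heuristic stand-in for a visual criterion;
(3) nuclear damage — a DAPI-negative cavity inside the embryo extent
larger than one third of embryo voxels. Criteria that are inherently
visual (embryo off frame, second embryo, mounting angle, truncated
stack) enter as manual flags on the manifest and pass through to the QC
result unchanged.

### Response model

Dark-subtracted, GFP-normalized signal is modeled by the
three-parameter logistic with lower asymptote fixed at zero:

    y(x) = c / (1 + exp(-a (x - b)))

with growth rate `a` (per min or per W/m²), inflection `b`, and upper
asymptote `c >= 0`. Kinetics data are split at the configured exposure
end (default 30 min) into an on phase and an off phase; off-phase time
is re-origined to time since light removal and fit with `a < 0`.
Characteristic points follow by inversion: rise solves y = p·c
(x = b − ln((1−p)/p)/a, giving tON_p and I_p), decay solves the
p-fractional decrease y = (1−p)·c (x = b − ln(p/(1−p))/a, giving
tOFF_p). At p = 0.5 both reduce to the inflection point exactly, which
the suite asserts to 1e-9. Derived values may be negative
(extrapolation below the first sample point) and are reported as-is.

Fitting is nonlinear least squares (trust-region reflective, analytic
Jacobian) from a deterministic multi-start grid: c0 = max(y), b0 at the
half-maximum crossing and at the median x, a0 in {0.05, 0.5, 5} signed
by phase; the lowest-SSE solution wins, making fits reproducible
without a random initializer. Degenerate data (no response) converge to
c ≈ 0 and are flagged rather than erroring. Fits require at least 4
points over at least 3 distinct x values.

### Uncertainty

Per-parameter (a, b, c) 95% intervals come from the delta method using
the Jacobian-based covariance. Derived parameters use a seeded residual
bootstrap: residuals about the fitted curve — inflated by
sqrt(n/(n−3)) so their variance matches the error variance — are
resampled with replacement, the model refit (warm-started at the point
estimate), and the derived value recomputed; the interval is the
2.5/97.5 percentile range. Intervals are marked unreliable when more
than 20% of refits fail. At the kinetics design (11 time points, 3
replicates, noise 10% of the asymptote) measured coverage of the
tON_50 interval is ≈ 90–93%, the mild undercoverage typical of
percentile intervals at this sample size.

### Group statistics

Technical replicates are averaged within (tool, condition, biological
replicate) after QC exclusion; groups with no passing record are kept
as explicit missing entries. Dark subtraction is key-matched (time- and
replicate-matched for kinetics, replicate-matched for the irradiance
design) and raises on a missing control; negative differences are
retained. The wavelength analysis uses a one-way random-intercept model
(condition fixed, biological replicate random) fit by direct profiled
REML over the single variance ratio; on balanced data the least-square
means equal the arithmetic group means exactly, and the fit agrees with
`statsmodels` MixedLM, which serves as an independent cross-check in
the tests. Post-hoc families (Tukey all-pairs; Dunnett versus the
time-zero control for kinetics) are adjusted by seeded Monte Carlo of
the null max-|t| distribution (100k+ draws); adjusted p-values are
clamped to at least the unadjusted t p-value so the family adjustment
is monotone despite simulation noise. The Wald F-test of the condition
effect uses the balanced error df n − k − q + 1, an approximation that
is exact for the balanced designs it targets. The phenotype-based mRNA
quality gate evaluates the 60%/20%/30% fractions with the comparisons
exactly as worded: "at least 60%" passes at exactly 60%, "more than
20%" passes at exactly 20%.

### Photometry

All internal units are SI. Irradiance is measured power over detector
(or scanned-ROI) area; dosage is irradiance × duration. For a
laser-scanned ROI the time-averaged irradiance is the sample-plane
power over the ROI area, optionally scaled by a scan duty factor. Note
one source of irreducible discrepancy with published exposure tables:
5.6 µW over 45,000 µm² is 124.44 W/m² and 2.1 µW is 46.67 W/m², so
printed values of 126.93 and 47.60 W/m² imply unrounded power readings;
this package always reports its own arithmetic from the stated inputs.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not embryo optics or biology: a hemispherical cap of tissue (animal
pole up, z = 0 at the stack top) on a dark background; non-overlapping
spherical nuclei placed by rejection sampling; mosaic reporter
expression as smoothed Gaussian noise thresholded at the
(1 − mosaic_fraction) quantile, mimicking clonal patches of injected
mRNA with a configurable patch scale; and an effector channel whose
expectation is `baseline + gain × activation × reporter`, optionally
confined to nuclei and/or an illuminated ROI box. Noise is additive
Gaussian, clipped to [0, saturation]; volumes are 16-bit. Every output
is a pure function of the truth parameters and seed (bit-identical on
repeat). Defaults: 64×128×128 voxels at (9, 5, 5) µm — the 9 µm z-step
matches the acquisition interval the analysis was designed around —
110 nuclei of 12 µm radius in a 220 µm embryo, 60% mosaic coverage.
Tests and the acceptance script use reduced grids (16×48×48 with a
100 µm embryo) so full image datasets render in seconds; grid size does
not enter the statistics beyond voxel counts.

What the generator does not model: point-spread functions and
out-of-plane light (including the cone-shaped illumination artifact of
scanned stimulation), cell movement, staining chemistry, or
pathway crosstalk. Passing tests therefore validate the measurement
and inference chain — masking, normalization, medians, QC logic,
subtraction, fitting, and uncertainty — under controlled truth, not
robustness to optical artifacts in real stacks.

Experiment-level datasets drive per-volume activation with the
programmed logistic (activation = y(x)/c at each sample point; dark
controls at zero) and write OME-TIFFs, a manifest CSV and a truth JSON.
A data-level simulator (`simulate_response_points`) produces
dark-subtracted response points directly for fitting studies where
rendering images would add nothing. Embryo-to-embryo variability
magnitudes are exposed as free parameters (`noise_sd`,
`rep_effect_sd`) rather than asserted, since no calibrated values are
available.

## Numerical and design choices

- Fits are deterministic given the data (fixed multi-start grid); all
  Monte-Carlo machinery (bootstrap, post-hoc null draws) is seeded.
- The exposure-end phase boundary (30 min), the derived fractions
  (0.2, 0.5, 0.9), the irradiance ladder and the kinetics time points
  are configuration defaults matching the experimental design the
  package targets.
- Replicate means are fit (one point per time × replicate); pooling
  individual technical replicates into the fit is available by passing
  the unaggregated table to `fit_logistic3`.
- Saturated voxels that survive the streaking gate are included in
  medians.
- Variance-component recovery by REML is validated at designs with ≥ 8
  replicate levels; with very few replicates (2–3) the REML estimate of
  the replicate variance is strongly right-skewed and its median sits
  well below the truth, which is a property of the estimator, not a
  defect of the optimizer (the balanced-data closed form and the
  `statsmodels` cross-check agree).

## Known limitations

- Thresholds are applied per sample; the interactive practice of fixing
  thresholds per replicate batch can be reproduced by passing manual
  thresholds in the config.
- The streak detector is a saturation-fraction heuristic and will not
  flag structured streaking below the voxel-fraction trigger.
- Bootstrap CIs for derived parameters are percentile intervals; at
  small n they run slightly narrow (see coverage above). Delta-method
  intervals for (a, b, c) are exposed for comparison.
- The BMP phenotype gate is not monotone in added severe phenotypes
  (they dilute the V1–V4 fraction); the FGF/Nodal rule is.
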