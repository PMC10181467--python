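# Methods

This note records the models, defaults and design choices behind
`phenorover`, and what the synthetic experiments do and do not demonstrate.

## Geo-referencing

GNSS fixes are projected to planar field coordinates with a local spherical
equirectangular projection: x = R·cos(lat₀)·Δλ, y = R·Δφ (radians),
R = 6 371 008.8 m. For fields under a kilometre the distortion is below a
centimetre, so no UTM zone machinery is warranted. The projection is
analytically invertible; round-trip error is below 10⁻⁹ degrees.

Boom sensors sit at signed lateral offsets from the vehicle centreline
(positive = left of travel, defaults ±1.2/±1.9/±2.6 m for the six
spectral/ultrasonic units, ±1.5 m for the two weather units). A sensor's
position is the vehicle fix plus the offset rotated 90° from the heading.
Headings come from the chord between fixes ±w positions apart within a
contiguous driving pass (passes are split on time gaps > 5× the median
sampling interval; endpoints use one-sided chords; coincident fixes carry
the previous heading). The default half-window w = 50 fixes (~2 m of travel
either side at 0.8 m/s and 20 Hz) is deliberate: at the default fix spacing
of 4 cm and GPS noise of 0.3 m, a short chord gives essentially random
headings, and rotating a 2.6 m offset by a random angle would scatter
readings across the wrong plots. A ~4 m chord keeps the induced lateral
error well inside the 2 m alleys. For handheld-style data with metres
between fixes, a smaller window is appropriate and configurable.

Plot containment is half-open (lower/left edge inclusive, upper/right
exclusive), so boundary points resolve deterministically to exactly one
plot. Layout rectangles are validated to be non-overlapping.

## Plot aggregation

Within a plot, trait readings are modelled as a two-component normal
mixture (soil and plant classes). Each plot × date × trait reading set is
thresholded at the interior edge of a uniform histogram maximizing the
between-class variance ω₀ω₁(μ₀ − μ₁)², computed from histogram bin centres.

Numerical choices:

- **Bins:** 64 by default. Plots collect hundreds to a few thousand
  readings per date; 64 bins resolve the two modes without starving
  individual bins. An exhaustive-scan oracle in the test suite keeps the
  histogram/threshold computation honest.
- **Tie-break:** with cleanly separated modes the variance curve is
  *exactly flat* across the empty gap between them (moving the edge over
  empty bins changes neither class), so ties are resolved to the midmost
  maximizing edge — the threshold sits centred in the gap rather than
  hugging a mode. Lowest-edge tie-breaking would bias the threshold against
  the lower class and is avoided deliberately.
- **Bimodality gate.** A split is flagged untrustworthy when (i) the
  winning edge lies in the outer 5% of bins, (ii) the class means differ by
  less than one pooled within-class standard deviation, or (iii) the
  between-class variance explains less than 0.8 of the total variance
  (Otsu's effectiveness metric). Gate (iii) is the operative unimodality
  test: because the optimal split truncates both classes, even a pure
  Gaussian shows ~2.6 within-class standard deviations of separation, but
  its effectiveness tops out near 0.64 (uniform data ~0.75) while genuine
  soil/plant mixtures exceed 0.85. When the gate trips — e.g. full canopy
  closure late in the season leaves no soil mode — the aggregate uses all
  readings and carries `bimodality_ok = False`.
- **Aggregates:** maximum over all readings, and the mean of readings
  *strictly above* the threshold (consistent with the half-open convention
  elsewhere). A plain mean (`simple_mean`) is always reported as the
  handheld-protocol benchmark. Sets smaller than 20 readings are not
  thresholded. Thresholding is per trait by default; a shared-mask option
  derives the above-threshold mask from one reference trait (e.g. NDVI)
  and applies it to all traits.
- Plant height is mount_height − distance, clipped below at zero, with a
  flag for readings beyond the mount height (bare-soil overshoot). The
  mount height is a required configuration value (default 1.5 m).

## Envirotyping

Weather records are averaged per plot × date, then expanded into four
temporal schemes: same date (a), previous *measured* date (b), cumulative
mean over measured dates ≤ d (c), and < d (d). "Previous" always means the
previous campaign date, not the previous calendar day — the platform only
records weather while scanning. Schemes b/d are undefined at the first
date; in model designs they fall back to the same-date value there, so a
model carrying a scheme-b/c/d feature remains estimable on all dates. Two
identities follow from the definitions and are enforced by tests: c = a at
the first date, and d at date k equals c at date k−1.

Soil chemistry is interpolated to plot centroids by IDW with power 2 using
all six core locations per depth (with six points a neighbourhood cutoff
would be meaningless). Queries within 10⁻⁹ m of a core return that core's
value exactly (the singular limit of the weights). Interpolating to
centroids (not polygon averages) is a deliberate simplification; at 15 m²
plots against ≥15 m soil-variation wavelengths the difference is
negligible.

## Trait models and screening

Responses are the per-plot `mean_above` aggregates (one model per trait:
NDVI, NDRE, CI, height) and yield. Candidates: the two management factors,
14 soil features (7 properties × 2 depths), each weather variable under
each scheme (a weather variable may enter with exactly one scheme — once
one scheme is selected the variable's other schemes leave the pool), and
variety as an all-or-nothing block of dummy columns (reference level
dropped). Greedy forward selection maximizes the plain R² averaged across
all campaign dates; averaging across dates is the guard against
overfitting any one date. Yield is a single-date fit (the mean degenerates
to that fit's R²), using the last campaign date's weather features.

**Stopping rule.** A candidate is accepted only if it improves the mean R²
by more than `tolerance × n_params(candidate)`, tolerance 0.01. The
per-parameter scaling is an adjusted-R²-style penalty chosen on first
principles: with n plots, a pure-noise single column improves a date's R²
by ~χ²₁/n (≈0.004 on average at n = 242, with a maximum over a realistic
candidate pool near 0.01), and a null 10-column variety block clears ~χ²₁₀/n
≈ 0.02 — so a flat, parameter-blind threshold either admits noise variables
freely or must be set so high that it rejects genuine small effects. Under
this rule, recovery experiments with a 3-predictor ground truth at
signal-to-noise 3 select the true support in 20/20 seeds with no false
inclusions, and the default end-to-end campaign selects 6–8 predictors per
trait with mean R² around 0.5–0.75.

Plain (not adjusted) R² is reported and averaged; interaction terms are
excluded by default.

**Residual screen.** The chosen model is refit per date, residuals pooled
across dates, and screened by one-way ANOVA with variety as the factor,
followed by Tukey HSD. Tukey is implemented directly on the studentized
range: CI half-width q₁₋α;k,df·√(MSE/2·(1/nᵢ+1/nⱼ)) at the pooled error df,
adjusted p from the studentized-range survival function (optional — the
quadrature is slow, and rejection needs only the cached quantile). The unit
suite cross-checks differences, intervals, p-values and decisions against
statsmodels' `pairwise_tukeyhsd`, and the k = 2 case against the pooled
t-test via q = √2·|t|. Varieties with fewer than two observations are
excluded with a warning; a zero-within-variance sample is flagged
degenerate rather than tested.

**Repeated measures.** The benchmark-protocol analysis is a balanced
split-plot ANOVA on the plots × dates aggregate matrix: between-subjects
factor variety (tested against subject-within-variety error), within
factors time and variety × time (tested against the within error). The
Greenhouse–Geisser ε̂ uses the covariance of the repeated measures pooled
*within varieties* — pooling across group means would count real
time-profile differences between varieties as non-sphericity. ε̂ = (Σλ)² /
((k−1)Σλ²) over eigenvalues of the double-centred covariance, clipped to
[1/(k−1), 1]; both degrees of freedom of the within-subject F tests are
multiplied by ε̂. For k = 2 the double-centred covariance has one non-zero
eigenvalue, so ε̂ = 1 exactly. F and p values agree exactly with pingouin's
`mixed_anova`; the epsilon conventions coincide on within-group-centred
data (epsilon is scale-invariant), which the test suite exploits for an
exact cross-check. Unbalanced designs are rejected rather than
approximated.

**Effect sizes.** Percent of total SS per category, via sequential (Type-I)
SS in the fixed order Environment → Management → Variety, with Error =
SSE/SST. The ordering convention matters for correlated predictors and is
therefore fixed and documented; percentages sum to 100 by the decomposition
identity.

## The synthetic generator

The generator emulates the trial the analysis assumes, with every
distributional parameter recorded for recovery testing.

- **Layout:** an 11 × 22 grid of 242 four-row plots of 15 m² (3 m × 5 m),
  2 m alleys between plot columns, 1 m gaps between rows; 11 varieties and
  two 2-level management factors (row spacing 559/762 mm, density
  24 700/37 100 plants/ha) assigned by seeded balanced randomization. The
  true plot map of any real trial is unknowable from published material, so
  randomization is the honest default. A 2 × 11 / 6.75 m² configuration
  reproduces a handheld-benchmark trial.
- **Trajectory:** serpentine passes through every alley at 0.8 m/s,
  sampled at 0.05 s by default (a desk-scale thinning of the hardware's
  6 ms stream; 6 ms remains configurable), with a 2 m overshoot past the
  field ends and the first fix half a step into each pass (fixes never sit
  exactly on plot-boundary coordinates, where containment would hinge on
  floating-point round-trips). GPS noise: isotropic Gaussian, sd 0.3 m
  (typical uncorrected GNSS), shared by all sensors at a fix.
- **Readings:** a record over a plot is soil with probability
  `mix_fraction` (default 0.3, matching a vehicle-view share of inter-row
  soil), always soil over alleys. NDVI/NDRE are drawn per class
  (soil ~ N(0.15, 0.04)/N(0.08, 0.03); plant means decline over the six
  campaign dates, e.g. NDVI 0.82 → 0.62, emulating a senescing crop) and
  the three band reflectances are *solved* from them with per-class NIR
  fixed (0.45 plant / 0.30 soil), so downstream VI code is genuinely
  exercised rather than bypassed. Height is drawn per class (soil ≈ 0 with
  1.5 cm sd — so roughly half the soil readings exceed the mount height
  and exercise the clipping flag) and converted to ultrasonic distance.
- **Spatial fields:** weather trends and soil surfaces are linear
  gradients plus six random sinusoids with wavelengths 0.12–0.6 of the
  field extent (≥ ~15 m, smooth at plot scale). The harmonic richness is
  load-bearing: with only long-wavelength structure, any two smooth fields
  over the same plane share a handful of spatial degrees of freedom and
  correlate at |r| ≈ 0.3–0.4 by chance, which makes distinct environmental
  variables statistically interchangeable and defeats selection-recovery
  experiments for reasons that have nothing to do with the selector.
- **Ground-truth responses:** each plot's plant-class mean is date base +
  variety effect + a sparse linear term in z-scored true covariates
  (defaults echo a realistic support: shallow organic matter, a deep
  cation, same-date temperature and PAR, row spacing for height/yield) +
  plot-level noise. Yield applies its own sparse model at the last date,
  in t/ha. Soil cores are sampled at six locations × two depths from the
  true surfaces (sampling noise configurable, default 0).

Everything is reproducible: a seed determines layouts, truths, logs and
files byte-for-byte, and all per-purpose RNG streams derive from
`(seed, stream, date)` tuples.

**What passing means — and does not.** The synthetic fields have exactly
bimodal, exactly normal reading mixtures, stationary sensors biases (none),
no row structure inside plots, no missing GNSS, and weather that varies
smoothly in space but not within a scan. Recovery results therefore
validate the *pipeline logic* — projection, assignment, thresholding,
feature algebra, selection, ANOVA — not robustness to real-world artefacts
(sun-angle drift, sensor cross-talk, lodged plants, RTK dropouts). The
thresholding fallback and malformed-row handling are exercised by
constructed cases, not by a realistic corruption model.

## Problem sizes used in tests and the acceptance script

Full-scale components run at the default trial size (242 plots, six dates,
~230 k spectral records per date); the end-to-end pipeline completes in
about a minute on one CPU. Calibration studies use 200 two-Gaussian
mixtures (n = 1000) for the Otsu oracle, 10⁵ reflectance triples for the
CI/NDRE identity, 20 seeds for selection recovery, 200 subjects for the
compound-symmetry ε̂ study, and 1000 null replicates (11 varieties × 2
replicates) for Tukey familywise-error calibration.

## Known limitations

- No mixed-effects or spatial-error models; plots are treated as
  independent given the modelled covariates.
- No kriging; IDW with six cores cannot represent variogram structure.
- The residual one-way ANOVA screens variety on residuals of models that
  may already contain variety; it is reported as specified for the
  protocol, but its power is limited by construction in that case.
- Scheme b/d values at the first campaign date are a same-date fallback,
  not data.
- GeoJSON maps carry one aggregate value per plot polygon; no rendering is
  provided (any GIS tool or `geopandas.read_file` can style them).
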