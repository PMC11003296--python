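# Methods

## Problem setting

Epiretinal prostheses such as the Argus II (a 6×10 grid of 200 µm platinum
disc electrodes, 575 µm pitch) elicit perceived flashes of light —
phosphenes — that participants draw on a touchscreen. Because epiretinal
electrodes sit on top of passing retinal ganglion cell axons, percepts are
typically elongated along the trajectory of the underlying nerve fiber
bundle (the *axon map* picture of epiretinal stimulation). `phoskit` turns
collections of such binary drawings into quantitative evidence about two
questions:

1. Do paired-electrode percepts behave like the **linear summation** of the
   two single-electrode percepts?
2. Is the **number** of perceived phosphenes for an electrode pair driven by
   the distance *between* their axon bundles rather than by retinal distance
   per se?

## Shape descriptors

Each cleaned drawing is split into maximal 8-connected foreground regions.
Per region we compute the four parameter-free descriptors built from raw
image moments `M_ij = Σ_x Σ_y x^i y^j I(x, y)` (x = column, y = row,
0-based):

- **area** `A = M00`;
- **centroid** `(M10/M00, M01/M00)`;
- **major/minor axis length** `4·√λ1`, `4·√λ2`, with λ the eigenvalues of
  the normalized second-central-moment matrix
  `[[µ′20, µ′11], [µ′11, µ′02]]` — the full axes of the
  equal-second-moment ellipse (the 4√λ convention matches the common
  region-properties implementations; the alternative 2√λ convention would
  halve all axis values and was rejected to keep descriptor ratios
  comparable across toolchains);
- **perimeter**: length of the polyline through the centers of connected
  border pixels. We delegate to `skimage.measure.perimeter`
  (4-neighborhood), which implements exactly this border-polyline
  estimator: orthogonal steps weigh 1, diagonal steps √2, with a
  corner-count correction of (1+√2)/2. Golden values locked by tests: a
  single pixel measures 0, a 4×4 filled square 12, a rasterized disk of
  radius 30 px is within 5% of 2π·30.

Connectivity is 8-connected by default (configurable); a single-pixel
region is flagged degenerate with axis lengths (0, 0) and perimeter 0.
Descriptors are computed in pixel units; `pixels_to_degrees` supplies a
per-pixel arctangent conversion, but because the normalization stage
divides by a per-participant reference, units cancel and pixels remain the
internal standard.

## Drawing cleanup

Drawings are assumed to arrive with contour lines closed and filled (an
optional `close_contours` flood-fill utility exists but is off by default).
Connected regions smaller than 10 px are treated as drawing specs and
removed, *unless* a region at a comparable location appears in at least
half of the trials of the same electrode/stimulus combination. "Comparable
location" is a deterministic surrogate for a manual rule: centroids within
two electrode radii (0.7° of visual angle, converted to pixels through the
screen geometry). A drawing left empty by cleanup is flagged and excluded
downstream. Cleaning is idempotent given a fixed sibling set.

## Axon map and distance decomposition

Nerve-fiber-bundle trajectories follow a fundus-derived model in polar
coordinates (r, φ) about the optic-disc center: φ(r) = φ0 + b(r − r0)^c,
r0 = 4°, with separate superior/inferior coefficient laws (see
`phoskit/axon.py` for the constants). The canonical frame is a right-eye
retinal coordinate system — fovea at origin, +x toward the optic disc at
(15°, 2°), +y superior — with a constant 280 µm per degree. Bundles are
traced from the disc outward, clipped where they would cross the temporal
raphe (y = 0, x < 0) and at 30° from the fovea, then resampled to 10 µm
arc-length steps. Defaults (500 bundles, 10 µm sampling) keep
dense-resampling oracle agreement under 1% while a nearest-bundle query
costs a few milliseconds; left-eye data are mirrored into the canonical
frame at load time.

For an electrode pair, roles are assigned by the nasal-axis coordinate
(ties broken by |y|, the more peripheral electrode counting as temporal —
arbitrary but deterministic). Both distance components are measured on the
**temporal** electrode's closest bundle:

- **between-axon**: minimum distance from the nasal electrode's center to
  that bundle;
- **along-axon**: arc length along that bundle between the two electrodes'
  foot points.

The source description of the decomposition is ambiguous about whose
bundle carries the along-axon walk; we follow the formulation in which both
components live on the temporal electrode's bundle (the alternative,
`axon_of="nasal"`, is retained as a switch — the two formulations give
similar decompositions). The definition works unchanged for pairs
straddling the raphe. Electrode extent is ignored: distances are
center-based.

## Normalization pipeline

The stage order is fixed and recorded in an audit log:

1. **Aggregate within drawing.** Paired drawings: descriptor-wise *sum*
   over regions (accounts for the variable number of perceived phosphenes).
   Single drawings: per-region *mean* by default (summation is available
   via config; the choice only matters for the ~minority of multi-region
   single drawings).
2. **Standard-pulse normalization.** Per participant, each descriptor is
   divided by the mean of that descriptor over all of the participant's
   single-electrode drawings at the standard pulse (2× threshold, 20 Hz),
   pooled over electrodes. This cancels individual drawing bias and scale.
   The reference is computed on drawing-level aggregates. A participant
   without standard-pulse drawings is a configuration error.
3. **Trial averaging.** One data point per (participant, electrode set,
   amplitude, frequency): arithmetic mean of descriptors and of the region
   count; eliminates repeated measures.
4. **Outlier removal.** A data point is dropped when any normalized
   (untransformed) descriptor lies more than 2.5 SD (n−1 estimator) from
   the pooled mean of its analysis set; single- and paired-electrode sets
   are filtered separately, pooled across participants. Zero-SD columns
   remove nothing. kept + removed = input, and removal is deterministic.
5. **Power transforms.** area → area^(1/3); perimeter, major, minor →
   square root. Monotone, hence rank-preserving; chosen to keep regression
   residuals near-normal.
6. **Covariate standardization.** Stimulus and neuroanatomical covariates
   (amplitude, frequency, electrode–fovea distance EFD, electrode–retina
   distance ERD, between-/along-axon distance) are z-scored across the
   pooled data set; a zero-variance covariate (e.g. ERD for a participant
   whose array is fully apposed) is dropped from the design with a log
   entry.

Swapping stages 4 and 5 would change which points are flagged, which is
why the order is locked and asserted.

## Statistical layer

- Participant-level models are OLS fits on standardized predictors;
  reported per predictor: standardized coefficient β, partial correlation
  r (correlation of the residuals of response and predictor on the
  remaining predictors; p from the t transform with n − |Z| − 2 df), raw
  and Bonferroni-adjusted p (family size per table block: predictors ×
  responses), and the variance inflation factor 1/(1 − R²).
- Across-participant models are linear mixed models with a random
  intercept per participant (REML for coefficient reports). Partial
  correlations are computed after subtracting the estimated random
  intercepts. A singular fit falls back to pooled OLS with a flag; a
  boundary estimate of zero between-participant variance is handled by
  setting the random intercepts to zero.
- The summation analysis regresses each paired-electrode descriptor on the
  sum of the two matched single-electrode descriptors without an intercept
  (a zero predictor must imply a zero response). Matching takes the single
  data point at the same frequency and nearest amplitude; unmatched pairs
  are excluded with a log entry. On the untransformed normalized scale the
  slope of the area regression estimates the generative gain directly;
  on the transformed scale the slopes compress toward
  g^(1/n)-style values and are reported as the table-style β.
- Model comparison fits two families on identical rows and compares
  AIC = 2k − 2ℓ̂ and BIC = k·ln n − 2ℓ̂ from the Gaussian (ML, not REML)
  likelihood. Verdict bands: Δ < 2 no preference; 2 ≤ ΔAIC < 7 (ΔBIC < 6)
  some evidence; beyond that, strong evidence against the higher-scoring
  model.
- Welch's t-test (unequal variances, Welch–Satterthwaite df) serves
  between-participant comparisons; two zero-variance groups with equal
  means return t = 0, p = 1 by convention.

## Synthetic cohorts

The generator plants known effect structure so every claim the pipeline
can make is checkable against ground truth. It is deliberately a
*simplified* percept model — a test harness, not a perceptual model:

- A single-electrode percept is a tapered band of disk stamps along the
  bundle closest to the electrode: axial half-length
  L = 140 µm · amp^0.15 · (f/20 Hz)^0.35 · (EFD/2 mm)^0.5 and radial
  half-width W = 28 µm · amp^0.5 · (EFD/2 mm)^0.2 at 1× threshold. These
  power laws plant the qualitative orderings of the real effects (larger
  and rounder with amplitude, longer with frequency, larger and more
  elongated with eccentricity); the numeric values were chosen once to
  give percepts of a few hundred pixels at the standard pulse and are not
  fitted to any reported coefficient.
- Trial noise: lognormal size jitter (SD 0.10 in log units), Gaussian
  percept position jitter (SD 30 µm), a fixed multiplicative
  per-participant scale bias, and with probability 0.10 a 2–8 px spec in a
  band at the top of the drawing frame, for the cleaning stage to remove.
  All trials of one condition share a fixed canvas frame (as on a real
  touchscreen) so locations are comparable across trials.
- A paired percept renders both constituent percepts scaled by √gain in
  each linear dimension (so descriptor sums scale by the planted gain,
  default 0.65). With probability 1 − P(two), where P(two) is a logistic
  in the between-axon distance (midpoint 2200 µm, slope 900 µm — placed
  near the median pair distance of the 575 µm grid so cohorts split
  roughly half/half), the pair *merges*: the two gain-scaled halves are
  laid end-to-end on the bundle under the pair midpoint, fused by a waist
  stamp, with the junction clamped so both halves fit on raphe-clipped
  bundles. An `along` mechanism (logistic in the along-axon distance) is
  available to verify that the model-comparison layer flips.
- Seeding is counter-based: every trial's generator derives from
  (master seed, participant index, condition index, trial index), so any
  single trial is regenerable in isolation and cohorts are byte-identical
  across runs.

Features of real data the generator does **not** emulate: multi-phosphene
single-electrode percepts, brightness/fading dynamics, drawing-order
artifacts, and fundus-specific axon maps. Passing the end-to-end tests
therefore demonstrates that the pipeline recovers effects of the planted
kinds at realistic noise levels — not that the clinical effect sizes are
reproduced.

## Problem sizes and numerical choices

The end-to-end checks run the default design (3 participants × 10
electrodes; amplitude sweep at 20 Hz plus frequency sweep at 2× threshold;
12 pairs × 3 amplitudes at 20 Hz; 5 trials per condition ⇒ ~2040 drawings,
~105 paired data points); the 20-seed model-selection study uses a reduced
design (6 electrodes, 8 pairs, 3 trials) per seed. Axon maps use 500
bundles at 10 µm sampling by default and 300 bundles in most tests.
Tolerances: moment operators match direct summation to 1e-9 relative;
axonal distances match dense oracles to 1%; the planted gain is recovered
within ±0.05; mixed-model CI coverage is checked at the 90% level over 50
replicates.

## Known limitations

- The regression layer is linear throughout; nonlinear shape predictors
  are out of scope.
- The Bonferroni family size per table is a convention (predictors ×
  responses per block) and configurable, since no single family size is
  canonical.
- The generator's merged-percept construction preserves the planted *area*
  sum well (its slope recovers the gain to within ~0.02 before noise) but
  cannot simultaneously preserve all four descriptor sums with one region;
  minor-axis summation slopes on merged-heavy cohorts sit below the
  planted gain's square root, which mirrors the real ambiguity of what a
  "merged" percept preserves.
- Electrode–retina distances and implant pose are inputs, not estimates;
  threshold measurement and OCT processing live outside the package.
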