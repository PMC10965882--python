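# Methods

This note documents the models, conventions and defaults behind
`aerialgaze`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Geometry conventions

Image coordinates have their origin at the top-left corner, x rightward and
y downward, in pixels. Two related but distinct conventions are used:

- **Event screening** treats the image region as the half-open pixel
  rectangle [0, W) × [0, H): pixel coordinate W−1 is inside, W is outside.
  Events recorded in the 100 ms pre-stimulus window carry negative onsets
  and are never valid.
- **Continuous geometry** (critical-object saliency, center bias, rotation
  of annotation vertices) treats the image as the closed rectangle
  [0, W] × [0, H] with center (W/2, H/2) and corners at distance
  √((W/2)² + (H/2)²). This makes the two analytic anchors exact: a polygon
  covering the whole image has Size = 1 and centroid at the center
  (COS = 1), and fixations placed at (W/2, H/2) give a center-bias score of
  exactly 100. A pixel-index center ((W−1)/2, (H−1)/2) would miss both
  anchors by a half-pixel term.

A counterclockwise 90° rotation maps a raster by index permutation
(`np.rot90`, no interpolation) and a point by (x, y) → (y, S − x). COS is
evaluated with exact rational arithmetic (shoelace area and centroid as
`fractions.Fraction`, square roots deferred to the final step), so for
integer-vertex annotations the statistic is bit-identical across the four
orientations rather than merely close.

## Screening

Order of operations: drop the recorded first fixation of every trial →
trial rules (incorrect response; not more than two valid fixations;
non-blink track-loss gap > 100 ms) → participant rule (> 25 % of viewing
time lost or > 25 % of trials excluded) → fixation filters (outside image;
duration < 100 ms; duration > grand mean + 2 SD) → saccade filters
(onset < 75 ms; either endpoint outside the image). The first recorded
saccade is retained.

Two points the procedure leaves open were resolved as follows:

- The "more than two valid fixations" trial rule interacts circularly with
  the dataset-wide duration cutoff (which is only computable after trials
  are selected). The rule therefore counts fixations that pass the local
  per-fixation checks — in-region, ≥ 100 ms, post-onset — and the 2-SD
  cutoff applies at the later fixation-filter stage.
- The 2-SD cutoff is computed on the raw millisecond scale (the reported
  grand mean/SD are in ms even though durations are log-normal), after the
  < 100 ms removal. Both choices are switchable
  (`ScreeningConfig.duration_sd_scale = "log"`,
  `sd_after_short_removal = False`).

The cutoff is a *dataset-level* parameter estimated once. Re-applying the
cascade with the estimated cutoff pinned
(`apply_screening(..., duration_cutoff_ms=...)`) removes nothing
(idempotence); naively re-estimating on already-trimmed data would keep
trimming, which is a property of 2-SD trimming itself, not of this
implementation. The per-rule percentages use the denominators of the
original bookkeeping: fixation filters relative to all fixations of valid
trials, saccade filters relative to all recorded saccades of valid trials.

## Eye-movement variables

- **FDM**: a unit impulse per fixation at its pixel, convolved with an
  isotropic Gaussian of FWHM 0.5° (σ = 0.5 · px_per_deg / 2.355 ≈ 8.5 px at
  40 px/deg), truncated at ±4σ; mass clipped at the image edge is restored
  by renormalization (not reflection) — the simplest choice that preserves
  unit mass exactly. Entropy is in bits; base 2 is used everywhere so the
  FDM entropy and GTE share units.
- **GTE**: computed per observer × image on the 6×6 partition (N = 36;
  5, 8, or 10 segments selectable). Transitions never cross trial
  boundaries. A fixation exactly on a partition boundary belongs to the
  higher-index cell (half-open cells). Empty AOIs have vᵢ = 0 and
  contribute nothing; their undefined transition rows are stored as zeros.
  Occupancy is empirical, not the stationary distribution of M.
- **Center bias**: the normalization is anchored at the two published
  reference points — 0 for a uniform fixation distribution and 100 for
  all-at-center — and interpolates linearly in mean center distance:
  `100·(1 − d̄/E[d|uniform])`. E[d|uniform] has a closed form
  (a(√2 + asinh 1)/6 for a square of side a ≈ 0.3826a; the rectangular
  case integrates the quadrant integral analytically). Samples more
  peripheral than uniform give negative scores; they are reported, not
  clamped. The SE resamples fixations with replacement (1000 runs by
  default).
- **Aggregation** is a strictly unweighted two-stage mean: observers →
  image, images → category, matching the design where each image has the
  same nominal number of observers.

## Image statistics

- **Gabor bank**: 12 orientations at 15° steps over 0–165°. Orientations
  180° apart are redundant for quadrature energy, so the 0–345° variant
  (selectable with `full_circle=True`) duplicates information; the
  half-circle set is the default. Eight frequencies are log-spaced
  0.35–8.56 cycles/degree and converted to cycles/pixel via `px_per_deg`
  (default 40; a frequency at or above Nyquist for the configured scale is
  a configuration error). Kernels are `skimage` Gabor kernels (bandwidth
  1 octave) with the even part made zero-DC by mean subtraction;
  convolution uses edge-replicate padding so a constant image yields zero
  energy everywhere, making the add-a-constant invariance exact rather than
  interior-only. Energy is pooled under population-receptive-field
  Gaussian windows and averaged across the grid; since the analysis
  immediately averages across pRFs, the default grid is a single uniform
  full-image window (a custom grid of (x, y, σ) Gaussians can be supplied).
  The statistics are means over the 4 lowest / 4 highest frequency bands.
- **GLCM homogeneity**: gray levels are a linear quantization of the
  image's own [min, max] onto 64 levels. The co-occurrence offset is
  (0, 1) at distance 1 by default, with an option to average the four
  distance-1 directions — that symmetric set is exactly invariant under
  90° rotation and is used in sensitivity checks. "3×3 processing window"
  is read as sliding-window homogeneity averaged over all fully interior
  windows (the default); a whole-image GLCM mode is retained. The windowed
  statistic is evaluated in closed form as the mean over windows of the
  mean pair weight 1/(1+|Δlevel|), which is algebraically identical to
  building each window's normalized GLCM — verified against a brute-force
  pair-counting oracle — and runs in vectorized time instead of ~360k
  per-window matrix constructions. Note that the common library
  "homogeneity" property is the inverse difference moment 1/(1+(i−j)²);
  the statistic here uses 1/(1+|i−j|) and is computed directly from the
  co-occurrence matrix.
- **COS**: polygon area and centroid by the shoelace formula on vertex
  coordinates (continuous geometry, resolution independent); rectangles
  are 4-vertex polygons. The Stevens 0.7 exponent applies to the size
  ratio only, before multiplication by Location. Zero-area (degenerate)
  annotations contribute 0 with a warning; self-intersecting polygons with
  positive area are rejected.
- **Embedding statistics**: the network is deliberately outside the core —
  embeddings arrive through `EmbeddingSet` (any per-image vectors with
  category labels), which keeps every downstream computation testable with
  synthetic clusters. Similarities are Pearson correlations of flattened
  vectors; an optional flag restricts comparison images to those the
  embedding model classified correctly. PCA keeps all components with mean
  centering only, so score-vector norms equal centered-vector norms
  exactly (the orthogonality property the tests assert).

## Regression

Responses are residualized on (intercept, luminance) by OLS; predictors are
not residualized (the control is applied to the eye-movement data).
Stepwise selection starts from the full nine-predictor model and evaluates
all single-predictor drops and add-backs per step, minimizing
AIC = n·log(RSS/n) + 2k; ties within 1e−9 resolve toward the smaller
model, then lexicographically, making the search deterministic and
invariant to column permutation. Rank-deficient designs are repaired by
dropping dependent columns first. Final estimates, standard errors,
two-sided t-based p-values (no multiple-testing correction) and adjusted R²
come from an ordinary `statsmodels` OLS fit of the selected model.
Category-level fits (n = 12 with 9 candidates) emit a small-sample warning.

A property worth knowing: with the AIC penalty of 2 per parameter, each
pure-noise covariate is spuriously retained with probability
≈ P(χ²₁ > 2) ≈ 0.157, so on null data the intercept-only model is the
modal but not majority outcome (≈ 0.84^p). The tests assert exactly that
calibration rather than an unattainable always-empty selection.

The power routine evaluates the within-factor repeated-measures F test
with noncentrality λ = f²·m·n/(1−ρ), df₁ = m−1, df₂ = (n−1)(m−1), no
sphericity correction, ρ = 0.5 by default (the conventions of the usual
power software; all are arguments). Under the study design (f = 0.25,
m = 12, α = 0.05) the minimal n for 80 % power is 13 and n = 20 gives
> 0.95 — both recomputed, not asserted, in the tests.

## Rotation analysis

Statistics are recomputed at 0°/90°/180°/270° with exact raster
permutation and the matching vertex transform; all images enter the
per-category one-way ANOVA regardless of any classifier correctness.
Orientation groups that are bit-identical are flagged `invariant_exact`
(with F undefined when the within-group variance is also zero) instead of
being run through a 0/0 F ratio. Embedding-derived statistics join the
table only when per-orientation embedding sets are supplied; otherwise the
ANOVA covers the raster and geometry statistics.

## Synthetic-data generator

The generator emulates the study conditions: 12 categories × 20 images ×
20 observers, 600×600 px at 40 px/deg, 3-s viewing, log-normal durations
with arithmetic mean 296 ms and SD 139 ms (location/scale converted
analytically), a central-Gaussian/object-attraction/uniform spatial
mixture, and invalid events at configurable rates (defaults follow the
reported dataset rates where available, e.g. 2.12 % incorrect trials).
Specific modeling choices:

- Fixations are i.i.d. draws from the spatial mixture given the trial's
  parameters — no saccade-length dynamics or inhibition of return. This is
  sufficient for every screening, metric, and regression property the
  tests exercise, but scanpath-sequential structure in real data
  (systematic saccade-amplitude distributions, leftward onset biases) is
  not emulated, so passing tests say nothing about such dynamics.
- Duration draws below 100 ms are folded upward (x → 200 − x, ~1.3 % of
  draws) so that *valid* fixations never trip the short-fixation rule and
  planted violations remain the only ones; the tests compare against the
  correspondingly folded log-normal law.
- The planted fixation-count model is n = base − 4·COS + noise, with
  base = 8: with ~296 ms fixations plus ~30 ms gaps, at most ~8.5
  fixations fit in 3 s, and a base above that capacity would let the
  window, not the planted slope, determine every count. Category texture
  follows a Gaussian-smoothing ladder so measured homogeneity
  rank-orders with category index.
- At most one trial-level violation is injected per trial and one
  event-level violation per event, so the screening report's per-rule
  counts equal the planted counts exactly (the precision/recall = 1
  fixture). Rare scanpaths that would come out with fewer than three
  valid fixations unplanted are redrawn.
- Embeddings are per-category Gaussian clusters (between-/within-category
  SDs configurable); they model separation, not network feature geometry.
- `gen_regression_dataset` emits image-level statistic tables with planted
  linear effects (negative COS → fixation count, negative homogeneity →
  FDM entropy, plus a luminance term removed by residualization) at a
  noise level putting the planted model near adjusted R² ≈ 0.4, the scale
  of the strongest image-level models; it exercises the regression stage
  at n = 240 without paying for image synthesis in every replicate.

Everything is driven by one `numpy` Generator; a fixed seed makes images,
events, embeddings, and therefore the whole pipeline bundle reproducible
byte for byte.

## Problem sizes in the test suite

Unit and property tests run the generator at reduced scale (typically 2–6
categories × 3–10 images × 3–12 observers, 100–300 px images, reduced
Gabor banks where the full 96-channel bank is not itself under test); the
full-scale defaults are exercised by the command-line `simulate`/`screen`
path and remain the package defaults. Oracle-equivalence checks use ≤10×10
instances where brute force is exact and cheap. The stepwise
parameter-recovery suite runs 100 replicates at n = 240.

## Known limitations

- The center-bias normalization is anchored only at its two published
  reference points; other linear-in-distance scores through those anchors
  are conceivable.
- The pRF grid of the original low-level feature pipeline is not
  recoverable in detail; the default collapses it to uniform pooling,
  which the immediate across-pRF averaging justifies but does not make
  identical.
- Windowed GLCM homogeneity averages only fully interior windows; images
  smaller than the window are rejected rather than padded.
- Category-level regressions are reported with their small-sample warning;
  nothing in the package can rescue n = 12 with nine candidates.
- Real deep-network embeddings, and hence the published similarity/PCA
  values, require the user to supply feature vectors through the
  `EmbeddingSet` adapter; the synthetic clusters validate the statistics'
  algebra, not network behavior.
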