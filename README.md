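# aerialgaze

Eye-movement and image-statistic analysis of aerial scene categorization.

When people categorize aerial (bird's-eye) photographs — scenes they have no
egocentric experience of — their viewing behavior reflects both what the
image offers (texture, spatial frequency content, diagnostic "critical
objects") and how they search it. `aerialgaze` is a library and command-line
tool for researchers in visual cognition who want to run this analysis
end to end: screen eye-tracking event tables, compute five eye-movement
variables and nine image statistics, relate them with luminance-controlled
stepwise regression, and test the image statistics for invariance under
right-angle image rotation. A synthetic-study generator reproduces the
statistical structure of such an experiment (12 scene categories × 20
images × 20 observers, 3-s trials, log-normal fixation durations with
M = 296 ms, SD = 139 ms, central fixation bias, attraction to annotated
objects) and carries ground-truth flags for every injected artifact, so
every pipeline stage is testable without human data.

## The quantities computed

**Eye-movement variables** (per observer × image, then averaged over
observers per image and over images per category):

- mean fixation duration (ms) and the number of fixations per 3-s viewing;
- mean saccade amplitude (degrees of visual angle, 40 px/dva);
- **fixation density map (FDM) entropy**: fixation locations are convolved
  with a Gaussian kernel (FWHM 0.5°), normalized to unit mass, and scored
  as Shannon entropy over pixels,
  `H = −Σᵢⱼ FDM(i,j) · log₂ FDM(i,j)` (bits);
- **gaze transition entropy (GTE)**: the image is partitioned into
  N = n² areas of interest (default n = 6, N = 36); with occupancy
  probabilities vᵢ and the row-stochastic transition matrix M of
  consecutive fixations,
  `GTE = −Σᵢ vᵢ Σⱼ M(i,j) · log₂ M(i,j)`, normalized by the maximum
  log₂ N so it lies in [0, 1];
- **center bias**: `100 · (1 − mean distance to center / E[distance |
  uniform])`, so 0 is the uniform baseline and 100 means every fixation at
  the image center; the standard error comes from 1000 bootstrap runs.

**Image statistics** (per image, recomputed at 0°/90°/180°/270°):
Gabor energy on the 4 low and 4 high spatial-frequency bands of a
12-orientation × 8-frequency quadrature bank (0.35–8.56 cycles/dva,
pooled over population-receptive-field windows into a 96-vector);
GLCM homogeneity `Σ P(i,j)/(1+|i−j|)` at 64 gray levels with a 3×3
processing window; within- and across-category perceptual similarity
(mean Pearson correlation of deep-feature embeddings); L2 norms of
full-rank PCA-rotated embeddings for three network layers; and
**critical-object saliency**

```
COS = Σ_c Size_c × Location_c,   Size_c = (area_c / image area)^0.7,
Location_c = 1 − dist(centroid_c, center) / dist(center, corner)
```

summed over annotated critical objects (Stevens' power law compresses
physical area into apparent size; an image fully covered by one object
scores exactly 1, an image with no objects scores 0).

**Screening** follows the event-level procedure: drop the recorded first
fixation; exclude incorrect trials, trials without more than two valid
fixations, and trials with a non-blink track-loss gap > 100 ms; exclude
participants losing > 25 % of viewing time or > 25 % of trials; then drop
fixations outside the image, shorter than 100 ms, or longer than the grand
mean + 2 SD; drop saccades starting within 75 ms of stimulus onset or with
an endpoint outside the image.

**Regression**: each eye-movement variable is residualized on mean CIE
L\*a\*b\* luminance, then submitted to bidirectional stepwise AIC selection
over the nine image statistics, at the image level (n = 240) and scene-
category level (n = 12, flagged as power-limited). Variance inflation
factors and a repeated-measures ANOVA power routine
(λ = f²·m·n/(1−ρ), df₁ = m−1, df₂ = (n−1)(m−1)) are included.

## Worked example

```python
import numpy as np
from aerialgaze import (
    Annotation, critical_object_saliency, required_n, rm_anova_power,
    SynthConfig, gen_images, gen_annotations, gen_scanpaths,
    apply_screening, ScreeningConfig, summarize, aggregate,
)

# saliency of a centered 60x60 px object in a 600x600 image
obj = Annotation("demo", "rectangle", [(270, 270), (330, 330)])
print(f"COS = {critical_object_saliency([obj], (600, 600)):.5f}")

# power analysis for a 12-level repeated-measures design
print(f"required n = {required_n(f=0.25, m=12, alpha=0.05, target_power=0.8, rho=0.5)}")
print(f"power at n=20: {rm_anova_power(0.25, 12, 20):.3f}")

# simulate a small study, screen it, compute per-image metrics
cfg = SynthConfig(n_categories=3, images_per_category=4, observers=6, seed=0)
rng = np.random.default_rng(cfg.seed)
images, categories, objects = gen_images(cfg, rng)
annotations = gen_annotations(cfg, objects)
trials, truth = gen_scanpaths(cfg, annotations, categories, rng)
screened = apply_screening(trials, ScreeningConfig())
print(f"trials kept: {len(screened.trials)}/{len(trials)}")
records = [summarize(t, seed=rng) for t in screened.trials]
per_image = aggregate(records, level="image")
print(per_image[["n_fixations", "fdm_entropy_bits", "gte_normalized"]].head(3).round(3))
```

prints

```
COS = 0.03981
required n = 13
power at n=20: 0.974
trials kept: 71/72
             n_fixations  fdm_entropy_bits  gte_normalized
image_id
cat00_img00        7.667            13.097           0.016
cat00_img01        7.667            13.113           0.034
cat00_img02        6.833            12.978           0.017
```

The 60×60 object covers 1 % of the image, so its Stevens-compressed size is
0.01^0.7 ≈ 0.0398 and, being perfectly centered (Location = 1), that is its
saliency. A medium within-factor effect (Cohen's f = 0.25) over 12 scene
categories needs 13 subjects for 80 % power; 20 subjects exceed 97 %. In the
simulated study one trial is lost to the incorrect-response rule, and the
per-image table shows about 7–8 fixations per 3-s trial with low normalized
transition entropy — scanpaths dominated by the central bias are highly
predictable.

## Command line

```bash
aerialgaze simulate --seed 3 --out synthetic          # events.csv, annotations.json, ...
aerialgaze screen   --events synthetic/events.csv --out results
aerialgaze metrics  --events synthetic/events.csv --out results
aerialgaze imagestats --annotations synthetic/annotations.json --out results
aerialgaze run-all  --seed 3 --out results            # full pipeline on synthetic data
```

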