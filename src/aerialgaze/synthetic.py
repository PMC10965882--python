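"""Synthetic study generator.

Emulates the structure of an aerial scene-viewing experiment: 12 scene
categories x 20 images x 20 observers, 3-s free viewing of 600 x 600 px
stimuli at 40 px per degree of visual angle, log-normally distributed
fixation durations (mean 296 ms, SD 139 ms), a central fixation bias,
attraction to annotated critical objects, and configurable rates of
invalid events (sub-100 ms fixations, out-of-image fixations, anticipatory
saccades, track-loss gaps, incorrect trials). Every injected violation is
recorded in a ground-truth ledger so screening accuracy is exactly
checkable.

Images are spectrally shaped noise with category-specific smoothing (and
hence GLCM homogeneity) plus planted geometric critical objects with
integer-vertex annotations, so the critical-object saliency of every image
is available in closed form.

The generator is a first-class module: all defaults are the study
conditions above and a fixed seed makes every output bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .events import FixationEvent, SaccadeEvent, Trial
from .features import EmbeddingSet
from .imstats import Annotation, critical_object_saliency


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Location/scale of a log-normal with the given arithmetic mean/SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass
class SynthConfig:
    n_categories: int = 12
    images_per_category: int = 20
    observers: int = 20
    viewing_ms: float = 3000.0
    px_per_deg: float = 40.0
    image_size_px: int = 600
    duration_mean_ms: float = 296.0
    duration_sd_ms: float = 139.0
    #: mixture weight of the central Gaussian fixation component
    center_bias_strength: float = 0.6
    center_sigma_px: float = 120.0
    #: mixture weight of the object-attraction component (used when the
    #: image has annotated objects; folded into the uniform component else)
    object_attraction_weight: float = 0.2
    object_sigma_px: float = 30.0
    #: category texture ladder: Gaussian smoothing sigmas, low to high
    #: homogeneity
    texture_sigma_min: float = 0.5
    texture_sigma_max: float = 6.0
    #: categories with index below this have no critical objects
    n_object_free_categories: int = 2
    max_objects_per_image: int = 3
    #: planted object side length as a fraction of the image side
    object_side_frac: tuple[float, float] = (1 / 12, 1 / 4)
    #: planted effects on viewing behavior
    n_fixations_base: float = 8.0
    cos_to_n_fixations: float = -4.0  # fewer fixations on object-salient scenes
    homogeneity_to_spread: float = -120.0  # px of spatial-spread sigma per unit
    #: invalid-event rates (all in [0, 1])
    p_incorrect_trial: float = 0.0212
    p_too_few_fixations_trial: float = 0.0
    p_trackloss_trial: float = 0.0
    p_blink_trial: float = 0.02
    p_short_fixation: float = 0.0
    p_out_fixation: float = 0.0
    p_early_saccade: float = 0.0
    embedding_dim: int = 64
    embedding_between_sd: float = 1.0
    embedding_within_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        self.object_side_frac = tuple(self.object_side_frac)
        for name in (
            "p_incorrect_trial", "p_too_few_fixations_trial", "p_trackloss_trial",
            "p_blink_trial", "p_short_fixation", "p_out_fixation", "p_early_saccade",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        min_fix_time = 3 * 80.0
        if self.viewing_ms < min_fix_time:
            raise ValueError("viewing window too short to hold three fixations")

    def category_names(self) -> list[str]:
        return [f"cat{i:02d}" for i in range(self.n_categories)]

    def image_ids(self) -> list[str]:
        return [
            f"cat{c:02d}_img{i:02d}"
            for c in range(self.n_categories)
            for i in range(self.images_per_category)
        ]

    def image_categories(self) -> dict[str, str]:
        return {img: img.split("_")[0] for img in self.image_ids()}

    def texture_sigmas(self) -> np.ndarray:
        return np.linspace(
            self.texture_sigma_min, self.texture_sigma_max, self.n_categories
        )


@dataclass
class GroundTruth:
    """Identifiers of every planted violation, keyed the way the screening
    report counts them."""

    incorrect_trials: list = field(default_factory=list)
    too_few_fixation_trials: list = field(default_factory=list)
    trackloss_trials: list = field(default_factory=list)
    short_fixations: list = field(default_factory=list)
    out_fixations: list = field(default_factory=list)
    early_saccades: list = field(default_factory=list)
    out_saccades: list = field(default_factory=list)
    n_fixations_planted: dict = field(default_factory=dict)
    cos: dict = field(default_factory=dict)
    homogeneity_rank: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=list)


# --------------------------------------------------------------------------
# images and annotations
# --------------------------------------------------------------------------

def gen_images(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], dict[str, str], dict[str, list[tuple]]]:
    """Textured RGB stimuli with planted rectangular critical objects.

    Returns (images, image -> category, image -> planted object rectangles
    as (x0, y0, x1, y1) integer corners). Category texture follows a
    smoothing ladder, so measured homogeneity rank-orders with category
    index; the first ``n_object_free_categories`` categories carry no
    objects.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    s = cfg.image_size_px
    sigmas = cfg.texture_sigmas()
    images: dict[str, np.ndarray] = {}
    categories: dict[str, str] = {}
    objects: dict[str, list[tuple]] = {}
    for c in range(cfg.n_categories):
        tint = rng.uniform(0.6, 1.4, size=3)
        for i in range(cfg.images_per_category):
            image_id = f"cat{c:02d}_img{i:02d}"
            noise = rng.standard_normal((s, s))
            tex = gaussian_filter(noise, sigma=sigmas[c], mode="reflect")
            tex = (tex - tex.min()) / max(np.ptp(tex), 1e-12)
            rgb = np.clip(tex[..., None] * tint * 200 + 25, 0, 255)

            rects: list[tuple] = []
            if c >= cfg.n_object_free_categories:
                n_obj = int(rng.integers(1, cfg.max_objects_per_image + 1))
                color = rng.uniform(0, 255, size=3)
                lo = max(2, int(s * cfg.object_side_frac[0]))
                hi = max(lo + 1, int(s * cfg.object_side_frac[1]))
                for _ in range(n_obj):
                    side = int(rng.integers(lo, hi))
                    x0 = int(rng.integers(0, s - side))
                    y0 = int(rng.integers(0, s - side))
                    if side * side > s * s:
                        raise ValueError("object area exceeds the image")
                    rgb[y0 : y0 + side, x0 : x0 + side] = color
                    rects.append((x0, y0, x0 + side, y0 + side))
            images[image_id] = rgb.astype(np.uint8)
            categories[image_id] = f"cat{c:02d}"
            objects[image_id] = rects
    return images, categories, objects


def gen_annotations(
    cfg: SynthConfig, objects: dict[str, list[tuple]]
) -> dict[str, list[Annotation]]:
    """Integer-vertex polygon annotations matching the planted rectangles
    (closed-form COS)."""
    out: dict[str, list[Annotation]] = {}
    for image_id, rects in objects.items():
        anns = []
        for x0, y0, x1, y1 in rects:
            anns.append(
                Annotation(
                    image_id=image_id,
                    shape="polygon",
                    vertices_px=[(x0, y0), (x1, y0), (x1, y1), (x0, y1)],
                )
            )
        out[image_id] = anns
    return out


# --------------------------------------------------------------------------
# scanpaths
# --------------------------------------------------------------------------

def _draw_position(
    cfg: SynthConfig,
    rng: np.random.Generator,
    spread_px: float,
    object_centroids: list[tuple[float, float]],
) -> tuple[float, float]:
    """Sample one in-image fixation position from the mixture of central
    Gaussian, object-attraction kernels, and uniform exploration."""
    s = cfg.image_size_px
    w_center = cfg.center_bias_strength
    w_obj = cfg.object_attraction_weight if object_centroids else 0.0
    for _ in range(200):
        u = rng.uniform()
        if u < w_center:
            x, y = rng.normal(s / 2.0, spread_px, size=2)
        elif u < w_center + w_obj:
            cx, cy = object_centroids[rng.integers(len(object_centroids))]
            x = rng.normal(cx, cfg.object_sigma_px)
            y = rng.normal(cy, cfg.object_sigma_px)
        else:
            x, y = rng.uniform(0, s, size=2)
        if 0 <= x < s and 0 <= y < s:
            return float(x), float(y)
    return s / 2.0, s / 2.0  # unreachable in practice


def gen_scanpaths(
    cfg: SynthConfig,
    annotations: dict[str, list[Annotation]],
    categories: dict[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[list[Trial], GroundTruth]:
    """Simulate trials for every observer x image with ground-truth flags.

    Fixation positions are i.i.d. draws from the spatial mixture; durations
    are log-normal with the configured mean/SD; saccades connect
    consecutive fixations; the planted fixation count decreases with the
    image's critical-object saliency. At most one trial-level violation is
    injected per trial and at most one fixation-level violation per
    fixation, so the screening report's per-rule counts are exactly the
    planted counts.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    s = cfg.image_size_px
    mu, sigma = lognormal_params(cfg.duration_mean_ms, cfg.duration_sd_ms)
    truth = GroundTruth()
    trials: list[Trial] = []

    cat_rank = {c: i for i, c in enumerate(cfg.category_names())}
    for image_id, cat in categories.items():
        anns = annotations.get(image_id, [])
        truth.cos[image_id] = critical_object_saliency(anns, (s, s))
        truth.homogeneity_rank[image_id] = cat_rank[cat]

    for p in range(cfg.observers):
        pid = f"p{p:02d}"
        for image_id, cat in categories.items():
            anns = annotations.get(image_id, [])
            cos_val = truth.cos[image_id]
            hom_frac = cat_rank[cat] / max(cfg.n_categories - 1, 1)
            spread = max(
                30.0, cfg.center_sigma_px + cfg.homogeneity_to_spread * hom_frac
            )
            centroids = [
                tuple(np.mean(a.vertices_px, axis=0)) for a in anns
            ]

            key = (pid, image_id)
            u = rng.uniform()
            p_inc = cfg.p_incorrect_trial
            p_few = cfg.p_too_few_fixations_trial
            p_tl = cfg.p_trackloss_trial
            violation = None
            if u < p_inc:
                violation = "incorrect"
            elif u < p_inc + p_few:
                violation = "too_few"
            elif u < p_inc + p_few + p_tl:
                violation = "trackloss"

            n_target = cfg.n_fixations_base + cfg.cos_to_n_fixations * cos_val
            n_target += rng.normal(0.0, 0.8)
            n_target = max(4, int(round(n_target)))
            if violation == "too_few":
                n_target = 2
                truth.too_few_fixation_trials.append(key)

            # recorded first fixation: begun on the pre-stimulus cross;
            # redraw the whole scanpath in the rare case that long duration
            # draws leave fewer than three valid fixations unplanted
            for _attempt in range(20):
                fixations: list[FixationEvent] = []
                flagged_short: list[tuple] = []
                flagged_out: list[tuple] = []
                first_offset = float(rng.uniform(120.0, 280.0))
                fixations.append(
                    FixationEvent(
                        participant_id=pid, image_id=image_id,
                        onset_ms=-100.0, offset_ms=first_offset,
                        x_px=s / 2.0 + rng.normal(0, 5),
                        y_px=s / 2.0 + rng.normal(0, 5),
                        is_first=True,
                    )
                )
                t = first_offset + float(rng.uniform(20.0, 40.0))  # saccade gap
                n_valid = 0
                while n_valid < n_target and t < cfg.viewing_ms - 90.0:
                    dur = float(rng.lognormal(mu, sigma))
                    if dur < 100.0:
                        dur = 200.0 - dur  # fold sub-threshold draws upward
                    if t + dur > cfg.viewing_ms:
                        break  # does not fit in the viewing window
                    x, y = _draw_position(cfg, rng, spread, centroids)
                    uv = rng.uniform()
                    if uv < cfg.p_short_fixation:
                        dur = float(rng.uniform(20.0, 95.0))
                        flagged_short.append((pid, image_id, t))
                    elif uv < cfg.p_short_fixation + cfg.p_out_fixation:
                        x = s + float(rng.uniform(1.0, 40.0))
                        flagged_out.append((pid, image_id, t))
                    else:
                        n_valid += 1
                    fixations.append(
                        FixationEvent(
                            participant_id=pid, image_id=image_id,
                            onset_ms=t, offset_ms=t + dur, x_px=x, y_px=y,
                        )
                    )
                    t += dur + float(rng.uniform(20.0, 40.0))
                if n_valid >= min(n_target, 3):
                    break
            truth.short_fixations.extend(flagged_short)
            truth.out_fixations.extend(flagged_out)

            saccades: list[SaccadeEvent] = []
            for a, b in zip(fixations[:-1], fixations[1:]):
                onset = a.offset_ms + 1.0
                if rng.uniform() < cfg.p_early_saccade:
                    onset = float(rng.uniform(0.0, 74.0))
                    truth.early_saccades.append((pid, image_id, onset))
                amp = math.hypot(b.x_px - a.x_px, b.y_px - a.y_px) / cfg.px_per_deg
                sac = SaccadeEvent(
                    participant_id=pid, image_id=image_id, onset_ms=onset,
                    start_x_px=a.x_px, start_y_px=a.y_px,
                    end_x_px=b.x_px, end_y_px=b.y_px, amplitude_dva=amp,
                )
                saccades.append(sac)
                out_of_region = not (
                    0 <= a.x_px < s and 0 <= a.y_px < s
                    and 0 <= b.x_px < s and 0 <= b.y_px < s
                )
                if onset >= 75.0 and out_of_region:
                    truth.out_saccades.append((pid, image_id, onset))

            trackloss = []
            if violation == "trackloss":
                start = float(rng.uniform(500.0, cfg.viewing_ms - 400.0))
                trackloss.append((start, start + float(rng.uniform(120.0, 300.0)), False))
                truth.trackloss_trials.append(key)
            if rng.uniform() < cfg.p_blink_trial:
                start = float(rng.uniform(500.0, cfg.viewing_ms - 400.0))
                trackloss.append((start, start + float(rng.uniform(120.0, 250.0)), True))

            correct = violation != "incorrect"
            if not correct:
                truth.incorrect_trials.append(key)
            truth.n_fixations_planted[f"{pid}:{image_id}"] = n_valid
            trials.append(
                Trial(
                    participant_id=pid, image_id=image_id, category=cat,
                    correct=correct, fixations=fixations, saccades=saccades,
                    trackloss_segments=trackloss, viewing_ms=cfg.viewing_ms,
                )
            )
    return trials, truth


# --------------------------------------------------------------------------
# embeddings
# --------------------------------------------------------------------------

def gen_embeddings(
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    layer_tag: str = "blk5",
    between_sd: float | None = None,
    within_sd: float | None = None,
) -> EmbeddingSet:
    """Per-category Gaussian embedding clusters: tight within-category
    spread around separated category means gives within-similarity above
    across-similarity with a margin controlled by between_sd/within_sd."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    between = cfg.embedding_between_sd if between_sd is None else between_sd
    within = cfg.embedding_within_sd if within_sd is None else within_sd
    means = rng.normal(0.0, between, size=(cfg.n_categories, cfg.embedding_dim))
    ids, vecs, cats = [], [], []
    for c in range(cfg.n_categories):
        for i in range(cfg.images_per_category):
            ids.append(f"cat{c:02d}_img{i:02d}")
            vecs.append(means[c] + rng.normal(0.0, within, size=cfg.embedding_dim))
            cats.append(f"cat{c:02d}")
    return EmbeddingSet(
        image_ids=ids, vectors=np.array(vecs), layer_tag=layer_tag,
        true_category=cats,
    )


# --------------------------------------------------------------------------
# regression-stage fixture
# --------------------------------------------------------------------------

#: planted image-level effects: response -> {predictor: slope}
DEFAULT_PLANTED_EFFECTS = {
    "n_fixations": {"cos": -3.0, "homogeneity": -2.5},
    "fdm_entropy_bits": {"homogeneity": -2.5},
}


def gen_regression_dataset(
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    planted_effects: dict | None = None,
    noise_sd: float = 0.75,
    luminance_slope: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, dict]:
    """Image-level table of the nine statistics plus responses with planted
    linear effects, for exercising the regression stage in isolation.

    Responses receive the planted predictor slopes, a luminance
    contribution (removed downstream by residualization), and Gaussian
    noise whose default scale puts the planted signal at an adjusted R^2 in
    the broad range reported for image-level models (~0.2-0.45). Returns
    (responses, X, luminance, truth).
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    n = cfg.n_categories * cfg.images_per_category
    effects = planted_effects or DEFAULT_PLANTED_EFFECTS

    hom = rng.uniform(0.35, 0.9, size=n)
    cos_zero = rng.uniform(size=n) < (cfg.n_object_free_categories / cfg.n_categories)
    cos = np.where(cos_zero, 0.0, rng.beta(2.0, 5.0, size=n))
    gabor_low = rng.normal(1.0, 0.25, size=n)
    X = pd.DataFrame(
        {
            "gabor_low_sf": gabor_low,
            "gabor_high_sf": 0.6 * gabor_low + rng.normal(0.0, 0.2, size=n),
            "homogeneity": hom,
            "within_sim": rng.normal(0.6, 0.1, size=n),
            "across_sim": rng.normal(0.3, 0.1, size=n),
            "cos": cos,
            "blk1_l2": rng.normal(10.0, 2.0, size=n),
            "blk5_l2": rng.normal(20.0, 4.0, size=n),
            "fc2_l2": rng.normal(15.0, 3.0, size=n),
        },
        index=[f"img{i:03d}" for i in range(n)],
    )
    lum = rng.normal(50.0, 10.0, size=n)

    responses = {}
    for resp, slopes in effects.items():
        y = np.zeros(n)
        for pred, slope in slopes.items():
            y = y + slope * X[pred].to_numpy()
        y = y + luminance_slope * lum + rng.normal(0.0, noise_sd, size=n)
        responses[resp] = y
    return pd.DataFrame(responses, index=X.index), X, lum, {"effects": effects}


# --------------------------------------------------------------------------
# file emission (formats consumed by the I/O layer)
# --------------------------------------------------------------------------

def write_events_csv(trials: list[Trial], path) -> None:
    rows = []
    for t in trials:
        for f in t.fixations:
            rows.append(
                dict(participant=t.participant_id, image=t.image_id,
                     category=t.category, event_type="fixation",
                     onset_ms=f.onset_ms, offset_ms=f.offset_ms,
                     x_px=f.x_px, y_px=f.y_px, end_x_px="", end_y_px="",
                     amplitude_dva="", correct=t.correct, blink="")
            )
        for sc in t.saccades:
            rows.append(
                dict(participant=t.participant_id, image=t.image_id,
                     category=t.category, event_type="saccade",
                     onset_ms=sc.onset_ms, offset_ms="",
                     x_px=sc.start_x_px, y_px=sc.start_y_px,
                     end_x_px=sc.end_x_px, end_y_px=sc.end_y_px,
                     amplitude_dva=sc.amplitude_dva, correct=t.correct, blink="")
            )
        for start, end, blink in t.trackloss_segments:
            rows.append(
                dict(participant=t.participant_id, image=t.image_id,
                     category=t.category, event_type="trackloss",
                     onset_ms=start, offset_ms=end, x_px="", y_px="",
                     end_x_px="", end_y_px="", amplitude_dva="",
                     correct=t.correct, blink=blink)
            )
    pd.DataFrame(rows).to_csv(path, index=False)
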