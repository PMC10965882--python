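"""End-to-end orchestration: screen -> metrics -> image statistics ->
luminance-controlled regression -> rotation report.

Every stage output is a pure function of (inputs, config, seed); the result
bundle is written with a manifest recording the configuration hash, package
version and seed so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .events import ScreeningConfig, apply_screening, load_events
from .features import pca_l2_norms, similarity_table
from .imstats import GaborBankConfig, STAT_COLUMNS, annotations_from_json, compute_image_stats
from .metrics import aggregate, records_to_frame, summarize
from .regress import luminance_controlled_stepwise
from .rotation import rotate_stats, rotation_anova
from .synthetic import (
    SynthConfig,
    gen_annotations,
    gen_embeddings,
    gen_images,
    gen_scanpaths,
)

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = [
    "mean_fixation_duration_ms",
    "n_fixations",
    "fdm_entropy_bits",
    "mean_saccade_amplitude_dva",
    "gte_normalized",
]


@dataclass
class PipelineConfig:
    """Paths, analysis parameters and the master seed of one run."""

    out_dir: str = "results"
    events_path: str | None = None  # None -> simulate
    annotations_path: str | None = None
    px_per_deg: float = 40.0
    image_size_px: int = 600
    fdm_fwhm_deg: float = 0.5
    n_segments: int = 6
    glcm_levels: int = 64
    glcm_mode: str = "windowed"
    glcm_average_directions: bool = False
    gabor_size_px: int = 240
    stepwise_direction: str = "both"
    run_rotation: bool = True
    run_image_stats: bool = True
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig(**d["synth"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the result bundle under ``out_dir``.

    Returns a dict with the in-memory artifacts: screening report, metrics
    tables, image-statistic table, regression results, rotation report.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    timings = {}
    bundle: dict = {}

    synth = dataclasses.replace(
        cfg.synth,
        seed=cfg.seed,
        px_per_deg=cfg.px_per_deg,
        image_size_px=cfg.image_size_px,
    )

    t0 = time.perf_counter()
    if cfg.events_path:
        trials = load_events(cfg.events_path)
        annotations = (
            annotations_from_json(cfg.annotations_path)
            if cfg.annotations_path
            else {}
        )
        categories = {
            t.image_id: t.category for t in trials if t.category is not None
        }
        images = None
        embeddings = None
    else:
        logger.info("no event table given: simulating a synthetic study")
        images, categories, objects = gen_images(synth, rng)
        annotations = gen_annotations(synth, objects)
        trials, truth = gen_scanpaths(synth, annotations, categories, rng)
        embeddings = {
            tag: gen_embeddings(synth, rng, layer_tag=tag)
            for tag in ("blk1", "blk5", "fc2")
        }
        truth.to_json(out / "ground_truth.json")
    timings["simulate_or_load"] = time.perf_counter() - t0

    # --- screening -------------------------------------------------------
    t0 = time.perf_counter()
    screening_cfg = ScreeningConfig(
        image_size_px=(cfg.image_size_px, cfg.image_size_px)
    )
    screened = apply_screening(trials, screening_cfg)
    (out / "screening_report.json").write_text(screened.report.to_json())
    (out / "screening_report.log").write_text(screened.report.summary())
    bundle["screening"] = screened
    timings["screen"] = time.perf_counter() - t0

    # --- observer x image metrics ---------------------------------------
    t0 = time.perf_counter()
    records = []
    for t in screened.trials:
        if len(t.fixations) < 2:
            continue
        records.append(
            summarize(
                t,
                image_size_px=(cfg.image_size_px, cfg.image_size_px),
                px_per_deg=cfg.px_per_deg,
                fwhm_deg=cfg.fdm_fwhm_deg,
                n_segments=cfg.n_segments,
                seed=rng,
            )
        )
    metrics_df = records_to_frame(records)
    metrics_df.to_csv(out / "metrics_observer_image.csv", index=False)
    per_image = aggregate(records, level="image")
    per_image.to_csv(out / "metrics_image.csv")
    per_category = aggregate(records, level="category", image_categories=categories)
    per_category.to_csv(out / "metrics_category.csv")
    bundle["metrics"] = metrics_df
    bundle["metrics_image"] = per_image
    bundle["metrics_category"] = per_category
    timings["metrics"] = time.perf_counter() - t0

    # --- image statistics -------------------------------------------------
    stats_df = None
    if cfg.run_image_stats and images is not None:
        t0 = time.perf_counter()
        gabor_cfg = GaborBankConfig(px_per_deg=cfg.px_per_deg)
        rows = []
        for image_id, img in images.items():
            rec = compute_image_stats(
                img,
                image_id,
                annotations.get(image_id, []),
                gabor_cfg=gabor_cfg,
                gabor_size_px=cfg.gabor_size_px,
                glcm_levels=cfg.glcm_levels,
                glcm_mode=cfg.glcm_mode,
                glcm_average_directions=cfg.glcm_average_directions,
            )
            rows.append(rec.as_dict())
        stats_df = pd.DataFrame(rows).set_index("image_id")
        if embeddings is not None:
            sim = similarity_table(embeddings["blk5"])
            stats_df["within_sim"] = sim["within_sim"]
            stats_df["across_sim"] = sim["across_sim"]
            for tag, e in embeddings.items():
                stats_df[f"{tag}_l2"] = pca_l2_norms(e)
        stats_df.to_csv(out / "image_stats.csv")
        bundle["image_stats"] = stats_df
        timings["image_stats"] = time.perf_counter() - t0

    # --- regression -------------------------------------------------------
    if stats_df is not None:
        t0 = time.perf_counter()
        joined = per_image.join(stats_df, how="inner").dropna(
            subset=STAT_COLUMNS + ["luminance"]
        )
        responses = joined[[c for c in RESPONSE_COLUMNS if c in joined]]
        X = joined[STAT_COLUMNS]
        results = luminance_controlled_stepwise(
            responses, X, joined["luminance"],
            level="image", direction=cfg.stepwise_direction,
        )
        reg_out = {
            name: {
                "predictors": r.predictors,
                "adj_r2": r.adj_r2,
                "table": r.table.to_dict(orient="index"),
            }
            for name, r in results.items()
        }
        (out / "regression_image.json").write_text(json.dumps(reg_out, indent=2))
        bundle["regression_image"] = results
        timings["regression"] = time.perf_counter() - t0

    # --- rotation ---------------------------------------------------------
    if cfg.run_rotation and images is not None:
        t0 = time.perf_counter()
        rot_df = rotate_stats(
            images,
            annotations,
            gabor_cfg=GaborBankConfig(px_per_deg=cfg.px_per_deg),
            gabor_size_px=cfg.gabor_size_px,
            glcm_mode=cfg.glcm_mode,
            glcm_average_directions=cfg.glcm_average_directions,
        )
        report = rotation_anova(rot_df, image_categories=categories)
        report.table.to_csv(out / "rotation_report.csv", index=False)
        bundle["rotation"] = report
        timings["rotation"] = time.perf_counter() - t0

    for stage, secs in timings.items():
        logger.info("stage %-16s %.2f s", stage, secs)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    bundle["timings_s"] = timings
    return bundle
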