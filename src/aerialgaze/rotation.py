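"""Rotational-invariance harness.

Every image statistic is recomputed at the four right-angle orientations
(0, 90, 180, 270 degrees counterclockwise); raster rotation is an exact
index permutation (no interpolation) and annotation vertices undergo the
same transform. Per scene category, a one-way fixed-effects ANOVA with
orientation as the factor tests whether a statistic is orientation
sensitive. Statistics defined purely on geometry (COS) are exactly
invariant and are flagged as such rather than tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import EmbeddingSet, pca_l2_norms, similarity_table
from .imstats import (
    Annotation,
    GaborBankConfig,
    STAT_COLUMNS,
    compute_image_stats,
)

ORIENTATIONS = (0, 90, 180, 270)


def rotate_image(image: np.ndarray, orientation_deg: int) -> np.ndarray:
    """Counterclockwise rotation by an exact multiple of 90 degrees via
    index permutation; requires a square raster."""
    if orientation_deg % 90 != 0:
        raise ValueError("only right-angle rotations are supported")
    img = np.asarray(image)
    if img.shape[0] != img.shape[1]:
        raise ValueError("rotation requires square images")
    return np.rot90(img, k=(orientation_deg // 90) % 4, axes=(0, 1))


def rotate_point(
    x: float, y: float, orientation_deg: int, size_px: float
) -> tuple[float, float]:
    """Counterclockwise right-angle rotation of a point about the image
    center in image coordinates (y down): one 90-degree step maps
    (x, y) -> (y, S - x)."""
    if orientation_deg % 90 != 0:
        raise ValueError("only right-angle rotations are supported")
    for _ in range((orientation_deg // 90) % 4):
        x, y = y, size_px - x
    return x, y


def rotate_annotation(ann: Annotation, orientation_deg: int, size_px: float) -> Annotation:
    return Annotation(
        image_id=ann.image_id,
        shape="polygon" if ann.shape == "rectangle" else ann.shape,
        vertices_px=[
            rotate_point(x, y, orientation_deg, size_px) for x, y in ann.vertices_px
        ],
    )


def rotate_stats(
    images: dict[str, np.ndarray],
    annotations: dict[str, list[Annotation]] | None = None,
    embeddings_per_orientation: dict[int, EmbeddingSet] | None = None,
    gabor_cfg: GaborBankConfig | None = None,
    gabor_size_px: int | None = 240,
    glcm_mode: str = "windowed",
    glcm_average_directions: bool = False,
    restrict_correct: bool = False,
) -> pd.DataFrame:
    """Recompute all image statistics at the four orientations.

    Embedding-derived statistics (similarities, PCA norms) are filled in
    when per-orientation embedding sets are supplied; raster and geometry
    statistics are always computed. Returns one row per
    (image, orientation).
    """
    annotations = annotations or {}
    rows = []
    for orient in ORIENTATIONS:
        emb_cols = None
        if embeddings_per_orientation and orient in embeddings_per_orientation:
            e = embeddings_per_orientation[orient]
            emb_cols = similarity_table(e, restrict_correct)
            emb_cols[f"{e.layer_tag}_l2"] = pca_l2_norms(e)
        for image_id, img in images.items():
            size = img.shape[0]
            rot_img = rotate_image(img, orient)
            rot_anns = [
                rotate_annotation(a, orient, size)
                for a in annotations.get(image_id, [])
            ]
            rec = compute_image_stats(
                rot_img,
                image_id,
                rot_anns,
                gabor_cfg=gabor_cfg,
                gabor_size_px=gabor_size_px,
                glcm_mode=glcm_mode,
                glcm_average_directions=glcm_average_directions,
                orientation_deg=orient,
            )
            d = rec.as_dict()
            if emb_cols is not None and image_id in emb_cols.index:
                for col in emb_cols.columns:
                    d[col] = emb_cols.loc[image_id, col]
            rows.append(d)
    return pd.DataFrame(rows)


@dataclass
class RotationReport:
    """Orientation-effect tests per (category, statistic)."""

    table: pd.DataFrame  # category, statistic, F, p, means per orientation, invariant_exact

    def max_p_violations(self, alpha: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(~t["invariant_exact"]) & (t["p"] < alpha)]


def rotation_anova(
    stats_df: pd.DataFrame,
    statistics: list[str] | None = None,
    image_categories: dict[str, str] | None = None,
) -> RotationReport:
    """One-way fixed-effects ANOVA of each statistic across orientation
    groups, per category (or pooled when no category map is given).

    Groups whose between- and within-group variances are both zero are
    exactly invariant; they are flagged ``invariant_exact`` with an
    undefined F.
    """
    df = stats_df.copy()
    if image_categories is not None:
        df["category"] = df["image_id"].map(image_categories)
    elif "category" not in df:
        df["category"] = "all"
    statistics = statistics or [
        c for c in STAT_COLUMNS if c in df.columns and df[c].notna().any()
    ]

    rows = []
    for cat, sub in df.groupby("category", sort=True):
        for stat in statistics:
            groups = [
                sub.loc[sub["orientation_deg"] == o, stat].dropna().to_numpy()
                for o in ORIENTATIONS
            ]
            groups = [g for g in groups if g.size]
            if len(groups) < 2 or any(g.size < 2 for g in groups):
                raise ValueError(
                    f"rotation ANOVA needs >= 2 orientations with >= 2 images "
                    f"each (category {cat!r}, statistic {stat!r})"
                )
            means = {f"mean_{o}": float(np.mean(g)) for o, g in zip(ORIENTATIONS, groups)}
            # bit-identical groups across orientations: the statistic is
            # exactly rotation invariant; F is undefined (0/0) when the
            # within-group variance is zero too
            sorted_groups = [np.sort(g) for g in groups]
            invariant = all(
                g.shape == sorted_groups[0].shape and np.array_equal(g, sorted_groups[0])
            for g in sorted_groups)
            if invariant and np.ptp(np.concatenate(groups)) == 0:
                rows.append(
                    dict(category=cat, statistic=stat, F=math.nan, p=math.nan,
                         invariant_exact=True, **means)
                )
                continue
            with np.errstate(invalid="ignore"):
                F, p = sps.f_oneway(*groups)
            rows.append(
                dict(category=cat, statistic=stat, F=float(F), p=float(p),
                     invariant_exact=bool(invariant), **means)
            )
    table = pd.DataFrame(rows)
    return RotationReport(table=table)
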