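"""High-level statistics over pluggable per-image embedding vectors.

Embeddings (e.g. flattened convolutional-network block outputs) arrive
through :class:`EmbeddingSet`; nothing here depends on how they were
extracted. Two families of statistics are provided: within-/across-category
perceptual similarity (mean Pearson correlation of an image's vector with
same-/different-category vectors) and L2 norms in a full-rank PCA rotation
of the embedding space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class EmbeddingSet:
    image_ids: list[str]
    vectors: np.ndarray  # (n_images, dim)
    layer_tag: str = "blk5"
    true_category: list[str] | None = None
    predicted_category: list[str] | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.image_ids):
            raise ValueError("vectors must be (n_images, dim)")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("image ids must be unique")
        self._index = {img: i for i, img in enumerate(self.image_ids)}

    def row(self, image_id: str) -> int:
        return self._index[image_id]

    @property
    def correct_mask(self) -> np.ndarray:
        """Images whose predicted category matches the true one (all True
        when no predictions are attached)."""
        n = len(self.image_ids)
        if self.true_category is None or self.predicted_category is None:
            return np.ones(n, dtype=bool)
        return np.array(
            [t == p for t, p in zip(self.true_category, self.predicted_category)]
        )


def _pearson_to_row(vectors: np.ndarray, row: np.ndarray) -> np.ndarray:
    """Pearson correlation of one vector against each row of a matrix."""
    vc = vectors - vectors.mean(axis=1, keepdims=True)
    rc = row - row.mean()
    denom = np.linalg.norm(vc, axis=1) * np.linalg.norm(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (vc @ rc) / denom


def _similarity(
    e: EmbeddingSet, image_id: str, same_category: bool, restrict_correct: bool
) -> float:
    if e.true_category is None:
        raise ValueError("similarity statistics require category labels")
    i = e.row(image_id)
    cat = e.true_category[i]
    mask = np.array([c == cat for c in e.true_category]) == same_category
    mask[i] = False
    if restrict_correct:
        mask &= e.correct_mask
    if not mask.any():
        return float("nan")
    corrs = _pearson_to_row(e.vectors[mask], e.vectors[i])
    return float(np.nanmean(corrs))


def within_similarity(
    e: EmbeddingSet, image_id: str, restrict_correct: bool = False
) -> float:
    """Mean Pearson correlation with all other same-category images; NaN for
    a category singleton (reported missing)."""
    return _similarity(e, image_id, same_category=True, restrict_correct=restrict_correct)


def across_similarity(
    e: EmbeddingSet, image_id: str, restrict_correct: bool = False
) -> float:
    """Mean Pearson correlation with all images of other categories."""
    return _similarity(e, image_id, same_category=False, restrict_correct=restrict_correct)


def similarity_table(e: EmbeddingSet, restrict_correct: bool = False) -> pd.DataFrame:
    """Within/across similarity per image, indexed by image id."""
    rows = {
        img: {
            "within_sim": within_similarity(e, img, restrict_correct),
            "across_sim": across_similarity(e, img, restrict_correct),
        }
        for img in e.image_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def pca_l2_norms(e: EmbeddingSet) -> pd.Series:
    """Euclidean norm of each image's score vector under a full-rank PCA
    rotation (all components kept, mean-centering only).

    Since the rotation is orthogonal and no components are discarded, each
    norm equals the distance of the centered original vector from the
    origin; the PCA fit is retained for the sake of the score-space
    interpretation.
    """
    if e.vectors.shape[0] < 2:
        raise ValueError("PCA norms require at least two images")
    scores = PCA(n_components=None).fit_transform(e.vectors)
    return pd.Series(np.linalg.norm(scores, axis=1), index=e.image_ids, name=f"{e.layer_tag}_l2")


def embeddings_to_csv(e: EmbeddingSet, path) -> None:
    df = pd.DataFrame(e.vectors, index=e.image_ids)
    df.insert(0, "category", e.true_category)
    df.to_csv(path, index_label="image_id")


def embeddings_from_csv(path, layer_tag: str = "blk5") -> EmbeddingSet:
    df = pd.read_csv(path, index_col="image_id")
    cats = df.pop("category").astype(str).tolist() if "category" in df else None
    return EmbeddingSet(
        image_ids=[str(i) for i in df.index],
        vectors=df.to_numpy(float),
        layer_tag=layer_tag,
        true_category=cats,
    )
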