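"""Eye-movement variables computed from screened events.

Five variables are computed per observer x image: mean fixation duration,
number of fixations within the viewing window, entropy of the fixation
density map (FDM), mean saccade amplitude, and normalized gaze transition
entropy (GTE). A center-bias score (0 = uniform baseline, 100 = all
fixations at the image center) is computed alongside.

All entropies are in bits (base-2 logarithms), so the FDM entropy and the
GTE numerator/denominator share units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .events import FixationEvent, Trial

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class FixationDensityMap:
    """Unit-mass Gaussian-smoothed fixation location map for one
    participant x image."""

    grid: np.ndarray
    participant_id: str | None = None
    image_id: str | None = None
    kernel_fwhm_deg: float = 0.5

    def __post_init__(self):
        if np.any(self.grid < 0):
            raise ValueError("FDM weights must be nonnegative")

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.grid.sum()) - 1.0) <= 1e-9


def build_fdm(
    fixations: list[FixationEvent],
    image_size_px: tuple[int, int] = (600, 600),
    px_per_deg: float = 40.0,
    fwhm_deg: float = 0.5,
) -> FixationDensityMap:
    """Convolve the fixation location map with an isotropic Gaussian kernel.

    The kernel width is given as full width at half maximum in degrees of
    visual angle (sigma = fwhm * px_per_deg / (2 sqrt(2 ln 2))); the kernel
    is truncated at +/-4 sigma and mass lost over the image edge is restored
    by renormalization, so the map always sums to one.
    """
    if not fixations:
        raise ValueError("cannot build an FDM from zero fixations")
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    w, h = image_size_px
    grid = np.zeros((h, w), dtype=float)  # row = y, col = x
    for f in fixations:
        col = min(int(f.x_px), w - 1)
        row = min(int(f.y_px), h - 1)
        grid[row, col] += 1.0
    sigma = fwhm_deg * px_per_deg * FWHM_TO_SIGMA
    grid = gaussian_filter(grid, sigma=sigma, mode="constant", truncate=4.0)
    grid /= grid.sum()
    first = fixations[0]
    return FixationDensityMap(
        grid=grid,
        participant_id=first.participant_id,
        image_id=first.image_id,
        kernel_fwhm_deg=fwhm_deg,
    )


def fdm_entropy(fdm: FixationDensityMap | np.ndarray) -> float:
    """Shannon entropy (bits) of a fixation density map,
    -sum p log2 p with 0 log 0 = 0."""
    grid = fdm.grid if isinstance(fdm, FixationDensityMap) else np.asarray(fdm, float)
    total = float(grid.sum())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"FDM is not normalized (sum = {total!r})")
    p = grid[grid > 0]
    return float(-np.sum(p * np.log2(p)))


@dataclass
class AOITransition:
    """Occupancy vector and transition matrix over an n x n AOI partition."""

    n_segments: int
    v: np.ndarray  # length N occupancy probabilities
    M: np.ndarray  # N x N row-stochastic transition probabilities

    def __post_init__(self):
        N = self.n_segments**2
        if self.v.shape != (N,) or self.M.shape != (N, N):
            raise ValueError("inconsistent AOI dimensions")
        if not math.isclose(float(self.v.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("occupancy vector must sum to 1")

    @property
    def n_aois(self) -> int:
        return self.n_segments**2


def aoi_index(
    x: float, y: float, n_segments: int, image_size_px: tuple[int, int]
) -> int:
    """Row-major AOI index of a fixation; cells are half-open so a fixation
    exactly on a partition boundary belongs to the higher-index AOI."""
    w, h = image_size_px
    col = min(int(x * n_segments / w), n_segments - 1)
    row = min(int(y * n_segments / h), n_segments - 1)
    return row * n_segments + col


def build_transitions(
    fixations: list[FixationEvent],
    n_segments: int = 6,
    image_size_px: tuple[int, int] = (600, 600),
) -> AOITransition:
    """Count AOI occupancies and consecutive-pair transitions of one ordered
    scanpath. Rows of M for never-visited source AOIs are stored as zeros."""
    if len(fixations) < 2:
        raise ValueError("at least two fixations are required for transitions")
    N = n_segments**2
    idx = [
        aoi_index(f.x_px, f.y_px, n_segments, image_size_px) for f in fixations
    ]
    v = np.bincount(idx, minlength=N).astype(float)
    v /= v.sum()
    counts = np.zeros((N, N), dtype=float)
    for a, b in zip(idx[:-1], idx[1:]):
        counts[a, b] += 1.0
    row_sums = counts.sum(axis=1, keepdims=True)
    M = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    return AOITransition(n_segments=n_segments, v=v, M=M)


def gaze_transition_entropy(t: AOITransition, normalized: bool = True) -> float:
    """Occupancy-weighted conditional entropy of AOI transitions,
    GTE = -sum_i v_i sum_j M_ij log2 M_ij, optionally divided by the
    theoretical maximum log2(N)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logM = np.where(t.M > 0, np.log2(np.where(t.M > 0, t.M, 1.0)), 0.0)
    row_entropy = -(t.M * logM).sum(axis=1)
    gte = float((t.v * row_entropy).sum())
    if normalized:
        gte /= math.log2(t.n_aois)
    return gte


def expected_uniform_center_distance(image_size_px: tuple[int, int]) -> float:
    """Mean distance to the center of a W x H rectangle under a uniform
    distribution (closed form)."""
    w, h = image_size_px
    if w == h:
        return w * (math.sqrt(2.0) + math.asinh(1.0)) / 6.0
    # general rectangle: mean over the four congruent quadrant rectangles
    a, b = w / 2.0, h / 2.0
    d = math.hypot(a, b)
    # integral of sqrt(x^2+y^2) over [0,a]x[0,b], closed form
    integral = (
        a * b * d / 3.0
        + a**3 / 6.0 * math.log((b + d) / a)
        + b**3 / 6.0 * math.log((a + d) / b)
    )
    return integral / (a * b)


def center_bias(
    fixations: list[FixationEvent] | np.ndarray,
    image_size_px: tuple[int, int] = (600, 600),
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Center-bias score and its bootstrap standard error.

    score = 100 * (1 - mean_dist / E[dist | uniform]); 0 corresponds to the
    uniform baseline and 100 to all fixations exactly at the image center
    (W/2, H/2). Peripherally concentrated samples give negative scores.
    The SE is estimated by resampling fixations with replacement.
    """
    if isinstance(fixations, np.ndarray):
        xy = np.asarray(fixations, dtype=float).reshape(-1, 2)
    else:
        xy = np.array([(f.x_px, f.y_px) for f in fixations], dtype=float)
    if xy.shape[0] == 0:
        raise ValueError("center bias requires at least one fixation")
    w, h = image_size_px
    center = np.array([w / 2.0, h / 2.0])
    dists = np.hypot(*(xy - center).T)
    baseline = expected_uniform_center_distance(image_size_px)
    score = 100.0 * (1.0 - float(dists.mean()) / baseline)
    rng = np.random.default_rng(seed)
    n = dists.shape[0]
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sample = dists[rng.integers(0, n, size=n)]
        boot[b] = 100.0 * (1.0 - sample.mean() / baseline)
    return score, float(boot.std(ddof=1)) if n_bootstrap > 1 else 0.0


@dataclass
class GazeMetricsRecord:
    """The five eye-movement variables plus center bias for one
    observer x image."""

    participant_id: str
    image_id: str
    mean_fixation_duration_ms: float
    n_fixations: int
    fdm_entropy_bits: float
    mean_saccade_amplitude_dva: float  # NaN when no valid saccades
    gte_normalized: float
    center_bias: float

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "image_id": self.image_id,
            "mean_fixation_duration_ms": self.mean_fixation_duration_ms,
            "n_fixations": self.n_fixations,
            "fdm_entropy_bits": self.fdm_entropy_bits,
            "mean_saccade_amplitude_dva": self.mean_saccade_amplitude_dva,
            "gte_normalized": self.gte_normalized,
            "center_bias": self.center_bias,
        }


METRIC_COLUMNS = [
    "mean_fixation_duration_ms",
    "n_fixations",
    "fdm_entropy_bits",
    "mean_saccade_amplitude_dva",
    "gte_normalized",
    "center_bias",
]


def summarize(
    trials: Trial | list[Trial],
    image_size_px: tuple[int, int] = (600, 600),
    px_per_deg: float = 40.0,
    fwhm_deg: float = 0.5,
    n_segments: int = 6,
    n_bootstrap: int = 0,
    seed: int | np.random.Generator | None = None,
) -> GazeMetricsRecord:
    """Compute the metrics record for one observer x image from screened
    trial(s). Transitions never cross trial boundaries; the occupancy vector
    and transition counts pool within-trial pairs across the given trials.
    """
    if isinstance(trials, Trial):
        trials = [trials]
    if not trials:
        raise ValueError("summarize requires at least one trial")
    pid = trials[0].participant_id
    img = trials[0].image_id
    fixations = [f for t in trials for f in t.fixations]
    saccades = [s for t in trials for s in t.saccades]
    if not fixations:
        raise ValueError("no fixations to summarize (trial should be screened out)")

    durations = np.array([f.duration_ms for f in fixations])
    fdm = build_fdm(fixations, image_size_px, px_per_deg, fwhm_deg)

    # pooled within-trial transitions
    N = n_segments**2
    counts = np.zeros((N, N))
    occ = np.zeros(N)
    for t in trials:
        idx = [
            aoi_index(f.x_px, f.y_px, n_segments, image_size_px) for f in t.fixations
        ]
        for i in idx:
            occ[i] += 1
        for a, b in zip(idx[:-1], idx[1:]):
            counts[a, b] += 1
    v = occ / occ.sum()
    row_sums = counts.sum(axis=1, keepdims=True)
    M = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    gte = gaze_transition_entropy(AOITransition(n_segments, v, M))

    if saccades:
        amp = float(np.mean([s.amplitude_dva for s in saccades]))
    else:
        logger.warning("no valid saccades for (%s, %s); amplitude missing", pid, img)
        amp = float("nan")

    cb, _ = center_bias(fixations, image_size_px, n_bootstrap=max(n_bootstrap, 2), seed=seed)
    return GazeMetricsRecord(
        participant_id=pid,
        image_id=img,
        mean_fixation_duration_ms=float(durations.mean()),
        n_fixations=len(fixations),
        fdm_entropy_bits=fdm_entropy(fdm),
        mean_saccade_amplitude_dva=amp,
        gte_normalized=gte,
        center_bias=cb,
    )


def records_to_frame(records: list[GazeMetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def aggregate(
    records: list[GazeMetricsRecord] | pd.DataFrame,
    level: str = "image",
    image_categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate observer x image records upward.

    Image value = unweighted mean over observers of that image; category
    value = unweighted mean over the category's image values. Images with no
    surviving observers simply do not appear (a warning is logged when a
    category loses images relative to ``image_categories``).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    per_image = df.groupby("image_id", sort=True)[METRIC_COLUMNS].mean()
    if level == "image":
        return per_image
    if level != "category":
        raise ValueError(f"unknown aggregation level {level!r}")
    if image_categories is None:
        raise ValueError("category aggregation requires an image -> category map")
    missing = set(image_categories) - set(per_image.index)
    if missing:
        logger.warning("%d images have no surviving observers", len(missing))
    cats = per_image.index.map(image_categories)
    per_image = per_image.assign(category=cats)
    return per_image.groupby("category", sort=True)[METRIC_COLUMNS].mean()


def pooled_center_bias(
    trials: list[Trial],
    image_size_px: tuple[int, int] = (600, 600),
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Center bias over all fixations of a set of trials pooled together
    (the per-category figure-level quantity)."""
    fixations = [f for t in trials for f in t.fixations]
    return center_bias(fixations, image_size_px, n_bootstrap, seed)
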