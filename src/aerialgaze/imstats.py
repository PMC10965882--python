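"""Low-, mid- and object-level image statistics.

* luminance: pixel-mean L* in CIE L*a*b* (D65).
* Gabor energies: quadrature-pair filter bank (12 orientations x 8 spatial
  frequencies), energy pooled over population-receptive-field (pRF)
  Gaussian windows, averaged across the pRF grid into a 96-vector; low- and
  high-spatial-frequency statistics are means over the 4 lowest / 4 highest
  frequency bands.
* homogeneity: GLCM statistic sum P(i,j)/(1+|i-j|) at offset distance 1
  after linear quantization to 64 gray levels, either per sliding 3x3
  window (averaged) or from one whole-image GLCM.
* critical-object saliency (COS): sum over annotated objects of
  (area/image_area)^0.7 * (1 - centroid-to-center distance / center-to-
  corner distance).

Geometry convention: the image raster covers the continuous rectangle
[0, W] x [0, H] with the center at (W/2, H/2) and corners at distance
hypot(W/2, H/2); a whole-image annotation therefore scores exactly 1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import fftconvolve
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.color import rgb2lab
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel
from skimage.transform import resize

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# luminance
# --------------------------------------------------------------------------

def luminance_L(image: np.ndarray) -> float:
    """Mean L* of a true-color image under the standard sRGB -> CIELAB
    conversion (D65 white). Grayscale input is rejected: the statistic is
    defined on the color image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("luminance_L requires a 3-channel true-color image")
    if image.dtype == np.uint8:
        image = image / 255.0
    lab = rgb2lab(image)
    return float(lab[..., 0].mean())


# --------------------------------------------------------------------------
# Gabor bank
# --------------------------------------------------------------------------

@dataclass
class GaborBankConfig:
    """Quadrature Gabor bank: orientations x log-spaced spatial frequencies.

    Orientations default to 0-165 deg in 15 deg steps (orientations 180 deg
    apart are redundant for quadrature energy); the 0-345 deg variant is
    available via ``full_circle=True``. Frequencies are in cycles per degree
    of visual angle and converted to cycles per pixel through
    ``px_per_deg``. ``prf_grid`` is a list of (x_px, y_px, sigma_px)
    Gaussian pooling windows; ``None`` means one uniform full-image window.
    """

    n_orientations: int = 12
    n_frequencies: int = 8
    freq_min_cpd: float = 0.35
    freq_max_cpd: float = 8.56
    px_per_deg: float = 40.0
    bandwidth: float = 1.0
    full_circle: bool = False
    prf_grid: list[tuple[float, float, float]] | None = None

    @property
    def orientations_deg(self) -> np.ndarray:
        span = 360.0 if self.full_circle else 180.0
        return np.arange(self.n_orientations) * (span / self.n_orientations)

    @property
    def frequencies_cpd(self) -> np.ndarray:
        return np.geomspace(self.freq_min_cpd, self.freq_max_cpd, self.n_frequencies)

    @property
    def frequencies_cpp(self) -> np.ndarray:
        return self.frequencies_cpd / self.px_per_deg

    @property
    def n_channels(self) -> int:
        return self.n_orientations * self.n_frequencies

    def validate(self) -> None:
        if np.any(self.frequencies_cpp >= 0.5):
            raise ValueError(
                "configured spatial frequencies exceed the Nyquist limit "
                f"(max {self.frequencies_cpd.max():.2f} cpd at "
                f"{self.px_per_deg} px/deg)"
            )


def gabor_activations(image: np.ndarray, cfg: GaborBankConfig | None = None) -> np.ndarray:
    """Pooled quadrature-energy activation vector, ordered by
    (orientation, frequency).

    Each channel convolves the image with a complex Gabor kernel (the even
    part is made zero-DC by mean subtraction so constant images give zero
    energy), takes the pointwise energy |response|, pools it under each pRF
    Gaussian window, and averages over the pRF grid.
    """
    cfg = cfg or GaborBankConfig()
    cfg.validate()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("gabor_activations expects a grayscale raster")
    h, w = img.shape

    if cfg.prf_grid is None:
        weights = [np.full(img.shape, 1.0 / (h * w))]
    else:
        yy, xx = np.mgrid[0:h, 0:w]
        weights = []
        for cx, cy, sig in cfg.prf_grid:
            g = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sig**2)))
            weights.append(g / g.sum())

    out = np.empty(cfg.n_channels)
    k = 0
    for theta_deg in cfg.orientations_deg:
        theta = math.radians(theta_deg)
        for f_cpp in cfg.frequencies_cpp:
            kern = gabor_kernel(frequency=f_cpp, theta=theta, bandwidth=cfg.bandwidth)
            kern = kern - kern.real.mean()  # zero-DC even part; odd part already is
            # edge-replicate padding: a constant image then yields zero
            # response everywhere, not just away from the borders
            ph, pw = kern.shape[0] // 2, kern.shape[1] // 2
            padded = np.pad(img, ((ph, ph), (pw, pw)), mode="edge")
            resp = fftconvolve(padded, kern, mode="valid")
            energy = np.abs(resp)
            out[k] = np.mean([float((wgt * energy).sum()) for wgt in weights])
            k += 1
    return out


def gabor_statistics(
    activations: np.ndarray, cfg: GaborBankConfig | None = None
) -> tuple[float, float]:
    """(low-SF, high-SF) statistics: means of the activation vector over the
    4 lowest and 4 highest frequency bands, across all orientations."""
    cfg = cfg or GaborBankConfig()
    activations = np.asarray(activations, dtype=float)
    if activations.shape != (cfg.n_channels,):
        raise ValueError(
            f"expected a length-{cfg.n_channels} activation vector, "
            f"got shape {activations.shape}"
        )
    by_band = activations.reshape(cfg.n_orientations, cfg.n_frequencies)
    half = cfg.n_frequencies // 2
    return float(by_band[:, :half].mean()), float(by_band[:, half:].mean())


# --------------------------------------------------------------------------
# GLCM homogeneity
# --------------------------------------------------------------------------

def quantize_gray(image: np.ndarray, levels: int = 64) -> np.ndarray:
    """Linear mapping of the image's [min, max] range onto integer levels
    0..levels-1; a constant image maps to level 0."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


#: distance-1 offsets as (drow, dcol)
_OFFSETS_SINGLE = ((0, 1),)
_OFFSETS_FOUR = ((0, 1), (1, 0), (0, -1), (-1, 0))


def _offset_weight_map(q: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Pairwise weight image w = 1/(1+|q[p] - q[p+offset]|) over all valid
    pixel pairs, indexed by the first pixel of the pair."""
    dr, dc = offset
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].astype(np.int16)
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].astype(np.int16)
    return 1.0 / (1.0 + np.abs(a - b))


def glcm_homogeneity(
    image: np.ndarray,
    levels: int = 64,
    window: int = 3,
    mode: str = "windowed",
    average_directions: bool = False,
) -> float:
    """GLCM homogeneity of a grayscale raster.

    ``mode='global'`` builds one whole-image co-occurrence matrix at offset
    (0, 1) (optionally averaging the four distance-1 directions) and returns
    sum P(i,j)/(1+|i-j|). ``mode='windowed'`` computes the same statistic
    per sliding ``window x window`` patch and averages it over all fully
    interior patches; this is evaluated in closed form as a mean of pairwise
    weights 1/(1+|level difference|), which equals the per-window GLCM
    computation exactly.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("glcm_homogeneity expects a grayscale raster")
    if img.shape[0] < window or img.shape[1] < window:
        raise ValueError("image smaller than the processing window")
    q = quantize_gray(img, levels)
    offsets = _OFFSETS_FOUR if average_directions else _OFFSETS_SINGLE

    if mode == "global":
        # NB: graycoprops' "homogeneity" is the inverse difference moment
        # 1/(1+(i-j)^2); the statistic here uses 1/(1+|i-j|), so it is
        # evaluated directly on the normalized co-occurrence matrix.
        ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
        weight = 1.0 / (1.0 + np.abs(ii - jj))
        vals = []
        for dr, dc in offsets:
            angle = math.atan2(-dr, dc)  # skimage angles: (0,1)->0, (1,0)->-pi/2
            glcm = graycomatrix(
                q, distances=[1], angles=[angle], levels=levels, normed=True
            )
            vals.append(float((glcm[:, :, 0, 0] * weight).sum()))
        return float(np.mean(vals))

    if mode != "windowed":
        raise ValueError(f"unknown GLCM mode {mode!r}")

    h, w = q.shape
    per_offset = []
    for offset in offsets:
        wmap = _offset_weight_map(q, offset)
        dr, dc = abs(offset[0]), abs(offset[1])
        # each window x window patch contains (window-dr)*(window-dc) pairs;
        # sliding windows of that pair map average them
        ph, pw = window - dr, window - dc
        sw = np.lib.stride_tricks.sliding_window_view(wmap, (ph, pw))
        # restrict to pair-blocks of fully interior image windows
        n_win_r, n_win_c = h - window + 1, w - window + 1
        sw = sw[:n_win_r, :n_win_c]
        per_offset.append(float(sw.mean()))
    return float(np.mean(per_offset))


# --------------------------------------------------------------------------
# critical-object saliency
# --------------------------------------------------------------------------

@dataclass
class Annotation:
    """Polygon or rectangle annotation of one critical object."""

    image_id: str
    shape: str  # "polygon" | "rectangle"
    vertices_px: list[tuple[float, float]]

    def __post_init__(self):
        if self.shape == "rectangle":
            if len(self.vertices_px) == 2:
                (x0, y0), (x1, y1) = self.vertices_px
                self.vertices_px = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
            elif len(self.vertices_px) != 4:
                raise ValueError("rectangle needs 2 corners or 4 vertices")
        elif self.shape == "polygon":
            if len(self.vertices_px) < 3:
                raise ValueError("polygon needs at least 3 vertices")
            poly = _ShapelyPolygon(self.vertices_px)
            # zero-area (degenerate) rings are tolerated and contribute 0
            # to COS; invalid rings with positive area are real errors
            if not poly.is_valid and poly.area > 0:
                raise ValueError("self-intersecting polygon annotation")
        else:
            raise ValueError(f"unknown annotation shape {self.shape!r}")

    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices_px)


def _exact_area_and_dist2(
    vertices: list[tuple[float, float]], center: tuple[Fraction, Fraction]
) -> tuple[Fraction, Fraction | None]:
    """Shoelace area and squared centroid-to-center distance in exact
    rational arithmetic (floats embed exactly into Fraction), so that
    geometry statistics are bit-identical under exact 90-degree rotations
    of the vertex set."""
    pts = [(Fraction(x), Fraction(y)) for x, y in vertices]
    a2 = Fraction(0)
    cx_num = Fraction(0)
    cy_num = Fraction(0)
    n = len(pts)
    for i in range(n):
        x0, y0 = pts[i]
        x1, y1 = pts[(i + 1) % n]
        cross = x0 * y1 - x1 * y0
        a2 += cross
        cx_num += (x0 + x1) * cross
        cy_num += (y0 + y1) * cross
    area = abs(a2) / 2
    if a2 == 0:
        return area, None
    cx = cx_num / (3 * a2)
    cy = cy_num / (3 * a2)
    dist2 = (cx - center[0]) ** 2 + (cy - center[1]) ** 2
    return area, dist2


def critical_object_saliency(
    annotations: list[Annotation],
    image_size_px: tuple[int, int] = (600, 600),
) -> float:
    """COS = sum_c Size_c * Location_c over a single image's annotations.

    Size_c = (polygon area / image area)^0.7 (Stevens-compressed apparent
    size); Location_c = 1 - dist(centroid, center)/dist(center, corner).
    An image without annotations scores 0; a single whole-image annotation
    scores exactly 1. Degenerate (zero-area) polygons contribute 0.
    """
    w, h = image_size_px
    center = (Fraction(w, 2), Fraction(h, 2))
    corner_dist = math.hypot(w / 2.0, h / 2.0)
    image_area = Fraction(w) * Fraction(h)
    cos = 0.0
    for ann in annotations:
        area, dist2 = _exact_area_and_dist2(ann.vertices_px, center)
        if area == 0 or dist2 is None:
            logger.warning(
                "degenerate zero-area annotation on %s ignored", ann.image_id
            )
            continue
        size = float(area / image_area) ** 0.7
        location = 1.0 - math.sqrt(float(dist2)) / corner_dist
        cos += size * location
    return cos


# --------------------------------------------------------------------------
# annotation I/O and the per-image record
# --------------------------------------------------------------------------

def annotations_from_json(path) -> dict[str, list[Annotation]]:
    """Read a JSON list of {image_id, shape, points: [[x, y], ...]} records
    grouped by image."""
    with open(path) as fh:
        records = json.load(fh)
    out: dict[str, list[Annotation]] = {}
    for rec in records:
        ann = Annotation(
            image_id=rec["image_id"],
            shape=rec["shape"],
            vertices_px=[tuple(p) for p in rec["points"]],
        )
        out.setdefault(ann.image_id, []).append(ann)
    return out


def annotations_to_json(annotations: dict[str, list[Annotation]], path) -> None:
    records = [
        {"image_id": a.image_id, "shape": a.shape,
         "points": [list(p) for p in a.vertices_px]}
        for anns in annotations.values()
        for a in anns
    ]
    with open(path, "w") as fh:
        json.dump(records, fh)


@dataclass
class ImageStatsRecord:
    """The nine image statistics plus luminance for one image at one
    orientation."""

    image_id: str
    orientation_deg: int = 0
    gabor_low_sf: float = math.nan
    gabor_high_sf: float = math.nan
    homogeneity: float = math.nan
    within_sim: float = math.nan
    across_sim: float = math.nan
    cos: float = math.nan
    blk1_l2: float = math.nan
    blk5_l2: float = math.nan
    fc2_l2: float = math.nan
    luminance: float = math.nan

    def as_dict(self) -> dict:
        return dict(self.__dict__)


STAT_COLUMNS = [
    "gabor_low_sf",
    "gabor_high_sf",
    "homogeneity",
    "within_sim",
    "across_sim",
    "cos",
    "blk1_l2",
    "blk5_l2",
    "fc2_l2",
]


def compute_image_stats(
    image: np.ndarray,
    image_id: str,
    annotations: list[Annotation] | None = None,
    gabor_cfg: GaborBankConfig | None = None,
    gabor_size_px: int | None = 240,
    glcm_levels: int = 64,
    glcm_window: int = 3,
    glcm_mode: str = "windowed",
    glcm_average_directions: bool = False,
    orientation_deg: int = 0,
) -> ImageStatsRecord:
    """Low-, mid- and object-level statistics of one true-color image.

    The Gabor statistics are computed on a grayscale copy downsampled to
    ``gabor_size_px`` square (block averaging; ``None`` disables resizing),
    homogeneity on the full-resolution grayscale image.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        lum = luminance_L(img)
        gray = np.asarray(img, dtype=float)[..., :3].mean(axis=2)
    else:
        lum = math.nan
        gray = np.asarray(img, dtype=float)

    g = gray
    if gabor_size_px and gray.shape != (gabor_size_px, gabor_size_px):
        g = resize(gray, (gabor_size_px, gabor_size_px), anti_aliasing=True)
    act = gabor_activations(g, gabor_cfg)
    low, high = gabor_statistics(act, gabor_cfg)

    hom = glcm_homogeneity(
        gray, levels=glcm_levels, window=glcm_window, mode=glcm_mode,
        average_directions=glcm_average_directions,
    )
    cos = critical_object_saliency(annotations or [], (gray.shape[1], gray.shape[0]))
    return ImageStatsRecord(
        image_id=image_id,
        orientation_deg=orientation_deg,
        gabor_low_sf=low,
        gabor_high_sf=high,
        homogeneity=hom,
        cos=cos,
        luminance=lum,
    )
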