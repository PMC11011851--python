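"""Colour and texture feature extraction from slice photographs.

Each photographed slice is reduced to rectangular regions of interest
(ROIs).  From every ROI the module computes an 18-value descriptor:

* three colour features — the CIELAB means L*, a*, b* (D65, 2° observer);
* three first-order grayscale statistics — mean intensity, standard
  deviation, skewness;
* seven grey-level co-occurrence (GLCM / Haralick) features — contrast,
  dissimilarity, energy, homogeneity, angular second moment, entropy,
  correlation;
* five grey-level run-length (GLRLM) features — short-run emphasis,
  long-run emphasis, grey-level non-uniformity, run-length
  non-uniformity, run percentage.

Texture statistics are computed on BT.601-luma grayscale quantised to
``levels`` grey levels (default 32), with co-occurrence pairs at distance
1 averaged over the four standard angles and runs averaged over the four
standard directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2lab
from skimage.feature import graycomatrix

__all__ = [
    "SliceImage",
    "ROI",
    "GrayROI",
    "GLCMatrix",
    "RunLengthMatrix",
    "FEATURE_NAMES",
    "DEFAULT_ANGLES",
    "DEFAULT_DIRECTIONS",
    "select_rois",
    "srgb_to_lab",
    "color_features",
    "to_gray",
    "quantize",
    "first_order",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "roi_feature_vector",
    "slice_feature_vector",
    "extract_feature_table",
]

#: the 18 feature names, in canonical column order
FEATURE_NAMES = (
    "L_star",
    "a_star",
    "b_star",
    "mean_intensity",
    "standard_deviation",
    "skewness",
    "contrast",
    "dissimilarity",
    "energy",
    "homogeneity",
    "angular_second_moment",
    "entropy",
    "correlation",
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
)

DEFAULT_ANGLES = (0, 45, 90, 135)
DEFAULT_DIRECTIONS = (0, 45, 90, 135)

# direction -> (row step, col step) for run extraction
_DIRECTION_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class SliceImage:
    """8-bit RGB raster of one product slice plus its labels."""

    pixels: np.ndarray  # (H, W, 3) uint8
    meat_type: str = "custom"
    day: int | None = None
    slice_id: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROI:
    """Rectangular region ``[x0, x1) x [y0, y1)``, 0-based half-open."""

    x0: int
    y0: int
    x1: int
    y1: int
    roi_index: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"invalid ROI bounds {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        h, w = pixels.shape[:2]
        if self.x1 > w or self.y1 > h:
            raise ValueError("ROI extends outside the image")
        return pixels[self.y0 : self.y1, self.x0 : self.x1]


@dataclass
class GrayROI:
    """Raw luma intensities and their quantised grey levels."""

    raw: np.ndarray  # intensities in [0, 255]
    levels: np.ndarray  # quantised to {0, ..., n_levels-1}
    n_levels: int


@dataclass
class GLCMatrix:
    """Per-angle normalised grey-level co-occurrence matrices."""

    P: np.ndarray  # (G, G, n_angles), each angle slice sums to 1
    distance: int
    angles: tuple[int, ...]
    symmetric: bool


@dataclass
class RunLengthMatrix:
    """Run counts by (grey level, run length) for one direction."""

    R: np.ndarray  # (G, Lmax)
    direction: int
    n_runs: int
    n_pixels: int


# ---------------------------------------------------------------------------
# ROI selection
# ---------------------------------------------------------------------------


def select_rois(
    image: SliceImage,
    n: int = 8,
    roi_size: tuple[int, int] = (96, 96),
    strategy: str = "grid",
    seed: int | None = None,
    central_fraction: float = 0.8,
) -> list[ROI]:
    """Place ``n`` non-overlapping ROIs of ``roi_size`` (w, h) on the slice.

    ``grid`` tiles the ROIs on a deterministic near-square grid inside the
    central ``central_fraction`` of the frame; ``random_nonoverlap`` draws
    seeded non-overlapping placements by rejection sampling.
    """
    w, h = roi_size
    W, H = image.width, image.height
    if w > W:
        raise ValueError(f"ROI width {w} exceeds image width {W}")
    if h > H:
        raise ValueError(f"ROI height {h} exceeds image height {H}")
    if n < 1:
        raise ValueError("n must be >= 1")

    if strategy == "grid":
        rows = max(1, int(math.floor(math.sqrt(n))))
        cols = int(math.ceil(n / rows))
        margin_x = int(round(W * (1 - central_fraction) / 2))
        margin_y = int(round(H * (1 - central_fraction) / 2))
        span_x = W - 2 * margin_x
        span_y = H - 2 * margin_y
        if cols * w > span_x:
            # fall back to the full width before giving up
            margin_x, span_x = 0, W
        if rows * h > span_y:
            margin_y, span_y = 0, H
        if cols * w > span_x:
            raise ValueError(f"{cols} ROI columns of width {w} exceed image width {W}")
        if rows * h > span_y:
            raise ValueError(f"{rows} ROI rows of height {h} exceed image height {H}")
        rois = []
        for k in range(n):
            r, c = divmod(k, cols)
            cx = margin_x + int(round((c + 0.5) * span_x / cols))
            cy = margin_y + int(round((r + 0.5) * span_y / rows))
            x0 = min(max(cx - w // 2, 0), W - w)
            y0 = min(max(cy - h // 2, 0), H - h)
            rois.append(ROI(x0, y0, x0 + w, y0 + h, roi_index=k))
        return rois

    if strategy == "random_nonoverlap":
        rng = np.random.default_rng(seed)
        placed: list[ROI] = []
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 10000 * n:
                raise ValueError("could not place non-overlapping ROIs; reduce n or roi_size")
            x0 = int(rng.integers(0, W - w + 1))
            y0 = int(rng.integers(0, H - h + 1))
            cand = ROI(x0, y0, x0 + w, y0 + h, roi_index=len(placed))
            if all(
                cand.x1 <= o.x0 or o.x1 <= cand.x0 or cand.y1 <= o.y0 or o.y1 <= cand.y0
                for o in placed
            ):
                placed.append(cand)
        return placed

    raise ValueError(f"unknown ROI strategy {strategy!r}; use 'grid' or 'random_nonoverlap'")


# ---------------------------------------------------------------------------
# colour
# ---------------------------------------------------------------------------


def srgb_to_lab(pixels: np.ndarray) -> np.ndarray:
    """Convert 8-bit sRGB pixels to CIELAB (D65, 2° observer)."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        raise ValueError("expected 8-bit sRGB input")
    return rgb2lab(arr.astype(np.float64) / 255.0)


def color_features(image: SliceImage, roi: ROI) -> tuple[float, float, float]:
    """Mean L*, a*, b* of the ROI."""
    patch = roi.crop(image.pixels)
    if patch.size == 0:
        raise ValueError("empty ROI")
    lab = srgb_to_lab(patch)
    means = lab.reshape(-1, 3).mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


# ---------------------------------------------------------------------------
# grayscale
# ---------------------------------------------------------------------------


def to_gray(image: SliceImage, roi: ROI, n_levels: int = 32) -> GrayROI:
    """BT.601 luma (0.299 R + 0.587 G + 0.114 B, rounded) and quantisation."""
    patch = roi.crop(image.pixels).astype(np.float64)
    raw = np.rint(0.299 * patch[..., 0] + 0.587 * patch[..., 1] + 0.114 * patch[..., 2])
    raw = raw.astype(np.int64)
    return GrayROI(raw=raw, levels=quantize(raw, n_levels), n_levels=n_levels)


def quantize(raw: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantise intensities in [0, 255] to ``floor(raw * G / 256)``."""
    if n_levels < 2:
        raise ValueError("need at least 2 grey levels")
    return (np.asarray(raw, dtype=np.int64) * n_levels) // 256


def first_order(gray: GrayROI) -> tuple[float, float, float]:
    """Population mean, SD and skewness of the raw intensities.

    Skewness is m3 / m2^1.5; a zero-variance patch has skewness 0 by
    convention.
    """
    x = gray.raw.astype(np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 pixels")
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d**2)
    if m2 == 0:
        return float(mean), 0.0, 0.0
    m3 = np.mean(d**3)
    return float(mean), float(np.sqrt(m2)), float(m3 / m2**1.5)


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------


def compute_glcm(
    levels: np.ndarray,
    n_levels: int,
    distance: int = 1,
    angles: Sequence[int] = DEFAULT_ANGLES,
    symmetric: bool = True,
) -> GLCMatrix:
    """Normalised co-occurrence matrices at one pixel distance.

    Angles are the four standard offsets {0°, 45°, 90°, 135°}; each angle's
    matrix is normalised to sum 1 (after symmetrisation when requested).
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    bad = set(angles) - set(DEFAULT_ANGLES)
    if bad:
        raise ValueError(f"unsupported angles {sorted(bad)}; allowed: {DEFAULT_ANGLES}")
    lv = np.asarray(levels)
    if min(lv.shape) <= distance:
        raise ValueError("ROI smaller than the co-occurrence offset")
    rad = [np.deg2rad(a) for a in angles]
    P = graycomatrix(
        lv.astype(np.uint8),
        distances=[distance],
        angles=rad,
        levels=n_levels,
        symmetric=symmetric,
        normed=False,
    )[:, :, 0, :].astype(np.float64)
    sums = P.sum(axis=(0, 1), keepdims=True)
    if np.any(sums == 0):
        raise ValueError("no pixel pairs at the requested offset")
    return GLCMatrix(P=P / sums, distance=distance, angles=tuple(angles), symmetric=symmetric)


def glcm_features(glcm: GLCMatrix) -> dict[str, float]:
    """Seven Haralick-family features averaged over the stored angles.

    contrast = Σ P (i-j)²; dissimilarity = Σ P |i-j|; homogeneity =
    Σ P / (1 + (i-j)²); ASM = Σ P²; energy = √ASM; entropy = −Σ P log2 P;
    correlation = Σ P (i-μi)(j-μj) / (σi σj), defined as 1 for a constant
    field (σi σj = 0).
    """
    G = glcm.P.shape[0]
    i = np.arange(G, dtype=np.float64)
    diff = i[:, None] - i[None, :]
    per_angle: dict[str, list[float]] = {k: [] for k in (
        "contrast", "dissimilarity", "energy", "homogeneity",
        "angular_second_moment", "entropy", "correlation")}
    for a in range(glcm.P.shape[2]):
        P = glcm.P[:, :, a]
        asm = float(np.sum(P**2))
        nz = P[P > 0]
        mu_i = float(np.sum(P.sum(axis=1) * i))
        mu_j = float(np.sum(P.sum(axis=0) * i))
        var_i = float(np.sum(P.sum(axis=1) * (i - mu_i) ** 2))
        var_j = float(np.sum(P.sum(axis=0) * (i - mu_j) ** 2))
        denom = np.sqrt(var_i * var_j)
        if denom == 0:
            corr = 1.0
        else:
            cov = float(np.sum(P * (i[:, None] - mu_i) * (i[None, :] - mu_j)))
            corr = cov / denom
        per_angle["contrast"].append(float(np.sum(P * diff**2)))
        per_angle["dissimilarity"].append(float(np.sum(P * np.abs(diff))))
        per_angle["homogeneity"].append(float(np.sum(P / (1.0 + diff**2))))
        per_angle["angular_second_moment"].append(asm)
        per_angle["entropy"].append(float(-np.sum(nz * np.log2(nz))))
        per_angle["correlation"].append(corr)
    out = {k: float(np.mean(v)) for k, v in per_angle.items() if k != "energy"}
    # energy is defined from the angle-averaged ASM so energy^2 == ASM holds
    # for the reported feature vector
    out["energy"] = float(np.sqrt(out["angular_second_moment"]))
    return out


# ---------------------------------------------------------------------------
# run length
# ---------------------------------------------------------------------------


def _lines(levels: np.ndarray, direction: int) -> Iterable[np.ndarray]:
    """Scan lines of the image along one of the four run directions."""
    lv = np.asarray(levels)
    if direction == 0:
        yield from lv
    elif direction == 90:
        yield from lv.T
    elif direction == 45:
        flipped = lv[::-1]  # anti-diagonals run up-right
        for k in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, offset=k)
    elif direction == 135:
        lv2 = lv[::-1, ::-1]  # diagonals running up-left
        for k in range(-lv2.shape[0] + 1, lv2.shape[1]):
            yield np.diagonal(lv2, offset=k)
    else:
        raise ValueError(f"unsupported direction {direction}; allowed: {DEFAULT_DIRECTIONS}")


def compute_glrlm(
    levels: np.ndarray,
    n_levels: int,
    directions: Sequence[int] = DEFAULT_DIRECTIONS,
) -> list[RunLengthMatrix]:
    """Maximal-run counts by (level, length), one matrix per direction."""
    lv = np.asarray(levels)
    n_pixels = int(lv.size)
    max_len = max(lv.shape)
    out = []
    for direction in directions:
        R = np.zeros((n_levels, max_len), dtype=np.int64)
        for line in _lines(lv, direction):
            if line.size == 0:
                continue
            # run-length encode the line
            change = np.nonzero(np.diff(line))[0]
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [line.size]))
            for s, e in zip(starts, ends):
                R[line[s], e - s - 1] += 1
        out.append(
            RunLengthMatrix(R=R, direction=direction, n_runs=int(R.sum()), n_pixels=n_pixels)
        )
    return out


def glrlm_features(matrices: Sequence[RunLengthMatrix]) -> dict[str, float]:
    """SRE, LRE, GLN, RLN, RP averaged over the run directions."""
    if not matrices:
        raise ValueError("no run-length matrices supplied")
    acc: dict[str, list[float]] = {k: [] for k in (
        "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
        "run_length_nonuniformity", "run_percentage")}
    for m in matrices:
        if m.n_runs < 1:
            raise ValueError("empty run-length matrix")
        R = m.R.astype(np.float64)
        lengths = np.arange(1, R.shape[1] + 1, dtype=np.float64)
        nr = float(m.n_runs)
        by_length = R.sum(axis=0)
        by_level = R.sum(axis=1)
        acc["short_run_emphasis"].append(float(np.sum(by_length / lengths**2)) / nr)
        acc["long_run_emphasis"].append(float(np.sum(by_length * lengths**2)) / nr)
        acc["gray_level_nonuniformity"].append(float(np.sum(by_level**2)) / nr)
        acc["run_length_nonuniformity"].append(float(np.sum(by_length**2)) / nr)
        acc["run_percentage"].append(nr / float(m.n_pixels))
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# feature vectors and tables
# ---------------------------------------------------------------------------


def roi_feature_vector(
    image: SliceImage,
    roi: ROI,
    n_levels: int = 32,
    distance: int = 1,
    angles: Sequence[int] = DEFAULT_ANGLES,
    directions: Sequence[int] = DEFAULT_DIRECTIONS,
) -> dict[str, float]:
    """The 18-feature descriptor of one ROI, keyed by FEATURE_NAMES."""
    L, a, b = color_features(image, roi)
    gray = to_gray(image, roi, n_levels)
    mean, sd, skew = first_order(gray)
    feats: dict[str, float] = {
        "L_star": L,
        "a_star": a,
        "b_star": b,
        "mean_intensity": mean,
        "standard_deviation": sd,
        "skewness": skew,
    }
    feats.update(glcm_features(compute_glcm(gray.levels, n_levels, distance, angles)))
    feats.update(glrlm_features(compute_glrlm(gray.levels, n_levels, directions)))
    return {k: feats[k] for k in FEATURE_NAMES}


def slice_feature_vector(
    image: SliceImage,
    rois: Sequence[ROI],
    aggregation: str = "per_roi",
    **kwargs,
) -> list[dict[str, float]]:
    """Per-ROI 18-vectors, or their feature-wise mean for the slice.

    Returns a list of dicts: one per ROI for ``per_roi``, a single-element
    list for ``slice_mean``.
    """
    if aggregation not in ("per_roi", "slice_mean"):
        raise ValueError("aggregation must be 'per_roi' or 'slice_mean'")
    vectors = [roi_feature_vector(image, roi, **kwargs) for roi in rois]
    missing = [k for k in FEATURE_NAMES for v in vectors if k not in v]
    if missing:
        raise ValueError(f"missing features: {sorted(set(missing))}")
    if aggregation == "per_roi":
        return vectors
    mean = {k: float(np.mean([v[k] for v in vectors])) for k in FEATURE_NAMES}
    return [mean]


def extract_feature_table(
    images: Sequence[SliceImage],
    n_rois: int = 8,
    roi_size: tuple[int, int] = (96, 96),
    aggregation: str = "per_roi",
    n_levels: int = 32,
    strategy: str = "grid",
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Feature table over a labelled image collection.

    Columns: sample_id, meat_type, day, slice_id, roi_index (or "mean"),
    then the 18 feature names.
    """
    rows = []
    for img in images:
        rois = select_rois(img, n=n_rois, roi_size=roi_size, strategy=strategy, seed=seed)
        vectors = slice_feature_vector(img, rois, aggregation=aggregation, n_levels=n_levels, **kwargs)
        for k, vec in enumerate(vectors):
            roi_index = "mean" if aggregation == "slice_mean" else k
            rows.append(
                {
                    "sample_id": f"{img.meat_type}_d{img.day}_s{img.slice_id}_r{roi_index}",
                    "meat_type": img.meat_type,
                    "day": img.day,
                    "slice_id": img.slice_id,
                    "roi_index": roi_index,
                    **vec,
                }
            )
    return pd.DataFrame(rows)
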