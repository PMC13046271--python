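"""Mask construction workflows for nuclear and EdU segmentation.

The workflows mirror the three ImageJ-style recipes used to quantify
imaginal disc images:

* ``dapi_moments`` — rolling-ball background subtraction (radius 100 px),
  CLAHE (block 127, 256 bins, max slope 3), "Moments" (Tsai) automatic
  threshold with dark background. Used for the DAPI nuclear mask in EdU
  quantification.
* ``dapi_otsu`` — the same chain with an Otsu threshold. Used for the
  nuclear mask in cell cycle phase-distribution analysis.
* ``averaged_otsu`` — sequential pairwise averaging of the nuclear
  channels (DAPI, GFP, RFP, marker) followed by an Otsu threshold. Used
  for the phase-resolved marker quantification.

EdU masks use a Gaussian blur (sigma 2 px) followed by a Moments
threshold. Region-restricted masks are produced with a pixelwise binary
AND against another mask or a rasterized polygon.

Segmentation here is per-pixel: touching nuclei are not split into
instances, because all downstream statistics are pixel-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage import draw, exposure, restoration, transform

__all__ = [
    "BinaryMask",
    "ThresholdSpec",
    "rolling_ball_subtract",
    "clahe",
    "auto_threshold",
    "otsu_threshold_index",
    "moments_threshold_index",
    "make_nuclear_mask",
    "make_edu_mask",
    "intersect_masks",
    "rasterize_polygon",
]

NUCLEAR_WORKFLOWS = ("dapi_moments", "dapi_otsu", "averaged_otsu")


@dataclass
class BinaryMask:
    """A boolean 2-D mask together with the workflow that produced it."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def area(self) -> int:
        """Number of True pixels."""
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class ThresholdSpec:
    """Automatic threshold method plus image polarity.

    ``dark_background=True`` means objects are brighter than background,
    so the foreground is ``image > threshold``.
    """

    method: Literal["otsu", "moments"] = "otsu"
    dark_background: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "moments"):
            raise ValueError(f"unknown threshold method {self.method!r}")


def rolling_ball_subtract(image: np.ndarray, radius: float) -> np.ndarray:
    """Remove smooth background with a rolling-ball estimate of radius ``radius``.

    The background is a grayscale morphological estimate: the maximal
    height a ball of the given radius can reach while staying below the
    image surface. A flat background of any constant level maps to ~0, and
    features narrower than the ball are preserved. For large radii the
    estimate is computed on a min-filtered, downscaled copy and upsampled
    (the standard trick for large structuring elements), which is accurate
    for smooth backgrounds.

    The result is clipped to be non-negative.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("rolling_ball_subtract expects a 2-D image")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")

    if radius <= 10:
        shrink = 1
    elif radius <= 30:
        shrink = 2
    elif radius <= 100:
        shrink = 4
    else:
        shrink = 8

    if shrink == 1:
        background = restoration.rolling_ball(image, radius=radius)
    else:
        # min-filter before decimation so nuclei do not inflate the estimate
        small = ndi.minimum_filter(image, size=shrink)[::shrink, ::shrink]
        bg_small = restoration.rolling_ball(small, radius=max(1.0, radius / shrink))
        background = transform.resize(
            bg_small, image.shape, order=1, mode="edge", anti_aliasing=False
        )
    background = np.minimum(background, image)
    return image - background


def clahe(
    image: np.ndarray,
    block_size: int = 127,
    n_bins: int = 256,
    max_slope: float = 3.0,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Parameters follow the ImageJ CLAHE convention: ``block_size`` is the
    local tile edge length in pixels, ``n_bins`` the number of histogram
    bins, and ``max_slope`` the slope limit of the local mapping. The
    slope limit is applied by clipping each tile histogram at
    ``max_slope / n_bins`` of the tile mass, which makes ``max_slope=1``
    approach an identity mapping and larger values allow stronger local
    stretching.

    The input is first rescaled to [0, 1] by its own min/max; the output
    is returned in [0, 1]. A constant image is returned unchanged (there
    is no contrast to enhance).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("clahe expects a 2-D image")
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if max_slope < 1:
        raise ValueError(f"max_slope must be >= 1, got {max_slope}")

    lo = float(image.min())
    hi = float(image.max())
    if hi == lo:
        return image.copy()
    norm = (image - lo) / (hi - lo)
    return exposure.equalize_adapthist(
        norm,
        kernel_size=block_size,
        nbins=n_bins,
        clip_limit=max_slope / n_bins,
    )


def _histogram(image: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts and bin-center gray levels for thresholding.

    Integer images whose value range fits in ``n_bins`` levels get one bin
    per integer level (exact 8-bit tool behaviour); other images use
    ``n_bins`` equal-width bins over [min, max].
    """
    lo = image.min()
    hi = image.max()
    if np.issubdtype(image.dtype, np.integer) and (hi - lo) < n_bins:
        levels = np.arange(int(lo), int(hi) + 1)
        edges = np.concatenate([levels - 0.5, [int(hi) + 0.5]])
        counts, _ = np.histogram(image, bins=edges)
        return counts.astype(float), levels.astype(float)
    counts, edges = np.histogram(image, bins=n_bins, range=(float(lo), float(hi)))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def otsu_threshold_index(counts: np.ndarray) -> int:
    """Otsu threshold on a histogram: the bin index maximizing between-class
    variance, with the lower class defined as bins ``<= index``.

    Exact ties (plateaus, e.g. across empty bins between two well-separated
    modes) resolve to the middle of the maximal plateau, so a two-delta
    histogram thresholds midway between its modes.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("histogram must be 1-D with >= 2 bins")
    total = counts.sum()
    if total <= 0 or np.count_nonzero(counts) < 2:
        raise ValueError("histogram is degenerate: threshold undefined")
    idx = np.arange(len(counts), dtype=float)
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    mu0 = np.cumsum(counts * idx)[:-1]
    mu_total = float((counts * idx).sum())
    valid = (w0 > 0) & (w1 > 0)
    between = np.full(len(counts) - 1, -np.inf)
    m0 = np.divide(mu0, w0, out=np.zeros_like(mu0), where=w0 > 0)
    m1 = np.divide(mu_total - mu0, w1, out=np.zeros_like(mu0), where=w1 > 0)
    between[valid] = (w0 * w1)[valid] * (m0 - m1)[valid] ** 2
    ties = np.nonzero(between == between.max())[0]
    return int(ties[(len(ties) - 1) // 2])


def moments_threshold_index(counts: np.ndarray) -> int:
    """Moment-preserving (Tsai / ImageJ "Moments") threshold on a histogram.

    Finds the two-level image preserving the first three gray-level
    moments of the input histogram, then returns the smallest bin index at
    which the cumulative histogram reaches the fraction assigned to the
    lower level.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("histogram must be 1-D with >= 2 bins")
    total = counts.sum()
    if total <= 0 or np.count_nonzero(counts) < 2:
        raise ValueError("histogram is degenerate: threshold undefined")
    p = counts / total
    idx = np.arange(len(counts), dtype=float)
    m1 = float((p * idx).sum())
    m2 = float((p * idx**2).sum())
    m3 = float((p * idx**3).sum())
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("histogram is degenerate: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise ValueError("moment-preserving levels are complex: threshold undefined")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate moment-preserving levels")
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels at the lower level
    cdf = np.cumsum(p)
    t = int(np.searchsorted(cdf, p0))
    return min(max(t, 0), len(counts) - 1)


def auto_threshold(
    image: np.ndarray,
    spec: ThresholdSpec | str = ThresholdSpec(),
    n_bins: int = 256,
) -> float:
    """Automatic intensity threshold by the Otsu or Moments method.

    The histogram uses one bin per gray level for 8-bit-like integer
    images and 256 equal bins over [min, max] otherwise. The returned
    value is the gray level of the selected bin; foreground (with a dark
    background) is ``image > threshold``. Raises on constant images, for
    which no threshold is defined.
    """
    if isinstance(spec, str):
        spec = ThresholdSpec(method=spec)  # type: ignore[arg-type]
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    counts, levels = _histogram(image, n_bins)
    if spec.method == "otsu":
        t = otsu_threshold_index(counts)
    else:
        t = moments_threshold_index(counts)
    return float(levels[t])


def _sequential_average(channels: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise sequential averaging, as done with the ImageJ Image
    Calculator: ``(((c0 + c1)/2 + c2)/2 + ...)``."""
    acc = np.asarray(channels[0], dtype=float)
    for ch in channels[1:]:
        acc = (acc + np.asarray(ch, dtype=float)) / 2.0
    return acc


def make_nuclear_mask(
    channels: Sequence[np.ndarray] | np.ndarray,
    workflow: str = "dapi_otsu",
    radius: float = 100.0,
    clahe_block: int = 127,
    clahe_bins: int = 256,
    clahe_slope: float = 3.0,
) -> BinaryMask:
    """Build a nuclear mask with one of the named preset workflows.

    ``dapi_moments`` and ``dapi_otsu`` run background subtraction →
    CLAHE → threshold on the first (DAPI) channel; ``averaged_otsu``
    sequentially averages all supplied channels and applies an Otsu
    threshold. See the module docstring for where each preset is used.
    """
    if isinstance(channels, np.ndarray) and channels.ndim == 2:
        channels = [channels]
    channels = [np.asarray(c, dtype=float) for c in channels]
    if not channels:
        raise ValueError("need at least one channel")
    if workflow not in NUCLEAR_WORKFLOWS:
        raise ValueError(
            f"unknown workflow {workflow!r}; expected one of {NUCLEAR_WORKFLOWS}"
        )
    if workflow == "averaged_otsu":
        avg = _sequential_average(channels)
        thr = auto_threshold(avg, ThresholdSpec("otsu"))
        return BinaryMask(avg > thr, provenance=workflow)

    processed = rolling_ball_subtract(channels[0], radius)
    processed = clahe(processed, clahe_block, clahe_bins, clahe_slope)
    method = "moments" if workflow == "dapi_moments" else "otsu"
    thr = auto_threshold(processed, ThresholdSpec(method))
    return BinaryMask(processed > thr, provenance=workflow)


def make_edu_mask(edu_image: np.ndarray, sigma: float = 2.0) -> BinaryMask:
    """EdU-positive pixel mask: Gaussian blur (sigma px) then Moments threshold."""
    edu_image = np.asarray(edu_image, dtype=float)
    if edu_image.ndim != 2:
        raise ValueError("make_edu_mask expects a 2-D image")
    blurred = ndi.gaussian_filter(edu_image, sigma=sigma) if sigma > 0 else edu_image
    thr = auto_threshold(blurred, ThresholdSpec("moments"))
    return BinaryMask(blurred > thr, provenance="edu_moments")


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon given as (x, y) vertices in pixel
    coordinates: pixels whose centers fall inside are included.

    Polygons are assumed simple (non-self-intersecting), for which the
    even-odd and nonzero fill rules coincide.
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise ValueError("polygon must be an (n >= 3) x 2 array of (x, y) vertices")
    # polygon2mask wants (row, col) = (y, x); pixel (i, j) covers
    # [j, j+1) x [i, i+1) with its center at (j+0.5, i+0.5)
    return draw.polygon2mask(shape, vertices[:, ::-1] - 0.5)


def intersect_masks(
    a: BinaryMask | np.ndarray,
    b: BinaryMask | np.ndarray,
) -> BinaryMask:
    """Pixelwise binary AND of a mask with another mask or a polygon.

    ``b`` may be a :class:`BinaryMask`, a boolean array of the same shape,
    or an (n, 2) array of polygon (x, y) vertices which is rasterized
    first.
    """
    a_arr = a.mask if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    if a_arr.ndim != 2:
        raise ValueError("first argument must be a 2-D mask")
    if isinstance(b, BinaryMask):
        b_arr = b.mask
    else:
        b_np = np.asarray(b)
        if b_np.ndim == 2 and b_np.shape[1] == 2 and b_np.shape != a_arr.shape:
            b_arr = rasterize_polygon(b_np, a_arr.shape)
        else:
            b_arr = b_np.astype(bool)
    if b_arr.shape != a_arr.shape:
        raise ValueError(f"shape mismatch: {a_arr.shape} vs {b_arr.shape}")
    return BinaryMask(a_arr & b_arr, provenance="and")
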