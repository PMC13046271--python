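"""Intensity statistics: phase-normalized profiles, ROI ratios, area
fractions, mean intensities and region areas.

These are the per-disc statistics behind the figure panels of a
phase-resolved immunofluorescence analysis:

* :func:`phase_normalized_means` — mean marker intensity per cell cycle
  phase, normalized either by the average of the four phase means
  (``mean_of_phases``, default: values average to 1) or by their sum
  (``sum_of_phases``: values sum to 1, each phase's relative contribution
  to the total signal).
* :func:`roi_ratio` — ratio of mean intensities between two ROI sets,
  e.g. pouch vs hinge, in-ZNC vs out-of-ZNC, or patch vs adjacent region.
* :func:`area_fraction` — e.g. EdU-positive nuclear area over the union
  of EdU- and DAPI-positive area within the pouch.
* :func:`mean_intensity`, :func:`region_area`, :func:`dapi_normalize`.

Cross-disc aggregation is a plain mean; group-level significance testing
is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from phasequant.fucci import PHASES, Phase, PhaseLabelMap
from phasequant.segmentation import BinaryMask, rasterize_polygon

__all__ = [
    "Roi",
    "PhaseProfileEstimate",
    "phase_normalized_means",
    "roi_ratio",
    "area_fraction",
    "mean_intensity",
    "region_area",
    "dapi_normalize",
    "place_rois",
]

ROI_ROLES = ("pouch", "hinge", "in_domain", "out_domain", "patch", "adjacent")


@dataclass(frozen=True)
class Roi:
    """A rectangular region of interest.

    ``x, y`` are the top-left pixel coordinates; width/height are given in
    micrometres and converted to pixels with the image pixel size.
    """

    name: str
    role: str
    x: int
    y: int
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}")
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("ROI side lengths must be > 0")

    def slices(self, pixel_size: float) -> tuple[slice, slice]:
        w = int(round(self.width_um / pixel_size))
        h = int(round(self.height_um / pixel_size))
        return slice(self.y, self.y + h), slice(self.x, self.x + w)


@dataclass
class PhaseProfileEstimate:
    """Normalized per-phase marker means in order (G1, early S, late S, G2).

    ``raw`` holds the unnormalized phase means; phases without pixels are
    NaN. In ``mean_of_phases`` mode the normalized values average to 1; in
    ``sum_of_phases`` mode they sum to 1.
    """

    normalized: np.ndarray
    raw: np.ndarray
    n_pixels: np.ndarray
    mode: str

    def as_dict(self) -> dict[str, float]:
        return {p.name: float(v) for p, v in zip(PHASES, self.normalized)}


def phase_normalized_means(
    marker: np.ndarray,
    labels: PhaseLabelMap | np.ndarray,
    mode: Literal["mean_of_phases", "sum_of_phases"] = "mean_of_phases",
) -> PhaseProfileEstimate:
    """Per-phase mean marker intensity, normalized across phases.

    The raw value of each phase is the mean marker intensity over that
    phase's labeled pixels. Normalization divides by the average
    (``mean_of_phases``) or the sum (``sum_of_phases``) of the raw means
    over the phases that are present. Raises if no phase has pixels.
    """
    if mode not in ("mean_of_phases", "sum_of_phases"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    marker = np.asarray(marker, dtype=float)
    lab = labels.labels if isinstance(labels, PhaseLabelMap) else np.asarray(labels)
    if marker.shape != lab.shape:
        raise ValueError("marker and labels must share a shape")

    raw = np.full(4, np.nan)
    n_pixels = np.zeros(4, dtype=int)
    for k, p in enumerate(PHASES):
        sel = lab == int(p)
        n_pixels[k] = int(sel.sum())
        if n_pixels[k]:
            raw[k] = float(marker[sel].mean())
    present = ~np.isnan(raw)
    if not present.any():
        raise ValueError("no labeled phases present")
    denom = np.nanmean(raw) if mode == "mean_of_phases" else np.nansum(raw)
    if denom == 0:
        raise ValueError("zero total signal: cannot normalize")
    return PhaseProfileEstimate(
        normalized=raw / denom, raw=raw, n_pixels=n_pixels, mode=mode
    )


def _roi_means(
    image: np.ndarray, rois: Sequence[Roi], pixel_size: float
) -> np.ndarray:
    means = []
    for roi in rois:
        sly, slx = roi.slices(pixel_size)
        if (
            sly.start < 0
            or slx.start < 0
            or sly.stop > image.shape[0]
            or slx.stop > image.shape[1]
        ):
            raise ValueError(f"ROI {roi.name!r} exceeds image bounds")
        means.append(float(image[sly, slx].mean()))
    return np.asarray(means)


def roi_ratio(
    image: np.ndarray,
    numerator_rois: Sequence[Roi],
    denominator_rois: Sequence[Roi],
    pixel_size: float,
) -> float:
    """Ratio of average ROI mean intensities (numerator over denominator).

    Each side is summarized as the mean of its per-ROI mean intensities;
    the result is e.g. the pouch-to-hinge intensity ratio for three 15x15
    um ROIs per compartment. Scale-invariant: multiplying the image by a
    positive constant leaves the ratio unchanged.
    """
    image = np.asarray(image, dtype=float)
    if not numerator_rois or not denominator_rois:
        raise ValueError("need at least one ROI on each side")
    num = _roi_means(image, numerator_rois, pixel_size).mean()
    den = _roi_means(image, denominator_rois, pixel_size).mean()
    if den == 0:
        raise ValueError("denominator ROI mean is zero")
    return float(num / den)


def area_fraction(
    mask_a: BinaryMask | np.ndarray,
    mask_b: BinaryMask | np.ndarray,
    region: BinaryMask | np.ndarray | None = None,
    denominator: Literal["union", "intersection"] = "union",
) -> float:
    """Fraction |A ∩ B ∩ R| / |(A ∪ B) ∩ R| (default union denominator).

    With ``denominator="union"`` this is the bounded fraction used for the
    EdU-to-DAPI area ratio: EdU-positive nuclear area over the total EdU-
    or DAPI-positive area within the region. The ``intersection`` variant
    divides |A ∩ B ∩ R| by |B ∩ R| instead.
    """
    a = mask_a.mask if isinstance(mask_a, BinaryMask) else np.asarray(mask_a, bool)
    b = mask_b.mask if isinstance(mask_b, BinaryMask) else np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    if region is None:
        r = np.ones(a.shape, dtype=bool)
    else:
        r = region.mask if isinstance(region, BinaryMask) else np.asarray(region, bool)
        if r.shape != a.shape:
            raise ValueError("region shape differs")
    inter = np.count_nonzero(a & b & r)
    if denominator == "union":
        den = np.count_nonzero((a | b) & r)
    elif denominator == "intersection":
        den = np.count_nonzero(b & r)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if den == 0:
        raise ValueError("empty denominator region")
    return float(inter / den)


def mean_intensity(
    image: np.ndarray,
    mask_or_roi: BinaryMask | np.ndarray | Roi,
    pixel_size: float | None = None,
) -> float:
    """Arithmetic mean intensity over a mask or a rectangular ROI."""
    image = np.asarray(image, dtype=float)
    if isinstance(mask_or_roi, Roi):
        if pixel_size is None:
            raise ValueError("pixel_size required for an ROI support")
        return float(_roi_means(image, [mask_or_roi], pixel_size)[0])
    m = (
        mask_or_roi.mask
        if isinstance(mask_or_roi, BinaryMask)
        else np.asarray(mask_or_roi, bool)
    )
    if m.shape != image.shape:
        raise ValueError("mask shape differs from image")
    if not m.any():
        raise ValueError("empty support")
    return float(image[m].mean())


def region_area(
    polygon: np.ndarray,
    pixel_size: float,
    shape: tuple[int, int],
) -> float:
    """Area of a polygonal region in um^2: rasterized pixel count times
    pixel_size^2. Raises on degenerate polygons (no interior pixels)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    mask = rasterize_polygon(np.asarray(polygon, float), shape)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("degenerate polygon: no interior pixels")
    return n * pixel_size**2


def dapi_normalize(ratio_marker: float, ratio_dapi: float) -> float:
    """Normalize a marker intensity ratio by the matching DAPI ratio.

    Removes the contribution of nuclear density differences to a
    compartment intensity ratio (applied e.g. to heterochromatin marks
    whose apparent enrichment tracks nuclear packing).
    """
    if ratio_dapi <= 0:
        raise ValueError("ratio_dapi must be > 0")
    return float(ratio_marker / ratio_dapi)


def place_rois(
    region_mask: np.ndarray,
    role: str,
    pixel_size: float,
    n: int = 3,
    size_um: float = 15.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[Roi]:
    """Place ``n`` non-overlapping square ROIs fully inside a region mask.

    A seeded stand-in for the manual ROI placement of the published
    workflow; positions are drawn uniformly and rejected when the square
    leaves the region or overlaps an accepted ROI.
    """
    region_mask = np.asarray(region_mask, bool)
    side = int(round(size_um / pixel_size))
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(region_mask)
    if len(rows) == 0:
        raise ValueError("empty region mask")
    n_restarts = 20
    for _restart in range(n_restarts):
        # restart from scratch when earlier squares block the rest
        placed: list[Roi] = []
        boxes: list[tuple[int, int]] = []
        for _ in range(max(1, max_tries // n_restarts)):
            if len(placed) == n:
                return placed
            i = rng.integers(0, len(rows))
            y, x = int(rows[i]), int(cols[i])
            if y + side > region_mask.shape[0] or x + side > region_mask.shape[1]:
                continue
            if not region_mask[y : y + side, x : x + side].all():
                continue
            if any(abs(x - bx) < side and abs(y - by) < side for by, bx in boxes):
                continue
            boxes.append((y, x))
            placed.append(
                Roi(
                    name=f"{role}_{len(placed) + 1}",
                    role=role,
                    x=x,
                    y=y,
                    width_um=size_um,
                    height_um=size_um,
                )
            )
        if len(placed) == n:
            return placed
    raise RuntimeError(
        f"could only place {len(placed)}/{n} ROIs of {size_um} um in the region"
    )
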