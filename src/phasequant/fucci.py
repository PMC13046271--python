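"""FUCCI-based per-pixel cell cycle phase classification.

The FUCCI system expresses two degradable fluorescent reporters (a
GFP-tagged E2F1 fragment and an RFP-tagged CycB fragment) whose joint
presence encodes four cell cycle states:

====== ===== =====
phase  GFP   RFP
====== ===== =====
G1     high  low
early S  low   low
late S   low   high
G2     high  high
====== ===== =====

A single threshold pair per image, derived from the average intensity of a
small set of reference early S-phase nuclei (five in the published
workflow), converts the two reporter channels into a per-pixel phase label:

* G2:        GFP > threshold and RFP > threshold
* G1:        GFP > threshold and RFP <= threshold
* early/mid S: GFP <= threshold and RFP <= threshold
* late S:    GFP <= threshold and RFP > threshold

Boundary equality goes to the ``<=`` branch. Mitotic cells are not
modelled or classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Phase",
    "PhaseThresholds",
    "PhaseLabelMap",
    "derive_thresholds",
    "classify_pixels",
    "phase_fractions",
    "auto_select_reference_nuclei",
]


class Phase(IntEnum):
    """Cell cycle phase labels; ``UNASSIGNED`` marks non-nuclear pixels."""

    UNASSIGNED = 0
    G1 = 1
    EARLY_S = 2
    LATE_S = 3
    G2 = 4


#: The four proper phases in canonical order (G1, early S, late S, G2).
PHASES: tuple[Phase, ...] = (Phase.G1, Phase.EARLY_S, Phase.LATE_S, Phase.G2)


@dataclass(frozen=True)
class PhaseThresholds:
    """GFP/RFP intensity cutoffs separating reporter-positive from -negative.

    Derived from reference early S-phase nuclei, which are negative for
    both reporters.
    """

    gfp_threshold: float
    rfp_threshold: float
    n_reference_nuclei: int = 0

    def __post_init__(self) -> None:
        for name in ("gfp_threshold", "rfp_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class PhaseLabelMap:
    """Per-pixel phase assignment inside a nuclear mask.

    ``labels`` holds :class:`Phase` values as ``uint8``; pixels outside the
    mask are ``Phase.UNASSIGNED``.
    """

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.max(initial=0) > int(Phase.G2):
            raise ValueError("labels contain values outside the Phase enum")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of labeled (nuclear) pixels."""
        return self.labels != int(Phase.UNASSIGNED)

    def pixel_counts(self) -> dict[str, int]:
        """Number of labeled pixels per phase, in canonical phase order."""
        return {p.name: int(np.count_nonzero(self.labels == int(p))) for p in PHASES}


def _reference_masks(
    reference_nuclei: Sequence[np.ndarray] | np.ndarray,
    nucleus_ids: Iterable[int] | None,
    shape: tuple[int, int],
) -> list[np.ndarray]:
    """Normalize the reference-nucleus argument into a list of boolean masks."""
    if isinstance(reference_nuclei, np.ndarray) and reference_nuclei.ndim == 2 and (
        reference_nuclei.dtype != bool
    ):
        # a label image plus explicit nucleus ids
        if nucleus_ids is None:
            raise ValueError("nucleus_ids required when passing a label image")
        masks = [reference_nuclei == int(i) for i in nucleus_ids]
    else:
        masks = [np.asarray(m, dtype=bool) for m in reference_nuclei]
    if not masks:
        raise ValueError("reference nucleus set is empty")
    for m in masks:
        if m.shape != shape:
            raise ValueError("reference mask shape does not match image shape")
        if not m.any():
            raise ValueError("a reference nucleus mask is empty")
    return masks


def derive_thresholds(
    gfp: np.ndarray,
    rfp: np.ndarray,
    reference_nuclei: Sequence[np.ndarray] | np.ndarray,
    nucleus_ids: Iterable[int] | None = None,
    method: Literal["nucleus_means", "pooled_pixels"] = "nucleus_means",
) -> PhaseThresholds:
    """Derive the GFP/RFP thresholds from reference early S-phase nuclei.

    Parameters
    ----------
    gfp, rfp
        Reporter channel images (same shape).
    reference_nuclei
        Either a sequence of boolean nucleus masks, or an integer label
        image combined with ``nucleus_ids``.
    method
        ``"nucleus_means"`` (default) averages the per-nucleus mean
        intensities, which is robust to nucleus-size variation;
        ``"pooled_pixels"`` averages over all reference pixels pooled.

    Returns
    -------
    PhaseThresholds
        With each threshold set to the average reference intensity of the
        corresponding channel.
    """
    gfp = np.asarray(gfp, dtype=float)
    rfp = np.asarray(rfp, dtype=float)
    if gfp.shape != rfp.shape:
        raise ValueError("gfp and rfp must share a shape")
    masks = _reference_masks(reference_nuclei, nucleus_ids, gfp.shape)
    if method == "nucleus_means":
        g = float(np.mean([gfp[m].mean() for m in masks]))
        r = float(np.mean([rfp[m].mean() for m in masks]))
    elif method == "pooled_pixels":
        pooled = np.zeros(gfp.shape, dtype=bool)
        for m in masks:
            pooled |= m
        g = float(gfp[pooled].mean())
        r = float(rfp[pooled].mean())
    else:
        raise ValueError(f"unknown method {method!r}")
    return PhaseThresholds(g, r, n_reference_nuclei=len(masks))


def classify_pixels(
    gfp: np.ndarray,
    rfp: np.ndarray,
    thresholds: PhaseThresholds,
    nuclear_mask: np.ndarray,
) -> PhaseLabelMap:
    """Classify every nuclear pixel into one of the four cell cycle phases.

    Applies the FUCCI decision rule (see module docstring) to each pixel of
    ``nuclear_mask``; pixels outside the mask are ``UNASSIGNED``. Equality
    with a threshold goes to the ``<=`` branch, so a pixel exactly at both
    thresholds is early S.
    """
    gfp = np.asarray(gfp, dtype=float)
    rfp = np.asarray(rfp, dtype=float)
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    if not (gfp.shape == rfp.shape == nuclear_mask.shape):
        raise ValueError("gfp, rfp and nuclear_mask must share a shape")

    g_hi = gfp > thresholds.gfp_threshold
    r_hi = rfp > thresholds.rfp_threshold
    labels = np.full(gfp.shape, int(Phase.EARLY_S), dtype=np.uint8)
    labels[g_hi & ~r_hi] = int(Phase.G1)
    labels[~g_hi & r_hi] = int(Phase.LATE_S)
    labels[g_hi & r_hi] = int(Phase.G2)
    labels[~nuclear_mask] = int(Phase.UNASSIGNED)
    return PhaseLabelMap(labels, provenance="classify_pixels")


def phase_fractions(labels: PhaseLabelMap | np.ndarray) -> np.ndarray:
    """Per-phase area fractions of labeled pixels, in order (G1, eS, lS, G2).

    The fractions are computed over labeled pixels only and sum to 1.
    Raises if no pixel is labeled.
    """
    arr = labels.labels if isinstance(labels, PhaseLabelMap) else np.asarray(labels)
    counts = np.array(
        [np.count_nonzero(arr == int(p)) for p in PHASES], dtype=float
    )
    total = counts.sum()
    if total == 0:
        raise ValueError("no labeled pixels: cannot compute phase fractions")
    return counts / total


def auto_select_reference_nuclei(
    gfp: np.ndarray,
    rfp: np.ndarray,
    nucleus_labels: np.ndarray,
    k: int = 5,
) -> list[int]:
    """Convenience helper: pick the ``k`` nuclei with lowest combined GFP+RFP.

    Reporter-negative nuclei are candidate early S-phase references. This
    is an optional extension of the manual reference selection used in the
    published workflow; prefer explicit reference nuclei when available.
    """
    nucleus_labels = np.asarray(nucleus_labels)
    ids = np.unique(nucleus_labels)
    ids = ids[ids > 0]
    if len(ids) < k:
        raise ValueError(f"need at least {k} nuclei, found {len(ids)}")
    combined = np.asarray(gfp, dtype=float) + np.asarray(rfp, dtype=float)
    means = [(float(combined[nucleus_labels == i].mean()), int(i)) for i in ids]
    means.sort()
    return [i for _, i in means[:k]]
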