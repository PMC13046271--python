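"""Synthetic imaging and count data with known ground truth.

Imaging track
-------------
:func:`generate_disc` renders a multi-channel image of a wing-disc-like
tissue: non-overlapping circular nuclei placed inside two disjoint
compartment polygons (pouch and hinge). Each nucleus carries a cell cycle
phase sampled from configurable proportions. Channels are built
generatively:

* DAPI — constant intensity per nucleus (optionally ramping 1x -> 2x
  across S phase to mimic DNA replication);
* GFP / RFP — the FUCCI reporter pair, with per-phase mean levels encoding
  the reporter logic (G1: GFP high / RFP low; early S: both low; late S:
  GFP low / RFP high; G2: both high);
* marker channels — ``base_intensity x phase_profile[phase]``, further
  multiplied by ``pouch_multiplier`` for nuclei whose centroid lies in the
  pouch compartment.

Every channel is ``background + nuclear contribution + additive Gaussian
noise`` clipped at zero. The generator returns the label image, the
per-nucleus phase/centroid/compartment table, and compartment masks, so
each downstream stage can be validated against ground truth.

Counts track
------------
:func:`generate_counts` emulates a CUT&Tag quantification over
categorized genomic regions (shared / unique to either condition /
500-bp no-peak bins): negative-binomial counts with per-category true
log2 fold changes in the knockdown condition and per-sample sequencing
depths implied by spike-in and histone-H3 totals, enabling end-to-end
validation of normalization and differential testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from shapely.geometry import Polygon

from phasequant.fucci import PHASES, Phase, PhaseThresholds
from phasequant.segmentation import rasterize_polygon

__all__ = [
    "PhaseProfile",
    "FucciScheme",
    "MarkerSpec",
    "DiscSpec",
    "SyntheticDisc",
    "generate_disc",
    "validation_thresholds",
    "CountSimSpec",
    "generate_counts",
    "COUNT_CATEGORIES",
]

COUNT_CATEGORIES = ("shared", "unique_wt", "unique_kd", "no_peak_bin")


@dataclass(frozen=True)
class PhaseProfile:
    """Relative marker intensity per cell cycle phase (unitless multipliers).

    The default profile reproduces the qualitative S-phase enrichment of
    H3K27ac observed in vivo: highest in early S, still elevated in late
    S, lower in G2 and G1.
    """

    g1: float = 0.85
    early_s: float = 1.30
    late_s: float = 1.25
    g2: float = 0.90

    def __post_init__(self) -> None:
        for name in ("g1", "early_s", "late_s", "g2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PhaseProfile.{name} must be > 0")

    def as_array(self) -> np.ndarray:
        """Multipliers in canonical phase order (G1, early S, late S, G2)."""
        return np.array([self.g1, self.early_s, self.late_s, self.g2], float)


@dataclass(frozen=True)
class FucciScheme:
    """Per-phase mean intensities of the GFP and RFP reporter channels.

    Must encode the FUCCI logic: GFP is high in G1 and G2 and low in S;
    RFP is high in late S and G2 and low in G1 and early S. The default
    low/high levels (10/100 a.u.) separate the four states cleanly in the
    absence of noise.
    """

    gfp: tuple[float, float, float, float] = (100.0, 10.0, 10.0, 100.0)
    rfp: tuple[float, float, float, float] = (10.0, 10.0, 100.0, 100.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.gfp, float)
        r = np.asarray(self.rfp, float)
        if g.shape != (4,) or r.shape != (4,):
            raise ValueError("gfp and rfp must each give 4 per-phase means")
        if (g < 0).any() or (r < 0).any():
            raise ValueError("reporter intensities must be >= 0")
        # reporter logic: order is (G1, early S, late S, G2)
        if not (min(g[0], g[3]) > max(g[1], g[2])):
            raise ValueError("GFP must be high in G1/G2 and low in S phases")
        if not (min(r[2], r[3]) > max(r[0], r[1])):
            raise ValueError("RFP must be high in late S/G2 and low in G1/early S")

    @classmethod
    def from_levels(cls, low: float = 10.0, high: float = 100.0) -> "FucciScheme":
        return cls(gfp=(high, low, low, high), rfp=(low, low, high, high))

    def gfp_array(self) -> np.ndarray:
        return np.asarray(self.gfp, float)

    def rfp_array(self) -> np.ndarray:
        return np.asarray(self.rfp, float)


@dataclass(frozen=True)
class MarkerSpec:
    """One nuclear marker channel: per-phase profile, base intensity (a.u.)
    and the pouch-compartment intensity multiplier."""

    profile: PhaseProfile = field(default_factory=PhaseProfile)
    base_intensity: float = 100.0
    pouch_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if self.pouch_multiplier <= 0:
            raise ValueError("pouch_multiplier must be > 0")


def _default_pouch() -> tuple[tuple[float, float], ...]:
    return ((20.0, 20.0), (280.0, 20.0), (280.0, 165.0), (20.0, 165.0))


def _default_hinge() -> tuple[tuple[float, float], ...]:
    return ((20.0, 194.0), (280.0, 194.0), (280.0, 339.0), (20.0, 339.0))


@dataclass(frozen=True)
class DiscSpec:
    """Parameters of a synthetic disc image.

    Defaults describe a densely populated epithelium imaged at confocal
    resolution: 0.25 um pixels, 500 nuclei of radius 1.0 +/- 0.1 um
    (~40% tissue coverage), FUCCI low/high levels 10/100 a.u., marker
    base intensity 100 a.u., camera background 2 a.u. and additive
    Gaussian noise of 5 a.u.
    """

    image_shape: tuple[int, int] = (360, 300)
    pixel_size: float = 0.25  # um per pixel
    n_nuclei: int = 500
    nucleus_radius_um: float = 1.0
    nucleus_radius_sd_um: float = 0.1
    pouch_polygon: tuple[tuple[float, float], ...] = field(default_factory=_default_pouch)
    hinge_polygon: tuple[tuple[float, float], ...] = field(default_factory=_default_hinge)
    phase_proportions: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    fucci: FucciScheme = field(default_factory=FucciScheme)
    markers: Mapping[str, MarkerSpec] = field(
        default_factory=lambda: {"H3K27ac": MarkerSpec()}
    )
    dapi_intensity: float = 80.0
    dapi_s_ramp: bool = False
    noise_sd: float = 5.0
    background_level: float = 2.0
    seed: int = 0
    max_placement_tries: int = 1000

    def __post_init__(self) -> None:
        props = np.asarray(self.phase_proportions, float)
        if props.shape != (4,) or (props < 0).any():
            raise ValueError("phase_proportions must be 4 non-negative values")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("phase_proportions must sum to 1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_um <= 0 or self.nucleus_radius_sd_um < 0:
            raise ValueError("nucleus radius parameters invalid")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be >= 0")
        pouch = Polygon(self.pouch_polygon)
        hinge = Polygon(self.hinge_polygon)
        if not pouch.is_valid or not hinge.is_valid:
            raise ValueError("compartment polygons must be simple (non-self-intersecting)")
        if pouch.intersects(hinge) and pouch.intersection(hinge).area > 0:
            raise ValueError("pouch and hinge polygons must be disjoint")


@dataclass
class SyntheticDisc:
    """A rendered disc: channels, ground-truth labels and compartment masks.

    ``truth_nuclei`` is a table with one row per nucleus:
    ``nucleus_id, phase, x, y, radius_px, region``.
    """

    channels: dict[str, np.ndarray]
    truth_labels: np.ndarray
    truth_nuclei: pd.DataFrame
    region_masks: dict[str, np.ndarray]
    spec: DiscSpec

    def truth_phase_map(self) -> np.ndarray:
        """Per-pixel ground-truth phase labels (uint8, Phase values)."""
        n = len(self.truth_nuclei)
        lut = np.zeros(n + 1, dtype=np.uint8)
        lut[self.truth_nuclei["nucleus_id"].to_numpy()] = self.truth_nuclei[
            "phase"
        ].to_numpy()
        return lut[self.truth_labels]

    def nuclear_truth_mask(self) -> np.ndarray:
        return self.truth_labels > 0


def _place_nuclei(spec: DiscSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping disc centers inside the compartments.

    Candidate centers are drawn from pixels whose distance to the outside
    of the compartment masks is at least the nucleus radius, so every
    nucleus lies fully inside a compartment.
    """
    shape = spec.image_shape
    pouch_mask = rasterize_polygon(np.asarray(spec.pouch_polygon), shape)
    hinge_mask = rasterize_polygon(np.asarray(spec.hinge_polygon), shape)
    union = pouch_mask | hinge_mask
    if spec.n_nuclei == 0:
        return np.empty((0, 2)), np.empty(0), np.empty(0, bool), pouch_mask, hinge_mask
    dist = ndi.distance_transform_edt(union)
    mean_r = spec.nucleus_radius_um / spec.pixel_size
    sd_r = spec.nucleus_radius_sd_um / spec.pixel_size

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    in_pouch: list[bool] = []
    acc_c = np.empty((0, 2))
    acc_r = np.empty(0)
    for _ in range(spec.n_nuclei):
        r = max(1.0, rng.normal(mean_r, sd_r))
        ok = False
        for _try in range(spec.max_placement_tries):
            y = rng.uniform(0, shape[0])
            x = rng.uniform(0, shape[1])
            iy, ix = int(y), int(x)
            # +1.5 px margin: the float center sits up to ~0.7 px from the
            # EDT grid point and rasterization includes pixels at distance r
            if iy >= shape[0] or ix >= shape[1] or dist[iy, ix] < r + 1.5:
                continue
            if len(acc_c):
                d2 = (acc_c[:, 0] - y) ** 2 + (acc_c[:, 1] - x) ** 2
                if (d2 < (acc_r + r) ** 2).any():
                    continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place nucleus {len(centers) + 1}/{spec.n_nuclei} after "
                f"{spec.max_placement_tries} tries: geometry too dense"
            )
        centers.append((y, x))
        radii.append(r)
        in_pouch.append(bool(pouch_mask[iy, ix]))
        acc_c = np.asarray(centers, float)
        acc_r = np.asarray(radii, float)
    return acc_c, acc_r, np.asarray(in_pouch, bool), pouch_mask, hinge_mask


def generate_disc(spec: DiscSpec) -> SyntheticDisc:
    """Render a synthetic disc image stack from ``spec``.

    Deterministic given ``spec.seed``: identical specs produce
    bit-identical arrays. Raises ``RuntimeError`` when nuclei cannot be
    placed without overlap within the bounded number of tries.
    """
    rng = np.random.default_rng(spec.seed)
    centers, radii, in_pouch, pouch_mask, hinge_mask = _place_nuclei(spec, rng)
    n = len(centers)
    shape = spec.image_shape

    phases = rng.choice(
        [int(p) for p in PHASES], size=n, p=np.asarray(spec.phase_proportions, float)
    )
    # per-nucleus position within S phase, used only for the optional DAPI ramp
    s_progress = rng.uniform(0.0, 1.0, size=n)

    labels = np.zeros(shape, dtype=np.int32)
    # per-nucleus footprint stored as (row slice, col slice, submask)
    footprints: list[tuple[slice, slice, np.ndarray]] = []
    for i in range(n):
        y, x = centers[i]
        r = radii[i]
        y0, y1 = max(0, int(y - r) - 1), min(shape[0], int(y + r) + 2)
        x0, x1 = max(0, int(x - r) - 1), min(shape[1], int(x + r) + 2)
        ys = np.arange(y0, y1)[:, None]
        xs = np.arange(x0, x1)[None, :]
        sub = (ys - y) ** 2 + (xs - x) ** 2 <= r**2
        sl = (slice(y0, y1), slice(x0, x1))
        footprints.append((sl[0], sl[1], sub))
        labels[sl][sub] = i + 1

    gfp_means = spec.fucci.gfp_array()
    rfp_means = spec.fucci.rfp_array()

    channels: dict[str, np.ndarray] = {}
    names = ["DAPI", "GFP", "RFP", *spec.markers.keys()]
    for name in names:
        img = np.full(shape, float(spec.background_level))
        for i in range(n):
            ph = int(phases[i]) - 1  # 0-based canonical phase index
            if name == "DAPI":
                val = spec.dapi_intensity
                if spec.dapi_s_ramp:
                    # DNA content: 1x in G1, ramping to 2x across S, 2x in G2
                    content = {0: 1.0, 1: 1.0 + 0.5 * s_progress[i],
                               2: 1.5 + 0.5 * s_progress[i], 3: 2.0}[ph]
                    val = spec.dapi_intensity * content
            elif name == "GFP":
                val = gfp_means[ph]
            elif name == "RFP":
                val = rfp_means[ph]
            else:
                m = spec.markers[name]
                val = m.base_intensity * m.profile.as_array()[ph]
                if in_pouch[i]:
                    val *= m.pouch_multiplier
            sly, slx, sub = footprints[i]
            img[sly, slx][sub] += val
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, None)

    region = np.where(in_pouch, "pouch", "hinge")
    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(1, n + 1),
            "phase": phases.astype(int),
            "phase_name": [Phase(int(p)).name for p in phases],
            "x": centers[:, 1] if n else np.empty(0),
            "y": centers[:, 0] if n else np.empty(0),
            "radius_px": radii,
            "region": region,
        }
    )
    return SyntheticDisc(
        channels=channels,
        truth_labels=labels,
        truth_nuclei=truth,
        region_masks={"pouch": pouch_mask, "hinge": hinge_mask},
        spec=spec,
    )


def validation_thresholds(spec: DiscSpec) -> PhaseThresholds:
    """Ground-truth-informed FUCCI thresholds for synthetic validation.

    Places each threshold midway between the generator's low and high
    reporter levels (plus the image background), where the classifier is
    maximally robust to the symmetric additive noise of the generator.
    Validation-only: on real images thresholds come from reference early
    S-phase nuclei via :func:`phasequant.fucci.derive_thresholds`.
    """
    g = spec.fucci.gfp_array()
    r = spec.fucci.rfp_array()
    g_mid = (min(g[0], g[3]) + max(g[1], g[2])) / 2.0
    r_mid = (min(r[2], r[3]) + max(r[0], r[1])) / 2.0
    return PhaseThresholds(
        gfp_threshold=spec.background_level + g_mid,
        rfp_threshold=spec.background_level + r_mid,
        n_reference_nuclei=0,
    )


# --------------------------------------------------------------------------
# Counts track
# --------------------------------------------------------------------------


def _default_n_regions() -> dict[str, int]:
    return {"shared": 800, "unique_wt": 200, "unique_kd": 200, "no_peak_bin": 800}


def _default_lfc() -> dict[str, float]:
    return {c: 0.0 for c in COUNT_CATEGORIES}


@dataclass(frozen=True)
class CountSimSpec:
    """Parameters of the synthetic region-count dataset.

    ``dispersion`` is the NB dispersion alpha with Var = mu + alpha mu^2;
    ``spikein_depths`` / ``h3_depths`` are per-sample library totals whose
    ratios induce the per-sample depth factors applied to the means.
    Samples are ordered WT replicates then KD replicates.
    """

    n_regions: Mapping[str, int] = field(default_factory=_default_n_regions)
    true_lfc: Mapping[str, float] = field(default_factory=_default_lfc)
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    n_replicates: int = 2
    spikein_depths: tuple[float, ...] = (9.5e5, 1.1e6, 1.05e6, 9.0e5)
    h3_depths: tuple[float, ...] = (1.0e6, 9.0e5, 1.1e6, 1.0e6)
    h3_baseline_mean: float = 200.0
    h3_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0 or self.h3_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        n_samples = 2 * self.n_replicates
        for name in ("spikein_depths", "h3_depths"):
            depths = np.asarray(getattr(self, name), float)
            if depths.shape != (n_samples,):
                raise ValueError(f"{name} must give one total per sample ({n_samples})")
            if (depths <= 0).any():
                raise ValueError(f"{name} must be positive")
        unknown = set(self.n_regions) | set(self.true_lfc)
        unknown -= set(COUNT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown region categories: {sorted(unknown)}")

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{cond}_rep{r + 1}"
            for cond in ("wt", "kd")
            for r in range(self.n_replicates)
        ]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draw with mean ``mu`` and Var = mu + alpha mu^2.

    alpha = 0 reduces to Poisson.
    """
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts(
    spec: CountSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a categorized region-count dataset.

    Returns
    -------
    table : DataFrame
        One row per region with BED-style coordinates, ``category``,
        ``true_lfc`` and raw counts in one column per sample.
    sample_sheet : DataFrame
        Per-sample ``condition``, ``replicate``, ``spikein_total`` and
        ``h3_sample``.
    h3_counts : DataFrame
        H3 counts (region x sample) for the matched H3 libraries, used to
        derive H3 size factors.

    Region means are ``baseline_mean x depth_s x 2^(true_lfc)`` in the KD
    condition, with per-sample depth factors implied by the spike-in and
    H3 totals (relative to their geometric means). Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_names
    n_samples = len(samples)
    is_kd = np.array([s.startswith("kd") for s in samples])

    spike = np.asarray(spec.spikein_depths, float)
    h3 = np.asarray(spec.h3_depths, float)
    depth = (spike / np.exp(np.mean(np.log(spike)))) * (
        h3 / np.exp(np.mean(np.log(h3)))
    )

    rows = []
    counts = []
    pos = {}
    chroms = ("chr2L", "chr2R", "chr3L", "chr3R", "chrX")
    for ci, cat in enumerate(COUNT_CATEGORIES):
        n = int(spec.n_regions.get(cat, 0))
        lfc = float(spec.true_lfc.get(cat, 0.0))
        chrom = chroms[ci % len(chroms)]
        start = pos.get(chrom, 0)
        width = 500 if cat == "no_peak_bin" else 1000
        for i in range(n):
            rows.append(
                {
                    "chromosome": chrom,
                    "start": start,
                    "end": start + width,
                    "name": f"{cat}_{i + 1}",
                    "category": cat,
                    "true_lfc": lfc,
                }
            )
            start += width + 500
        pos[chrom] = start
        mu = spec.baseline_mean * depth[None, :] * np.where(is_kd, 2.0**lfc, 1.0)
        mu = np.broadcast_to(mu, (n, n_samples))
        counts.append(_nb_draw(rng, mu, spec.dispersion))
    table = pd.DataFrame(rows)
    count_mat = (
        np.vstack(counts) if counts else np.empty((0, n_samples), dtype=int)
    )
    table = pd.concat(
        [table, pd.DataFrame(count_mat.astype(int), columns=samples)], axis=1
    )

    sample_sheet = pd.DataFrame(
        {
            "sample": samples,
            "condition": np.where(is_kd, "kd", "wt"),
            "replicate": [int(s.split("rep")[1]) for s in samples],
            "spikein_total": spike,
            "h3_sample": [f"h3_{s}" for s in samples],
        }
    )

    # H3 libraries: per-region baselines shared across samples, scaled by
    # H3 depth; gamma-distributed baselines give a realistic dynamic range.
    n_h3_regions = max(1000, len(table))
    h3_base = rng.gamma(shape=4.0, scale=spec.h3_baseline_mean / 4.0, size=n_h3_regions)
    h3_rel = h3 / np.exp(np.mean(np.log(h3)))
    h3_mu = h3_base[:, None] * h3_rel[None, :]
    h3_counts = pd.DataFrame(
        _nb_draw(rng, h3_mu, spec.h3_dispersion),
        columns=[f"h3_{s}" for s in samples],
    )
    return table, sample_sheet, h3_counts
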