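"""End-to-end pipeline: simulate -> segment -> classify -> quantify, plus
the genomics track (simulate counts -> size factors -> differential ->
category summaries).

Every output table carries a provenance header (package version + config
hash) and the whole run is deterministic given the config seed: running
the same config twice produces byte-identical table bodies.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import phasequant
from phasequant import io as pio
from phasequant.config import RunConfig
from phasequant.cuttag import compute_size_factors, nb_differential, summarize_categories
from phasequant.fucci import PHASES, classify_pixels, derive_thresholds, phase_fractions
from phasequant.quantify import phase_normalized_means, place_rois, roi_ratio
from phasequant.segmentation import intersect_masks, make_nuclear_mask
from phasequant.synthetic import generate_counts, generate_disc

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("phasequant")


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"phasequant {phasequant.__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full synthetic pipeline described by ``config``.

    Returns a mapping from output name to file path. See the module
    docstring for the stage chain; intermediate images (channel stack,
    masks, phase label map) are also written for inspection.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    outputs: dict[str, Path] = {}

    # ---- imaging track -------------------------------------------------
    log.info("[simulate] generating synthetic disc (seed=%d)", config.disc.seed)
    disc = generate_disc(config.disc)
    outputs["channels"] = outdir / "disc_channels.tif"
    pio.write_channels(outputs["channels"], disc.channels)
    outputs["truth"] = outdir / "truth_nuclei.tsv"
    pio.write_table(outputs["truth"], disc.truth_nuclei, prov)

    log.info("[segment] workflow=%s", config.segmentation.workflow)
    seg = config.segmentation
    nuclear = make_nuclear_mask(
        [disc.channels["DAPI"]],
        workflow=seg.workflow,
        radius=seg.rolling_ball_radius,
        clahe_block=seg.clahe_block,
        clahe_bins=seg.clahe_bins,
        clahe_slope=seg.clahe_slope,
    )
    pouch_nuclear = intersect_masks(nuclear, disc.region_masks["pouch"])
    outputs["nuclear_mask"] = outdir / "nuclear_mask.tif"
    pio.write_mask(outputs["nuclear_mask"], nuclear.mask)
    outputs["pouch_nuclear_mask"] = outdir / "pouch_nuclear_mask.tif"
    pio.write_mask(outputs["pouch_nuclear_mask"], pouch_nuclear.mask)

    log.info("[classify] deriving thresholds from %d reference nuclei",
             config.classify.n_reference_nuclei)
    early_s = disc.truth_nuclei.query("phase == 2")["nucleus_id"].to_numpy()
    k = config.classify.n_reference_nuclei
    if len(early_s) < k:
        raise PipelineError("classify", f"need {k} early S nuclei, found {len(early_s)}")
    thresholds = derive_thresholds(
        disc.channels["GFP"],
        disc.channels["RFP"],
        disc.truth_labels,
        nucleus_ids=early_s[:k],
        method=config.classify.threshold_method,
    )
    labels = classify_pixels(
        disc.channels["GFP"], disc.channels["RFP"], thresholds, pouch_nuclear.mask
    )
    outputs["phase_labels"] = outdir / "phase_labels.tif"
    pio.write_label_map(outputs["phase_labels"], labels.labels)
    fractions = phase_fractions(labels)
    frac_table = pd.DataFrame(
        {
            "phase": [p.name for p in PHASES],
            "area_fraction": fractions,
            "n_pixels": [labels.pixel_counts()[p.name] for p in PHASES],
        }
    )
    outputs["phase_fractions"] = outdir / "phase_fractions.tsv"
    pio.write_table(outputs["phase_fractions"], frac_table, prov)

    log.info("[quantify] phase profiles and compartment ratios")
    q = config.quantify
    stat_rows = []
    for name in config.disc.markers:
        est = phase_normalized_means(
            disc.channels[name], labels, mode=q.normalization_mode
        )
        for p, v, r in zip(PHASES, est.normalized, est.raw):
            stat_rows.append(
                {
                    "marker": name,
                    "statistic": f"normalized_mean_{p.name}",
                    "value": v,
                    "raw_mean": r,
                }
            )
    profile_table = pd.DataFrame(stat_rows)
    outputs["phase_profiles"] = outdir / "phase_profiles.tsv"
    pio.write_table(outputs["phase_profiles"], profile_table, prov)

    ratio_rows = []
    pouch_rois = place_rois(
        disc.region_masks["pouch"], "pouch", config.disc.pixel_size,
        n=q.n_rois, size_um=q.roi_size_um, seed=config.seed,
    )
    hinge_rois = place_rois(
        disc.region_masks["hinge"], "hinge", config.disc.pixel_size,
        n=q.n_rois, size_um=q.roi_size_um, seed=config.seed + 1,
    )
    for name in config.disc.markers:
        ratio = roi_ratio(
            disc.channels[name], pouch_rois, hinge_rois, config.disc.pixel_size
        )
        ratio_rows.append(
            {"marker": name, "statistic": "pouch_hinge_ratio", "value": ratio}
        )
    outputs["roi_ratios"] = outdir / "roi_ratios.tsv"
    pio.write_table(outputs["roi_ratios"], pd.DataFrame(ratio_rows), prov)

    # ---- genomics track -------------------------------------------------
    log.info("[cuttag] simulating counts and testing (seed=%d)", config.counts.seed)
    table, sample_sheet, h3_counts = generate_counts(config.counts)
    factors = compute_size_factors(
        pd.Series(
            sample_sheet["spikein_total"].to_numpy(),
            index=sample_sheet["sample"],
        ),
        h3_counts,
        h3_of=dict(zip(sample_sheet["sample"], sample_sheet["h3_sample"])),
    )
    outputs["size_factors"] = outdir / "size_factors.tsv"
    pio.write_table(outputs["size_factors"], factors.as_frame(), prov)
    outputs["counts"] = outdir / "region_counts.tsv"
    pio.write_table(outputs["counts"], table, prov)
    outputs["sample_sheet"] = outdir / "sample_sheet.tsv"
    pio.write_table(outputs["sample_sheet"], sample_sheet, prov)

    result = nb_differential(
        table.drop(columns=["true_lfc"]),
        sample_sheet,
        factors,
        basemean_min=config.cuttag.basemean_min,
        alpha=config.cuttag.alpha,
    )
    outputs["differential"] = outdir / "differential.tsv"
    pio.write_table(outputs["differential"], result.table, prov)
    outputs["category_summary"] = outdir / "category_summary.tsv"
    pio.write_table(outputs["category_summary"], summarize_categories(result), prov)

    log.info("[done] %d outputs in %s", len(outputs), outdir)
    return outputs
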