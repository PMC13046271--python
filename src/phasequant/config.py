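"""Run configuration: validated stage parameters with published defaults.

Every default matches the parameter stated for the corresponding
analysis step: rolling-ball radius 100 px, CLAHE block 127 / 256 bins /
max slope 3, EdU blur sigma 2 px, 5 reference nuclei, 15 x 15 um ROIs
(3 per compartment), 500-bp genome bins, basemean cutoff 25 and
significance at adjusted p < 0.1. Unknown keys are rejected so typos
fail loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from phasequant.synthetic import (
    CountSimSpec,
    DiscSpec,
    FucciScheme,
    MarkerSpec,
    PhaseProfile,
)

__all__ = ["RunConfig", "SegmentationParams", "ClassifyParams", "QuantifyParams", "CuttagParams"]


@dataclass(frozen=True)
class SegmentationParams:
    workflow: str = "dapi_otsu"
    rolling_ball_radius: float = 100.0
    clahe_block: int = 127
    clahe_bins: int = 256
    clahe_slope: float = 3.0
    edu_sigma: float = 2.0


@dataclass(frozen=True)
class ClassifyParams:
    n_reference_nuclei: int = 5
    threshold_method: str = "nucleus_means"


@dataclass(frozen=True)
class QuantifyParams:
    roi_size_um: float = 15.0
    n_rois: int = 3
    normalization_mode: str = "mean_of_phases"
    area_fraction_denominator: str = "union"


@dataclass(frozen=True)
class CuttagParams:
    bin_size: int = 500
    basemean_min: float = 25.0
    alpha: float = 0.1


def _build(cls: type, data: Mapping[str, Any], context: str):
    """Instantiate a (frozen) dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def _build_disc(data: Mapping[str, Any]) -> DiscSpec:
    data = dict(data)
    if "fucci" in data and isinstance(data["fucci"], Mapping):
        data["fucci"] = _build(FucciScheme, data["fucci"], "disc.fucci")
    if "markers" in data and isinstance(data["markers"], Mapping):
        markers = {}
        for name, m in data["markers"].items():
            m = dict(m)
            if "profile" in m and isinstance(m["profile"], Mapping):
                m["profile"] = _build(
                    PhaseProfile, m["profile"], f"disc.markers.{name}.profile"
                )
            markers[name] = _build(MarkerSpec, m, f"disc.markers.{name}")
        data["markers"] = markers
    for key in ("image_shape", "phase_proportions", "spikein_depths"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    for key in ("pouch_polygon", "hinge_polygon"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(tuple(v) for v in data[key])
    return _build(DiscSpec, data, "disc")


def _build_counts(data: Mapping[str, Any]) -> CountSimSpec:
    data = dict(data)
    for key in ("spikein_depths", "h3_depths"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return _build(CountSimSpec, data, "counts")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Sections mirror the pipeline stages; the single top-level ``seed``
    overrides the generator seeds so one value drives the whole run.
    """

    seed: int = 0
    outdir: str = "phasequant_out"
    log_level: str = "INFO"
    disc: DiscSpec = field(default_factory=DiscSpec)
    counts: CountSimSpec = field(default_factory=CountSimSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    quantify: QuantifyParams = field(default_factory=QuantifyParams)
    cuttag: CuttagParams = field(default_factory=CuttagParams)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown key(s) in config: {sorted(unknown)}")
        if "disc" in data and isinstance(data["disc"], Mapping):
            data["disc"] = _build_disc(data["disc"])
        if "counts" in data and isinstance(data["counts"], Mapping):
            data["counts"] = _build_counts(data["counts"])
        for key, sub in (
            ("segmentation", SegmentationParams),
            ("classify", ClassifyParams),
            ("quantify", QuantifyParams),
            ("cuttag", CuttagParams),
        ):
            if key in data and isinstance(data[key], Mapping):
                data[key] = _build(sub, data[key], key)
        cfg = cls(**data)
        # one seed drives both generators
        object.__setattr__(
            cfg, "disc", dataclasses.replace(cfg.disc, seed=cfg.seed)
        )
        object.__setattr__(
            cfg, "counts", dataclasses.replace(cfg.counts, seed=cfg.seed + 1)
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the scientific configuration, for provenance headers.

        Output location and logging verbosity do not change results and
        are excluded, so runs of the same parameters hash identically.
        """
        skip = {"outdir", "log_level"}

        def encode(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                    if f.name not in skip
                }
            if isinstance(obj, Mapping):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, np.floating):  # pragma: no cover - defensive
                return float(obj)
            return obj

        payload = json.dumps(encode(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
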