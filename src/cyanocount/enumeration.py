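"""Unit-cell-area calibration and cell enumeration.

The workflow has two phases.  Phase 1 calibrates the mean projected area
of one isolated cell per species from micrographs of sonicated,
filtered suspensions in which only well-separated single cells remain.
Phase 2 enumerates mixed samples: round unicellular classes are counted
directly as the number of foreground objects, whereas filamentous classes
— whose connected components span many cells — are enumerated by dividing
the total class area by the calibrated unit-cell area.  Counts per imaged
field are finally converted to cells/ml through the counting-chamber
geometry (grid area × chamber depth) and the sample dilution factor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classification import ClassLabel, RuleThresholds, classify_rule_all
from .errors import CalibrationError, ContractError, LowSampleWarning
from .io import MonoImage, RunConfig
from .morphology import ComponentFeatures, featurize
from .segmentation import LabelField, segment

logger = logging.getLogger(__name__)


@dataclass
class CalibrationModel:
    """Calibrated projected area of a single cell of one species."""

    species: ClassLabel
    unit_cell_area_um2: float
    unit_cell_area_sd_um2: float
    n_cells: int

    def __post_init__(self) -> None:
        if not self.unit_cell_area_um2 > 0:
            raise ContractError("unit cell area must be positive")
        if self.unit_cell_area_sd_um2 < 0:
            raise ContractError("unit cell area SD must be >= 0")
        if self.n_cells < 1:
            raise ContractError("n_cells must be >= 1")
        if self.n_cells < 10:
            warnings.warn(
                f"calibration for {self.species.value} based on only "
                f"{self.n_cells} cells (>= 10 recommended)",
                LowSampleWarning, stacklevel=2,
            )

    def unit_area_px(self, um_per_pixel: float) -> float:
        return self.unit_cell_area_um2 / um_per_pixel**2


@dataclass
class ClassResult:
    """Per-class enumeration outcome for one batch of images."""

    object_count: int = 0
    total_area_um2: float = 0.0
    estimated_cells: float = 0.0
    cells_per_ml: float = 0.0
    sd: float = 0.0


@dataclass
class EnumerationReport:
    """Counts, areas, estimated cell numbers and concentrations per class."""

    per_class: dict[str, ClassResult]
    image_ids: list[str]
    chamber_volume_ul: float
    proportions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                cls: {
                    "object_count": r.object_count,
                    "total_area_um2": r.total_area_um2,
                    "estimated_cells": r.estimated_cells,
                    "cells_per_ml": r.cells_per_ml,
                    "sd": r.sd,
                }
                for cls, r in self.per_class.items()
            },
            "image_ids": list(self.image_ids),
            "chamber_volume_ul": self.chamber_volume_ul,
            "proportions": dict(self.proportions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnumerationReport":
        return cls(
            per_class={k: ClassResult(**v) for k, v in d["per_class"].items()},
            image_ids=list(d["image_ids"]),
            chamber_volume_ul=d["chamber_volume_ul"],
            proportions=dict(d.get("proportions", {})),
        )


def calibrate_unit_area(
    single_cell_images: list[MonoImage],
    species: ClassLabel,
    config: RunConfig,
) -> CalibrationModel:
    """Phase-1 calibration: mean ± SD projected single-cell area (µm²).

    Each image is segmented with the learned threshold rule; retained
    components are those passing the minimum-area filter and — when the
    config carries rule thresholds — classified as the target species.
    Without thresholds every retained component is treated as one isolated
    cell of the target species (the pure-culture calibration setting).
    """
    areas: list[float] = []
    for image in single_cell_images:
        _, lf = segment(
            image, connectivity=config.connectivity,
            min_area_px=config.min_component_area_px,
        )
        feats = featurize(lf, config.um_per_pixel)
        if config.rule_thresholds is not None:
            labels = classify_rule_all(feats, config.rule_thresholds)
            kept = [f for f, l in zip(feats, labels) if l is species]
            dropped = len(feats) - len(kept)
            if dropped:
                logger.debug("calibration: excluded %d non-%s components "
                             "in %s", dropped, species.value, image.source_id)
        else:
            kept = feats
        areas.extend(f.area_um2 for f in kept)
    if not areas:
        raise CalibrationError(
            f"no components retained for species {species.value}"
        )
    arr = np.asarray(areas)
    return CalibrationModel(
        species=species,
        unit_cell_area_um2=float(arr.mean()),
        unit_cell_area_sd_um2=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n_cells=int(arr.size),
    )


def enumerate_unicellular(
    label_field: LabelField,
    labels: list[ClassLabel],
    target: ClassLabel = ClassLabel.MICROCYSTIS,
) -> int:
    """Count foreground objects classified as the (unicellular) target."""
    if label_field.n_components is not None and (
        len(labels) != label_field.n_components
    ):
        raise ContractError("one class label required per component")
    return sum(1 for l in labels if l is target)


def enumerate_filamentous(
    features: list[ComponentFeatures],
    labels: list[ClassLabel],
    target: ClassLabel = ClassLabel.ANABAENA,
    calibration: CalibrationModel | None = None,
) -> tuple[float, float]:
    """Estimate cells in a filamentous class by total area division.

    Returns ``(estimated_cells, sd)`` where estimated cells = Σ component
    area (µm²) / calibrated unit-cell area, and the SD propagates the
    unit-area uncertainty by the delta method:
    sd = estimate × (σ_unit / unit area).
    """
    if calibration is None:
        raise ContractError("filamentous enumeration requires a calibration")
    total = sum(
        f.area_um2 for f, l in zip(features, labels, strict=True) if l is target
    )
    estimate = total / calibration.unit_cell_area_um2
    sd = estimate * (
        calibration.unit_cell_area_sd_um2 / calibration.unit_cell_area_um2
    ) / math.sqrt(calibration.n_cells)
    return float(estimate), float(sd)


def to_concentration(
    estimated_cells: float, n_images: int, config: RunConfig
) -> float:
    """Convert a batch cell estimate to cells/ml.

    cells/ml = (cells per imaged field) / (field volume in ml) × dilution,
    with the field volume given by the chamber grid area × depth.
    """
    if n_images < 1:
        raise ContractError("n_images must be >= 1")
    volume_ml = config.chamber_volume_ml
    if not volume_ml > 0:
        raise ContractError("imaged chamber volume must be positive")
    return (estimated_cells / n_images) / volume_ml * config.dilution_factor


def mixture_proportions(report: EnumerationReport) -> dict[str, float]:
    """Normalise per-class estimated cells to fractions summing to 1.

    The "neither" class is excluded.  If every counted class is zero the
    proportions are undefined: NaN is returned for each class, with a
    warning.
    """
    counted = {
        cls: r.estimated_cells
        for cls, r in report.per_class.items()
        if cls != ClassLabel.NONE.value
    }
    if not counted:
        raise ContractError("report contains no counted classes")
    total = sum(counted.values())
    if total == 0:
        warnings.warn("all class counts are zero; proportions undefined",
                      LowSampleWarning, stacklevel=2)
        return {cls: float("nan") for cls in counted}
    return {cls: v / total for cls, v in counted.items()}
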