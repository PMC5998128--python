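"""End-to-end enumeration pipeline and run manifests.

Chains segmentation → morphology → classification → enumeration over a
batch of micrographs, with two classification modes:

* ``two-species`` — the threshold rule cascade (filamentous vs round
  unicellular vs neither);
* ``three-species`` — a fitted quadratic-kernel SVM over all seven
  morphological features.

The threshold θ is learned independently per image by default (each
acquisition gets its own decision boundary); ``global_theta=True`` learns
θ once, on the first image, and applies it to the whole batch — useful
for homogeneous dilution series where sparse images may contain no
foreground to learn from.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classification import (
    ClassLabel, RuleThresholds, SvmModel, classify_rule_all,
)
from .enumeration import (
    CalibrationModel, ClassResult, EnumerationReport, enumerate_filamentous,
    mixture_proportions, to_concentration,
)
from .errors import ContractError
from .io import (
    MonoImage, RunConfig, config_to_dict, read_image, write_features_csv,
    write_image, write_report,
)
from .morphology import featurize
from .segmentation import learn_threshold, segment

logger = logging.getLogger(__name__)

#: classes enumerated by direct object counting.
UNICELLULAR = (ClassLabel.MICROCYSTIS, ClassLabel.ANKISTRODESMUS)
#: classes enumerated by total-area division.
FILAMENTOUS = (ClassLabel.ANABAENA,)


@dataclass
class RunManifest:
    """Reproducibility record: config, inputs, software version, seeds."""

    config: dict
    inputs: list[dict]
    version: str
    seed: int
    mode: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    images: list[MonoImage | str | Path],
    config: RunConfig,
    mode: str = "two-species",
    calibrations: dict[str, CalibrationModel] | None = None,
    svm_model: SvmModel | None = None,
    out_dir: str | Path | None = None,
    global_theta: bool = False,
) -> tuple[EnumerationReport, RunManifest]:
    """Segment, featurize, classify and enumerate a batch of micrographs.

    Unicellular classes are enumerated by object counting; the
    filamentous class by total area over the calibrated unit-cell area
    (its :class:`CalibrationModel` must then be present in
    ``calibrations``).  Returns the enumeration report and a run manifest;
    when ``out_dir`` is given, per-image masks, label rasters, feature
    tables and the report itself are written there.
    """
    if not images:
        raise ContractError("no inputs")
    if mode not in ("two-species", "three-species"):
        raise ContractError(f"unknown mode {mode!r}")
    if mode == "three-species" and svm_model is None:
        raise ContractError("three-species mode requires a fitted SVM model")
    calibrations = calibrations or {}
    thresholds = config.rule_thresholds
    if thresholds is None:
        if calibrations:
            umpp2 = config.um_per_pixel**2
            cal_m = calibrations.get(ClassLabel.MICROCYSTIS.value)
            cal_a = calibrations.get(ClassLabel.ANABAENA.value)
            if cal_m and cal_a:
                thresholds = RuleThresholds.from_unit_areas(
                    cal_m.unit_cell_area_um2 / umpp2,
                    cal_a.unit_cell_area_um2 / umpp2,
                )
        if thresholds is None:
            thresholds = RuleThresholds()

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    manifest_inputs = []
    loaded: list[MonoImage] = []
    for item in images:
        if isinstance(item, MonoImage):
            loaded.append(item)
            manifest_inputs.append({"id": item.source_id, "sha256": None})
        else:
            p = Path(item)
            loaded.append(read_image(p, config))
            manifest_inputs.append({"id": p.name, "sha256": _sha256(p)})

    decision = None
    if global_theta:
        decision = learn_threshold(loaded[0])
        logger.info("global theta=%s learned from %s",
                    decision.theta, loaded[0].source_id)

    class_values = [c.value for c in (*FILAMENTOUS, *UNICELLULAR)] + [
        ClassLabel.NONE.value
    ]
    per_image: dict[str, list[float]] = {c: [] for c in class_values}
    counts = {c: 0 for c in class_values}
    areas = {c: 0.0 for c in class_values}

    for idx, image in enumerate(loaded):
        dec, lf = segment(
            image, connectivity=config.connectivity,
            min_area_px=config.min_component_area_px,
            decision=decision,
        )
        feats = featurize(lf, image.um_per_pixel)
        if mode == "two-species":
            labels = classify_rule_all(feats, thresholds)
        else:
            if feats:
                X = np.vstack([f.as_vector() for f in feats])
                labels = [ClassLabel(v) for v in svm_model.predict(X)]
            else:
                labels = []
        logger.info(
            "image %s: theta=%s, %d components, counts=%s",
            image.source_id, dec.theta, len(feats),
            {c: sum(1 for l in labels if l.value == c) for c in class_values},
        )
        img_est = {c: 0.0 for c in class_values}
        for f, l in zip(feats, labels):
            counts[l.value] += 1
            areas[l.value] += f.area_um2
        for cls in class_values:
            lab = ClassLabel(cls)
            if lab in FILAMENTOUS and cls in calibrations:
                est, _ = enumerate_filamentous(
                    feats, labels, lab, calibrations[cls]
                )
                img_est[cls] = est
            else:
                img_est[cls] = float(
                    sum(1 for l in labels if l is lab)
                )
            per_image[cls].append(img_est[cls])
        if out_path is not None:
            stem = f"img{idx:03d}"
            write_image(
                MonoImage((lf.mask * (2**image.bit_depth - 1)).astype(
                    image.pixels.dtype), image.bit_depth,
                    image.um_per_pixel, f"{stem}:mask"),
                out_path / f"{stem}_mask.tif",
            )
            import tifffile

            tifffile.imwrite(out_path / f"{stem}_labels.tif", lf.labels)
            write_features_csv(feats, out_path / f"{stem}_features.csv",
                               labels=labels)

    n_images = len(loaded)
    per_class: dict[str, ClassResult] = {}
    for cls in class_values:
        lab = ClassLabel(cls)
        if lab in FILAMENTOUS:
            if cls in calibrations:
                estimated = float(np.sum(per_image[cls]))
            elif counts[cls] > 0 and mode == "two-species":
                raise ContractError(
                    f"filamentous class {cls!r} present but no calibration "
                    "supplied"
                )
            else:
                estimated = float(np.sum(per_image[cls]))
        else:
            estimated = float(np.sum(per_image[cls]))
        sd = (
            float(np.std(per_image[cls], ddof=1)) if n_images > 1 else 0.0
        )
        per_class[cls] = ClassResult(
            object_count=counts[cls],
            total_area_um2=areas[cls],
            estimated_cells=estimated,
            cells_per_ml=(
                to_concentration(estimated, n_images, config)
                if cls != ClassLabel.NONE.value else 0.0
            ),
            sd=sd,
        )

    report = EnumerationReport(
        per_class=per_class,
        image_ids=[im.source_id for im in loaded],
        chamber_volume_ul=config.chamber_volume_ml * 1000.0,
    )
    report.proportions = mixture_proportions(report)
    manifest = RunManifest(
        config=config_to_dict(config),
        inputs=manifest_inputs,
        version=__version__,
        seed=config.rng_seed,
        mode=mode,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    if out_path is not None:
        write_report(report, out_path / "report.json", "json")
        write_report(report, out_path / "report.csv", "csv")
        (out_path / "manifest.json").write_text(manifest.to_json())
    return report, manifest
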