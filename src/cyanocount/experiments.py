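"""Self-contained validation experiments on synthetic scenes.

Each function builds its own ground-truthed inputs with the synthetic
generator, runs the pipeline end to end, and returns the measured
quantities.  They mirror the classical validation designs for automated
enumeration methods — dilution-series linearity, mixed-culture proportion
recovery, unit-area calibration recovery and classifier benchmarks — and
are shared by the test suite and the reproduction script.

Field sizes are chosen so that cells occupy roughly 0.5–5 % of the pixels,
matching an adequately populated counting-chamber field: the threshold
learner maximises between-class variance, and below ~0.1 % foreground
coverage that objective degenerates to splitting the background noise
mode (a well-known failure of Otsu-style thresholding on near-empty
images; see the methods notes).  Dilute frames in the dilution series are
therefore thresholded with a global θ learned on the densest frame.
Problem sizes keep every experiment within seconds to a couple of
minutes on one core.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classification import (
    ClassLabel, RuleThresholds, classify_rule_all, cross_validate,
)
from .enumeration import (
    calibrate_unit_area, enumerate_filamentous, enumerate_unicellular,
)
from .io import RunConfig
from .morphology import featurize
from .segmentation import segment
from .synthdata import (
    FilamentSpec, GroundTruth, SceneSpec, generate_dilution_series,
    generate_feature_table, generate_scene,
)

DEFAULT_UM_PER_PIXEL = 0.645


def default_config(**overrides) -> RunConfig:
    return RunConfig(um_per_pixel=DEFAULT_UM_PER_PIXEL, **overrides)


def _segment_and_classify(image, config, thresholds=None):
    _, lf = segment(image, connectivity=config.connectivity,
                    min_area_px=config.min_component_area_px)
    feats = featurize(lf, config.um_per_pixel)
    labels = classify_rule_all(feats, thresholds or RuleThresholds())
    return lf, feats, labels


def single_cell_spec(species: str, n_cells: int, seed: int) -> SceneSpec:
    """Scene of isolated single cells of one morphotype (the sonicated,
    size-filtered calibration condition), on a small, well-populated
    field."""
    spec = SceneSpec(counts={species: n_cells}, image_size=(300, 400),
                     seed=seed)
    if species == "A":
        spec = dataclasses.replace(
            spec,
            filament=FilamentSpec(cells_per_filament=(1.0, 0.0), min_cells=1),
        )
    return spec


def calibrate_species(
    species: str, seed: int, n_images: int = 5, cells_per_image: int = 10,
    config: RunConfig | None = None,
):
    """Phase-1 calibration on synthetic single-cell images."""
    config = config or default_config()
    images = [
        generate_scene(single_cell_spec(species, cells_per_image,
                                        seed * 1000 + i))[0]
        for i in range(n_images)
    ]
    return calibrate_unit_area(images, ClassLabel(species), config)


# ---------------------------------------------------------------------------
# count recovery (unicellular exact; filamentous by area division)
# ---------------------------------------------------------------------------

def disc_count_recovery(n_discs: int, seed: int) -> tuple[int, int]:
    """Returns (recovered count, true count) for a disc-only scene."""
    config = default_config()
    image, truth = generate_scene(
        SceneSpec(counts={"M": n_discs}, image_size=(480, 640), seed=seed)
    )
    lf, feats, labels = _segment_and_classify(image, config)
    recovered = enumerate_unicellular(lf, labels, ClassLabel.MICROCYSTIS)
    return recovered, truth.count("M")


def filament_count_recovery(
    n_filaments: int, cells_per_filament: int, seed: int
) -> tuple[float, int]:
    """Returns (area-based cell estimate, true cell count) for a
    filament-only scene with a fixed number of cells per filament."""
    config = default_config()
    calibration = calibrate_species("A", seed=seed + 7, config=config)
    spec = SceneSpec(
        counts={"A": n_filaments},
        image_size=(480, 640),
        filament=FilamentSpec(
            cells_per_filament=(float(cells_per_filament), 0.0)
        ),
        seed=seed,
    )
    image, truth = generate_scene(spec)
    _, feats, labels = _segment_and_classify(image, config)
    estimate, _ = enumerate_filamentous(
        feats, labels, ClassLabel.ANABAENA, calibration
    )
    return estimate, truth.count("A")


# ---------------------------------------------------------------------------
# dilution-series linearity
# ---------------------------------------------------------------------------

@dataclass
class DilutionResult:
    slope: float
    intercept: float
    r_squared: float
    true_counts: list[int]
    estimated_counts: list[float]


def dilution_linearity(
    seed: int,
    factors: tuple[float, ...] = (1.0, 2.0, 10.0, 100.0, 500.0),
    base_count: int = 150,
    n_images: int = 5,
) -> DilutionResult:
    """Serial-dilution experiment: regress recovered vs true counts.

    A single θ is learned on the densest image and applied globally, so
    that near-empty high-dilution frames (which contain nothing to learn
    a boundary from) are thresholded consistently.
    """
    from .segmentation import binarize, connected_components, learn_threshold

    config = default_config()
    base = SceneSpec(counts={"M": base_count}, image_size=(600, 800),
                     seed=seed)
    levels = generate_dilution_series(base, list(factors), n_images, seed)
    decision = learn_threshold(levels[0][0][0])
    true_counts, est_counts = [], []
    for level in levels:
        for image, truth in level:
            lf = connected_components(
                binarize(image, decision).mask,
                config.connectivity, config.min_component_area_px,
            )
            feats = featurize(lf, config.um_per_pixel)
            labels = classify_rule_all(feats, RuleThresholds())
            est_counts.append(
                float(enumerate_unicellular(lf, labels,
                                            ClassLabel.MICROCYSTIS))
            )
            true_counts.append(truth.count("M"))
    fit = stats.linregress(true_counts, est_counts)
    return DilutionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        true_counts=true_counts, estimated_counts=est_counts,
    )


# ---------------------------------------------------------------------------
# mixed-culture proportion recovery
# ---------------------------------------------------------------------------

@dataclass
class MixtureResult:
    true_fractions: list[float]
    recovered_fractions: list[float]

    @property
    def max_abs_error(self) -> float:
        return max(
            abs(t - r)
            for t, r in zip(self.true_fractions, self.recovered_fractions)
        )


def mixture_proportion_recovery(
    seed: int,
    fractions: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0),
    total_cells: int = 240,
    n_images: int = 2,
    cells_per_filament: float = 8.0,
) -> MixtureResult:
    """Two-species mixtures at several volumetric proportions.

    For each target fraction p of filamentous cells, scenes carry
    ``p*total`` cells as filaments and the rest as unicells; the recovered
    fraction is the area-based filament estimate over the total estimate.
    True fractions are taken from the rendered ground truth.
    """
    config = default_config()
    calibration = calibrate_species("A", seed=seed + 101, config=config)
    true_fr, rec_fr = [], []
    for fi, p in enumerate(fractions):
        n_fil = int(round(p * total_cells / cells_per_filament))
        n_disc = int(round((1 - p) * total_cells))
        est_a = est_m = 0.0
        true_a = true_m = 0
        for ii in range(n_images):
            spec = SceneSpec(
                counts={"A": n_fil, "M": n_disc},
                image_size=(600, 800),
                filament=FilamentSpec(
                    cells_per_filament=(cells_per_filament, 1.0)
                ),
                seed=seed + 13 * fi + 977 * ii,
            )
            image, truth = generate_scene(spec)
            lf, feats, labels = _segment_and_classify(image, config)
            ea, _ = enumerate_filamentous(
                feats, labels, ClassLabel.ANABAENA, calibration
            )
            est_a += ea
            est_m += enumerate_unicellular(lf, labels,
                                           ClassLabel.MICROCYSTIS)
            true_a += truth.count("A")
            true_m += truth.count("M")
        true_fr.append(true_a / max(true_a + true_m, 1))
        rec_fr.append(est_a / max(est_a + est_m, 1e-12))
    return MixtureResult(true_fractions=true_fr, recovered_fractions=rec_fr)


# ---------------------------------------------------------------------------
# rule-classifier separation and SVM benchmarks
# ---------------------------------------------------------------------------

def rule_separation_errors(seed: int, n_each: int = 40) -> int:
    """Cross-class errors of the rule cascade on a disc + filament scene."""
    config = default_config()
    spec = SceneSpec(counts={"M": n_each, "A": n_each},
                     image_size=(600, 800), seed=seed)
    image, truth = generate_scene(spec)
    _, lf = segment(image, connectivity=config.connectivity,
                    min_area_px=config.min_component_area_px)
    feats = featurize(lf, config.um_per_pixel)
    labels = classify_rule_all(feats, RuleThresholds())
    # match each component to its ground-truth class by majority label
    errors = 0
    for f, pred in zip(feats, labels):
        r, c = (int(round(x)) for x in f.centroid)
        gt_label = truth.labels[r, c]
        if gt_label == 0:
            continue
        true_cls = truth.per_object[gt_label - 1].cls
        if true_cls == "M" and pred is ClassLabel.ANABAENA:
            errors += 1
        elif true_cls == "A" and pred is ClassLabel.MICROCYSTIS:
            errors += 1
    return errors


def svm_benchmark_accuracy(seed: int, n_per_class: int = 272) -> float:
    """Five-fold CV accuracy of the quadratic-kernel SVM on the Gaussian
    feature benchmark (272 cells per species by default)."""
    table = generate_feature_table(n_per_class=n_per_class, seed=seed)
    X = table.drop(columns="label").to_numpy()
    y = table["label"].to_numpy()
    return cross_validate(X, y, k=5, seed=seed).accuracy


def permutation_null_accuracy(seed: int, n_per_class: int = 100) -> float:
    """CV accuracy after randomly permuting labels (chance level ≈ 1/3)."""
    table = generate_feature_table(n_per_class=n_per_class, seed=seed)
    X = table.drop(columns="label").to_numpy()
    rng = np.random.default_rng(seed)
    y = rng.permutation(table["label"].to_numpy())
    return cross_validate(X, y, k=5, seed=seed).accuracy


# ---------------------------------------------------------------------------
# unit-area calibration recovery
# ---------------------------------------------------------------------------

@dataclass
class CalibrationRecovery:
    recovered_mean_um2: float
    target_mean_um2: float
    target_sd_um2: float
    n_cells: int

    @property
    def standard_error(self) -> float:
        return self.target_sd_um2 / np.sqrt(self.n_cells)


def calibration_recovery(
    seed: int,
    mean_um2: float = 24.6,
    sd_um2: float = 3.4,
    n_cells: int = 100,
    cells_per_image: int = 10,
) -> CalibrationRecovery:
    """Recover the mean projected single-cell area from synthetic discs
    whose areas are drawn from N(mean, sd²) µm²."""
    config = default_config()
    n_images = n_cells // cells_per_image
    images = []
    for i in range(n_images):
        spec = SceneSpec(
            counts={"M": cells_per_image},
            image_size=(300, 400),
            disc_area_um2=(mean_um2, sd_um2),
            seed=seed * 977 + i,
        )
        images.append(generate_scene(spec)[0])
    model = calibrate_unit_area(images, ClassLabel.MICROCYSTIS, config)
    return CalibrationRecovery(
        recovered_mean_um2=model.unit_cell_area_um2,
        target_mean_um2=mean_um2, target_sd_um2=sd_um2,
        n_cells=model.n_cells,
    )
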