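"""Ground-truthed synthetic fluorescence micrographs and feature tables.

Real acquisitions of autofluorescing cyanobacteria show bright cells on a
dark, noisy background.  The generator emulates the three morphotypes the
pipeline must tell apart:

* ``M`` — *Microcystis*-like round unicells, rendered as discs whose
  projected areas are drawn from a normal distribution (default
  24.6 ± 3.4 µm², a typical single-cell value for this species);
* ``A`` — *Anabaena*-like filaments, rendered as chains of abutting
  ellipses (one ellipse per cell, default unit-cell area ≈ 26.8 µm²) with
  optional curvature, so the true cell count per filament is explicit;
* ``K`` — *Ankistrodesmus*-like needle/spindle cells, single thin
  elongated ellipses.

Optional non-cell fluorescent debris (irregular polygons) and a linear
illumination gradient emulate an untreated surface-water matrix.  Every
rendered object is recorded in a :class:`GroundTruth` with its pixel
label, class, area and true cell count; debris never enters class totals.

The intensity model is per-pixel Gaussian (cell and background each with
mean/SD), clipped to the bit depth — enough to stress the threshold
learner without simulating fluorescence optics.  Identical seeds yield
bit-identical images.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError, GenerationError
from .io import MonoImage

#: Per-class feature means/SDs (area, ε, c, convex area, solidity, extent,
#: perimeter) used as defaults for the Gaussian feature-table generator.
#: They reflect representative per-cell measurements of the three species
#: (areas/perimeters in pixel units of the reference optics).
DEFAULT_FEATURE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "M": {
        "area": (11.41, 5.05), "eccentricity": (0.59, 0.22),
        "compactness": (1.82, 0.34), "convex_area": (11.63, 5.32),
        "solidity": (0.99, 0.03), "extent": (0.81, 0.11),
        "perimeter": (8.94, 2.65),
    },
    "A": {
        "area": (150.04, 157.53), "eccentricity": (0.90, 0.14),
        "compactness": (0.61, 0.51), "convex_area": (342.84, 711.74),
        "solidity": (0.70, 0.22), "extent": (0.43, 0.23),
        "perimeter": (75.12, 69.45),
    },
    "K": {
        "area": (47.46, 31.84), "eccentricity": (0.98, 0.03),
        "compactness": (0.44, 0.30), "convex_area": (63.29, 58.24),
        "solidity": (0.81, 0.10), "extent": (0.30, 0.18),
        "perimeter": (40.93, 20.75),
    },
}

FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "area": (1e-9, np.inf), "eccentricity": (0.0, 1.0),
    "compactness": (1e-9, np.inf), "convex_area": (1e-9, np.inf),
    "solidity": (0.0, 1.0), "extent": (1e-9, 1.0),
    "perimeter": (1e-9, np.inf),
}


@dataclass
class FilamentSpec:
    """Geometry of filament rendering (chains of abutting elliptical cells)."""

    cells_per_filament: tuple[float, float] = (8.0, 3.0)
    #: a filament is multicellular by definition; sampled chains shorter
    #: than this are lengthened to it.  Set to 1 to render isolated
    #: single cells (the sonicated/filtered calibration condition).
    min_cells: int = 2
    cell_length_um: float = 6.5
    cell_width_um: float = 5.25
    #: SD of the per-cell heading change, radians (global curvature).
    curvature: float = 0.12
    #: centre spacing as a fraction of cell length; < 1 keeps the chain
    #: 8-connected after rasterization.
    spacing: float = 0.97
    #: multiplicative SD of per-filament cell-area jitter.
    area_jitter: float = 0.09


@dataclass
class SpindleSpec:
    length_um: tuple[float, float] = (30.0, 8.0)
    width_um: float = 2.5


@dataclass
class IntensitySpec:
    """Per-pixel Gaussian intensity model on the 8-bit scale; scaled up
    for deeper bit depths."""

    cell: tuple[float, float] = (180.0, 12.0)
    background: tuple[float, float] = (30.0, 6.0)


@dataclass
class DebrisSpec:
    count: int = 0
    size_um: tuple[float, float] = (3.0, 12.0)
    intensity: tuple[float, float] = (90.0, 25.0)


@dataclass
class SceneSpec:
    """Full specification of one synthetic micrograph."""

    image_size: tuple[int, int] = (1200, 1600)
    um_per_pixel: float = 0.645
    counts: dict[str, int] = field(default_factory=dict)
    disc_area_um2: tuple[float, float] = (24.6, 3.4)
    filament: FilamentSpec = field(default_factory=FilamentSpec)
    spindle: SpindleSpec = field(default_factory=SpindleSpec)
    intensity: IntensitySpec = field(default_factory=IntensitySpec)
    debris: DebrisSpec = field(default_factory=DebrisSpec)
    bit_depth: int = 8
    illumination_gradient: float = 0.0
    max_overlap_fraction: float = 0.0
    #: minimum separation (px) between distinct objects, so that
    #: neighbours never merge under 8-connectivity.
    margin_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) < 8:
            raise ContractError("image_size too small")
        if not self.um_per_pixel > 0:
            raise ContractError("um_per_pixel must be positive")
        for cls, n in self.counts.items():
            if cls not in ("M", "A", "K"):
                raise ContractError(f"unknown class {cls!r} in counts")
            if n < 0:
                raise ContractError("counts must be >= 0")
        if not 0 <= self.max_overlap_fraction < 1:
            raise ContractError("max_overlap_fraction must be in [0, 1)")


@dataclass
class ObjectTruth:
    label: int
    cls: str  # "M", "A", "K" or "debris"
    area_px: int
    area_um2: float
    cell_count: int


@dataclass
class GroundTruth:
    """Per-pixel labels and per-object records of a rendered scene."""

    labels: np.ndarray
    per_object: list[ObjectTruth]
    totals: dict[str, int]
    overlap_px: int = 0

    def count(self, cls: str) -> int:
        return self.totals.get(cls, 0)


def _ellipse_coords(r0, c0, a, b, phi, shape):
    """Integer pixel coordinates inside an ellipse.

    Semi-axes ``a`` (along heading ``phi``) and ``b`` across it; returns
    None if the ellipse leaves the image.
    """
    ext = max(a, b) + 1.5
    rmin, rmax = int(math.floor(r0 - ext)), int(math.ceil(r0 + ext))
    cmin, cmax = int(math.floor(c0 - ext)), int(math.ceil(c0 + ext))
    if rmin < 0 or cmin < 0 or rmax >= shape[0] or cmax >= shape[1]:
        return None
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    y = rr - r0
    x = cc - c0
    u = x * math.cos(phi) + y * math.sin(phi)
    v = -x * math.sin(phi) + y * math.cos(phi)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _disc_coords(r0, c0, radius, shape):
    return _ellipse_coords(r0, c0, radius, radius, 0.0, shape)


def _polygon_coords(rng, r0, c0, radius, shape):
    """Irregular star-convex polygon (debris)."""
    k = int(rng.integers(5, 10))
    angles = np.sort(rng.uniform(0, 2 * np.pi, k))
    radii = radius * rng.uniform(0.4, 1.0, k)
    rows = r0 + radii * np.sin(angles)
    cols = c0 + radii * np.cos(angles)
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= shape[0] or cols.max() >= shape[1]):
        return None
    from skimage.draw import polygon

    rr, cc = polygon(rows, cols, shape=shape)
    if rr.size == 0:
        return None
    return rr, cc


def _filament_coords(rng, spec: SceneSpec, shape):
    """One filament: chain of abutting elliptical cells.

    Returns (rows, cols, n_cells) or None if the sampled chain leaves the
    image bounds.
    """
    f = spec.filament
    n_cells = max(f.min_cells, int(round(rng.normal(*f.cells_per_filament))))
    scale = math.sqrt(max(rng.normal(1.0, f.area_jitter), 0.25))
    a = (f.cell_length_um / spec.um_per_pixel) * scale / 2.0
    b = (f.cell_width_um / spec.um_per_pixel) * scale / 2.0
    step = 2.0 * a * f.spacing
    r = rng.uniform(0, shape[0])
    c = rng.uniform(0, shape[1])
    phi = rng.uniform(0, 2 * np.pi)
    pieces = []
    for _ in range(n_cells):
        coords = _ellipse_coords(r, c, a, b, phi, shape)
        if coords is None:
            return None
        pieces.append(coords)
        phi += rng.normal(0.0, f.curvature)
        r += step * math.sin(phi)
        c += step * math.cos(phi)
    rows = np.concatenate([p[0] for p in pieces])
    cols = np.concatenate([p[1] for p in pieces])
    flat = np.unique(rows.astype(np.int64) * shape[1] + cols.astype(np.int64))
    return flat // shape[1], flat % shape[1], n_cells


_MAX_TRIES = 300


def generate_scene(
    spec: SceneSpec, seed: int | None = None
) -> tuple[MonoImage, GroundTruth]:
    """Render one micrograph with full per-object ground truth.

    Objects are placed by rejection sampling; a candidate is accepted when
    it lies fully inside the frame and keeps ``margin_px`` clearance from
    everything already placed (or overlaps at most ``max_overlap_fraction``
    of its own pixels).  A spec too dense to satisfy raises
    :class:`GenerationError` naming the failing class.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = spec.image_size
    occupied = np.zeros(shape, dtype=bool)
    blocked = np.zeros(shape, dtype=bool)
    gt_labels = np.zeros(shape, dtype=np.int32)
    per_object: list[ObjectTruth] = []
    overlap_px = 0
    umpp2 = spec.um_per_pixel**2

    struct = None
    if spec.margin_px > 0:
        n = 2 * spec.margin_px + 1
        yy, xx = np.mgrid[-spec.margin_px:spec.margin_px + 1,
                          -spec.margin_px:spec.margin_px + 1]
        struct = (yy**2 + xx**2) <= spec.margin_px**2

    def sample(cls: str):
        if cls == "A":
            return _filament_coords(rng, spec, shape)
        if cls == "M":
            area = max(rng.normal(*spec.disc_area_um2), 4 * umpp2)
            radius = math.sqrt(area / math.pi) / spec.um_per_pixel
            r = rng.uniform(0, shape[0])
            c = rng.uniform(0, shape[1])
            coords = _disc_coords(r, c, radius, shape)
            return None if coords is None else (*coords, 1)
        if cls == "K":
            length = max(rng.normal(*spec.spindle.length_um), 2.0)
            a = length / spec.um_per_pixel / 2.0
            b = max(spec.spindle.width_um / spec.um_per_pixel / 2.0, 0.6)
            r = rng.uniform(0, shape[0])
            c = rng.uniform(0, shape[1])
            phi = rng.uniform(0, 2 * np.pi)
            coords = _ellipse_coords(r, c, a, b, phi, shape)
            return None if coords is None else (*coords, 1)
        # debris
        radius = rng.uniform(*spec.debris.size_um) / spec.um_per_pixel
        r = rng.uniform(0, shape[0])
        c = rng.uniform(0, shape[1])
        coords = _polygon_coords(rng, r, c, radius, shape)
        return None if coords is None else (*coords, 0)

    def place(cls: str, label: int) -> ObjectTruth:
        nonlocal overlap_px
        for _ in range(_MAX_TRIES):
            cand = sample(cls)
            if cand is None:
                continue
            rows, cols, n_cells = cand
            if rows.size == 0:
                continue
            if spec.max_overlap_fraction > 0:
                n_over = int(occupied[rows, cols].sum())
                if n_over > spec.max_overlap_fraction * rows.size:
                    continue
            else:
                if blocked[rows, cols].any():
                    continue
                n_over = 0
            overlap_px += n_over
            occupied[rows, cols] = True
            gt_labels[rows, cols] = label
            # dilate the new object's footprint into the blocked mask
            if struct is not None:
                m = spec.margin_px
                r0 = max(rows.min() - m, 0)
                r1 = min(rows.max() + m + 1, shape[0])
                c0 = max(cols.min() - m, 0)
                c1 = min(cols.max() + m + 1, shape[1])
                local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
                local[rows - r0, cols - c0] = True
                blocked[r0:r1, c0:c1] |= ndimage.binary_dilation(
                    local, structure=struct
                )
            else:
                blocked[rows, cols] = True
            return ObjectTruth(
                label=label, cls=cls, area_px=int(rows.size),
                area_um2=float(rows.size * umpp2), cell_count=int(n_cells),
            )
        raise GenerationError(
            f"could not place a {cls!r} object after {_MAX_TRIES} attempts "
            "(scene too dense)"
        )

    label = 0
    # big, wandering shapes first: improves packing and keeps determinism
    for cls in ("A", "K", "M"):
        for _ in range(spec.counts.get(cls, 0)):
            label += 1
            per_object.append(place(cls, label))
    for _ in range(spec.debris.count):
        label += 1
        per_object.append(place("debris", label))

    # ---- render intensities -------------------------------------------
    depth_scale = (2**spec.bit_depth - 1) / 255.0
    img = rng.normal(
        spec.intensity.background[0], spec.intensity.background[1], shape
    )
    for obj in per_object:
        rows, cols = np.nonzero(gt_labels == obj.label)
        mean, sd = (
            spec.debris.intensity if obj.cls == "debris" else spec.intensity.cell
        )
        img[rows, cols] = rng.normal(mean, sd, rows.size)
    if spec.illumination_gradient:
        ramp = 1.0 + spec.illumination_gradient * (
            np.linspace(0, 1, shape[1]) - 0.5
        )
        img = img * ramp[None, :]
    img = np.clip(np.rint(img * depth_scale), 0, 2**spec.bit_depth - 1)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    image = MonoImage(
        pixels=img.astype(dtype), bit_depth=spec.bit_depth,
        um_per_pixel=spec.um_per_pixel,
        source_id=f"synthetic:seed={spec.seed if seed is None else seed}",
    )
    totals: dict[str, int] = {}
    for obj in per_object:
        if obj.cls != "debris":
            totals[obj.cls] = totals.get(obj.cls, 0) + obj.cell_count
    truth = GroundTruth(
        labels=gt_labels, per_object=per_object, totals=totals,
        overlap_px=overlap_px,
    )
    return image, truth


def generate_feature_table(
    class_stats: dict[str, dict[str, tuple[float, float]]] | None = None,
    n_per_class: int = 272,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled 7-feature table of independent truncated-Gaussian draws.

    Each feature is drawn from N(mean, SD²) and resampled into its valid
    range (e.g. eccentricity into [0, 1]).  Defaults reproduce the layout
    of a 272-cells-per-species benchmark (816 rows over three classes).
    """
    stats = DEFAULT_FEATURE_STATS if class_stats is None else class_stats
    rng = np.random.default_rng(seed)
    frames = []
    for cls in sorted(stats):
        cols: dict[str, np.ndarray] = {}
        for feat, (mean, sd) in stats[cls].items():
            if feat not in FEATURE_BOUNDS:
                raise ContractError(f"unknown feature {feat!r}")
            if sd < 0:
                raise ContractError("feature SD must be >= 0")
            lo, hi = FEATURE_BOUNDS[feat]
            v = rng.normal(mean, sd, n_per_class)
            bad = (v < lo) | (v > hi)
            while bad.any():
                v[bad] = rng.normal(mean, sd, int(bad.sum()))
                bad = (v < lo) | (v > hi)
            cols[feat] = v
        df = pd.DataFrame(cols)
        df["label"] = cls
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _child_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def generate_dilution_series(
    base_spec: SceneSpec,
    factors: list[float],
    n_images: int = 1,
    seed: int = 0,
) -> list[list[tuple[MonoImage, GroundTruth]]]:
    """Serial-dilution scenes: per level, object counts are Poisson draws
    with expectation ``base count / factor``; one list of (image, truth)
    pairs per dilution level, with per-image seeds derived from ``seed``.
    """
    if any(f <= 0 for f in factors):
        raise ContractError("dilution factors must be positive")
    levels = []
    for li, factor in enumerate(factors):
        images = []
        for ii in range(n_images):
            child = _child_seed(seed, li, ii)
            rng = np.random.default_rng(child)
            counts = {
                cls: int(rng.poisson(n / factor))
                for cls, n in base_spec.counts.items()
            }
            spec = dataclasses.replace(base_spec, counts=counts, seed=child)
            images.append(generate_scene(spec))
        levels.append(images)
    return levels
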