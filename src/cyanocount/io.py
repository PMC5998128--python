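"""Image and artifact I/O plus run configuration.

The pipeline operates on single-channel ("mono") fluorescence micrographs in
which autofluorescing cells appear bright against a dark background.  This
module normalises TIFF/PNG input into :class:`MonoImage`, the canonical
in-memory raster, and reads/writes the tabular artifacts the pipeline emits
(feature tables, enumeration reports, flat key=value run configuration).

Intensities are never rescaled on input: an 8-bit image keeps its native
0–255 levels and a 12-bit acquisition stored in a 16-bit container keeps its
0–4095 levels, with the container/bit-depth ambiguity resolved by max-value
inspection unless the caller overrides it explicitly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Any, Mapping

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ContractError, FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .classification import RuleThresholds

# ITU-R BT.601 luminance weights used for the RGB->mono convenience path.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_SUPPORTED_BIT_DEPTHS = (8, 12, 16)


@dataclass
class MonoImage:
    """Single-channel intensity raster with calibration metadata.

    Parameters
    ----------
    pixels:
        2-D integer array of non-negative intensities.
    bit_depth:
        Native bit depth of the acquisition (8, 12 or 16); all intensities
        must lie in ``[0, 2**bit_depth - 1]``.
    um_per_pixel:
        Spatial calibration in micrometres per pixel (> 0).
    source_id:
        Free-text identifier of the acquisition (file name, scene seed, ...).
    """

    pixels: np.ndarray
    bit_depth: int
    um_per_pixel: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ContractError("MonoImage requires a 2-D raster")
        if min(self.pixels.shape) < 2:
            raise ContractError("MonoImage raster dimensions must be >= 2")
        if self.bit_depth not in _SUPPORTED_BIT_DEPTHS:
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.max_level
        ):
            raise ContractError(
                f"intensities outside [0, {self.max_level}] for "
                f"bit depth {self.bit_depth}"
            )
        if not self.um_per_pixel > 0:
            raise ContractError("um_per_pixel must be positive")

    @property
    def max_level(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RunConfig:
    """Run-level configuration: optics calibration, chamber geometry and
    pipeline parameters.

    ``chamber_depth_um`` defaults to 100 µm and ``grid_area_um2`` to 1 mm²,
    the geometry of a standard hemocytometer counting grid, so that one
    imaged field corresponds to 0.1 µL of sample.
    """

    um_per_pixel: float
    chamber_depth_um: float = 100.0
    grid_area_um2: float = 1.0e6
    dilution_factor: float = 1.0
    rule_thresholds: "RuleThresholds | None" = None
    min_component_area_px: int = 4
    connectivity: int = 8
    rng_seed: int = 0
    bit_depth_override: int | None = None

    def __post_init__(self) -> None:
        if not self.um_per_pixel > 0:
            raise ContractError("um_per_pixel must be positive")
        if not self.chamber_depth_um * self.grid_area_um2 > 0:
            raise ContractError("implied chamber volume must be positive")
        if self.dilution_factor < 1:
            raise ContractError("dilution_factor must be >= 1")
        if self.connectivity not in (4, 8):
            raise ContractError("connectivity must be 4 or 8")
        if self.min_component_area_px < 0:
            raise ContractError("min_component_area_px must be >= 0")

    @property
    def chamber_volume_ml(self) -> float:
        """Imaged volume per field in millilitres (1 ml = 1e12 µm³)."""
        return self.grid_area_um2 * self.chamber_depth_um * 1e-12


_CONFIG_SCALAR_FIELDS = {
    "um_per_pixel": float,
    "chamber_depth_um": float,
    "grid_area_um2": float,
    "dilution_factor": float,
    "min_component_area_px": int,
    "connectivity": int,
    "rng_seed": int,
    "bit_depth_override": int,
}
_CONFIG_THRESHOLD_FIELDS = {
    "omega": float,
    "tau": float,
    "psi_al": float,
    "psi_au": float,
    "psi_ml": float,
    "psi_mu": float,
}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` text file into a :class:`RunConfig`.

    Lines starting with ``#`` are comments.  Rule-threshold keys
    (``omega``, ``tau``, ``psi_al`` ...) may be given alongside the scalar
    fields; unknown keys are rejected.
    """
    from .classification import RuleThresholds

    scalars: dict[str, Any] = {}
    thresh: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"malformed config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in _CONFIG_SCALAR_FIELDS:
            scalars[key] = _CONFIG_SCALAR_FIELDS[key](value)
        elif key in _CONFIG_THRESHOLD_FIELDS:
            thresh[key] = _CONFIG_THRESHOLD_FIELDS[key](value)
        else:
            raise FormatError(f"unknown config key: {key!r}")
    if "um_per_pixel" not in scalars:
        raise FormatError("config must set um_per_pixel")
    cfg = RunConfig(**scalars)
    if thresh:
        cfg.rule_thresholds = RuleThresholds(**thresh)
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    lines = []
    for key in _CONFIG_SCALAR_FIELDS:
        value = getattr(config, key)
        if value is not None:
            lines.append(f"{key} = {value}")
    if config.rule_thresholds is not None:
        for key in _CONFIG_THRESHOLD_FIELDS:
            lines.append(f"{key} = {getattr(config.rule_thresholds, key)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _infer_bit_depth(arr: np.ndarray, override: int | None) -> int:
    if override is not None:
        if override not in _SUPPORTED_BIT_DEPTHS:
            raise FormatError(f"unsupported bit depth override {override}")
        return override
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        # 12-bit cameras commonly ship data in 16-bit containers; detect by
        # max-value inspection, overridable through the config.
        return 12 if arr.max(initial=0) <= 4095 else 16
    raise FormatError(f"unsupported pixel dtype {arr.dtype}")


def rgb_to_mono(arr: np.ndarray, max_level: int) -> np.ndarray:
    """Collapse an (H, W, 3) array to mono via BT.601 luminance weights."""
    mono = np.tensordot(arr.astype(np.float64), _LUMA_WEIGHTS, axes=([-1], [0]))
    return np.clip(np.rint(mono), 0, max_level).astype(arr.dtype)


def read_image(
    path: str | Path,
    config: RunConfig | None = None,
    *,
    um_per_pixel: float | None = None,
    bit_depth: int | None = None,
) -> MonoImage:
    """Read a TIFF or PNG micrograph into the canonical mono representation.

    Mono inputs pass through untouched (no rescaling); 3-channel inputs are
    reduced by the luminance rule.  Calibration is taken from ``um_per_pixel``
    or, failing that, from ``config``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = np.asarray(Image.open(path))
        else:
            raise FormatError(f"unsupported image format: {suffix}")
    except FormatError:
        raise
    except Exception as exc:  # unreadable/corrupt file
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[-1] != 3:
        raise FormatError(f"expected 1 or 3 channels, got shape {arr.shape}")
    if arr.ndim not in (2, 3):
        raise FormatError(f"expected 2-D image, got shape {arr.shape}")

    override = bit_depth
    if override is None and config is not None:
        override = config.bit_depth_override
    depth = _infer_bit_depth(arr, override)
    if arr.ndim == 3:
        arr = rgb_to_mono(arr, 2**depth - 1)

    if um_per_pixel is None:
        if config is None:
            raise ContractError(
                "um_per_pixel must be supplied directly or through config"
            )
        um_per_pixel = config.um_per_pixel
    return MonoImage(
        pixels=arr, bit_depth=depth, um_per_pixel=um_per_pixel,
        source_id=path.name,
    )


def write_image(image: MonoImage, path: str | Path) -> None:
    """Write a MonoImage as PNG (8-bit) or TIFF (any depth), lossless."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    if path.suffix.lower() == ".png":
        Image.fromarray(arr).save(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported output format: {path.suffix}")


FEATURE_COLUMNS = [
    "area_px", "eccentricity", "compactness", "convex_area_px",
    "solidity", "extent", "perimeter_px",
]


def write_features_csv(features, path: str | Path, labels=None) -> None:
    """Write one CSV row per component: id, class, 7 features, centroid."""
    rows = []
    for i, f in enumerate(features):
        row = {"label": f.label, "class": labels[i].value if labels else ""}
        for col in FEATURE_COLUMNS:
            row[col] = getattr(f, col)
        row["area_um2"] = f.area_um2
        row["centroid_row"], row["centroid_col"] = f.centroid
        rows.append(row)
    cols = ["label", "class", *FEATURE_COLUMNS, "area_um2",
            "centroid_row", "centroid_col"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialise an :class:`~cyanocount.enumeration.EnumerationReport`.

    The JSON form round-trips every numeric field at full precision via
    :func:`read_report`; the CSV form is one row per class.
    """
    path = Path(path)
    payload = report.to_dict()
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    elif format == "csv":
        rows = []
        for cls, res in payload["per_class"].items():
            rows.append({"class": cls, **res,
                         "proportion": payload["proportions"].get(cls)})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported report format: {format}")


def read_report(path: str | Path):
    """Read back a JSON enumeration report written by :func:`write_report`."""
    from .enumeration import EnumerationReport

    return EnumerationReport.from_dict(json.loads(Path(path).read_text()))


def config_to_dict(config: RunConfig) -> dict:
    """JSON-serialisable snapshot of a RunConfig (for run manifests)."""
    d = dataclasses.asdict(config)
    if config.rule_thresholds is not None:
        d["rule_thresholds"] = dataclasses.asdict(config.rule_thresholds)
    return d
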