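"""Morphological descriptors of connected components.

Seven shape features drive cell recognition: area, perimeter, eccentricity,
compactness, convex area, solidity and extent.  Their definitions:

* eccentricity ε — of the ellipse with the same second central moments as
  the region: distance between foci divided by major-axis length.  0 for a
  circle, → 1 for a line segment.
* compactness c = 4πA/P².  Exactly 1 for an ideal circle, lower for
  irregular shapes.  Discretized perimeter estimates can push c above 1
  for small round objects; values > 1 are reported as-is with a warning
  rather than clipped, preserving their ranking information.
* convex area — area of the smallest convex polygon containing the region,
  computed on pixel-corner points (each pixel a unit square) so that the
  hull area is never smaller than the pixel count and solidity stays ≤ 1.
* solidity = A / convex area;  extent = A / bounding-box area.
* perimeter — boundary contour length with diagonal steps weighted √2
  (a raw border-pixel count would systematically inflate c).

Filamentous cells (e.g. *Anabaena*) score high ε and low c; round unicells
(e.g. *Microcystis*) score low ε and high c, which is what the downstream
rule classifier exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import CompactnessWarning, ContractError

__all__ = [
    "ComponentFeatures", "eccentricity", "compactness", "convex_area",
    "solidity", "extent", "perimeter", "featurize",
]


@dataclass
class ComponentFeatures:
    """The seven morphological descriptors of one connected component."""

    label: int
    area_px: int
    perimeter_px: float
    eccentricity: float
    compactness: float
    convex_area_px: float
    solidity: float
    extent: float
    centroid: tuple[float, float]
    area_um2: float

    def as_vector(self) -> np.ndarray:
        """Feature vector in canonical column order (area, ε, c, convex
        area, solidity, extent, perimeter)."""
        return np.array([
            self.area_px, self.eccentricity, self.compactness,
            self.convex_area_px, self.solidity, self.extent,
            self.perimeter_px,
        ], dtype=float)


def _as_mask(component: np.ndarray) -> np.ndarray:
    """Accept a boolean mask or an (N, 2) pixel-coordinate array."""
    component = np.asarray(component)
    if component.ndim == 2 and component.dtype != bool and component.shape[1] == 2:
        coords = component.astype(int)
        if coords.size == 0:
            raise ContractError("empty component")
        rmin, cmin = coords.min(axis=0)
        mask = np.zeros(
            (coords[:, 0].max() - rmin + 1, coords[:, 1].max() - cmin + 1),
            dtype=bool,
        )
        mask[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
        return mask
    mask = component.astype(bool)
    if not mask.any():
        raise ContractError("empty component")
    return mask


def _single_region(mask: np.ndarray):
    regions = measure.regionprops(mask.astype(np.uint8))
    return regions[0]


def eccentricity(component: np.ndarray) -> float:
    """Eccentricity of the moment-fitted ellipse, in [0, 1].

    A single-pixel component is defined to have ε = 0 (a degenerate
    "circle"); such components are normally removed upstream by the
    minimum-area filter.
    """
    mask = _as_mask(component)
    if mask.sum() == 1:
        return 0.0
    return float(_single_region(mask).eccentricity)


def compactness(area: float, perimeter: float) -> float:
    """c = 4πA/P² (unclipped; warns when the discretized value exceeds 1)."""
    if not perimeter > 0:
        raise ContractError("perimeter must be positive")
    if not area > 0:
        raise ContractError("area must be positive")
    c = 4.0 * np.pi * area / perimeter**2
    if c > 1.0:
        # static message so repeated warnings collapse under "once" filters
        warnings.warn(
            "compactness exceeds the theoretical bound of 1 "
            "(perimeter discretization)", CompactnessWarning, stacklevel=2,
        )
    return float(c)


def _corner_hull_area(coords: np.ndarray) -> float:
    """Convex-hull area of the pixel-corner point set of a region.

    Treating every pixel (r, c) as the unit square [r, r+1) × [c, c+1)
    guarantees hull area ≥ pixel count, so solidity never exceeds 1.
    """
    from scipy.spatial import ConvexHull

    coords = np.asarray(coords)
    corners = np.concatenate([
        coords + np.array([dr, dc])
        for dr in (0, 1) for dc in (0, 1)
    ])
    return float(ConvexHull(corners).volume)


def convex_area(component: np.ndarray) -> float:
    """Area (px²) of the smallest convex polygon containing the region."""
    mask = _as_mask(component)
    if mask.sum() == 1:
        return 1.0
    return _corner_hull_area(np.argwhere(mask))


def solidity(area: float, convex_area_px: float) -> float:
    """Region area divided by convex-hull area."""
    if not convex_area_px > 0:
        raise ContractError("convex area must be positive")
    return float(area / convex_area_px)


def extent(area: float, bbox_area: float) -> float:
    """Region area divided by bounding-box area."""
    if not bbox_area > 0:
        raise ContractError("bounding-box area must be positive")
    return float(area / bbox_area)


def perimeter(component: np.ndarray) -> float:
    """Boundary contour length in pixels (diagonal steps weighted √2).

    A single-pixel component is assigned perimeter 1 by convention to keep
    compactness finite (capped at 4π, with a warning downstream).
    """
    mask = _as_mask(component)
    if mask.sum() == 1:
        return 1.0
    p = float(_single_region(mask).perimeter)
    return p if p > 0 else 1.0


def featurize(label_field, um_per_pixel: float) -> list[ComponentFeatures]:
    """Compute all seven descriptors for every component of a label field.

    Returns one record per component, ordered by label id.  ``area_um2``
    applies the spatial calibration (area_px × um_per_pixel²).
    """
    if label_field.labels is None:
        raise ContractError("label field has no component labels")
    if not um_per_pixel > 0:
        raise ContractError("um_per_pixel must be positive")
    out: list[ComponentFeatures] = []
    with warnings.catch_warnings():
        # compactness > 1 is common for small round cells; warn once per call
        warnings.simplefilter("once", CompactnessWarning)
        for region in measure.regionprops(label_field.labels):
            a = int(region.area)
            if a == 1:
                p, ecc, ca = 1.0, 0.0, 1.0
            else:
                p = float(region.perimeter) or 1.0
                ecc = float(region.eccentricity)
                ca = _corner_hull_area(region.coords)
            out.append(ComponentFeatures(
                label=int(region.label),
                area_px=a,
                perimeter_px=p,
                eccentricity=ecc,
                compactness=compactness(a, p),
                convex_area_px=ca,
                solidity=solidity(a, ca),
                extent=float(region.extent),
                centroid=tuple(float(x) for x in region.centroid),
                area_um2=a * um_per_pixel**2,
            ))
    return out
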