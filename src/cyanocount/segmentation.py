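"""Foreground/background pixel classification and connected components.

A pixel is assigned to the foreground class when its intensity reaches a
decision boundary θ learned by maximising the between-class variance of the
intensity histogram (Otsu's criterion).  The learned rule is

    L1(x) = C_f  if  f(x) >= θ,   C_b otherwise,

which makes no distributional assumption about either class — the key
property that lets one threshold rule cope with both dim and bright
fluorescence acquisitions.  Foreground pixels are then grouped into
connected components (default 8-connectivity) with an area filter that
suppresses shot-noise specks.

The threshold search runs over the native gray levels for 8-bit data and
over 256 equal-width bins for 12/16-bit data, with θ mapped back to the
native intensity scale; ties in the objective are broken toward the lowest
threshold so the learner is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import ContractError, DegenerateImageError
from .io import MonoImage

logger = logging.getLogger(__name__)


@dataclass
class BinaryDecision:
    """Learned pixel-classification boundary.

    ``theta`` is on the image's native intensity scale; a pixel is
    foreground iff its intensity is >= theta.  ``between_class_variance``
    is the maximised Otsu objective (on the binned histogram scale).
    """

    theta: float
    between_class_variance: float
    bit_depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.theta <= 2**self.bit_depth - 1:
            raise ContractError("theta outside intensity range")
        if self.between_class_variance < 0:
            raise ContractError("between-class variance must be >= 0")


@dataclass
class LabelField:
    """Binary foreground mask plus (optionally) component labels.

    ``labels`` is 0 on background and ``1..n_components`` on retained
    foreground components, assigned in raster-scan order of each
    component's first pixel.  ``n_filtered_px`` counts foreground pixels
    discarded by the minimum-area filter, so that
    ``(labels > 0).sum() + n_filtered_px == mask.sum()``.
    """

    mask: np.ndarray
    labels: np.ndarray | None = None
    n_components: int | None = None
    n_filtered_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ContractError("mask must be 2-D")


def _histogram(image: MonoImage, training_region=None) -> tuple[np.ndarray, int]:
    """256-bin histogram of the training region; returns (counts, shift).

    ``shift`` is the power-of-two bin width exponent: a pixel p falls in
    bin ``p >> shift``, so a bin-scale threshold t maps back to native
    intensity ``t << shift``.
    """
    px = image.pixels
    if training_region is not None:
        r0, c0, r1, c1 = training_region
        if not (0 <= r0 < r1 <= px.shape[0] and 0 <= c0 < c1 <= px.shape[1]):
            raise ContractError(f"training_region {training_region} out of bounds")
        px = px[r0:r1, c0:c1]
    shift = max(image.bit_depth - 8, 0)
    binned = px.astype(np.int64) >> shift
    counts = np.bincount(binned.ravel(), minlength=256)[:256]
    return counts, shift


def otsu_objective(hist: np.ndarray) -> np.ndarray:
    """Between-class variance for every candidate threshold t = 1..n-1.

    Entry ``t`` of the returned array scores the split {bins < t} vs
    {bins >= t}; entry 0 (no split) is -inf, as are one-sided splits.
    """
    hist = np.asarray(hist, dtype=np.float64)
    levels = np.arange(hist.size, dtype=np.float64)
    total = hist.sum()
    w_b = np.cumsum(hist)            # weight of background class for t = level+1
    s_b = np.cumsum(hist * levels)
    sigma = np.full(hist.size, -np.inf)
    for t in range(1, hist.size):
        wb, wf = w_b[t - 1], total - w_b[t - 1]
        if wb == 0 or wf == 0:
            continue
        mb = s_b[t - 1] / wb
        mf = (s_b[-1] - s_b[t - 1]) / wf
        sigma[t] = wb * wf * (mb - mf) ** 2
    return sigma


def learn_threshold(
    image: MonoImage, training_region: tuple[int, int, int, int] | None = None
) -> BinaryDecision:
    """Learn θ by maximising the between-class variance of the histogram.

    ``training_region`` is an optional ``(r0, c0, r1, c1)`` rectangle
    (half-open); by default the whole image is the training set.  Ties are
    broken toward the lowest threshold.

    Raises
    ------
    DegenerateImageError
        If the training region is constant-valued (no split exists).
    """
    hist, shift = _histogram(image, training_region)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError(
            "training region is constant-valued; no foreground/background "
            "split exists"
        )
    sigma = otsu_objective(hist)
    t = int(np.argmax(sigma))  # first (=lowest) argmax on ties
    theta = float(t << shift)
    logger.debug("learned theta=%s (bin %d, sigma_b=%.6g)", theta, t, sigma[t])
    return BinaryDecision(
        theta=theta, between_class_variance=float(sigma[t]),
        bit_depth=image.bit_depth,
    )


def binarize(image: MonoImage, decision: BinaryDecision) -> LabelField:
    """Apply the learned rule: foreground iff intensity >= θ."""
    if decision.bit_depth != image.bit_depth:
        raise ContractError(
            f"decision learned at bit depth {decision.bit_depth}, "
            f"image is {image.bit_depth}-bit"
        )
    return LabelField(mask=image.pixels >= decision.theta)


def connected_components(
    mask: np.ndarray | LabelField,
    connectivity: int = 8,
    min_area_px: int = 4,
) -> LabelField:
    """Label maximal connected foreground regions.

    Regions smaller than ``min_area_px`` are removed (and their pixel count
    logged in ``n_filtered_px``).  Surviving labels are renumbered
    ``1..n`` in raster-scan order of each region's first pixel, making the
    labelling deterministic.
    """
    if isinstance(mask, LabelField):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ContractError("connectivity must be 4 or 8")
    raw = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    areas = np.bincount(raw.ravel())
    small = np.flatnonzero(areas < min_area_px)
    small = small[small != 0]
    n_filtered_px = int(areas[small].sum())
    if small.size:
        keep_mask = np.ones(areas.size, dtype=bool)
        keep_mask[small] = False
        raw = np.where(keep_mask[raw], raw, 0)
        logger.debug("filtered %d components (<%d px, %d px total)",
                     small.size, min_area_px, n_filtered_px)

    flat = raw.ravel()
    present, first_idx = np.unique(flat, return_index=True)
    order = present[np.argsort(first_idx)]
    order = order[order != 0]
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[order] = np.arange(1, order.size + 1)
    labels = remap[raw]
    return LabelField(
        mask=mask, labels=labels, n_components=int(order.size),
        n_filtered_px=n_filtered_px,
    )


def segment(
    image: MonoImage,
    connectivity: int = 8,
    min_area_px: int = 4,
    training_region=None,
    decision: BinaryDecision | None = None,
) -> tuple[BinaryDecision, LabelField]:
    """Convenience chain: learn θ (unless given), binarize, label."""
    if decision is None:
        decision = learn_threshold(image, training_region)
    field_ = binarize(image, decision)
    lf = connected_components(field_.mask, connectivity, min_area_px)
    return decision, lf
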