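"""Choriocapillaris flow-void segmentation and morphometry.

A flow void is a region of the choriocapillaris slab whose decorrelation
signal falls below the detection floor — nonperfusion or flow below the
detectable minimum. Voids are segmented with the 1-standard-deviation
strategy: the threshold is the mean minus one (population) SD of the
intensities over the analyzed region, i.e. the image minus the large-vessel
and FAZ exclusions. Void density is expressed relative to the analyzed area;
a single void is one connected component of the binarized void mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .dataio import EnfaceAngiogram
from .errors import EmptyRegionError, UsageError, ValidationError
from .masking import BinaryMask

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class FlowVoidResult:
    """Density, count and average size of flow voids over the analyzed area.

    The identity ``density_pct * analyzed_area_um2 / 100 ==
    count * mean_size_um2`` is asserted at construction (float tolerance).
    """

    density_pct: float
    count: int
    mean_size_um2: float
    total_void_area_um2: float
    analyzed_area_um2: float
    threshold_used: float
    connectivity: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.density_pct <= 100.0):
            raise ValidationError("density_pct must lie in [0, 100]")
        if self.count < 0:
            raise ValidationError("count must be non-negative")
        if (self.count == 0) != (self.total_void_area_um2 == 0.0):
            raise ValidationError("count == 0 iff total void area == 0")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        lhs = self.density_pct * self.analyzed_area_um2 / 100.0
        rhs = self.count * self.mean_size_um2
        if not math.isclose(lhs, rhs, rel_tol=1e-9, abs_tol=1e-6):
            raise ValidationError(
                f"self-consistency identity violated: {lhs} != {rhs}")


def flow_void_threshold(cc: EnfaceAngiogram,
                        exclusion: Optional[BinaryMask] = None) -> float:
    """Mean minus one population SD of intensities over analyzed pixels.

    Statistics are computed on the non-excluded region only: the excluded
    bright large-vessel shadows would otherwise bias the mean upward.
    """
    if cc.slab != "CC":
        raise UsageError(f"flow_void_threshold expects a CC angiogram, got {cc.slab}")
    analyzed = _analyzed(cc.pixels.shape, exclusion)
    vals = cc.pixels[analyzed]
    if vals.size == 0:
        raise EmptyRegionError("exclusion mask covers the entire image")
    return float(vals.mean() - vals.std(ddof=0))


def segment_flow_voids(cc: EnfaceAngiogram, exclusion: Optional[BinaryMask],
                       threshold: float) -> BinaryMask:
    """Void pixel := intensity strictly below threshold AND not excluded.

    The strict inequality means a constant image (SD = 0, threshold = the
    constant) yields zero voids.
    """
    if not (0.0 <= threshold <= 1.0):
        raise UsageError(f"threshold {threshold} outside the [0, 1] intensity range")
    analyzed = _analyzed(cc.pixels.shape, exclusion)
    return BinaryMask((cc.pixels < threshold) & analyzed, "void")


def quantify_flow_voids(void_mask: BinaryMask,
                        exclusion: Optional[BinaryMask],
                        lateral_scale_um: float,
                        connectivity: int = 8,
                        min_void_px: int = 0) -> FlowVoidResult:
    """Connected-component morphometry of the void mask.

    density_pct = 100 * void px / analyzed px; count = number of connected
    components (4- or 8-connectivity); mean size = total void area / count
    (0 when there are no voids). ``min_void_px`` optionally drops components
    below a pixel size (off by default).
    """
    if lateral_scale_um <= 0:
        raise UsageError("lateral_scale_um must be positive")
    if connectivity not in _STRUCTURES:
        raise UsageError("connectivity must be 4 or 8")
    analyzed = _analyzed(void_mask.shape, exclusion)
    if exclusion is not None and exclusion.shape != void_mask.shape:
        raise UsageError("void mask and exclusion mask shapes differ")
    analyzed_px = int(analyzed.sum())
    if analyzed_px == 0:
        raise EmptyRegionError("no analyzed pixels")

    voids = void_mask.pixels & analyzed
    labels, count = ndimage.label(voids, structure=_STRUCTURES[connectivity])
    if count and min_void_px > 0:
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= min_void_px) + 1
        voids = np.isin(labels, keep)
        labels, count = ndimage.label(voids, structure=_STRUCTURES[connectivity])

    px_area = lateral_scale_um ** 2
    void_px = int(voids.sum())
    total_um2 = void_px * px_area
    analyzed_um2 = analyzed_px * px_area
    density = 100.0 * void_px / analyzed_px
    mean_size = total_um2 / count if count else 0.0
    return FlowVoidResult(
        density_pct=density, count=int(count), mean_size_um2=mean_size,
        total_void_area_um2=total_um2, analyzed_area_um2=analyzed_um2,
        threshold_used=float("nan"), connectivity=connectivity)


def analyze_cc(cc: EnfaceAngiogram, exclusion: Optional[BinaryMask] = None,
               connectivity: int = 8, min_void_px: int = 0):
    """Threshold, segment and quantify in one call.

    Returns ``(FlowVoidResult, void_mask)`` with ``threshold_used`` recorded.
    """
    thr = flow_void_threshold(cc, exclusion)
    thr_clipped = min(max(thr, 0.0), 1.0)
    voids = segment_flow_voids(cc, exclusion, thr_clipped)
    result = quantify_flow_voids(voids, exclusion, cc.lateral_scale_um,
                                 connectivity=connectivity, min_void_px=min_void_px)
    result.threshold_used = thr_clipped
    return result, voids


def void_size_map(void_mask: BinaryMask, connectivity: int = 8) -> np.ndarray:
    """Color-code voids by size tertile (small/medium/large) for display.

    Returns an (H, W, 3) uint8 RGB image: small voids green, medium blue,
    large red, background black.
    """
    labels, count = ndimage.label(void_mask.pixels,
                                  structure=_STRUCTURES[connectivity])
    rgb = np.zeros((*void_mask.shape, 3), dtype=np.uint8)
    if count == 0:
        return rgb
    sizes = np.bincount(labels.ravel())[1:]
    lo, hi = np.quantile(sizes, [1 / 3, 2 / 3])
    tier = np.digitize(sizes, [lo, hi], right=True)  # 0 small, 1 medium, 2 large
    colors = np.array([[0, 200, 0], [0, 90, 255], [255, 40, 40]], dtype=np.uint8)
    component_color = colors[tier]
    fg = labels > 0
    rgb[fg] = component_color[labels[fg] - 1]
    return rgb


def _analyzed(shape: tuple, exclusion: Optional[BinaryMask]) -> np.ndarray:
    if exclusion is None:
        return np.ones(shape, dtype=bool)
    if exclusion.shape != shape:
        raise UsageError(f"exclusion shape {exclusion.shape} != image shape {shape}")
    return ~exclusion.pixels
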