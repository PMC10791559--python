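"""Pixel contents and degrees of subcellular enrichment.

Definitions (single analysis plane, background-subtracted):

* pixel content of a region: ``(mean intensity over region - background) *
  region area (µm²)`` — an expression surrogate.
* % pixel content of a sub-region: ``100 * PC(region) / PC(cell)``.
* degree of enrichment: % pixel content divided by the region's % share of
  cellular area; 1 means a uniform distribution.

The lateral-surface region is the 1-µm rim inside the cell contour; the ICD
region is the area demarcated by the junction-marker channel at cell ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imgeo import RegionMask


@dataclass
class EnrichmentResult:
    pixel_content_total: float  # intensity * µm² over the whole cell
    pixel_content_region: float
    pct_pixel_content_region: float
    pct_area_region: float
    enrichment: float
    region_kind: str
    background: float


def pixel_content(image: np.ndarray, mask: RegionMask, background: float) -> float:
    """Background-subtracted mean pixel value times region area (µm²)."""
    if mask.is_empty():
        raise ValueError("mask is empty")
    if background < 0:
        raise ValueError("background must be >= 0")
    image = np.asarray(image, dtype=float)
    mean = float(image[mask.mask].mean())
    return (mean - background) * mask.area_um2


def _region_enrichment(image, cell: RegionMask, region: RegionMask,
                       background: float, kind: str) -> EnrichmentResult:
    if not np.all(cell.mask[region.mask]):
        raise ValueError(f"{kind} region extends outside the cell mask")
    pc_cell = pixel_content(image, cell, background)
    if pc_cell <= 0:
        raise ValueError(
            "whole-cell pixel content <= 0: image indistinguishable from background"
        )
    pc_region = pixel_content(image, region, background)
    pct_pc = 100.0 * pc_region / pc_cell
    pct_pc_clipped = max(pct_pc, 0.0)  # negativity from bg subtraction
    if pct_pc < 0:
        warnings.warn(
            f"negative {kind} pixel content ({pct_pc:.3g}%) clipped to 0 in "
            "percentage reporting; raw value retained"
        )
    pct_area = 100.0 * region.area_um2 / cell.area_um2
    return EnrichmentResult(
        pixel_content_total=pc_cell,
        pixel_content_region=pc_region,
        pct_pixel_content_region=pct_pc_clipped,
        pct_area_region=pct_area,
        enrichment=pct_pc / pct_area,
        region_kind=kind,
        background=background,
    )


def lateral_enrichment(image: np.ndarray, cell: RegionMask, rim: RegionMask,
                       background: float = 0.0) -> EnrichmentResult:
    """Degree of enrichment along the lateral surface (rim region)."""
    if rim.is_empty():
        raise ValueError("rim mask is empty")
    return _region_enrichment(image, cell, rim, background, "lateral")


def icd_enrichment(image: np.ndarray, cell: RegionMask, icd: RegionMask,
                   background: float = 0.0) -> EnrichmentResult | None:
    """Degree of enrichment within the junction-marker-demarcated ICD region.

    An empty ICD mask yields ``None`` with a warning (no junction signal in
    this cell) rather than an exception.
    """
    if icd.is_empty():
        warnings.warn("empty ICD mask; enrichment reported as missing")
        return None
    return _region_enrichment(image, cell, icd, background, "icd")
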