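"""Proximity-ligation-assay puncta density and expression correction.

PLA puncta appear where two tagged proteins lie within 30–40 nm, so puncta
density proxies interaction frequency — but it scales with the expression of
both partners.  The corrected density divides each cell's raw density by the
product of its two normalized expression pixel contents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clusters import cluster_stats, segment_clusters
from .imgeo import ImageStack, RegionMask, zproject_max


@dataclass
class PLAResult:
    puncta_density_pct: float
    n_puncta: int
    pc_channel1: float = np.nan
    pc_channel2: float = np.nan
    corrected_density: float = np.nan


def pla_density(
    stack: ImageStack,
    pla_channel,
    cell: RegionMask,
    threshold_method="otsu",
    min_size_px: int = 2,
) -> tuple[float, int]:
    """Percent of cellular area occupied by PLA puncta, and the puncta count.

    The z-stack is collapsed by maximum projection, then segmented within the
    cell contour.  For batch comparability, pass a fixed numeric
    ``threshold_method`` determined once per batch ("systemic" segmentation)
    rather than a per-image adaptive rule.
    """
    if cell.is_empty():
        raise ValueError("cell mask is empty")
    proj = zproject_max(stack, pla_channel)
    cs = segment_clusters(proj, cell, threshold_method, min_size_px)
    stats = cluster_stats(cs)
    return stats.density_pct, cs.n_clusters


def corrected_pla_density(
    result: PLAResult,
    group_mean_pc1: float,
    group_mean_pc2: float,
) -> float:
    """Expression-corrected density: raw density divided by the product of the
    two normalized expression pixel contents."""
    if group_mean_pc1 <= 0 or group_mean_pc2 <= 0:
        raise ValueError("group mean pixel contents must be > 0")
    if not (result.pc_channel1 > 0 and result.pc_channel2 > 0):
        warnings.warn("non-positive expression pixel content; correction missing")
        return np.nan
    norm1 = result.pc_channel1 / group_mean_pc1
    norm2 = result.pc_channel2 / group_mean_pc2
    return result.puncta_density_pct / (norm1 * norm2)
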