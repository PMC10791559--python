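"""Immunofluorescence cluster segmentation and the three cluster parameters.

The analysis mirrors the standard surface-cluster workflow: demarcate an ROI,
clear signal outside it, threshold the remainder, and report per-cluster area
together with three summary parameters — density (% of ROI area occupied by
clusters), average cluster size (µm²), and mean immunofluorescence intensity
within clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imgeo import ImageStack, RegionMask, reslice_yz

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class ClusterSet:
    """Labeled connected components within an ROI."""

    label_map: np.ndarray  # 0 = background, labels 1..n
    roi: RegionMask
    pixel_area_um2: float
    threshold: float
    threshold_method: str
    ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    areas_um2: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_intensities: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_clusters(self) -> int:
        return len(self.ids)


@dataclass
class ClusterStats:
    """Density, mean size, and mean in-cluster intensity for one ROI."""

    density_pct: float
    mean_size_um2: float
    mean_intensity: float
    mean_intensity_raw: float
    n_clusters: int
    threshold: float


def _resolve_threshold(values: np.ndarray, method, k_sd: float = 2.0) -> tuple[float, str]:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method), "fixed"
    if method == "otsu":
        if np.ptp(values) == 0:
            return float(values[0]) if values.size else 0.0, "otsu"
        return float(threshold_otsu(values)), "otsu"
    if method == "mean_sd":
        return float(values.mean() + k_sd * values.std()), f"mean+{k_sd}sd"
    raise ValueError(f"unknown threshold method {method!r}")


def segment_clusters(
    image: np.ndarray,
    roi: RegionMask,
    threshold_method="otsu",
    min_size_px: int = 4,
    k_sd: float = 2.0,
) -> ClusterSet:
    """Segment clusters inside the ROI.

    Pixels at or above the threshold (computed within the ROI) form the
    foreground; 8-connected components of at least ``min_size_px`` pixels
    become clusters.  An all-foreground or all-background outcome yields a
    warning and a full/empty result rather than an exception.
    """
    image = np.asarray(image, dtype=float)
    if roi.is_empty():
        raise ValueError("ROI is empty")
    if image.shape != roi.mask.shape:
        raise ValueError("image and ROI shapes differ")
    inside = image[roi.mask]
    thr, method_name = _resolve_threshold(inside, threshold_method, k_sd)
    fg = roi.mask & (image >= thr)
    n_fg = int(fg.sum())
    if n_fg == 0:
        warnings.warn("no pixels above threshold; empty cluster set")
    elif n_fg == roi.n_pixels:
        warnings.warn("every ROI pixel above threshold; ROI-filling cluster set")
    label_map, _ = ndimage.label(fg, structure=EIGHT_CONNECTED)
    if label_map.max() > 0 and min_size_px > 1:
        counts = np.bincount(label_map.ravel())
        small = np.flatnonzero(counts < min_size_px)
        label_map[np.isin(label_map, small[small > 0])] = 0
        # relabel contiguously
        label_map, _ = ndimage.label(label_map > 0, structure=EIGHT_CONNECTED)
    n = int(label_map.max())
    ids = np.arange(1, n + 1)
    px_area = roi.pixel_area_um2
    if n:
        counts = np.bincount(label_map.ravel())[1:]
        sums = ndimage.sum_labels(image, label_map, ids)
        areas = counts * px_area
        means = sums / counts
    else:
        areas = np.array([])
        means = np.array([])
    return ClusterSet(
        label_map=label_map, roi=roi, pixel_area_um2=px_area,
        threshold=thr, threshold_method=method_name,
        ids=ids, areas_um2=areas, mean_intensities=means,
    )


def cluster_stats(cs: ClusterSet, background: float = 0.0) -> ClusterStats:
    """Summarize a cluster set; intensity is background-subtracted."""
    if background < 0:
        raise ValueError("background must be >= 0")
    roi_area = cs.roi.area_um2
    if cs.n_clusters == 0:
        return ClusterStats(0.0, np.nan, np.nan, np.nan, 0, cs.threshold)
    total_area = float(cs.areas_um2.sum())
    pix = cs.label_map > 0
    # area-weighted mean over all cluster pixels
    weights = cs.areas_um2
    raw = float(np.average(cs.mean_intensities, weights=weights))
    return ClusterStats(
        density_pct=100.0 * total_area / roi_area,
        mean_size_um2=total_area / cs.n_clusters,
        mean_intensity=raw - background,
        mean_intensity_raw=raw,
        n_clusters=int(pix.any() and cs.n_clusters),
        threshold=cs.threshold,
    )


def occupancy_pct(image: np.ndarray, region: RegionMask, **params) -> float:
    """Percent of a region occupied by segmented puncta (density only)."""
    cs = segment_clusters(image, region, **params)
    return cluster_stats(cs).density_pct


def _icd_roi_from_marker(plane: np.ndarray, pixel_area_um2: float,
                         min_area_um2: float, threshold_method) -> np.ndarray | None:
    """Segment the junction-marker channel of a YZ plane into the ICD ROI."""
    vals = plane.ravel()
    if np.ptp(vals) == 0:
        return None
    thr, _ = _resolve_threshold(vals, threshold_method)
    fg = plane >= thr
    fg = ndimage.binary_fill_holes(fg)
    lab, n = ndimage.label(fg, structure=EIGHT_CONNECTED)
    if n == 0:
        return None
    counts = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(counts * pixel_area_um2 >= min_area_um2) + 1
    if keep.size == 0:
        return None
    return np.isin(lab, keep)


def icd_cluster_profile(
    stack: ImageStack,
    ncad_channel,
    target_channel,
    x_positions_um,
    threshold_method="otsu",
    min_size_px: int = 4,
    min_icd_area_um2: float = 0.5,
    background: float = 0.0,
    marker_threshold_method="otsu",
) -> list[ClusterStats | None]:
    """Cluster parameters of the target channel within marker-demarcated ICD
    ROIs, one en-face (YZ) view per requested x position.

    Positions where the junction marker shows no usable signal are reported
    as ``None`` rather than raising.
    """
    ci_marker = stack.channel_index(ncad_channel)
    ci_target = stack.channel_index(target_channel)
    planes = reslice_yz(stack, x_positions_um)
    # YZ plane pixels are (z_step, pixel_xy); use the geometric-mean pitch for
    # areas so count * pixel_area remains exact
    px_area = stack.z_step_um * stack.pixel_xy_um
    pitch_eq = float(np.sqrt(px_area))
    out: list[ClusterStats | None] = []
    for pl in planes:
        roi_arr = _icd_roi_from_marker(pl[ci_marker], px_area,
                                       min_icd_area_um2, marker_threshold_method)
        if roi_arr is None:
            out.append(None)
            continue
        roi = RegionMask(roi_arr, pitch_eq)
        cs = segment_clusters(pl[ci_target], roi, threshold_method, min_size_px)
        out.append(cluster_stats(cs, background))
    return out
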