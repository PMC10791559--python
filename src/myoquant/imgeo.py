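"""Image containers, mask geometry, projections, and orthogonal reslicing.

Conventions used throughout the package:

* Voxel grids are ``(channel, z, y, x)`` float arrays; 2-D planes are
  ``(y, x)``.
* Indices are 0-based; the physical position of pixel ``i`` along an axis
  with pitch ``p`` is ``(i + 0.5) * p`` (pixel-center convention).
* All areas are reported in µm² and satisfy ``area = count * pixel_area``
  exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.measure import points_in_poly


@dataclass
class ImageStack:
    """Multi-channel voxel grid with physical pixel sizes.

    Parameters
    ----------
    voxels
        Intensity array of shape ``(n_channels, nz, ny, nx)``.
    pixel_xy_um
        Lateral pixel pitch in µm (isotropic in X and Y).
    z_step_um
        Axial step between planes in µm.
    channel_names
        One name per channel.
    """

    voxels: np.ndarray
    pixel_xy_um: float
    z_step_um: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (channel, z, y, x)")
        if self.pixel_xy_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("one channel name per channel required")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the ``(z, y, x)`` sub-array for one channel."""
        return self.voxels[self.channel_index(channel)]


@dataclass
class RegionMask:
    """Boolean region (cell, rim, ICD, ROI) on a 2-D plane or 3-D grid."""

    mask: np.ndarray
    pixel_xy_um: float
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError("mask must be 2-D or 3-D")
        if self.pixel_xy_um <= 0:
            raise ValueError("pixel_xy_um must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_xy_um**2

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        """Area (2-D) or per-plane pixel area total (3-D not supported)."""
        if self.mask.ndim != 2:
            raise ValueError("area_um2 is defined for 2-D masks")
        return self.n_pixels * self.pixel_area_um2

    @property
    def volume_um3(self) -> float:
        if self.mask.ndim != 3:
            raise ValueError("volume_um3 is defined for 3-D masks")
        if self.z_step_um is None:
            raise ValueError("3-D mask requires z_step_um")
        return self.n_pixels * self.pixel_area_um2 * self.z_step_um

    def is_empty(self) -> bool:
        return not self.mask.any()


def mask_from_contour(
    polygon_vertices_um: np.ndarray,
    plane_shape: tuple[int, int],
    pixel_xy_um: float,
) -> RegionMask:
    """Rasterize a polygonal contour given in physical (x, y) µm coordinates.

    A pixel is included iff its center ``((ix+0.5)p, (iy+0.5)p)`` lies inside
    the polygon under the even-odd rule.
    """
    verts = np.asarray(polygon_vertices_um, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    # shoelace area; degenerate (collinear) polygons have zero area
    x, y = verts[:, 0], verts[:, 1]
    shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if shoelace == 0.0:
        raise ValueError("degenerate polygon (zero area)")
    ny, nx = plane_shape
    cx = (np.arange(nx) + 0.5) * pixel_xy_um
    cy = (np.arange(ny) + 0.5) * pixel_xy_um
    gx, gy = np.meshgrid(cx, cy)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = points_in_poly(pts, verts)
    return RegionMask(inside.reshape(ny, nx), pixel_xy_um)


def rim_mask(cell: RegionMask, width_um: float, pixel_xy_um: float | None = None) -> RegionMask:
    """Band of the cell within ``width_um`` of the cell contour.

    Membership: cell pixels whose exact Euclidean distance (µm, pixel
    centers) to the nearest outside-cell pixel is ≤ ``width_um``.  Width 0
    yields an empty rim, since every inside pixel is at least one pitch from
    the nearest outside pixel center.
    """
    if width_um < 0:
        raise ValueError("width_um must be >= 0")
    if cell.is_empty():
        raise ValueError("empty cell mask")
    pitch = pixel_xy_um if pixel_xy_um is not None else cell.pixel_xy_um
    if cell.mask.ndim != 2:
        raise ValueError("rim_mask operates on 2-D cell masks")
    # pad with one outside ring so the frame border counts as outside-cell
    padded = np.pad(cell.mask, 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=(pitch, pitch))[1:-1, 1:-1]
    return RegionMask(cell.mask & (dist <= width_um), pitch)


def zproject_max(stack: ImageStack, channel: int | str) -> np.ndarray:
    """Collapse a z-stack into a 2-D image by per-pixel maximum over z."""
    vol = stack.channel(channel)
    if vol.shape[0] < 1:
        raise ValueError("stack has no z-planes")
    return vol.max(axis=0)


def reslice_yz(stack: ImageStack, x_positions_um) -> list[np.ndarray]:
    """Extract YZ planes at given physical x positions (nearest pixel column).

    Each returned plane has shape ``(nz, ny)`` with pixel sizes
    ``(z_step_um, pixel_xy_um)``.
    """
    nz, ny, nx = stack.shape_zyx
    extent = nx * stack.pixel_xy_um
    planes = []
    for pos in np.atleast_1d(np.asarray(x_positions_um, dtype=float)):
        if pos < 0 or pos > extent:
            raise ValueError(
                f"x position {pos} µm outside stack extent [0, {extent}] µm"
            )
        idx = int(round(pos / stack.pixel_xy_um - 0.5))
        idx = min(max(idx, 0), nx - 1)
        planes.append(stack.voxels[:, :, :, idx].copy())
    return planes


def estimate_background(image: np.ndarray, bg_mask: RegionMask,
                        cell_mask: RegionMask | None = None) -> float:
    """Mean intensity over a cell-free background region.

    ``bg_mask`` must be non-empty and, when a cell mask is supplied, disjoint
    from it.
    """
    if bg_mask.is_empty():
        raise ValueError("background mask is empty")
    if cell_mask is not None and np.any(bg_mask.mask & cell_mask.mask):
        raise ValueError("background mask overlaps the cell mask")
    return float(np.asarray(image, dtype=float)[bg_mask.mask].mean())


def central_plane_index(cell_mask_3d: np.ndarray) -> int:
    """Pick the z-plane with maximal cell-mask area (analysis-plane default)."""
    areas = cell_mask_3d.reshape(cell_mask_3d.shape[0], -1).sum(axis=1)
    if areas.max() == 0:
        raise ValueError("cell mask is empty in every plane")
    return int(np.argmax(areas))


def write_stack(path, stack: ImageStack) -> None:
    """Write an OME-TIFF with PhysicalSize metadata."""
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_xy_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_xy_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": stack.channel_names},
        },
    )


def read_stack(path, pixel_xy_um: float | None = None,
               z_step_um: float | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF stack; explicit pitches override metadata."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        px, pz, names = None, None, []
        if tf.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                pix = root.find(".//ome:Pixels", ns)
                if pix is not None:
                    px = float(pix.get("PhysicalSizeX", "nan"))
                    pz = float(pix.get("PhysicalSizeZ", "nan"))
                    names = [
                        c.get("Name") or f"ch{i}"
                        for i, c in enumerate(pix.findall("ome:Channel", ns))
                    ]
            except Exception:  # metadata is advisory only
                warnings.warn("could not parse OME metadata; pass pitches explicitly")
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[None]
    px = pixel_xy_um if pixel_xy_um is not None else px
    pz = z_step_um if z_step_um is not None else pz
    if px is None or pz is None or not np.isfinite([px, pz]).all():
        raise ValueError("pixel sizes not found in metadata; pass them explicitly")
    return ImageStack(arr, px, pz, names or [])


def write_mask(path, region: RegionMask) -> None:
    tifffile.imwrite(path, region.mask.astype(np.uint8) * 255)
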