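"""Image reading, DAPI nucleus segmentation, and ROI measurements.

Segmentation follows the standard DAPI recipe: Gaussian smoothing (in
physical units, so results are resolution-stable), a global threshold
(Otsu by default), hole filling, connected-component labeling, and a
small-object filter.  All measurements carry physical units derived
from the pixel/voxel size.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "NucleusMask",
    "RoiMetrics",
    "read_image",
    "write_image",
    "segment_nuclei",
    "measure_roi",
    "measure_volume",
    "estimate_cytoplasmic_volume",
    "yz_aspect_ratio",
]


@dataclass
class ImageStack:
    """Intensity data plus the physical calibration needed downstream."""

    data: np.ndarray
    pixel_size_xy: float
    channel_names: tuple = ()
    z_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")


@dataclass
class NucleusMask:
    """Integer-labeled, hole-free nucleus regions.

    When produced by :func:`segment_nuclei`, the smoothed intensity
    image and threshold that defined the mask are kept so that boundary
    extraction can place the contour at sub-pixel precision instead of
    re-quantizing the binary mask.
    """

    label_image: np.ndarray
    pixel_size_xy: float
    smoothed: np.ndarray | None = None
    threshold: float | None = None
    smooth_sigma: float | None = None  # um, the segmentation smoothing scale

    @property
    def n_labels(self) -> int:
        return int(self.label_image.max())

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.label_image)
        return lab[lab > 0]


@dataclass(frozen=True)
class RoiMetrics:
    label: int
    area: float                 # um^2
    mean_intensity: float
    integrated_density: float   # intensity * um^2
    volume: float | None = None  # um^3, 3D only


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    import re
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', meta)
    return float(m.group(1)) if m else None


def read_image(path, pixel_size: float | None = None) -> ImageStack:
    """Read a TIFF/OME-TIFF; pixel size comes from OME metadata when
    present, else from the ``pixel_size`` override (error if neither)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        px = _ome_pixel_size(tif)
    if px is None:
        px = pixel_size
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata and no override given")
    return ImageStack(data=data, pixel_size_xy=float(px))


def write_image(path, data: np.ndarray, pixel_size: float) -> None:
    """Write an OME-TIFF carrying the XY pixel size in micrometres."""
    tifffile.imwrite(
        path, np.asarray(data), ome=True,
        metadata={"PhysicalSizeX": pixel_size, "PhysicalSizeXUnit": "um",
                  "PhysicalSizeY": pixel_size, "PhysicalSizeYUnit": "um"})


def segment_nuclei(dapi: np.ndarray, pixel_size: float,
                   smooth_sigma: float = 0.5,
                   threshold_method: str = "otsu",
                   min_area: float = 20.0) -> NucleusMask:
    """Segment nuclei from a 2D DAPI image.

    Pipeline: Gaussian smooth at ``smooth_sigma`` (um) -> global
    threshold -> fill holes -> 4-connected labeling -> drop regions
    smaller than ``min_area`` (um^2).  Raises on a constant image;
    returns an empty mask with a logged warning if nothing survives the
    area filter.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim == 3:  # stack: operate on the maximum projection
        dapi = dapi.max(axis=0)
    if np.ptp(dapi) == 0:
        raise ValueError("constant image cannot be segmented")
    smoothed = ndimage.gaussian_filter(dapi, smooth_sigma / pixel_size)
    if threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
    elif threshold_method == "mean":
        thr = smoothed.mean()
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = smoothed > thr
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary, structure=np.array([[0, 1, 0],
                                                          [1, 1, 1],
                                                          [0, 1, 0]]))
    min_px = min_area / pixel_size**2
    out = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, n + 1):
        region = labels == lab
        if region.sum() >= min_px:
            next_label += 1
            out[ndimage.binary_fill_holes(region)] = next_label
    if next_label == 0:
        logger.warning("segmentation produced no region above %.1f um^2", min_area)
    return NucleusMask(label_image=out, pixel_size_xy=pixel_size,
                       smoothed=smoothed, threshold=float(thr),
                       smooth_sigma=smooth_sigma)


def measure_roi(mask: NucleusMask, channel: np.ndarray, label: int) -> RoiMetrics:
    """Area, mean intensity and integrated density of one labeled region.

    area = pixel count x pixel_size^2; integrated density = mean x area,
    i.e. the plain pixel sum expressed in intensity * um^2.
    """
    region = mask.label_image == label
    if not region.any():
        raise ValueError(f"label {label} not present in mask")
    n_px = int(region.sum())
    area = n_px * mask.pixel_size_xy**2
    mean = float(np.asarray(channel, dtype=float)[region].mean())
    return RoiMetrics(label=int(label), area=area, mean_intensity=mean,
                      integrated_density=mean * area)


def measure_volume(stack_mask: np.ndarray,
                   voxel_size: tuple[float, float, float]) -> float:
    """Volume of a 3D binary mask: voxel count x voxel volume (um^3).
    Empty mask gives 0 with a warning."""
    stack_mask = np.asarray(stack_mask, dtype=bool)
    if stack_mask.ndim != 3:
        raise ValueError("expected a 3D binary mask")
    n = int(stack_mask.sum())
    if n == 0:
        warnings.warn("empty 3D mask; volume is 0", stacklevel=2)
        return 0.0
    vx, vy, vz = voxel_size
    return n * vx * vy * vz


def estimate_cytoplasmic_volume(cell_vol: float, nuclear_vol: float,
                                lipid_vol: float) -> float:
    """Cytoplasmic volume estimate: cell - nucleus - lipid (um^3)."""
    if min(cell_vol, nuclear_vol, lipid_vol) < 0:
        raise ValueError("volumes must be non-negative")
    out = cell_vol - nuclear_vol - lipid_vol
    if out < 0:
        raise ValueError("inconsistent inputs: negative cytoplasmic volume")
    return out


def yz_aspect_ratio(stack_mask: np.ndarray,
                    voxel_size: tuple[float, float, float]) -> float:
    """YZ aspect ratio of a 3D nucleus mask ordered (z, y, x).

    The stack is resliced to the YZ plane, maximum-projected along X,
    and the width (Y) over height (Z) of the moment-fit ellipse is
    returned in physical units, so anisotropic voxels do not bias the
    answer.  Values > 1 indicate a flattened (spread-compressed)
    nucleus.
    """
    stack_mask = np.asarray(stack_mask, dtype=bool)
    if stack_mask.ndim != 3 or not stack_mask.any():
        raise ValueError("expected a nonempty 3D binary mask")
    vx, vy, vz = voxel_size
    proj = stack_mask.max(axis=2)  # (z, y) maximum projection along x
    zz, yy = np.nonzero(proj)
    y_um = yy * vy
    z_um = zz * vz
    var_y = np.var(y_um)
    var_z = np.var(z_um)
    if var_z == 0:
        raise ValueError("degenerate projection (single Z plane)")
    return float(math.sqrt(var_y / var_z))
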