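"""Perineuronal-net quantification: density and surface contiguity.

Contiguity of a binarized net is the fraction of its foreground pixels that
fall in the largest connected component (8-connectivity by default); low
values indicate a fragmented surface. Thresholding uses the IsoData
iterative-intermeans algorithm computed on within-ROI intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile
from skimage import measure
from skimage.draw import polygon2mask
from skimage.filters import threshold_isodata, threshold_otsu

from .errors import ConfigError, ThresholdError


@dataclass
class ImageStack:
    """A z-stack with pixel calibration (µm per pixel, µm z-step)."""

    voxels: np.ndarray
    um_per_px: float
    z_step_um: float = 0.37

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ConfigError("voxels must be a non-empty z*y*x array")
        if self.um_per_px <= 0 or self.z_step_um <= 0:
            raise ConfigError("pixel calibration must be positive")


@dataclass
class PNNMask:
    """Binarized net within a traced ROI."""

    mask: np.ndarray
    roi_outline: np.ndarray
    threshold_value: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.roi_outline = np.asarray(self.roi_outline, dtype=float)


@dataclass
class ContiguityResult:
    fraction: float
    n_components: int
    largest_component_px: int
    total_px: int


@dataclass
class DensityResult:
    cell_count: int
    area_mm2: float
    density: float


def read_tiff(path, um_per_px: float | None = None, z_step_um: float | None = None) -> ImageStack:
    """Read a multi-page TIFF; calibration from ImageJ metadata or arguments."""
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        if voxels.ndim == 2:
            voxels = voxels[None]
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        if um_per_px is None:
            res = page.tags.get("XResolution")
            if res is not None and res.value[0]:
                um_per_px = res.value[1] / res.value[0]
        if z_step_um is None:
            z_step_um = meta.get("spacing")
    if um_per_px is None:
        raise ConfigError(f"{path}: no pixel size in metadata; pass um_per_px")
    return ImageStack(voxels=voxels, um_per_px=um_per_px, z_step_um=z_step_um or 0.37)


def write_tiff(stack: ImageStack, path) -> None:
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / stack.um_per_px, 1.0 / stack.um_per_px),
        metadata={"spacing": stack.z_step_um, "unit": "um", "axes": "ZYX"},
    )


def project_top_half(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection over the top half of the z-range.

    Planes [0, ceil(Z/2)) are projected; a single-plane stack is returned
    unchanged (with a warning, since there is nothing to project).
    """
    z = stack.voxels.shape[0]
    if z < 2:
        import warnings

        warnings.warn("single-plane stack: projection is the identity", stacklevel=2)
        return stack.voxels[0].copy()
    top = int(np.ceil(z / 2))
    return stack.voxels[:top].max(axis=0)


def binarize_default(image: np.ndarray, roi: np.ndarray, method: str = "isodata") -> PNNMask:
    """Binarize within a traced ROI polygon.

    The threshold is computed by IsoData iterative intermeans (the common
    "default" auto-threshold; ``method="otsu"`` selects Otsu instead) on the
    intensities inside the ROI only. Pixels strictly above the threshold and
    inside the ROI are foreground.

    ``roi`` is a polygon as (row, col) vertices.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi, dtype=float)
    if image.ndim != 2:
        raise ConfigError("binarize_default expects a 2D image")
    roi_mask = polygon2mask(image.shape, roi)
    vals = image[roi_mask]
    if vals.size == 0:
        raise ThresholdError("ROI contains no pixels")
    if np.ptp(vals) == 0:
        raise ThresholdError("uniform intensity within ROI: threshold undefined")
    if method == "isodata":
        thresh = float(threshold_isodata(vals))
    elif method == "otsu":
        thresh = float(threshold_otsu(vals))
    else:
        raise ConfigError(f"unknown threshold method '{method}'")
    mask = roi_mask & (image > thresh)
    if not mask.any():
        raise ThresholdError("no foreground pixels above threshold within ROI")
    return PNNMask(mask=mask, roi_outline=roi, threshold_value=thresh)


def contiguity(mask: PNNMask | np.ndarray, connectivity: int = 2) -> ContiguityResult:
    """Fraction of foreground in the largest connected component.

    ``connectivity`` follows skimage: 2 = 8-neighbourhood (default),
    1 = 4-neighbourhood.
    """
    arr = mask.mask if isinstance(mask, PNNMask) else np.asarray(mask, dtype=bool)
    total = int(arr.sum())
    if total == 0:
        raise ConfigError("empty mask: contiguity undefined")
    labels, n_comp = measure.label(arr, connectivity=connectivity, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(sizes.max())
    return ContiguityResult(
        fraction=largest / total,
        n_components=int(n_comp),
        largest_component_px=largest,
        total_px=total,
    )


def density(cell_count: int, area_mm2: float) -> DensityResult:
    """Cells per square millimetre."""
    if area_mm2 <= 0:
        raise ConfigError("area_mm2 must be positive")
    if cell_count < 0:
        raise ConfigError("cell_count must be >= 0")
    return DensityResult(cell_count=int(cell_count), area_mm2=float(area_mm2), density=cell_count / area_mm2)


def polygon_area_mm2(vertices: np.ndarray, um_per_px: float) -> float:
    """Area of a traced polygon (pixel vertices) in mm², via the shoelace sum."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise ConfigError("polygon needs at least 3 vertices")
    r, c = v[:, 0], v[:, 1]
    area_px2 = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    return area_px2 * (um_per_px**2) / 1e6


def read_roi_json(path) -> list[np.ndarray]:
    """Read ROI polygons from JSON: {"rois": [[[r,c],...], ...]}."""
    with open(path) as fh:
        data = json.load(fh)
    return [np.asarray(p, dtype=float) for p in data["rois"]]
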