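"""Binarization of grayscale vessel images and region-of-interest masks.

The upstream clinical workflow produced binary vessel images and ROI masks
by hand; this module automates that step (Otsu or fixed thresholding plus
small-object cleanup) while remaining overridable: already-binary inputs
pass through untouched and user-supplied ROI files are accepted.

Conventions: arrays are (row, col), 0-based; foreground is True (written
as 255 in PNG masks); all results are in pixel units.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image, remove_small_objects
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = ["binarize", "detect_roi", "SegmentationError"]


class SegmentationError(ValueError):
    """Binarization or ROI construction failed on a degenerate input."""


def _is_binary(image: np.ndarray) -> bool:
    if image.dtype == bool:
        return True
    vals = np.unique(image)
    return vals.size <= 2 and set(vals.tolist()) <= {0, 1, 255}


def binarize(image: np.ndarray, method: str = "otsu",
             threshold: float | None = None,
             min_object_px: int = 20) -> np.ndarray:
    """Threshold a grayscale vessel image to a boolean vessel mask.

    Parameters
    ----------
    image : 2D uint8/bool array, single channel.
    method : ``"otsu"`` (automatic) or ``"fixed"`` (requires ``threshold``).
    min_object_px : connected components (8-connectivity) smaller than this
        are removed as speckle; an already-binary input is returned
        unchanged (identity), mirroring externally curated masks.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise SegmentationError("expected a non-empty single-channel 2D image")
    if _is_binary(image):
        return image.astype(bool)

    if method == "fixed":
        if threshold is None:
            raise SegmentationError("method='fixed' requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.unique(image).size < 2:
            raise SegmentationError(
                "degenerate histogram: uniform image has no Otsu threshold")
        thr = float(threshold_otsu(image))
    else:
        raise SegmentationError(f"unknown binarization method '{method}'")

    mask = image > thr
    if min_object_px > 1:
        # drop components strictly smaller than min_object_px (8-connectivity)
        mask = remove_small_objects(mask, max_size=min_object_px - 1,
                                    connectivity=2)
    if not mask.any():
        raise SegmentationError("empty vessel mask after thresholding/cleanup")
    return mask


def detect_roi(mask: np.ndarray, mode: str = "hull", dilation_px: int = 0,
               roi_file_mask: np.ndarray | None = None) -> np.ndarray:
    """Construct the ROI over which density metrics are normalized.

    ``hull``  : convex hull of the vessel foreground, dilated by
                ``dilation_px`` (Euclidean); always a superset of the mask.
    ``frame`` : the full image frame.
    ``file``  : a user-supplied mask (validated against shape; if it fails
                to cover the vessel mask a warning reports the uncovered
                pixel count and the vessel mask is intersected downstream).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise SegmentationError("vessel mask must be 2D")
    if mode == "frame":
        return np.ones_like(mask, dtype=bool)
    if mode == "hull":
        if not mask.any():
            raise SegmentationError("cannot build hull ROI from empty mask")
        roi = convex_hull_image(mask)
        if dilation_px > 0:
            roi = ndi.distance_transform_edt(~roi) <= dilation_px
        return roi
    if mode == "file":
        if roi_file_mask is None:
            raise SegmentationError("mode='file' requires roi_file_mask")
        roi = np.asarray(roi_file_mask, dtype=bool)
        if roi.shape != mask.shape:
            raise SegmentationError(
                f"ROI shape {roi.shape} does not match image shape {mask.shape}")
        uncovered = int((mask & ~roi).sum())
        if uncovered:
            warnings.warn(
                f"user ROI does not cover {uncovered} vessel pixels; "
                "densities will use the intersection", stacklevel=2)
        return roi
    raise SegmentationError(f"unknown ROI mode '{mode}'")
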