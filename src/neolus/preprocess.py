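"""Artifact removal and geometric normalization of LUS frames.

Overlay artifacts (patient info, probe marks) sit at fixed x-y positions
throughout a video and are near the display maximum, so they are removed
ROI-wise: inside each ROI, pixels brighter than half the ROI maximum plus
their 8-connected neighbours are replaced by the ROI median.  Geometric
normalization resamples every frame to 520x420 and trims a 10-pixel
border, giving the canonical 500x400 raster that all downstream stages
consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.transform import resize

#: canonical output shape (rows, cols) after normalization
NORMALIZED_SHAPE = (500, 400)
_RESIZE_SHAPE = (520, 420)
_TRIM = 10


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangle, 0-based half-open on both axes."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def validate(self, shape: tuple[int, int]) -> None:
        if not (0 <= self.row_start < self.row_end <= shape[0]):
            raise ValueError(f"ROI rows {self.row_start}:{self.row_end} "
                             f"outside image of {shape[0]} rows")
        if not (0 <= self.col_start < self.col_end <= shape[1]):
            raise ValueError(f"ROI cols {self.col_start}:{self.col_end} "
                             f"outside image of {shape[1]} cols")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_end),
                slice(self.col_start, self.col_end))


def _lower_median(values: np.ndarray) -> float:
    """Median as the lower of the two middle order statistics.

    Keeps the replacement value an actual observed intensity, which is
    stable for integer-valued 8-bit input.
    """
    flat = np.sort(values, axis=None)
    return float(flat[(flat.size - 1) // 2])


def remove_artifacts(image: np.ndarray, rois: list[RoiRect]) -> np.ndarray:
    """Replace bright overlay pixels inside each ROI by the ROI median.

    Within each ROI, pixels with intensity strictly greater than half the
    ROI maximum are selected, their 8-connected neighbours (clipped to
    the ROI) are added, and all selected pixels are set to the ROI median
    computed over the original (pre-replacement) ROI values.  Pixels
    outside every ROI are untouched; an empty ROI list is the identity.
    """
    image = np.asarray(image, dtype=float)
    out = image.copy()
    for roi in rois:
        roi.validate(image.shape)
        rs, cs = roi.slices()
        patch = image[rs, cs]
        mask = patch > 0.5 * patch.max()
        if not mask.any():
            continue
        mask = binary_dilation(mask, structure=np.ones((3, 3), bool))
        out[rs, cs] = np.where(mask, _lower_median(patch), out[rs, cs])
    return out


def normalize_geometry(image: np.ndarray) -> np.ndarray:
    """Resample to 520x420 (bilinear) then trim 10 px per side -> 500x400."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("input must be a 2D image with at least 2 px per side")
    resized = resize(image, _RESIZE_SHAPE, order=1, mode="reflect",
                     anti_aliasing=True, preserve_range=True)
    out = resized[_TRIM:-_TRIM, _TRIM:-_TRIM]
    # interpolation must not expand the intensity range
    return np.clip(out, image.min(), image.max())


def preprocess_image(image: np.ndarray,
                     rois: list[RoiRect] | None = None) -> np.ndarray:
    """Full preprocessing: artifact removal (optional ROIs) + normalization."""
    if rois:
        image = remove_artifacts(image, rois)
    return normalize_geometry(image)
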