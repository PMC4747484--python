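"""Shared domain types and pixel-level primitives for phantom calcium scoring.

Calcium deposits embedded in a tissue-mimicking agar block are imaged as
stacks of 2-D slices, either with B-mode ultrasound (8-bit gray scale,
pixel values 0--250) or with micro-CT (16-bit, pixel values 0--65535 with a
water/air Hounsfield calibration).  Scoring always follows the same pixel
pipeline: restrict a slice to a user-drawn region of interest, select
calcium by a global intensity threshold, and measure the selected area and
its maximum intensity.  This module holds the data containers and those
elementary operations; the modality-specific score arithmetic lives in
:mod:`calscore.us` and :mod:`calscore.ct`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional, Sequence

import numpy as np
from skimage.draw import polygon as _sk_polygon

# --------------------------------------------------------------------------
# Constants (modality conventions)
# --------------------------------------------------------------------------

#: Representable pixel-value range of the gray-scale ultrasound images.
US_PV_RANGE = (0, 250)
#: Representable pixel-value range of the 16-bit micro-CT reconstructions.
CT_PV_RANGE = (0, 65535)
#: Default global threshold (pixel value) separating calcium from agar on US.
US_THRESHOLD_PV = 130
#: Default density threshold (HU) separating calcium from agar on micro-CT.
CT_THRESHOLD_HU = 700.0


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class CalScoreError(Exception):
    """Base class for all calscore errors."""


class ValidationError(CalScoreError):
    """Invalid input values or inconsistent domain objects (CLI exit code 2)."""


class FormatError(CalScoreError):
    """Unreadable or malformed file / array format (CLI exit code 3)."""


class GeometryError(ValidationError):
    """Region geometry outside image bounds or otherwise ill-formed."""


# --------------------------------------------------------------------------
# Enumerations
# --------------------------------------------------------------------------

class Modality(str, Enum):
    US = "US"
    CT = "CT"


class AxisLabel(str, Enum):
    SHORT = "short"
    LONG = "long"
    NONE = "none"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A 3-D stack of 2-D image slices with physical spacing metadata.

    Parameters
    ----------
    pixels
        Array of shape ``(n_slices, n_rows, n_cols)``; non-negative pixel
        values unless ``hu_scaled`` is set.
    pixel_spacing_mm
        In-plane spacing ``(row, col)`` in millimetres.
    slice_spacing_mm
        Distance between consecutive slices along the stepping axis, mm.
    modality
        ``US`` or ``CT``; fixes the admissible ``pv_range``.
    pv_range
        ``(min, max)`` representable pixel values.
    axis_label
        Probe orientation of an ultrasound stack (``short``/``long``), or
        ``none`` when not applicable.
    hu_scaled
        True when the pixel values are already Hounsfield units (e.g. a
        DICOM series with rescale slope/intercept applied); range checks
        against the raw CT pixel-value convention are then skipped.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_spacing_mm: float
    modality: Modality
    pv_range: tuple[float, float] = None  # type: ignore[assignment]
    axis_label: AxisLabel = AxisLabel.NONE
    hu_scaled: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.modality = Modality(self.modality)
        self.axis_label = AxisLabel(self.axis_label)
        if self.pixels.ndim != 3:
            raise FormatError(
                f"stack must be 3-D (slice, row, col); got shape {self.pixels.shape}"
            )
        if self.pv_range is None:
            self.pv_range = US_PV_RANGE if self.modality is Modality.US else CT_PV_RANGE
        self.pv_range = (float(self.pv_range[0]), float(self.pv_range[1]))
        self.validate()

    def validate(self) -> None:
        if self.pixel_spacing_mm[0] <= 0 or self.pixel_spacing_mm[1] <= 0:
            raise ValidationError("pixel_spacing_mm must be strictly positive")
        if self.slice_spacing_mm <= 0:
            raise ValidationError("slice_spacing_mm must be strictly positive")
        if self.modality is Modality.US and tuple(self.pv_range) != (0.0, 250.0):
            raise ValidationError("US stacks use the fixed pixel-value range (0, 250)")
        if (
            self.modality is Modality.CT
            and not self.hu_scaled
            and tuple(self.pv_range) != (0.0, 65535.0)
        ):
            raise ValidationError("raw CT stacks use the fixed pixel-value range (0, 65535)")
        if self.pixels.size:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < self.pv_range[0] or hi > self.pv_range[1]:
                raise ValidationError(
                    f"pixel values [{lo}, {hi}] outside pv_range {self.pv_range}"
                )

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass(frozen=True)
class CTCalibration:
    """Water/air reference pixel values anchoring the Hounsfield scale.

    Water maps to 0 HU and air to -1000 HU; any pixel value is converted
    linearly through these two anchors.
    """

    pv_water: float
    pv_air: float

    def __post_init__(self) -> None:
        if not self.pv_water > self.pv_air:
            raise ValidationError(
                "degenerate calibration: pv_water must exceed pv_air "
                f"(got water={self.pv_water}, air={self.pv_air})"
            )


# A region is a plain dict: {"type": "rect", "coords": [r0, c0, r1, c1]}
# (half-open in both directions) or {"type": "polygon", "coords": [[r, c], ...]}
# with 0-based pixel coordinates.
Region = Dict[str, object]


def _validate_rect(coords: Sequence[float], shape: tuple[int, int]) -> tuple[int, int, int, int]:
    if len(coords) != 4:
        raise GeometryError(f"rect region needs 4 coords [r0, c0, r1, c1]; got {coords!r}")
    r0, c0, r1, c1 = (int(v) for v in coords)
    if r0 > r1 or c0 > c1:
        raise GeometryError(f"rect region corners out of order: {coords!r}")
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise GeometryError(f"rect region {coords!r} outside slice bounds {shape}")
    return r0, c0, r1, c1


def region_mask(region: Region, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a rect/polygon region into a boolean mask of ``shape``."""
    kind = region.get("type")
    coords = region.get("coords")
    mask = np.zeros(shape, dtype=bool)
    if kind == "rect":
        r0, c0, r1, c1 = _validate_rect(coords, shape)  # type: ignore[arg-type]
        mask[r0:r1, c0:c1] = True
    elif kind == "polygon":
        verts = np.asarray(coords, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise GeometryError(f"polygon region needs >= 3 (row, col) vertices; got {coords!r}")
        if (
            verts[:, 0].min() < 0
            or verts[:, 1].min() < 0
            or verts[:, 0].max() > shape[0]
            or verts[:, 1].max() > shape[1]
        ):
            raise GeometryError("polygon vertices outside slice bounds")
        rr, cc = _sk_polygon(verts[:, 0], verts[:, 1], shape=shape)
        mask[rr, cc] = True
    else:
        raise GeometryError(f"unknown region type {kind!r}")
    return mask


@dataclass
class ROISet:
    """Per-slice region specifications for one calcium deposit.

    ``kind`` is ``explicit_per_slice`` when every relevant slice carries its
    own region, or ``endpoints_interpolated`` when only the first and last
    slice of the deposit are drawn and the regions in between are generated
    by linear interpolation (see :func:`calscore.ct.interpolate_rois`).
    """

    regions: Dict[int, Region] = field(default_factory=dict)
    kind: str = "explicit_per_slice"

    def __post_init__(self) -> None:
        if self.kind not in ("explicit_per_slice", "endpoints_interpolated"):
            raise ValidationError(f"unknown ROISet kind {self.kind!r}")
        self.regions = {int(k): v for k, v in self.regions.items()}
        if self.kind == "endpoints_interpolated" and len(self.regions) != 2:
            raise ValidationError(
                "endpoints_interpolated ROISet needs regions on exactly two slices"
            )

    def get(self, slice_index: int) -> Optional[Region]:
        return self.regions.get(int(slice_index))


@dataclass
class SliceMeasurement:
    """Per-slice calcium measurement.

    ``score`` is ``area_calcium_mm2`` times a modality-specific weight: the
    maximum pixel value for ultrasound, the Agatston-style weighting factor
    for CT.  ``hu_max``/``wf`` are populated by CT scoring only.
    """

    slice_index: int
    area_calcium_mm2: float
    pv_max: float
    score: float = 0.0
    hu_max: Optional[float] = None
    wf: Optional[int] = None

    def __post_init__(self) -> None:
        if self.area_calcium_mm2 < 0:
            raise ValidationError("area_calcium_mm2 must be >= 0")
        if self.area_calcium_mm2 == 0 and (self.pv_max != 0 or self.score != 0):
            raise ValidationError("empty selection must have pv_max = 0 and score = 0")


@dataclass
class StackScore:
    """Stack-level aggregate of per-slice measurements.

    ``total_volume_index`` is the plain sum of per-slice areas (mm^2 summed
    over the stepped slices; numerically mm^3 when the stepping is 1 mm).
    ``total_volume_mm3`` additionally multiplies by the slice spacing.
    """

    per_slice: list[SliceMeasurement]
    total_score: float
    total_volume_index: float
    total_volume_mm3: float
    axis_label: AxisLabel = AxisLabel.NONE

    @classmethod
    def from_slices(
        cls,
        slices: Sequence[SliceMeasurement],
        slice_spacing_mm: float,
        axis_label: AxisLabel = AxisLabel.NONE,
    ) -> "StackScore":
        total_score = float(sum(m.score for m in slices))
        total_area = float(sum(m.area_calcium_mm2 for m in slices))
        return cls(
            per_slice=list(slices),
            total_score=total_score,
            total_volume_index=total_area,
            total_volume_mm3=total_area * slice_spacing_mm,
            axis_label=AxisLabel(axis_label),
        )


# --------------------------------------------------------------------------
# Pixel-level operations
# --------------------------------------------------------------------------

def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def rgb_to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB frame to the 0--250 ultrasound gray scale.

    Uses ITU-R 601 luma (0.299 R + 0.587 G + 0.114 B) followed by a linear
    rescale of [0, 255] to [0, 250] with round-half-up, so an achromatic
    pixel (v, v, v) maps to ``round(v * 250 / 255)`` and pure white maps to
    the top of the ultrasound pixel-value range.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB frame; got shape {frame.shape}")
    luma = (
        0.299 * frame[..., 0].astype(float)
        + 0.587 * frame[..., 1].astype(float)
        + 0.114 * frame[..., 2].astype(float)
    )
    gray = _round_half_up(luma * US_PV_RANGE[1] / 255.0)
    return np.clip(gray, 0, US_PV_RANGE[1]).astype(np.uint8)


def zero_outside_roi(image: np.ndarray, region: Region) -> np.ndarray:
    """Return a copy of ``image`` with every pixel outside ``region`` set to 0."""
    image = np.asarray(image)
    mask = region_mask(region, image.shape)
    out = np.zeros_like(image)
    out[mask] = image[mask]
    return out


def select_calcium_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Global thresholding: boolean mask of pixels with value >= ``threshold``.

    The comparison is inclusive and no connectivity or minimum-size
    filtering is applied -- isolated supra-threshold pixels count.
    """
    return np.asarray(image) >= threshold


def measure_slice(
    mask: np.ndarray,
    image: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    slice_index: int = 0,
) -> SliceMeasurement:
    """Measure calcium area (mm^2) and maximum intensity of the selected pixels.

    Area is the selected-pixel count times the pixel area; ``pv_max`` is 0
    when nothing is selected.  The returned measurement carries no score --
    the modality-specific weighting is applied by the caller.
    """
    mask = np.asarray(mask, dtype=bool)
    image = np.asarray(image)
    if mask.shape != image.shape:
        raise FormatError(
            f"mask shape {mask.shape} does not match slice shape {image.shape}"
        )
    count = int(mask.sum())
    area = count * float(pixel_spacing_mm[0]) * float(pixel_spacing_mm[1])
    pv_max = float(image[mask].max()) if count else 0.0
    return SliceMeasurement(
        slice_index=slice_index, area_calcium_mm2=area, pv_max=pv_max, score=0.0
    )
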