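"""Agatston-style micro-CT calcium scoring.

Raw micro-CT pixel values are mapped to Hounsfield units through a linear
calibration anchored at water (0 HU) and air (-1000 HU).  Calcium is
selected with a 700 HU threshold -- well above agar and consistent with
dense bone and hydroxyapatite -- applied in pixel-value space.  Per slice,
the maximal density HU_max inside the region of interest assigns an
integer weighting factor (1 from 700 HU, 2 from 1000 HU, 3 from 2000 HU,
4 from 3000 HU), and the slice calcification score is wf x area.  Regions
are drawn on the first and last slice of a deposit only; intermediate
regions are linearly interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    AxisLabel,
    CTCalibration,
    CT_THRESHOLD_HU,
    GeometryError,
    ImageStack,
    Modality,
    ROISet,
    Region,
    SliceMeasurement,
    ValidationError,
    measure_slice,
    select_calcium_mask,
    zero_outside_roi,
)


# --------------------------------------------------------------------------
# Hounsfield calibration
# --------------------------------------------------------------------------

def hu_from_pv(pv, cal: CTCalibration):
    """Convert pixel value(s) to Hounsfield units: (pv - water)/(water - air) x 1000."""
    pv = np.asarray(pv, dtype=float)
    hu = (pv - cal.pv_water) / (cal.pv_water - cal.pv_air) * 1000.0
    return float(hu) if hu.ndim == 0 else hu


def pv_from_hu(hu, cal: CTCalibration, as_threshold: bool = False):
    """Invert :func:`hu_from_pv`.

    With ``as_threshold=True`` the continuous result is ceiled to the next
    integer pixel value, so that selecting ``pv >= pv_from_hu(h)`` admits no
    pixel whose density is below ``h``.
    """
    hu = np.asarray(hu, dtype=float)
    pv = hu * (cal.pv_water - cal.pv_air) / 1000.0 + cal.pv_water
    if as_threshold:
        if pv.ndim == 0:
            return int(math.ceil(float(pv)))
        return np.ceil(pv).astype(int)
    return float(pv) if pv.ndim == 0 else pv


# --------------------------------------------------------------------------
# Weighting-factor table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WfTable:
    """Density-weighting bins: ordered (HU lower bound inclusive, wf).

    Below the first bound the weighting factor is 0; at or above the last
    bound it is the last wf.  A density of exactly 3000 HU therefore maps
    to wf 4, keeping the mapping monotone.
    """

    bins: tuple[tuple[float, int], ...] = (
        (700.0, 1),
        (1000.0, 2),
        (2000.0, 3),
        (3000.0, 4),
    )

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.bins]
        wfs = [w for _, w in self.bins]
        if not self.bins:
            raise ValidationError("WfTable needs at least one bin")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError("WfTable bounds must be strictly increasing")
        if any(w2 <= w1 for w1, w2 in zip(wfs, wfs[1:])) or any(w < 0 for w in wfs):
            raise ValidationError("WfTable wf values must be non-negative and strictly increasing")


DEFAULT_WF_TABLE = WfTable()


def weighting_factor(hu_max: float, table: WfTable = DEFAULT_WF_TABLE) -> int:
    """Weighting factor of the highest bin whose lower bound <= ``hu_max``."""
    wf = 0
    for bound, value in table.bins:
        if hu_max >= bound:
            wf = value
        else:
            break
    return wf


# --------------------------------------------------------------------------
# ROI interpolation
# --------------------------------------------------------------------------

def _region_vertices(region: Region) -> np.ndarray:
    if region["type"] == "rect":
        return np.asarray(region["coords"], dtype=float)
    return np.asarray(region["coords"], dtype=float)


def interpolate_rois(
    first_region: Region,
    last_region: Region,
    slice_span: int,
    first_index: int = 0,
) -> ROISet:
    """Linearly interpolate regions between a first and last drawn region.

    Returns an explicit per-slice :class:`~calscore.core.ROISet` covering
    ``slice_span`` consecutive slices starting at ``first_index``; the
    endpoint regions are reproduced exactly.
    """
    if slice_span < 2:
        raise ValidationError("interpolate_rois needs a slice span of at least 2")
    if first_region["type"] != last_region["type"]:
        raise GeometryError("endpoint regions must share the same type")
    a = _region_vertices(first_region)
    b = _region_vertices(last_region)
    if a.shape != b.shape:
        raise GeometryError(
            f"endpoint regions must have matching vertex counts; got {a.shape} vs {b.shape}"
        )
    regions: dict[int, Region] = {}
    for k in range(slice_span):
        t = k / (slice_span - 1)
        coords = (1.0 - t) * a + t * b
        regions[first_index + k] = {
            "type": first_region["type"],
            "coords": coords.tolist(),
        }
    return ROISet(regions=regions, kind="explicit_per_slice")


def resolve_rois(rois: ROISet, n_slices: int) -> ROISet:
    """Materialize an endpoints-interpolated ROI set into per-slice regions."""
    if rois.kind != "endpoints_interpolated":
        return rois
    lo, hi = sorted(rois.regions)
    if hi >= n_slices:
        raise GeometryError(f"endpoint slice {hi} outside stack of {n_slices} slices")
    return interpolate_rois(rois.regions[lo], rois.regions[hi], hi - lo + 1, first_index=lo)


# --------------------------------------------------------------------------
# Stack scoring
# --------------------------------------------------------------------------

@dataclass
class CTCalciumResult:
    """CT calcium score (sum of wf x area) and volume (sum of areas)."""

    per_slice: list[SliceMeasurement] = field(default_factory=list)
    ct_calcium_score: float = 0.0
    ct_calcium_volume: float = 0.0
    ct_calcium_volume_mm3: float = 0.0
    axis_label: AxisLabel = AxisLabel.NONE


def score_slice_ct(
    image,
    region: Region,
    pixel_spacing_mm: tuple[float, float],
    cal: CTCalibration,
    hu_threshold: float = CT_THRESHOLD_HU,
    table: WfTable = DEFAULT_WF_TABLE,
    slice_index: int = 0,
) -> SliceMeasurement:
    """Score one CT slice: threshold at ``hu_threshold``, then wf(HU_max) x area."""
    restricted = zero_outside_roi(image, region)
    pv_threshold = pv_from_hu(hu_threshold, cal, as_threshold=True)
    mask = select_calcium_mask(restricted, pv_threshold)
    m = measure_slice(mask, restricted, pixel_spacing_mm, slice_index=slice_index)
    if m.area_calcium_mm2 > 0:
        m.hu_max = hu_from_pv(m.pv_max, cal)
        m.wf = weighting_factor(m.hu_max, table)
        m.score = m.wf * m.area_calcium_mm2
    else:
        m.hu_max = 0.0
        m.wf = 0
    return m


def score_stack_ct(
    stack: ImageStack,
    rois: ROISet,
    cal: Optional[CTCalibration],
    hu_threshold: float = CT_THRESHOLD_HU,
    table: WfTable = DEFAULT_WF_TABLE,
) -> CTCalciumResult:
    """Score a CT stack slice by slice and sum scores and areas.

    ``cal`` may be omitted only for HU-scaled stacks (e.g. DICOM input with
    rescale tags), in which case the identity calibration (water 0, air
    -1000) is used.
    """
    if stack.modality is not Modality.CT:
        raise ValidationError(f"expected a CT stack; got modality {stack.modality}")
    if cal is None:
        if not stack.hu_scaled:
            raise ValidationError("raw CT stacks require a water/air calibration")
        cal = CTCalibration(pv_water=0.0, pv_air=-1000.0)
    rois = resolve_rois(rois, stack.n_slices)
    measurements = []
    for i in range(stack.n_slices):
        region = rois.get(i)
        if region is None:
            measurements.append(SliceMeasurement(i, 0.0, 0.0, 0.0, hu_max=0.0, wf=0))
            continue
        measurements.append(
            score_slice_ct(
                stack.pixels[i],
                region,
                stack.pixel_spacing_mm,
                cal,
                hu_threshold=hu_threshold,
                table=table,
                slice_index=i,
            )
        )
    total_area = float(sum(m.area_calcium_mm2 for m in measurements))
    return CTCalciumResult(
        per_slice=measurements,
        ct_calcium_score=float(sum(m.score for m in measurements)),
        ct_calcium_volume=total_area,
        ct_calcium_volume_mm3=total_area * stack.slice_spacing_mm,
        axis_label=stack.axis_label,
    )
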