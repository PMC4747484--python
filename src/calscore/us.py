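"""Gray-scale ultrasound calcium scoring.

Each B-mode slice is restricted to a wide region of interest drawn around
the deposit, calcium is selected by a global pixel-value threshold
(default 130, chosen above the maximum gray-scale density of agar), and the
slice score is ``area_calcium x PV_max``.  Slice scores are summed over the
stack, the procedure is repeated for short-axis and long-axis sweeps, and
the mean of the two axis totals is the US calcium score.  The US calcium
volume is the corresponding mean of the summed areas.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    AxisLabel,
    ImageStack,
    Modality,
    ROISet,
    Region,
    SliceMeasurement,
    StackScore,
    US_THRESHOLD_PV,
    ValidationError,
    measure_slice,
    select_calcium_mask,
    zero_outside_roi,
)


@dataclass
class USCalciumResult:
    """Two-axis ultrasound result: per-axis stack scores and their means."""

    short_axis: StackScore
    long_axis: StackScore
    us_calcium_score: float
    us_calcium_volume: float
    us_calcium_volume_mm3: float


def score_slice_us(
    image,
    region: Region,
    pixel_spacing_mm: tuple[float, float],
    threshold: float = US_THRESHOLD_PV,
    slice_index: int = 0,
) -> SliceMeasurement:
    """Score one ultrasound slice: zero outside ROI, threshold, area x PV_max."""
    restricted = zero_outside_roi(image, region)
    mask = select_calcium_mask(restricted, threshold)
    m = measure_slice(mask, restricted, pixel_spacing_mm, slice_index=slice_index)
    m.score = m.area_calcium_mm2 * m.pv_max
    return m


def score_stack_us(
    stack: ImageStack,
    rois: ROISet,
    threshold: float = US_THRESHOLD_PV,
) -> StackScore:
    """Sum slice scores and areas over a one-axis ultrasound stack.

    Slices without a region contribute (0, 0, 0), as do slices whose mask is
    empty; the totals are therefore sums over the slices that contain
    calcium.
    """
    if stack.modality is not Modality.US:
        raise ValidationError(f"expected an US stack; got modality {stack.modality}")
    measurements = []
    for i in range(stack.n_slices):
        region = rois.get(i)
        if region is None:
            measurements.append(SliceMeasurement(i, 0.0, 0.0, 0.0))
            continue
        measurements.append(
            score_slice_us(
                stack.pixels[i],
                region,
                stack.pixel_spacing_mm,
                threshold=threshold,
                slice_index=i,
            )
        )
    return StackScore.from_slices(
        measurements, stack.slice_spacing_mm, axis_label=stack.axis_label
    )


def combine_axes(short: StackScore, long: StackScore) -> USCalciumResult:
    """Average the short-axis and long-axis stack totals."""
    if short.axis_label is not AxisLabel.SHORT or long.axis_label is not AxisLabel.LONG:
        raise ValidationError(
            "combine_axes needs one short-axis and one long-axis stack "
            f"(got {short.axis_label.value!r} and {long.axis_label.value!r})"
        )
    return USCalciumResult(
        short_axis=short,
        long_axis=long,
        us_calcium_score=(short.total_score + long.total_score) / 2.0,
        us_calcium_volume=(short.total_volume_index + long.total_volume_index) / 2.0,
        us_calcium_volume_mm3=(short.total_volume_mm3 + long.total_volume_mm3) / 2.0,
    )
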