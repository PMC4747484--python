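"""Calibrated integrated-backscatter (cIB) calcium scoring.

Integrated backscatter (IB) is the average backscattered ultrasound energy,
in decibels, inside a region of interest.  Per slice, IB is measured in an
ellipse delineating the calcium deposit and, for calibration, in a small
circular agar reference region above it; the calibrated value is
``cIB = (IB_calcium - IB_agar) x area`` with the ellipse area
``(d_long / 2)(d_short / 2) pi``.  Axis sums over the short- and long-axis
sweeps are averaged into the cIB calcium score.  IB readings themselves are
measurement inputs (per-slice CSV); this module only performs the score
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .core import ValidationError


@dataclass(frozen=True)
class IBReading:
    """One slice's IB measurements and the delineating ellipse diameters (mm)."""

    slice_index: int
    ib_calcium_db: float
    ib_agar_db: float
    d_long_mm: float
    d_short_mm: float

    def __post_init__(self) -> None:
        if not self.d_short_mm > 0:
            raise ValidationError("ellipse diameters must be strictly positive")
        if self.d_long_mm < self.d_short_mm:
            raise ValidationError("d_long_mm must be >= d_short_mm")


@dataclass(frozen=True)
class CIBResult:
    short_axis_sum: float
    long_axis_sum: float
    cib_calcium_score: float


def ellipse_area(d_long_mm: float, d_short_mm: float) -> float:
    """Area of an ellipse from its two diameters: (d_long/2)(d_short/2) pi."""
    if d_long_mm <= 0 or d_short_mm <= 0:
        raise ValidationError("ellipse diameters must be strictly positive")
    return (d_long_mm / 2.0) * (d_short_mm / 2.0) * math.pi


def cib_slice(reading: IBReading) -> float:
    """Calibrated IB of one slice: (IB_calcium - IB_agar) x ellipse area.

    A deposit dimmer than the agar reference yields a negative value, which
    is preserved.
    """
    contrast = reading.ib_calcium_db - reading.ib_agar_db
    return contrast * ellipse_area(reading.d_long_mm, reading.d_short_mm)


def cib_score(
    short_readings: Sequence[IBReading],
    long_readings: Sequence[IBReading],
) -> CIBResult:
    """Sum cIB per axis and average the two axis sums."""
    if not short_readings or not long_readings:
        raise ValidationError("cib_score needs at least one reading per axis")
    short_sum = float(sum(cib_slice(r) for r in short_readings))
    long_sum = float(sum(cib_slice(r) for r in long_readings))
    return CIBResult(
        short_axis_sum=short_sum,
        long_axis_sum=long_sum,
        cib_calcium_score=(short_sum + long_sum) / 2.0,
    )
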