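"""Readers and writers: image stacks, ROI files, score tables, manifests.

Stacks travel as multi-page TIFF (uint8 for ultrasound, uint16 for CT) or
NPZ, always accompanied by a JSON sidecar carrying the physical metadata
(modality, spacings, pixel-value range, axis label and, for CT, the
water/air calibration).  DICOM series are read with pydicom; when rescale
slope/intercept tags are present the pixels are converted to Hounsfield
units directly and the water/air calibration is bypassed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from . import __version__
from .cib import IBReading
from .core import (
    AxisLabel,
    CTCalibration,
    FormatError,
    ImageStack,
    Modality,
    ROISet,
    SliceMeasurement,
    ValidationError,
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


# --------------------------------------------------------------------------
# Image stacks
# --------------------------------------------------------------------------

def write_stack(
    stack: ImageStack,
    path: str | Path,
    calibration: Optional[CTCalibration] = None,
) -> Path:
    """Write a stack as multi-page TIFF or NPZ plus its JSON sidecar."""
    path = Path(path)
    dtype = np.uint8 if stack.modality is Modality.US else np.uint16
    if stack.hu_scaled:
        dtype = np.float32
    pixels = stack.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        if stack.hu_scaled:
            raise FormatError("HU-scaled stacks must be written as NPZ, not TIFF")
        tifffile.imwrite(path, pixels, photometric="minisblack")
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, pixels=pixels)
    else:
        raise FormatError(f"unsupported stack format {path.suffix!r} (use .tif/.tiff/.npz)")
    sidecar = {
        "modality": stack.modality.value,
        "pixel_spacing_mm": list(stack.pixel_spacing_mm),
        "slice_spacing_mm": stack.slice_spacing_mm,
        "pv_range": list(stack.pv_range),
        "axis_label": stack.axis_label.value,
        "hu_scaled": stack.hu_scaled,
    }
    if calibration is not None:
        sidecar["calibration"] = {"pv_water": calibration.pv_water, "pv_air": calibration.pv_air}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def read_stack(
    path: str | Path,
    sidecar: Optional[str | Path] = None,
) -> tuple[ImageStack, Optional[CTCalibration]]:
    """Read a TIFF/NPZ stack and its sidecar; returns (stack, calibration)."""
    path = Path(path)
    sidecar_path = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path} for stack {path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable sidecar {sidecar_path}: {exc}") from exc
    for key in ("modality", "pixel_spacing_mm", "slice_spacing_mm"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} missing required key {key!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    elif path.suffix.lower() == ".npz":
        with np.load(path) as data:
            pixels = data["pixels"]
    else:
        raise FormatError(f"unsupported stack format {path.suffix!r}")
    if pixels.ndim == 2:
        pixels = pixels[None]
    stack = ImageStack(
        pixels=pixels,
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        slice_spacing_mm=float(meta["slice_spacing_mm"]),
        modality=Modality(meta["modality"]),
        pv_range=tuple(meta["pv_range"]) if "pv_range" in meta else None,
        axis_label=AxisLabel(meta.get("axis_label", "none")),
        hu_scaled=bool(meta.get("hu_scaled", False)),
    )
    cal = None
    if "calibration" in meta:
        cal = CTCalibration(
            pv_water=float(meta["calibration"]["pv_water"]),
            pv_air=float(meta["calibration"]["pv_air"]),
        )
    return stack, cal


def read_dicom_series(directory: str | Path) -> tuple[ImageStack, Optional[CTCalibration]]:
    """Read a DICOM series directory into an :class:`ImageStack`.

    Slices are ordered by InstanceNumber.  When RescaleSlope/Intercept are
    present the pixel values are converted to Hounsfield units, the stack is
    flagged ``hu_scaled`` and the returned calibration is the identity HU
    anchor (water 0, air -1000), so downstream scoring needs no separate
    water/air calibration.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no .dcm files found in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    modalities = {str(getattr(d, "Modality", "CT")) for d in datasets}
    if len(modalities) > 1:
        raise FormatError(f"mixed-modality DICOM series: {sorted(modalities)}")
    modality = Modality.US if modalities == {"US"} else Modality.CT

    first = datasets[0]
    spacing = getattr(first, "PixelSpacing", [1.0, 1.0])
    slice_spacing = float(
        getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 1.0))
    )
    has_rescale = hasattr(first, "RescaleSlope") or hasattr(first, "RescaleIntercept")
    frames = []
    for d in datasets:
        arr = d.pixel_array.astype(float)
        if has_rescale:
            arr = arr * float(getattr(d, "RescaleSlope", 1.0)) + float(
                getattr(d, "RescaleIntercept", 0.0)
            )
        frames.append(arr)
    pixels = np.stack(frames)
    hu_scaled = bool(has_rescale and modality is Modality.CT)
    stack = ImageStack(
        pixels=pixels,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        slice_spacing_mm=slice_spacing,
        modality=modality,
        pv_range=(float(pixels.min()), float(pixels.max())) if hu_scaled else None,
        hu_scaled=hu_scaled,
    )
    cal = CTCalibration(pv_water=0.0, pv_air=-1000.0) if hu_scaled else None
    return stack, cal


# --------------------------------------------------------------------------
# ROI files
# --------------------------------------------------------------------------

def read_rois(path: str | Path) -> ROISet:
    """Read a ROI JSON file: {"kind": ..., "regions": {slice: region}}."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable ROI file {path}: {exc}") from exc
    if "regions" not in data:
        raise FormatError(f"ROI file {path} missing 'regions'")
    return ROISet(
        regions={int(k): v for k, v in data["regions"].items()},
        kind=data.get("kind", "explicit_per_slice"),
    )


def write_rois(rois: ROISet, path: str | Path) -> Path:
    path = Path(path)
    payload = {"kind": rois.kind, "regions": {str(k): v for k, v in sorted(rois.regions.items())}}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


# --------------------------------------------------------------------------
# Scores
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_scores(result, csv_path: str | Path, json_path: Optional[str | Path] = None) -> Path:
    """Write per-slice measurements as CSV and stack totals as JSON.

    ``result`` is a ``StackScore``, ``USCalciumResult``, ``CTCalciumResult``
    or ``CIBResult``.  Column order is fixed and floats are written with six
    significant digits, so identical inputs produce byte-identical files.
    """
    csv_path = Path(csv_path)
    per_slice: list[SliceMeasurement] = []
    totals: dict[str, float] = {}
    ct_columns = False
    if hasattr(result, "us_calcium_score"):  # USCalciumResult
        per_slice = list(result.short_axis.per_slice) + list(result.long_axis.per_slice)
        totals = {
            "us_calcium_score": result.us_calcium_score,
            "us_calcium_volume": result.us_calcium_volume,
            "us_calcium_volume_mm3": result.us_calcium_volume_mm3,
            "short_axis_total_score": result.short_axis.total_score,
            "long_axis_total_score": result.long_axis.total_score,
        }
    elif hasattr(result, "ct_calcium_score"):  # CTCalciumResult
        per_slice = list(result.per_slice)
        ct_columns = True
        totals = {
            "ct_calcium_score": result.ct_calcium_score,
            "ct_calcium_volume": result.ct_calcium_volume,
            "ct_calcium_volume_mm3": result.ct_calcium_volume_mm3,
        }
    elif hasattr(result, "cib_calcium_score"):  # CIBResult
        totals = {
            "short_axis_sum": result.short_axis_sum,
            "long_axis_sum": result.long_axis_sum,
            "cib_calcium_score": result.cib_calcium_score,
        }
    elif hasattr(result, "total_score"):  # bare StackScore
        per_slice = list(result.per_slice)
        totals = {
            "total_score": result.total_score,
            "total_volume_index": result.total_volume_index,
            "total_volume_mm3": result.total_volume_mm3,
        }
    else:
        raise ValidationError(f"cannot serialize result of type {type(result).__name__}")

    header = ["slice_index", "area_calcium_mm2", "pv_max", "score"]
    if ct_columns:
        header = ["slice_index", "area_calcium_mm2", "pv_max", "hu_max", "wf", "ccs"]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for m in per_slice:
            if ct_columns:
                writer.writerow(
                    [m.slice_index, _fmt(m.area_calcium_mm2), _fmt(m.pv_max),
                     _fmt(m.hu_max or 0.0), m.wf or 0, _fmt(m.score)]
                )
            else:
                writer.writerow(
                    [m.slice_index, _fmt(m.area_calcium_mm2), _fmt(m.pv_max), _fmt(m.score)]
                )
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps({k: float(_fmt(v)) for k, v in totals.items()}, indent=2, sort_keys=True)
            + "\n"
        )
    return csv_path


def write_score_table(table, path: str | Path) -> Path:
    """Write the tidy per-deposit score table deterministically."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["speck_id", "mass_mg", "method", "value"])
        for _, row in table.iterrows():
            writer.writerow(
                [int(row["speck_id"]), _fmt(row["mass_mg"]), row["method"], _fmt(row["value"])]
            )
    return path


def read_score_table(path: str | Path):
    import pandas as pd

    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas raises various types
        raise FormatError(f"unreadable score table {path}: {exc}") from exc
    missing = {"speck_id", "mass_mg", "method", "value"} - set(table.columns)
    if missing:
        raise FormatError(f"score table {path} missing columns {sorted(missing)}")
    return table


def read_ib_csv(path: str | Path) -> dict[str, list[IBReading]]:
    """Read per-slice IB readings; returns readings grouped by axis label.

    Expected columns: slice_index, axis, ib_calcium_db, ib_agar_db,
    d_long_mm, d_short_mm.
    """
    import pandas as pd

    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"unreadable IB readings file {path}: {exc}") from exc
    required = {"slice_index", "axis", "ib_calcium_db", "ib_agar_db", "d_long_mm", "d_short_mm"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"IB readings {path} missing columns {sorted(missing)}")
    grouped: dict[str, list[IBReading]] = {}
    for _, row in table.iterrows():
        grouped.setdefault(str(row["axis"]), []).append(
            IBReading(
                slice_index=int(row["slice_index"]),
                ib_calcium_db=float(row["ib_calcium_db"]),
                ib_agar_db=float(row["ib_agar_db"]),
                d_long_mm=float(row["d_long_mm"]),
                d_short_mm=float(row["d_short_mm"]),
            )
        )
    return grouped


def write_ib_csv(readings_by_axis: dict[str, list[IBReading]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "axis", "ib_calcium_db", "ib_agar_db", "d_long_mm", "d_short_mm"])
        for axis in sorted(readings_by_axis):
            for r in readings_by_axis[axis]:
                writer.writerow(
                    [r.slice_index, axis, _fmt(r.ib_calcium_db), _fmt(r.ib_agar_db),
                     _fmt(r.d_long_mm), _fmt(r.d_short_mm)]
                )
    return path


# --------------------------------------------------------------------------
# Run manifest
# --------------------------------------------------------------------------

@dataclass
class Manifest:
    """Self-describing record of a simulation/scoring run."""

    run_id: str
    seed: int
    modality: str
    geometry: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)
    version: str = __version__

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
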