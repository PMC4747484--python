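"""Synthetic agar-phantom renderer with known calcium masses.

The simulated object is a 100 x 100 x 25 mm agar block containing nine
rectangular pockets of 15 x 3 x 5 mm, their tops 10 mm below the surface,
each holding a known mass of dry hydroxyapatite powder (2, 4, 6, 8, 10,
20, 30, 40 and 50 mg by default).  Spreading a dry powder evenly in a
pocket produces a level layer at the powder's bulk packing density, so the
simulator models each deposit as a slab filling the pocket from the bottom:
the 50 mg deposit fills the pocket completely, fixing the packing density
at 50/225 mg/mm^3, and smaller masses form proportionally thinner layers.

Three renderers share this geometry:

* :func:`render_us` -- B-mode slices (0--250 gray scale) stepped every
  millimetre along either probe axis.  Agar is Rayleigh speckle kept below
  the 130 calcium threshold; deposit pixels take a mean intensity that
  rises with the column areal density and saturates towards 250,
  emulating the plateau of the gray-scale score at high masses.  Optional
  acoustic shadowing attenuates everything below a deposit.
* :func:`render_ct` -- micro-CT slices (83 um pixels) with a water/air
  pixel-value calibration; agar sits near water density and the deposit at
  the packing density's Hounsfield value, with optional Gaussian noise and
  partial-volume blur.
* :func:`render_ib` -- synthetic per-slice integrated-backscatter readings
  whose calcium/agar contrast grows logarithmically with areal density.

Every renderer also returns a :class:`GroundTruth` with per-slice binary
deposit masks, so threshold-selection and parameter-recovery behaviour can
be checked against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    AxisLabel,
    CTCalibration,
    ImageStack,
    Modality,
    ROISet,
    US_THRESHOLD_PV,
    ValidationError,
)
from .cib import IBReading
from .ct import pv_from_hu

# --------------------------------------------------------------------------
# Geometry defaults (mm)
# --------------------------------------------------------------------------

PAPER_MASSES_MG = (2.0, 4.0, 6.0, 8.0, 10.0, 20.0, 30.0, 40.0, 50.0)
BLOCK_DIMS_MM = (100.0, 100.0, 25.0)  # (x, y, z); z measured down from the surface
HOLE_DIMS_MM = (15.0, 3.0, 5.0)  # (long, short, vertical)
HOLE_TOP_DEPTH_MM = 10.0  # depth of the pocket top below the surface
#: Bulk packing density of the powder: the largest deposit fills its pocket.
PACKING_DENSITY_MG_MM3 = 50.0 / (15.0 * 3.0 * 5.0)


@dataclass(frozen=True)
class Speck:
    """One calcium deposit: nominal mass and pocket placement."""

    mass_mg: float
    center_xy_mm: tuple[float, float]
    dims_mm: tuple[float, float, float] = HOLE_DIMS_MM
    depth_mm: float = HOLE_TOP_DEPTH_MM

    def __post_init__(self) -> None:
        if self.mass_mg < 0:
            raise ValidationError("speck mass must be non-negative")

    @property
    def z_span_mm(self) -> tuple[float, float]:
        return self.depth_mm, self.depth_mm + self.dims_mm[2]

    def fill_height_mm(self, packing_density: float = PACKING_DENSITY_MG_MM3) -> float:
        """Thickness of the settled powder layer at the pocket bottom."""
        if self.mass_mg == 0:
            return 0.0
        footprint = self.dims_mm[0] * self.dims_mm[1]
        return min(self.mass_mg / (packing_density * footprint), self.dims_mm[2])

    def areal_density_mg_mm2(self) -> float:
        """Mass per unit footprint area seen by a vertical beam."""
        return self.mass_mg / (self.dims_mm[0] * self.dims_mm[1])


@dataclass
class PhantomScene:
    """The full phantom: deposits, block geometry and the master RNG seed."""

    specks: list[Speck]
    block_dims_mm: tuple[float, float, float] = BLOCK_DIMS_MM
    rng_seed: int = 0
    packing_density_mg_mm3: float = PACKING_DENSITY_MG_MM3

    def __post_init__(self) -> None:
        for s in self.specks:
            x, y = s.center_xy_mm
            hx, hy = s.dims_mm[0] / 2, s.dims_mm[1] / 2
            z0, z1 = s.z_span_mm
            if (
                x - hx < 0
                or x + hx > self.block_dims_mm[0]
                or y - hy < 0
                or y + hy > self.block_dims_mm[1]
                or z0 < 0
                or z1 > self.block_dims_mm[2]
            ):
                raise ValidationError(f"speck at {s.center_xy_mm} extends outside the block")
        for i, a in enumerate(self.specks):
            for b in self.specks[i + 1 :]:
                if (
                    abs(a.center_xy_mm[0] - b.center_xy_mm[0]) < (a.dims_mm[0] + b.dims_mm[0]) / 2
                    and abs(a.center_xy_mm[1] - b.center_xy_mm[1]) < (a.dims_mm[1] + b.dims_mm[1]) / 2
                ):
                    raise ValidationError("specks overlap")


def default_scene(seed: int = 0, masses_mg: Optional[Sequence[float]] = None) -> PhantomScene:
    """The nine-deposit phantom with masses 2--50 mg in a row of pockets.

    Pockets are centred at x = 50 mm and spaced 10 mm centre-to-centre along
    y, which keeps the full row inside the stated 100 mm block.
    """
    masses = tuple(PAPER_MASSES_MG if masses_mg is None else masses_mg)
    n = len(masses)
    y0 = (BLOCK_DIMS_MM[1] - (n - 1) * 10.0) / 2.0
    specks = [
        Speck(mass_mg=float(m), center_xy_mm=(BLOCK_DIMS_MM[0] / 2.0, y0 + 10.0 * i))
        for i, m in enumerate(masses)
    ]
    return PhantomScene(specks=specks, rng_seed=int(seed))


@dataclass
class GroundTruth:
    """Per-stack truth: nominal mass, per-slice deposit masks, effective density.

    ``density_mg_per_mm3`` is chosen so that (mask voxel volume) x density
    reproduces the nominal mass exactly; it equals the nominal packing
    density whenever the layer boundaries align with the voxel grid and
    deviates only by the rasterization of the layer thickness otherwise.
    """

    mass_mg: float
    masks: np.ndarray  # (n_slices, rows, cols) bool
    density_mg_per_mm3: float
    speck_index: int = 0

    def voxel_volume_mm3(self, pixel_spacing_mm: tuple[float, float], slice_spacing_mm: float) -> float:
        return float(self.masks.sum()) * pixel_spacing_mm[0] * pixel_spacing_mm[1] * slice_spacing_mm


# --------------------------------------------------------------------------
# Noise parameterisations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class USNoise:
    """Ultrasound texture parameters.

    ``speckle`` draws the agar background from a Rayleigh distribution
    (scale ``agar_sigma_pv``, clipped below the calcium threshold) and
    perturbs deposit pixels with Gaussian noise of ``calcium_sigma_pv``.
    ``shadow_db_per_mm`` attenuates every pixel beneath a deposit layer by
    that many decibels per millimetre of depth below it (0 disables
    shadowing).
    """

    speckle: bool = True
    agar_sigma_pv: float = 32.0
    calcium_sigma_pv: float = 8.0
    shadow_db_per_mm: float = 0.0
    agar_level_pv: float = 40.0

    @classmethod
    def none(cls) -> "USNoise":
        return cls(speckle=False, agar_sigma_pv=0.0, calcium_sigma_pv=0.0, shadow_db_per_mm=0.0)

    def __post_init__(self) -> None:
        if self.agar_sigma_pv < 0 or self.calcium_sigma_pv < 0 or self.shadow_db_per_mm < 0:
            raise ValidationError("US noise parameters must be non-negative")
        if not 0 <= self.agar_level_pv < US_THRESHOLD_PV:
            raise ValidationError("agar_level_pv must lie below the calcium threshold")


@dataclass(frozen=True)
class CTNoise:
    """CT noise: additive Gaussian HU noise and partial-volume Gaussian blur."""

    sigma_hu: float = 25.0
    blur_sigma_px: float = 0.5

    @classmethod
    def none(cls) -> "CTNoise":
        return cls(sigma_hu=0.0, blur_sigma_px=0.0)

    def __post_init__(self) -> None:
        if self.sigma_hu < 0 or self.blur_sigma_px < 0:
            raise ValidationError("CT noise parameters must be non-negative")


# --------------------------------------------------------------------------
# Shared geometry helpers
# --------------------------------------------------------------------------

_LATERAL_MARGIN_MM = 5.0


def _axis_geometry(speck: Speck, axis: AxisLabel) -> tuple[int, float, float]:
    """(lateral axis index, step-axis centre, lateral extent) for a sweep.

    Long-axis images keep the probe's long axis parallel to the deposit's
    15 mm axis (in-plane lateral = x, stepping along y); short-axis images
    are perpendicular (in-plane lateral = y, stepping along x).
    """
    if axis is AxisLabel.LONG:
        return 0, speck.center_xy_mm[1], speck.dims_mm[0]
    if axis is AxisLabel.SHORT:
        return 1, speck.center_xy_mm[0], speck.dims_mm[1]
    raise ValidationError("axis must be 'short' or 'long'")


def _slice_positions(lo: float, hi: float, step: float, margin: float) -> np.ndarray:
    k0 = math.ceil((lo - margin) / step)
    k1 = math.floor((hi + margin) / step)
    return np.arange(k0, k1 + 1) * step


def _centers(extent: float, spacing: float, origin: float = 0.0) -> np.ndarray:
    n = int(round(extent / spacing))
    return origin + (np.arange(n) + 0.5) * spacing


def us_mean_intensity(
    areal_density_mg_mm2: float,
    rho_sat_mg_mm2: float = 3.0,
    base_pv: float = float(US_THRESHOLD_PV),
    top_pv: float = 250.0,
) -> float:
    """Mean deposit brightness: rises from the threshold and saturates at top.

    ``base + (top - base) (1 - exp(-rho / rho_sat))`` -- nearly linear over
    the 2--40 mg range with the default saturation scale and visibly bending
    towards the 250 ceiling only above that.
    """
    return base_pv + (top_pv - base_pv) * (1.0 - math.exp(-areal_density_mg_mm2 / rho_sat_mg_mm2))


def _rng_for(scene: PhantomScene, speck_index: int, axis: AxisLabel, channel: int) -> np.random.Generator:
    axis_code = {"short": 0, "long": 1, "none": 2}[axis.value]
    return np.random.default_rng([int(scene.rng_seed), int(speck_index), axis_code, channel])


# --------------------------------------------------------------------------
# Renderers
# --------------------------------------------------------------------------

def render_us(
    scene: PhantomScene,
    axis: str | AxisLabel,
    speck_index: int = 0,
    pixel_spacing_mm: float = 0.1,
    slice_step_mm: float = 1.0,
    noise: Optional[USNoise] = None,
    threshold_pv: float = float(US_THRESHOLD_PV),
    rho_sat_mg_mm2: float = 3.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render the B-mode sweep of one deposit along one probe axis.

    Returns the image stack (rows = depth below the surface, columns =
    lateral position, one slice per millimetre of phantom translation with
    one agar-only slice of margin at each end) and the matching ground
    truth.  With ``noise=USNoise.none()`` every deposit pixel is at least
    the calcium threshold and every agar pixel is below it, so global
    thresholding recovers the ground-truth mask exactly.
    """
    axis = AxisLabel(axis)
    noise = USNoise() if noise is None else noise
    speck = scene.specks[speck_index]
    lat_axis, _, lat_extent = _axis_geometry(speck, axis)

    # stepping span: the deposit extent along the translation axis
    step_axis = 1 - lat_axis  # x<->y complement
    half_step_extent = speck.dims_mm[step_axis] / 2.0
    s_center = speck.center_xy_mm[step_axis]
    s0, s1 = s_center - half_step_extent, s_center + half_step_extent
    positions = _slice_positions(s0, s1, slice_step_mm, slice_step_mm)

    lat_center = speck.center_xy_mm[lat_axis]
    lat0 = lat_center - lat_extent / 2.0 - _LATERAL_MARGIN_MM
    lat_w = lat_extent + 2.0 * _LATERAL_MARGIN_MM
    col_centers = _centers(lat_w, pixel_spacing_mm, origin=lat0)
    row_centers = _centers(scene.block_dims_mm[2], pixel_spacing_mm)

    z_top, z_bot = speck.z_span_mm
    h = speck.fill_height_mm(scene.packing_density_mg_mm3)
    mu = us_mean_intensity(
        speck.areal_density_mg_mm2(), rho_sat_mg_mm2, base_pv=threshold_pv
    )

    in_lat = (col_centers >= lat_center - lat_extent / 2.0) & (
        col_centers < lat_center + lat_extent / 2.0
    )
    in_fill_rows = (row_centers >= z_bot - h) & (row_centers < z_bot)

    rng = _rng_for(scene, speck_index, axis, channel=0)
    n_rows, n_cols = row_centers.size, col_centers.size
    slices = np.empty((positions.size, n_rows, n_cols), dtype=np.uint8)
    masks = np.zeros_like(slices, dtype=bool)

    for i, p in enumerate(positions):
        if noise.speckle:
            agar = rng.rayleigh(noise.agar_sigma_pv, size=(n_rows, n_cols))
            img = np.minimum(agar, threshold_pv - 1.0)
        else:
            img = np.full((n_rows, n_cols), noise.agar_level_pv, dtype=float)
        fill = np.zeros((n_rows, n_cols), dtype=bool)
        if h > 0 and s0 <= p < s1:
            fill = np.outer(in_fill_rows, in_lat)
            vals = np.full(int(fill.sum()), mu)
            if noise.speckle and noise.calcium_sigma_pv > 0:
                vals = vals + rng.normal(0.0, noise.calcium_sigma_pv, size=vals.size)
            img[fill] = vals
            if noise.shadow_db_per_mm > 0:
                below = row_centers >= z_bot
                depth_below = (row_centers[below] - z_bot)[:, None]
                atten = 10.0 ** (-noise.shadow_db_per_mm * depth_below / 20.0)
                shadow_cols = in_lat
                img[np.ix_(below, shadow_cols)] *= atten
        slices[i] = np.clip(np.floor(img + 0.5), 0, 250).astype(np.uint8)
        masks[i] = fill

    stack = ImageStack(
        pixels=slices,
        pixel_spacing_mm=(pixel_spacing_mm, pixel_spacing_mm),
        slice_spacing_mm=slice_step_mm,
        modality=Modality.US,
        axis_label=axis,
    )
    gt = _ground_truth(speck, masks, (pixel_spacing_mm, pixel_spacing_mm), slice_step_mm, speck_index)
    return stack, gt


def render_ct(
    scene: PhantomScene,
    cal: CTCalibration,
    speck_index: int = 0,
    pixel_spacing_mm: float = 0.083,
    slice_step_mm: float = 1.0,
    noise: Optional[CTNoise] = None,
    agar_hu: float = 30.0,
    hu_offset: float = 700.0,
    hu_per_density: float = 12600.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render the micro-CT cross-sections through one deposit.

    Slices step along the deposit's short (3 mm) axis; rows are depth,
    columns the 15 mm long axis.  Agar sits near water density and the
    settled powder layer at ``hu_offset + hu_per_density x packing density``
    (3500 HU with the defaults), so every deposit pixel clears the 700 HU
    selection threshold.  Pixel values come from the water/air calibration
    and are clipped to the 16-bit range.
    """
    noise = CTNoise() if noise is None else noise
    speck = scene.specks[speck_index]
    lat_center = speck.center_xy_mm[0]
    lat_extent = speck.dims_mm[0]
    s_center = speck.center_xy_mm[1]
    s0, s1 = s_center - speck.dims_mm[1] / 2.0, s_center + speck.dims_mm[1] / 2.0
    positions = _slice_positions(s0, s1, slice_step_mm, slice_step_mm)

    lat0 = lat_center - lat_extent / 2.0 - _LATERAL_MARGIN_MM
    col_centers = _centers(lat_extent + 2 * _LATERAL_MARGIN_MM, pixel_spacing_mm, origin=lat0)
    row_centers = _centers(scene.block_dims_mm[2], pixel_spacing_mm)

    z_top, z_bot = speck.z_span_mm
    h = speck.fill_height_mm(scene.packing_density_mg_mm3)
    fill_hu = hu_offset + hu_per_density * scene.packing_density_mg_mm3

    in_lat = (col_centers >= lat_center - lat_extent / 2.0) & (
        col_centers < lat_center + lat_extent / 2.0
    )
    in_fill_rows = (row_centers >= z_bot - h) & (row_centers < z_bot)

    rng = _rng_for(scene, speck_index, AxisLabel.NONE, channel=1)
    n_rows, n_cols = row_centers.size, col_centers.size
    slices = np.empty((positions.size, n_rows, n_cols), dtype=np.uint16)
    masks = np.zeros((positions.size, n_rows, n_cols), dtype=bool)

    for i, p in enumerate(positions):
        hu = np.full((n_rows, n_cols), agar_hu, dtype=float)
        fill = np.zeros((n_rows, n_cols), dtype=bool)
        if h > 0 and s0 <= p < s1:
            fill = np.outer(in_fill_rows, in_lat)
            hu[fill] = fill_hu
        if noise.blur_sigma_px > 0:
            hu = gaussian_filter(hu, noise.blur_sigma_px)
        if noise.sigma_hu > 0:
            hu = hu + rng.normal(0.0, noise.sigma_hu, size=hu.shape)
        pv = pv_from_hu(hu, cal)
        slices[i] = np.clip(np.floor(pv + 0.5), 0, 65535).astype(np.uint16)
        masks[i] = fill

    stack = ImageStack(
        pixels=slices,
        pixel_spacing_mm=(pixel_spacing_mm, pixel_spacing_mm),
        slice_spacing_mm=slice_step_mm,
        modality=Modality.CT,
    )
    gt = _ground_truth(speck, masks, (pixel_spacing_mm, pixel_spacing_mm), slice_step_mm, speck_index)
    return stack, gt


def render_ib(
    scene: PhantomScene,
    axis: str | AxisLabel,
    speck_index: int = 0,
    slice_step_mm: float = 1.0,
    baseline_db: float = -50.0,
    gain_db: float = 20.0,
    noise_sigma_db: float = 0.0,
) -> list[IBReading]:
    """Synthesize per-slice integrated-backscatter readings for one deposit.

    The calcium/agar contrast is ``gain x log1p(areal density)`` so the mean
    contrast grows monotonically with mass and is exactly zero for an empty
    pocket.  Ellipse diameters delineate the deposit cross-section in the
    image plane (lateral extent by layer thickness).
    """
    axis = AxisLabel(axis)
    speck = scene.specks[speck_index]
    lat_axis, _, lat_extent = _axis_geometry(speck, axis)
    step_axis = 1 - lat_axis
    s_center = speck.center_xy_mm[step_axis]
    half = speck.dims_mm[step_axis] / 2.0
    positions = _slice_positions(s_center - half, s_center + half, slice_step_mm, 0.0)
    positions = positions[(positions >= s_center - half) & (positions < s_center + half)]

    h = speck.fill_height_mm(scene.packing_density_mg_mm3)
    d_vert = h if h > 0 else speck.dims_mm[2]
    d_long = max(lat_extent, d_vert)
    d_short = min(lat_extent, d_vert)
    contrast = gain_db * math.log1p(speck.areal_density_mg_mm2())

    rng = _rng_for(scene, speck_index, axis, channel=2)
    readings = []
    for i, _ in enumerate(positions):
        eps_c = rng.normal(0.0, noise_sigma_db) if noise_sigma_db > 0 else 0.0
        eps_a = rng.normal(0.0, noise_sigma_db) if noise_sigma_db > 0 else 0.0
        readings.append(
            IBReading(
                slice_index=i,
                ib_calcium_db=baseline_db + contrast + eps_c,
                ib_agar_db=baseline_db + eps_a,
                d_long_mm=d_long,
                d_short_mm=d_short,
            )
        )
    return readings


def _ground_truth(
    speck: Speck,
    masks: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    slice_step_mm: float,
    speck_index: int,
) -> GroundTruth:
    volume = float(masks.sum()) * pixel_spacing_mm[0] * pixel_spacing_mm[1] * slice_step_mm
    density = speck.mass_mg / volume if volume > 0 else 0.0
    return GroundTruth(
        mass_mg=speck.mass_mg,
        masks=masks,
        density_mg_per_mm3=density,
        speck_index=speck_index,
    )


# --------------------------------------------------------------------------
# Convenience: wide ROIs and the full scene scoring table
# --------------------------------------------------------------------------

def rois_from_ground_truth(gt: GroundTruth, margin_px: int = 10) -> ROISet:
    """A wide rectangular ROI around the deposit, replicated on every slice.

    Mimics the manual workflow of drawing one generous box around the
    calcium: the union bounding box of the ground-truth masks, dilated by
    ``margin_px`` and clipped to the slice, is assigned to each slice.  An
    all-empty ground truth yields an empty ROI set (nothing is scored).
    """
    any_mask = gt.masks.any(axis=0)
    if not any_mask.any():
        return ROISet(regions={})
    rows = np.flatnonzero(any_mask.any(axis=1))
    cols = np.flatnonzero(any_mask.any(axis=0))
    n_rows, n_cols = any_mask.shape
    r0 = max(int(rows[0]) - margin_px, 0)
    r1 = min(int(rows[-1]) + 1 + margin_px, n_rows)
    c0 = max(int(cols[0]) - margin_px, 0)
    c1 = min(int(cols[-1]) + 1 + margin_px, n_cols)
    region = {"type": "rect", "coords": [r0, c0, r1, c1]}
    return ROISet(regions={i: dict(region) for i in range(gt.masks.shape[0])})


def score_scene(
    scene: PhantomScene,
    cal: Optional[CTCalibration] = None,
    us_noise: Optional[USNoise] = None,
    ct_noise: Optional[CTNoise] = None,
    ib_noise_sigma_db: float = 0.0,
    threshold_pv: float = float(US_THRESHOLD_PV),
    hu_threshold: float = 700.0,
    us_pixel_spacing_mm: float = 0.1,
    ct_pixel_spacing_mm: float = 0.083,
):
    """Simulate and score every deposit; return a tidy score table.

    Runs the full pipeline per deposit -- ultrasound sweeps on both axes,
    the micro-CT stack, and synthetic backscatter readings -- scores them
    with the package's own scoring routines, and returns a DataFrame with
    columns ``speck_id, mass_mg, method, value`` where method is one of
    ``US, US_volume, CT, CT_volume, cIB``.
    """
    import pandas as pd

    from .cib import cib_score
    from .ct import score_stack_ct
    from .us import combine_axes, score_stack_us

    cal = cal if cal is not None else CTCalibration(pv_water=1000.0, pv_air=0.0)
    rows = []
    for idx in range(len(scene.specks)):
        mass = scene.specks[idx].mass_mg
        axis_scores = {}
        for axis in (AxisLabel.SHORT, AxisLabel.LONG):
            stack, gt = render_us(
                scene, axis, speck_index=idx, pixel_spacing_mm=us_pixel_spacing_mm,
                noise=us_noise, threshold_pv=threshold_pv,
            )
            rois = rois_from_ground_truth(gt)
            axis_scores[axis] = score_stack_us(stack, rois, threshold=threshold_pv)
        us_result = combine_axes(axis_scores[AxisLabel.SHORT], axis_scores[AxisLabel.LONG])

        ct_stack, ct_gt = render_ct(
            scene, cal, speck_index=idx, pixel_spacing_mm=ct_pixel_spacing_mm, noise=ct_noise
        )
        ct_result = score_stack_ct(ct_stack, rois_from_ground_truth(ct_gt), cal, hu_threshold)

        short_ib = render_ib(scene, AxisLabel.SHORT, speck_index=idx, noise_sigma_db=ib_noise_sigma_db)
        long_ib = render_ib(scene, AxisLabel.LONG, speck_index=idx, noise_sigma_db=ib_noise_sigma_db)
        cib = cib_score(short_ib, long_ib)

        for method, value in (
            ("US", us_result.us_calcium_score),
            ("US_volume", us_result.us_calcium_volume),
            ("CT", ct_result.ct_calcium_score),
            ("CT_volume", ct_result.ct_calcium_volume),
            ("cIB", cib.cib_calcium_score),
        ):
            rows.append(
                {"speck_id": idx, "mass_mg": mass, "method": method, "value": float(value)}
            )
    return pd.DataFrame(rows, columns=["speck_id", "mass_mg", "method", "value"])
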