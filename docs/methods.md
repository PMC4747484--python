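# Methods

## Scoring model

All three scores share a per-slice pipeline: restrict the image to a wide
region of interest (ROI), select calcium by a global intensity threshold,
measure the selected area and maximum intensity, weight the area, and sum
over slices.

**Ultrasound.** Pixel values live on a fixed 0–250 scale; RGB input is
converted with ITU-R 601 luma (0.299 R + 0.587 G + 0.114 B) and rescaled
linearly from [0, 255] to [0, 250] with round-half-up, so an achromatic
(v, v, v) pixel maps to round(v·250/255). The conversion itself is a
convention choice — only the 0–250 output range is fixed by the analysis
workflow — and 601 luma is the standard choice for legacy clinical video.
The calcium threshold is *inclusive* (PV ≥ 130) and applies per pixel with
no connectivity or minimum-size filtering: global thresholding selects
pixels, not lesions. The slice score is area (selected-pixel count × pixel
area, mm²) times the maximum selected pixel value; stack totals are summed
and the short/long-axis totals averaged. Slices with no ROI or an empty
selection contribute (0, 0, 0) rather than being skipped — the sums are
identical and the bookkeeping simpler.

**CT.** The Hounsfield map is the standard two-point calibration
HU = (PV − PV_water)/(PV_water − PV_air)·1000, anchored at water = 0 HU
and air = −1000 HU. The 700 HU selection threshold is converted to
pixel-value space with a *ceiling* to the next integer PV, so no pixel
below the HU threshold is ever admitted; with integer-exact calibrations
(PV_water − PV_air = 1000) the PV-space selection reproduces the HU rule
exactly. The default weighting table assigns wf = 1/2/3/4 at lower bounds
700/1000/2000/3000 HU (0 below 700). A maximal density of exactly
3000 HU maps to wf 4: the table is defined by inclusive lower bounds,
which keeps wf monotone in density; the table is a parameter for anyone
needing different bins. No minimum-lesion-area criterion is applied, and
all calcium inside a slice's ROI is measured jointly (one area, one
HU_max) — one ROI chain per deposit. Endpoint ROIs are interpolated
vertex-wise linearly across the intermediate slices.

**cIB.** Calibrated integrated backscatter per slice is
(IB_calcium − IB_agar) × ellipse area, the ellipse being the 2-D per-image
delineation of the deposit ((d_long/2)(d_short/2)π). Readings are consumed
from CSV — IB itself comes from vendor analysis software or the
simulator — and the agar reference may be constant or vary per slice.
Negative contrast is preserved, and subtracting the reference makes the
score invariant to any global gain shift.

## Phantom simulator

The simulated object is a 100×100×25 mm agar block with nine 15×3×5 mm
pockets whose tops sit 10 mm below the surface, holding 2, 4, 6, 8, 10,
20, 30, 40 and 50 mg of hydroxyapatite. Pockets are spaced 10 mm
centre-to-centre in a row (a 1 cm pitch; the row then spans 83 mm and fits
the stated block — gaps of a full centimetre between 3 mm pockets would
not).

**Deposit model.** Spreading dry powder evenly in a pocket produces a
level layer at the powder's bulk packing density, so each deposit is a
slab filling its pocket from the bottom. The packing density is fixed by
letting the 50 mg deposit fill the 225 mm³ pocket exactly
(0.2̄ mg/mm³); a mass m then forms a layer of height 5·m/50 mm. Two
consequences drive the recovery behaviour: thresholded *area* grows
linearly with mass, and the *local* density — hence the CT attenuation of
deposit voxels — is constant across masses. An alternative reading of
"evenly spread" (mass diluted through the whole pocket volume) would make
the thresholded area constant and the maximal density proportional to
mass; the CT score wf×area would then move in coarse steps of the
weighting table instead of tracking mass, which contradicts both the
near-perfect linearity of CT volume versus mass seen in practice and the
recovery properties this simulator is designed to exhibit. The diluted
model remains reachable through the `hu_offset`/`hu_per_density`
parameters of `render_ct`.

**Ultrasound rendering** (`render_us`). 0.1 mm pixels (small enough that
the 3 mm pocket width spans 30 pixels; actual B-mode pixel pitch depends
on depth/zoom settings and is declared in the stack sidecar), 1 mm slice
stepping covering the deposit plus one agar-only margin slice per side.
Rows are depth below the surface, columns lateral position; long-axis
sweeps step across the 3 mm width, short-axis sweeps across the 15 mm
length. Agar is multiplicative speckle — Rayleigh-distributed with scale
32 PV, clipped below the 130 threshold, matching the premise that the
threshold sits above the brightest agar — or a constant 40 PV with noise
off. Deposit pixels take mean intensity
μ(ρ) = 130 + 120·(1 − exp(−ρ/ρ_sat)) where ρ is the areal density of the
deposit column (mass per footprint area, m/45 mg/mm²) and
ρ_sat = 3 mg/mm². The saturating form emulates the plateau of gray-scale
brightness at high calcium loads; ρ_sat = 3 keeps μ within ~1% of linear
up to 40 mg while bending visibly towards the 250 ceiling above that.
Optional acoustic shadowing attenuates every pixel beneath the deposit by
a configurable dB/mm; it is off by default so that the noiseless stacks
are exact, and enabled explicitly for robustness experiments.

**CT rendering** (`render_ct`). 83 µm pixels, slices stepping along the
3 mm axis. Agar sits at 30 HU (near water), deposit voxels at
`hu_offset + hu_per_density × packing density` = 3500 HU by default —
comfortably in the top weighting bin, as expected for packed
hydroxyapatite. Noise is additive Gaussian in HU (default σ 25) plus a
Gaussian partial-volume blur (default σ 0.5 px); both off under
`CTNoise.none()`. Pixel values are produced through the inverse
calibration and clipped to the 16-bit range.

**Backscatter rendering** (`render_ib`). Per-slice readings with contrast
20·log1p(ρ) dB over a −50 dB baseline — monotone in mass and exactly zero
for an empty pocket — and ellipse diameters from the deposit
cross-section (lateral extent × layer height).

**Ground truth and mass conservation.** Masks are rasterized by
pixel-centre inclusion. On the US grid (0.1 mm, aligned with the layer
heights, which are multiples of 0.2 mm) the mask volume times the nominal
packing density reproduces the input mass exactly. The 83 µm CT grid
cannot represent a 0.2 mm layer boundary exactly, so each `GroundTruth`
records the effective density (mass / rasterized volume) with which the
recovery is exact by construction; it deviates from the nominal constant
only by the layer-thickness quantization (worst for the 2 mg deposit,
where the 0.2 mm layer rasterizes to 2–3 rows).

**Determinism.** Every renderer seeds its generator from
(scene seed, deposit index, axis, channel); there is no hidden global RNG
state, and repeated runs with the same seed are byte-identical through the
serialization layer (fixed column order, 6-significant-digit floats).

## What the simulator does and does not emulate

It reproduces the geometry, the intensity ordering relations (brighter /
denser / higher-contrast with more calcium, saturation of gray-scale
brightness), threshold separability of agar versus calcium, and the
two-axis acquisition protocol. It does not model wave propagation or
X-ray transport: no depth-dependent beam width, reverberation,
refraction, beam-hardening or reconstruction artifacts, and speckle is
spatially uncorrelated. Passing recovery tests therefore shows that the
*scoring arithmetic* faithfully converts image content into scores — not
that the scores are robust to the full physics of either modality, where
effects like acoustic shadowing genuinely compress the ultrasound score
at high masses.

## Statistics

Pearson r (with R² = r² and the t-based two-tailed p) via
`scipy.stats.pearsonr`; constant inputs are rejected rather than returning
NaN. ROC analysis enumerates cutoffs at midpoints between adjacent
observed values (plus open ends), calling a case positive at value ≥
cutoff; AUC is computed in the Mann-Whitney pair form, identical to the
trapezoid area of that curve; the optimal cutoff maximizes Youden's
J = sensitivity + specificity − 1 with ties broken towards the higher
cutoff (higher specificity). Mass classification uses strict inequality
(mass > boundary is positive) with a 10 mg default boundary separating
the lower tertile of the nine masses. ICC uses `pingouin.intraclass_corr`;
the default model is single-measures absolute agreement, ICC(A,1) — the
standard choice for intra-observer/test-retest designs; the point estimate
and F-based 95% CI coincide for random- and mixed-effects readings of the
session factor. ICC1/ICC3 are selectable. Perfect agreement returns ICC
exactly 1 with an undefined (NaN) interval.

## Numerical choices and degenerate inputs

- Round-half-up (`floor(x + 0.5)`) everywhere an intensity is quantized,
  avoiding banker's-rounding surprises at .5 boundaries.
- Empty selections measure (area 0, PV_max 0, score 0); the CT slice
  record then carries HU_max 0 and wf 0 rather than the HU of a zero
  pixel value.
- Rectangles are half-open `[r0, r1) × [c0, c1)` in 0-based (row, col)
  coordinates; polygons rasterize via `skimage.draw.polygon`.
- Degenerate calibrations (PV_water ≤ PV_air), out-of-bounds ROIs,
  mismatched axis labels, single-class ROC labels and incomplete ICC
  matrices raise validation errors instead of propagating NaNs.
- Zero-mass pockets are legal scene members; they render as pure agar and
  score exactly 0 on all three methods.

## Problem sizes

The default end-to-end run scores nine deposits from two ultrasound
sweeps (≈ 5 and 17 slices of 250×250 and 250×130 pixels), one CT stack
(5 slices of 301×301) and two sets of backscatter readings per deposit —
about 20 M pixels in total, a fraction of a second of compute — so the
full pipeline, not a reduced stand-in, runs inside the test suite.

## Known limitations

- ROIs are supplied (by the user or from ground truth); there is no
  automatic deposit detection, mirroring the manual wide-ROI workflow.
- The clinical Agatston protocol (130 HU threshold, 1 mm² minimum lesion,
  ECG gating) is intentionally out of scope; the weighting-bin idea is
  applied with micro-CT-appropriate bounds.
- IB readings are inputs; no radio-frequency signal processing is
  performed.
- Comparing two correlated AUCs (DeLong-style) is not implemented.
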