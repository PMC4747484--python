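# calscore

Quantifying calcium with ultrasound and micro-CT in tissue-mimicking
phantoms.

Calcification burden drives prognosis and treatment decisions in calcific
aortic valve disease, but CT — the reference technique for calcium
quantification — is poorly suited to serial follow-up because of radiation.
A gray-scale B-mode ultrasound score offers a radiation-free alternative,
validated *in vitro* against agar phantoms containing known masses of
hydroxyapatite (Ca₅(PO₄)₃OH). `calscore` implements the three scoring
methods used in that setting, a synthetic phantom simulator with ground
truth, and the statistics used to validate scores against known masses. It
is aimed at researchers developing or benchmarking calcium-quantification
pipelines on phantom data.

## The scores

All three scores work slice-by-slice on image stacks swept across a
calcium deposit in 1 mm steps, within a wide region of interest (ROI)
drawn around the deposit:

- **US calcium score.** RGB frames are converted to a 0–250 gray scale
  (ITU-R 601 luma, rescaled). Pixels outside the ROI are zeroed, calcium is
  selected by global thresholding at PV ≥ 130 (above the maximum gray-scale
  density of agar), and each slice scores
  *area*₍calcium₎ × *PV*₍max₎. Slice scores are summed per stack; the mean
  of the short-axis and long-axis stack totals is the US calcium score, and
  the mean of the summed areas (∑ *area*₍calcium₎) is the US calcium
  volume.
- **CT calcium score** (Agatston-style). Raw micro-CT pixel values map to
  Hounsfield units through a water/air calibration,
  HU = (PV − PV_water)/(PV_water − PV_air) × 1000. Calcium is selected at
  ≥ 700 HU (agar excluded; consistent with dense bone/hydroxyapatite),
  with ROIs drawn on the first and last slice of the deposit and linearly
  interpolated in between. Per slice, the maximal density HU_max sets an
  integer weighting factor wf (1 from 700 HU, 2 from 1000, 3 from 2000,
  4 from 3000) and the slice calcification score is wf × area; scores and
  areas are summed over the stack.
- **cIB calcium score.** Integrated backscatter (IB, in dB) is measured in
  an ellipse delineating the deposit and calibrated against a small agar
  reference ROI: cIB = (IB₍calcium₎ − IB₍agar₎) × area, with
  area = (d_long/2)(d_short/2)π. Axis sums are averaged as for ultrasound.

The simulator renders the standard validation object: a 100×100×25 mm
agar block with nine 15×3×5 mm pockets holding 2–50 mg of hydroxyapatite,
imaged every millimetre along both probe axes (US) and at 83 µm pixel
pitch (micro-CT), with per-slice ground-truth masks.

## Worked example

Simulate, score and evaluate the full nine-deposit phantom without noise:

```bash
calscore all --seed 0 --out-dir demo --noise off
```

which logs

```
INFO calscore: [all-seed0] US: r2=0.9979 auc=1.0000
INFO calscore: [all-seed0] CT: r2=0.9997 auc=1.0000
INFO calscore: [all-seed0] US_volume: r2=1.0000 auc=1.0000
INFO calscore: [all-seed0] CT_volume: r2=0.9997 auc=1.0000
INFO calscore: [all-seed0] cIB: r2=0.9657 auc=1.0000
```

and writes `demo/score_table.csv` (per-deposit scores; e.g. the 2 mg
deposit scores US 1188, CT 44.9, cIB 6.15, rising monotonically to
US 37575, CT 912.7, cIB 2640.9 at 50 mg), `demo/evaluation.json`
(per-method Pearson R² against mass, ROC AUC for separating deposits
≤ 10 mg from > 10 mg, and the Youden-optimal cutoff with its
sensitivity/specificity — e.g. US cutoff 9742.5 at sensitivity 1.0 and
specificity 1.0) and a run manifest. R² near 1 means the score tracks the
true calcium mass linearly; AUC 1.0 means low- and high-mass deposits are
perfectly separable by the score.

The same pipeline is available from Python:

```python
import calscore as cs

scene = cs.default_scene(seed=0)
table = cs.score_scene(scene, us_noise=cs.USNoise.none(), ct_noise=cs.CTNoise.none())
print(cs.evaluate_scores(table, "US"))
```

Individual steps (`simulate`, `score-us`, `score-ct`, `score-cib`,
`evaluate`) operate on files — multi-page TIFF/NPZ stacks with JSON
sidecars, DICOM series (rescale slope/intercept honoured), ROI JSON, and
CSV tables; see `calscore --help`.

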