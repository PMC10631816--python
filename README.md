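# endooct

Quantitative analysis of endoscopic OCT / OCT-angiography scans of mucosal
tissue, built around two objective markers of vaginal health in the
genitourinary syndrome of menopause (GSM) and its laser treatment:

* **Blood vessel density (BVD)** — the fraction of en-face area occupied by
  detected blood flow, and
* **Vaginal epithelial thickness (VET)** — the depth extent, in micrometres,
  of the epithelium (the dark band between the bright surface reflection and
  the bright lamina propria in a structural B-scan).

Estrogen deficiency thins the epithelium and reduces vascularization, and
GSM assessment otherwise relies on subjective scores (the clinician-rated
Vaginal Health Index, VHI, and the patient-reported Vulvovaginal Symptom
Questionnaire, VSQ).  This package implements the full computational chain
that turns repeated-B-scan OCT amplitude volumes into BVD and VET and into
longitudinal cohort statistics — plus a speckle-realistic phantom and cohort
generator, so that every stage is verifiable against known ground truth
without any patient data.

## The methods

**Doppler-variance angiography.**  At each slow-axis position, J + 1
repeated B-scans are acquired.  For amplitudes `A_j` of the same voxel in
consecutive frames, the intensity-based Doppler variance is

    sigma^2 = 1 - [ sum_{j=1..J} A_j A_{j+1} ] / [ sum_{j=1..J} (A_j^2 + A_{j+1}^2) / 2 ]

which is 0 for static tissue (identical speckle across repeats) and rises
toward the fully-decorrelated Rayleigh limit `1 - pi/4 ≈ 0.2146` where
moving blood redraws the speckle between frames.  By AM-GM it always lies
in [0, 1].  Inter-frame pairing (same A-line across repeats) is the default;
intra-frame pairing (neighbouring A-lines) is available as an option.

**Vessel density.**  The variance volume is average-projected over a depth
slab to an en-face angiogram, enhanced with a multi-scale Hessian (Frangi)
vesselness filter (`exp(-Rb^2/2 beta^2) (1 - exp(-S^2/2 c^2))` on the
scale-normalized Hessian eigenvalues, bright-ridge polarity), binarized,
and BVD = vessel pixels / measured pixels.

**Epithelial thickness.**  A classical boundary tracker finds the surface
reflection as the brightest smooth path (dynamic programming with a
per-column jump constraint) and the lower epithelial boundary as the
strongest dark-to-bright axial gradient below it; thickness is the boundary
separation × 14 um/pixel.  A lightweight 3-level convolutional
encoder-decoder with skip connections (numpy, trained on the synthetic
generator, probability threshold 0.6) provides an alternative segmentation
path, evaluated with pixel accuracy, IoU and Dice.

**Cohort statistics.**  Tidy tables of (patient, visit 1-4, location ∈
{da, dp, pa, pp}) records are aggregated per visit and location; later
visits are compared to baseline with paired tests and annotated
`*** p<0.001 / ** p<0.01 / * p<0.05 / ns`; Pearson correlations between
the objective metrics and VHI/VSQ are classified by |r| as negligible
(< 0.1), weak (< 0.3), moderate (< 0.5) or strong (≥ 0.5).

## Worked example

`examples/02_vessel_density.py` builds a phantom whose true en-face vessel
fraction is 25% and runs the whole imaging chain on the rendered speckle
frames:

```
true en-face vessel fraction: 0.250
recovered BVD:                0.277 (4544/16384 px)
support threshold used:       0.0082
```

The recovered density differs from truth by 2.7 percentage points — within
the ±5 points the pipeline is tested to across fractions 10-30%.
`examples/03_epithelial_thickness.py` does the same for thickness:

```
true thickness   100 um -> measured mean VET  91.4 um (valid columns: 100%)
true thickness   150 um -> measured mean VET 147.9 um (valid columns: 100%)
true thickness   200 um -> measured mean VET 188.5 um (valid columns: 100%)
```

accurate to about one axial pixel (14 um).  The other examples cover
angiography contrast, cohort statistics and network training; each prints
and explains its numbers.

There is also a thin CLI mirroring the library stages:

```bash
endooct run-all --seed 7 --out out/demo
endooct simulate | octa | vessels | vet | stats   # individual stages
```

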