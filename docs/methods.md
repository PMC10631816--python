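# Methods

This note records the models implemented in `endooct`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Doppler-variance angiography (`ibdv`)

The flow statistic is the amplitude-only (intensity-based) Doppler
variance over J consecutive-frame pairs,

    sigma^2 = 1 - sum_j A_j A_{j+1} / sum_j (A_j^2 + A_{j+1}^2)/2 ,

optionally summed over a small lateral window before the ratio is taken.
Properties relied on throughout:

* AM-GM gives `A_j A_{j+1} <= (A_j^2 + A_{j+1}^2)/2` for non-negative
  amplitudes, so sigma^2 ∈ [0, 1] for any input — asserted on random data.
* For identical frames the numerator equals the denominator: sigma^2 = 0.
* For independent Rayleigh amplitudes, `E[A_j A_{j+1}] / E[A^2] =
  E[A]^2 / E[A^2] = pi/4`, so sigma^2 → 1 − pi/4 ≈ 0.2146 as J grows.
  This is the contrast ceiling for fully decorrelated blood flow.

Defaults: inter-frame pairing (same A-line across repeated B-scans; the
long inter-frame interval maximizes sensitivity to slow microvascular
flow), lateral window 3 (light denoising without visible resolution
loss), zero-denominator voxels defined as sigma^2 = 0 so signal-free
background stays dark.  Intra-frame pairing is exposed as a mode flag for
completeness; it is only sensitive to fast flow.

The en-face angiogram is the mean of sigma^2 over a half-open depth slab.
The default slab [40, 100) pixels was chosen for two reasons: it starts
below the deepest rendered surface position — air above the tissue carries
pure detection noise, which is fully decorrelated and would otherwise
contaminate the average with spurious signal — and it covers the depth
band where the generator places vessels (see below).  Repeat count,
window, and slab are configuration, not constants.

## Phantom generator (`phantom`)

The generator emulates exactly the features the pipeline exploits:

* **Layered structure.**  Per (x, y) column: air (reflectivity 0), a
  two-pixel surface-reflection line (relative backscatter 16 then 4, so
  boundary trackers localize the brighter first pixel), a dark epithelium
  band (0.25) spanning `[surface, surface + round(thickness/14 um))`, and
  bright lamina propria (1.0) below.  The surface undulates gently
  (sinusoids, slope < 1 px/column).
* **Fully developed speckle.**  Each voxel's field is complex circular
  Gaussian with variance equal to its reflectivity; amplitude is the
  magnitude, hence Rayleigh with mean/SD = sqrt(pi/(4−pi)) ≈ 1.913 —
  verified by test.
* **Flow as decorrelation.**  Static voxels reuse one speckle realization
  across repeats (plus additive complex detection noise, scale
  `noise_floor`); voxels inside vessels evolve as a first-order
  autoregression `g' = sqrt(1−d) g + sqrt(d) g_new`, so d = 0 is static
  and d = 1 fully independent.  Vessel contrast in sigma^2 is strictly
  increasing in d (tested at d ∈ {0, 0.25, 0.5, 1}).
* **Vessels.**  Random-walk polyline centerlines with en-face radius 1-4
  px and roughly isotropic cross-section, confined to a 40-px
  "subepithelial plexus" band beginning 4 px below the epithelium.
  Rasterization continues until the en-face footprint reaches the target
  area fraction and the most recently added columns are trimmed back, so
  the true fraction matches the request to within one column (≪ the 0.02
  contract).  Confining vessels to a shallow plexus matches mucosal
  microanatomy and keeps their projected contrast well above background;
  scattering the same tubes over the full imaging depth dilutes thin
  vessels below detectability in an averaged projection, which is an
  instrument-realistic failure mode but not a useful test condition.
* **Treatment pattern.**  Optionally, a grid of shallow decorrelating
  spots emulates the appearance of fractional laser ablation in en-face
  angiograms.

Not emulated: light attenuation and shadowing, refraction, probe motion,
flow pulsatility, vessel-diameter-dependent decorrelation.  Passing tests
on these phantoms therefore demonstrate the correctness of the computation
chain and its recovery behaviour under realistic speckle statistics — not
robustness to every clinical artifact.

Default geometry is 256 (z) × 256 (x) × 64 (y) voxels at 14 um axial /
35 um lateral pixels with 4 repeats: an endoscopic large-field scan
(9 × 9 mm) scaled to desk runtime.

## Vessel analysis (`vessels`)

2-D Frangi vesselness on the scale-normalized Hessian (sigma^2-weighted,
Gaussian derivatives, reflective boundaries — constant-padding would
manufacture edge responses on uniform images).  Eigenvalues are ordered
|l1| ≤ |l2|; response `exp(−Rb^2/2 beta^2)(1 − exp(−S^2/2 c^2))` where
l2 < 0 (bright vessels), else 0; maximum over scales {1, 2, 3, 4} px;
beta = 0.5; c defaults to half the maximum Hessian norm over the image and
all scales; the map is max-normalized.  An ideal isotropic Gaussian blob
(Rb = 1) scores exp(−2) ≈ 0.135 of an ideal ridge at beta = 0.5 — the
ridge/blob contrast is e² ≈ 7.4, frozen in the tests.

Binarization offers three rules.  `fixed` and `otsu` threshold the
vesselness map directly.  The default `seeded` rule exists because a hard
vesselness threshold keeps only centerlines — the Frangi response decays
toward tube edges — and an area fraction computed from it undercounts
systematically (about 2× on phantoms).  Instead, Otsu-selected vesselness
pixels act as detections, and the mask is the set of connected en-face
flow regions containing a detection, with "flow" defined as values above
the geometric mean of the background median and the detection-region
median.  The geometric mean is the half-contrast point on a log scale,
the natural midpoint for the multiplicative statistics of speckle-derived
maps, and makes the rule parameter-free.  On phantoms with true fractions
0.10-0.30 the recovered BVD lands within ±0.035 of truth across held-out
seeds.

BVD itself is a count ratio (`vessel ∧ roi` / `roi`) and is monotone in
the mask by construction.

## Epithelium segmentation (`epithelium`, `unet`)

**Classical path.**  The B-scan is Gaussian-smoothed (sigma 1 px).  The
upper boundary is the minimum-cost left-to-right path through the negated
normalized intensity — dynamic programming with depth changes limited to
±2 px per column, each px costing 0.05 — which locks onto the surface
reflection.  If no prominent reflection exists (image max below 2.2× the
median), the image is rejected ("surface not found").  A dip statistic
then decides whether an epithelium is present at all: the median over
columns of the darkest pixel within a few pixels below the surface,
compared to the lamina level; values above 0.75 of lamina mean no dark
band, and the thickness is zero (boundaries coincide, empty mask — not an
error).  A per-column minimum is used rather than a band median because
smoothing bleeds the bright surface line into very thin bands.  Otherwise
the lower boundary is the minimum-cost path through the negated axial
intensity gradient, restricted per column to [upper + 3, upper + 60] px —
a gate bracketing the 100-200 um clinical range at 14 um/px with
headroom.  On default phantoms the recovered mean VET is within one axial
pixel of truth at 100/150/200 um and the per-column boundary MAD is below
1 px; the residual −0.5 px bias comes from the discrete position of the
dark-to-bright edge.  Below ~85 um (≤ 6 px) the dark band thins toward
the surface-line width and the classical tracker becomes unreliable; the
network path should be preferred there.

**Network path.**  A 3-level encoder-decoder (8/16/32 channels, 3×3
convolutions, 2×2 max-pooling, nearest-neighbour upsampling, skip
concatenation, ~30k parameters) implemented directly on numpy with
hand-written backpropagation (verified against finite differences to
1e-4), trained with Adam on BCE + soft-Dice loss.  Training runs on
(B-scan, mask) pairs from the generator; the best-validation-Dice
checkpoint is kept; training is deterministic under a seed.  Inference
thresholds the probability map at 0.6 by default, keeps the largest
connected band, and extracts per-column boundaries, making its output
interchangeable with the classical segmenter's.  On 200 synthetic
training pairs it exceeds 0.95 validation Dice within ~5 epochs
(~1 min/10 epochs on one core).  It is trained and evaluated exclusively
on synthetic data; no claim is made about clinical images.

Overlap metrics: pixel accuracy, IoU and Dice, with empty-vs-empty
defined as perfect agreement (score 1) — the identity
`dice = 2·iou/(1 + iou)` holds for all mask pairs and is property-tested.

## Cohort simulation and statistics (`cohort`, `stats`)

One record per (patient, visit 1-4, location ∈ {da, dp, pa, pp}).  Visit
means interpolate linearly between baseline and final values — defaults:
BVD 21.7% → 29.6%, VET 123.3 → 160.3 um, with the proximal-anterior
location offset +0.9 BVD points and the remaining offsets balancing to
keep the grand mean on the stated trajectory.  Patient random effects
(between-SD) and record noise (within-SD) are shared between the two
metrics with a correlation chosen in closed form so that the pooled
VET-BVD Pearson correlation lands on a configured value (default 0.44,
the ratio implied by the configured score-correlation targets).

Scores derive from the standardized VET signal as the latent-health
proxy: VHI loads 0.853 and VSQ 0.721 on it (their residuals correlated so
that |r(VHI, VSQ)| → 0.754), then are discretized — VHI to the integer
5-25 scale (five 1-5 items), VSQ to 0-21 oriented so that higher = worse,
which makes its correlations with health negative; analyses compare
magnitudes.  Because scores load on VET, their BVD correlations follow as
`r_score_vet × r_vet_bvd` (≈ 0.38 and 0.32).  Discretization attenuates
the correlations by ~1%; recovery tests allow ±0.05 at n = 400 records.

Statistics: cell and pooled means with SE; paired t-test on per-patient
deltas against baseline (Wilcoxon signed-rank as option; all-zero deltas
defined as p = 1), pairwise exclusion of incomplete patients, ≥ 3 pairs
required; stars *** / ** / * at p < 0.001 / 0.01 / 0.05, else ns.
Pearson correlations are computed on records pooled across visits and
locations (grouping exposed as an option) and classified by |r| with
closed-left bins: negligible < 0.1 ≤ weak < 0.3 ≤ moderate < 0.5 ≤
strong — the closed-left convention is what makes |r| = 0.310 moderate
and 0.5 strong.  No multiple-testing correction by default (Holm
available): the comparisons mirror a study design in which each
visit-location contrast is reported individually.  Type-I calibration is
verified by simulation: on null cohorts the visit-4 rejection rate at
alpha = 0.05 stays inside the binomial 95% band over 1000 replicates.

## Pipeline, formats, determinism

Volumes and maps travel as multi-page float32 TIFF with JSON sidecars
(geometry, page order, provenance); masks as 0/255 TIFF; cohorts and
metric tables as CSV with fixed columns `patient_id, visit, location,
bvd, vet_um, vhi, vsq`.  Writers round-trip through their readers at
float32 precision (tested).  Every run writes its resolved configuration
(pydantic-validated, JSON-schema available) and a SHA-256 manifest;
identical configurations produce bit-identical manifests.  All
randomness flows through `numpy.random.default_rng` seeds carried in the
configuration.

Problem sizes used in the test-suite recovery experiments — 256×256×64
voxel phantoms, 200-patient cohorts, 200-pair training sets, 1000-replicate
calibration — were chosen as the smallest sizes at which the Monte-Carlo
error bands in the contracts are comfortably resolvable on a single core.

## Known limitations

* The phantom's optical model is statistical, not physical: no
  attenuation, shadowing below large vessels, refraction, or motion.
* BVD recovery is validated for en-face fractions ≤ 0.3 and the plexus
  depth model; very deep or very sparse vasculature in a wide projection
  slab will be under-detected (dilution), as on any averaged projection.
* The classical segmenter assumes a single epithelium layer with the
  canonical bright-dark-bright signature; multi-layer pathology is out of
  scope.
* The network is a demonstration-scale model trained on synthetic data
  only.
* Clinical metric values from any particular study (correlation
  coefficients, segmentation scores on expert-labelled images) are not
  reproducible here by construction — patient imaging is not available —
  and are used only as generator inputs for recovery testing.
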