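# Methods

This note documents the model, the tunable parameters, the synthetic data,
and the numerical and design choices behind `pdrscreen`.

## Problem and pipeline

The package grades color fundus photographs for proliferative diabetic
retinopathy by detecting neovascularization — tortuous clusters of thin,
newly grown vessels — and locating it relative to the optic disc: within
one disc distance (1dd = D + D/2, disc diameter D) it is NVD (grade 2),
elsewhere NVE (grade 1), absent means healthy (grade 0). An image can carry
both grades. There is no trained classifier anywhere in the pipeline; all
decisions are filter responses, morphology, and interval thresholds.

Stage order: preprocess → dual-path Gabor vessel maps → candidate map →
optic disc → zone masks → region extraction → layer-1 thresholds → layer-2
thresholds → grading.

## Preprocessing

Images are rescaled to a working width of 720 px (MESSIDOR-class images
downscaled about 2×), preserving aspect ratio. The field of view (FOV) is
segmented from the camera background on the red+green average: a pixel is
foreground when its own value exceeds half the global mean **and** its
15×15 local mean supports it, or when the local variance is high and the
pixel is not dark. Thresholding the windowed mean alone dilates the rim by
about half the window, which is why the per-pixel term leads. The largest
connected component is opened (disc radius 3) and hole-filled; the result
must be a single component, otherwise the input is rejected as non-fundus.
The working intensity field is the inverted green channel (255 − G)/255,
zero outside the FOV; vessels are darkest in green and become bright
ridges. The original 8-bit planes are retained for feature extraction.

## Gabor wavelet bank

The 2D Gabor wavelet is a complex exponential with carrier k₀ under an
anisotropic Gaussian, ψ(x) = exp(jk₀·x) exp(−|Ax|²/2) with
A = diag(ε^{−1/2}, 1); its Fourier transform is a Gaussian centered at k₀.
The transform at angle θ and scale a is evaluated for all positions at once
as a·IFFT[ĝ(k)·ψ̂(a r₋θ k)]. Numerical choices:

- The admissibility constant C_ψ is fixed to 1; only relative magnitudes
  are thresholded.
- The kernel's DC bin is zeroed, so flat regions give exactly zero
  response (wavelet admissibility; prevents background leakage).
- Images are mirror-padded to the next power of two per axis and cropped
  after filtering, suppressing wrap-around ridges at the field edge;
  padding preserves linearity.
- Orientations span {0°, 10°, …, 170°} (line detection is 180°-periodic);
  the per-pixel maximum modulus over θ is the enhancement map.
- Carrier magnitudes quoted as bracketed pairs [0, |k₀|] are interpreted
  as the vector (0, |k₀|) before rotation.

Filter-bank parameters ship per path and zone. Dilations are quoted at a
reference width of 1440 px and multiplied by working/reference at run time,
so geometry scales coherently. The normal-vessel paths use the published
screening values (NVD: a = 11, ε = 5, |k₀| = 2.5; NVE: a = 7, ε = 10,
|k₀| = 2.5). The detail paths use a = 4, ε = 1, |k₀| = 2.5 (effective
a = 2, wavelength ≈ 5 px at working scale), re-tuned on phantoms: effective
scales below ~1.5 px respond mostly to sensor noise at realistic noise
levels, and an isotropic λ ≈ 5 px kernel is the best tuft-versus-background
separator we measured.

## Dual-path candidate extraction

The normal path blurs with a 3×3 Gaussian (σ = 1) before the coarse
elongated bank; the detail path sharpens with a 3×3 unsharp kernel (center
9, neighbors −1, unit sum) before the fine isotropic bank. Outside-FOV
pixels are first replaced by their nearest in-FOV value: otherwise the
intensity step at the rim is the strongest ridge in the image and floods
the response quantiles. A 6-px rim band is likewise excluded from
thresholding.

Each response map is normalized to [0, 1] over the FOV and binarized by
**multilayered adaptive thresholding**: layer l (of 3) keeps pixels above
the global (1 − l·top_frac) quantile *and* above their 25×25 local mean by
l·offset. Deeper layers reach dimmer vessels but demand more local
contrast. Defaults: normal path top_frac 0.05, offset 0.01; detail path
top_frac 0.04, offset 0.01. The detail threshold is deliberately strict —
in a healthy image the top response quantiles are noise by construction,
and noise-cluster suppression is what limits the false-positive rate
downstream.

The subtraction guard is the **union of both normal-path masks** (both
banks enhance the same physical vasculature). Before use, each mask is
cleaned: components are kept only when both large (area ≥ 200 px) and
extended (bounding diagonal ≥ 100 px) — vasculature forms long runs, while
a *compact* blob in the coarse mask is dense fine structure, often the
lesion itself, which must not be subtracted — and remaining gaps are
bridged by a radius-2 closing. The guard is dilated by 3 px and the
candidate map is detail AND NOT guard; by construction it is disjoint from
the dilated guard and confined to the FOV.

## Optic disc

Bright candidates are found on the green plane after subtracting a low-pass
illumination estimate (lowest 2% of the frequency radius). The green plane
is FOV-extended before the FFT and an 8-px rim excluded so the estimate
sees no rim step. The brightest 1% of pixels are thresholded, closed, and
labeled; each candidate's full extent is recovered by region growing at
half its core brightness (the top-percentile core alone underestimates D by
roughly half). Selection: candidates whose refined diameter lies within
[0.4, 2.0]× the expected disc diameter (64 px at working scale) are
preferred — exudates are an order of magnitude smaller — and among those
the window with maximal segmented-vessel energy wins, since the
vasculature converges at the disc. D is the equivalent-circle diameter of
the grown region; 1dd = 1.5·D exactly. The NVD/NVE zone masks partition
the FOV with an inclusive boundary (exactly 1dd ⇒ NVD).

## Regions and object classification

The disc surface and its rim (a circle of radius D/2 plus a 5-px margin
around the detected center) are excluded from the candidate map first: the
bright disc edge excites the detail filter strongly but belongs to no
vessel guard, and would otherwise merge with nearby lesions into a single
sprawling region.

Candidate pixels are then gated by local density before labeling: a pixel
survives when at least 40 candidate pixels lie within radius 12 — a
neovascular tuft is a dense cluster of strokes, scattered noise is not —
and surviving cores are merged by a radius-3 closing so one lesion labels
as one 8-connected region. Moment-based object classification drops
components with area < 30 px² (0th moment) or second-moment axis ratio
> 3.5 (thin strips are residue of under-subtracted vessel segments, not
tufts). Finally, NVE-zone regions whose parent component in the *detail*
mask spans more than 300 px diagonally are rejected: junctions and tips of
thin vessels belong to a sprawling vessel network, while genuine tufts form
compact components. The rule is not applied in the NVD zone, where
neovascularization grows among the converging vasculature and network
membership carries no evidence. Each cut is a config key.

## Features and double-layered thresholds

Layer 1 reads a fixed window on the inverted 8-bit green plane — 101 px for
NVD (on-disc bunches sprawl), 51 px for NVE — and computes entropy (M = 32
bins over [0, 255]), energy (sum of squared intensities), GLCM homogeneity
(Σ P(i,j)/(1+|i−j|), 32 levels, offsets {(0,1),(1,0),(1,1),(1,−1)}
averaged), and Sobel gradient statistics (mean magnitude; sample standard
deviation of atan2 directions over gradient-bearing pixels). The NVD test
set is {entropy, energy, homogeneity}; the NVE set is {energy, gradient
mean, gradient-direction std}.

Layer 2 computes f1–f10: intensity statistics over the region's own pixels
(f1/f2 mean/max green, f3 green skewness with the (n−1)·s³ normalization,
f8/f9 red/blue means, f10 mean L* after sRGB→LAB D65), and adaptive-window
statistics (f4 entropy, f5 energy, f6/f7 Sobel mean/direction std) on the
bounding box padded 20% per side. Region-pixel intensity statistics
separate faint tufts (≈60% of vessel contrast) from dark vessel residue
and bright artifacts much more sharply than window averages. The selected
layer-2 sets — NVD {f1, f4, f6, f8, f10}, NVE {f2, f5, f8, f10} — come
from box-plot analysis of true/false detections on phantom cohorts.

Every band is [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the true-detection
distribution (Tukey fences, linear-interpolation quartiles — the common
spreadsheet convention, also used by the test oracles). Calibration flags
features whose true/false interquartile boxes overlap by more than 0.5 as
non-discriminative; such features stay in the set with their fences (the
report is a warning, not an automatic drop). The packaged defaults were
calibrated on a 160-phantom cohort (20% healthy / 40% NVD / 40% NVE, its
own fixed seed). A region counts as a true detection during calibration
when at least 20% of its pixels lie on the planted lesion mask *or* it
carries at least 25% of the lesion's pixels — without the second clause,
large regions that merge a lesion with adjacent residue would be labeled
false and the fences would then reject exactly the regions that carry the
lesion at inference. `pdrscreen calibrate` re-derives bands from any
labeled CSV.

## Grading and evaluation

Region distance to the disc uses the nearest region pixel by default
(config `distance_mode`): lesions straddling the 1dd boundary are split by
the guard into fragments, and nearest-pixel distance keeps a fragment just
outside the boundary from spuriously adding grade 1. Region-level
evaluation counts a prediction as true positive when ≥ 20% of its pixels
lie on the truth lesion mask; unmatched truth lesions are false negatives;
true negatives come from labeled lesion-free units. Sensitivity,
specificity, PPV and accuracy follow the standard confusion-matrix
definitions; undefined ratios are NaN with a warning. An image-level mode
(any neovascular grade = positive) is also provided.

## Synthetic phantoms

A phantom is a pure function of its spec (same spec ⇒ byte-identical image
and truth): dark red-brown field with radial illumination falloff and
low-frequency mottling inside a circular FOV; noisy near-black background
with border specks; a bright yellowish disc (default D = 64 px,
alpha-blended so crossing vessels stay visible); 5–7 smooth wide vessels
(width 4–6.5 px, 3°/step direction jitter, two branching levels with ×0.7
width decay) walking from the disc rim; optional exudates (sharp bright
blobs, radius 3–7 px); optional neovascular tufts — 22–34 strokes of width
1–1.5 px and ~30°/step tortuosity inside a radius-≈22 px disk, at 60% of
the main-vessel green contrast, planted at a controlled multiple of 1dd.
Gaussian sensor noise (σ = 2.5) is added per channel. Main vessels are
smooth because retinal arcades are; tufts are lacy (fill ≈ 0.2) because
real neovascularization is a fine net, and a solid dense cluster would be
indistinguishable from a wide vessel at coarse scale. Cohorts derive each
phantom's RNG stream from (seed, index), with jittered disc position and
diameter, vessel counts, and lesion geometry; NVD lesions sit at 0.3–0.8
× 1dd and NVE lesions at 1.4–2.1 × 1dd, away from the boundary where the
planted label itself would be ambiguous.

The phantoms do not model hemorrhages, drusen, vessel central reflexes,
camera optics, or inter-image color variation. Passing tests therefore
demonstrate recovery of planted structure under the stated noise — not
clinical performance, which in the literature is established on
expert-annotated datasets.

## Problem sizes and runtime

Default tests and the acceptance script run 50-phantom cohorts at
720×480 px, the package's standard desk-scale validation size; a full
pipeline run takes a few seconds per image on one CPU.

## Known limitations

- Sensitivity at the shipped operating point is pixel-partial: roughly the
  brighter third of tuft pixels survives the strict detail threshold. That
  is sufficient for region-level detection and grading, but the candidate
  masks are not dense lesion segmentations.
- The vessel-network rejection assumes tufts rarely touch the detail-mask
  vessel network; lesions growing directly on a major vessel can be
  discarded with it (the main residual failure mode on phantoms).
- Threshold bands are calibrated on phantoms; real images need
  recalibration from a labeled region CSV (`pdrscreen calibrate`).
- The disc detector assumes one bright disc-sized region is present;
  severely occluded or peripapillary-atrophic discs would mislocalize, and
  the image is then reported ungradable or misgraded rather than flagged.
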