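# Methods

## The measurement

Net water uptake treats the contralateral hemisphere as each patient's own
density control. If ischemic tissue has taken up a water volume fraction
`w`, its CT density falls to approximately `(1 − w) · D_normal`, so

```
NWU = 1 − D_ischemic / D_normal
```

estimates `w` directly (reported ×100, in percent). The estimate is only
as good as the two regions entering the means, which is where all the
machinery lives:

1. **Region definition.** On follow-up scans the ischemic region is the
   segmented visible hypodensity; at baseline it is the CTP-derived core
   (or a supplied visible-infarct mask). The normal region is the ischemic
   mask reflected across the mid-sagittal plane, minus any overlap with
   the lesion and minus voxels outside the brain.
2. **CSF exclusion.** CSF at ~0–15 HU inside either region would mimic
   edema; segmented CSF is removed from both regions before anything else.
3. **HU windows (inclusive).** Follow-up infarct: `[0, 40]` — the 0 floor
   keeps severely edematous voxels that the historical 20 HU floor
   discarded (underestimating NWU), while the 40 ceiling rejects
   hemorrhagic transformation and contrast staining, which are hyperdense
   and would cancel the deficit. Normal side and baseline core: `[20, 80]`.
   Exclusion counts per region and step are recorded on every result.
4. **Floors.** A region with fewer than 50 surviving voxels (5 for the
   deliberately small manual-protocol ROIs) aborts with a pipeline error
   rather than returning a noise-dominated mean.

An asymmetric-window subtlety worth knowing: for weak lesions whose
density approaches 40 HU (uptake ≲ 10% on ~38 HU parenchyma), the 0–40
ceiling clips the upper noise tail of the lesion only, biasing NWU upward
by up to ~1 point at 2–3 HU voxel noise. This is inherent to the window
protocol, not to the implementation; with symmetric windows (baseline-core
mode) identical-statistics regions measure 0 ± noise.

## Midline and mirroring

The midline is a single plane found by reflective symmetry: Powell
refinement (seeded by a coarse grid) of lateral offset, axial rotation,
and in-plane rotation, maximizing the normalized cross-correlation between
brain-voxel intensities and trilinear samples at their mirror points. On
phantoms with 0–8° of axial tilt the plane is recovered to ≲ 0.2°, and a
unilateral 50 ml lesion perturbs it by well under a degree. A per-slice
midline (as an atlas with delineated midline would give) is deliberately
reduced to one plane; any caller holding a better plane can pass it in,
since all downstream operations take a `MidlinePlane` value.

Mask mirroring reflects inside-voxel centers across the plane and snaps to
the nearest voxel — a pure geometric operation; clipping to the brain is
the measurement code's concern. Reflection preserves voxel counts within
~2% and is an involution up to resampling (Dice ≥ 0.95 on the phantom).

Rigid CTP→NCCT registration uses Mattes mutual information over the six
rigid parameters, multi-resolution, with seeded regular sampling so runs
are reproducible; masks are resampled nearest-neighbor (binarity),
intensities trilinearly (densitometry).

## Classical segmenters

The clinical workflow this package automates uses trained U-Nets for CSF
and infarct segmentation. Those are out of scope here; the classical
detectors below honor the same contracts (`callable → VoxelMask`) and are
the defaults the pipelines call.

**CSF**: brain voxels in `[-5, 15]` HU, cleaned by an in-plane 1-voxel
opening **by reconstruction** — erosion survivors re-seed their entire
connected component, so speckle vanishes while genuine compartments keep
their partial-volume boundary voxels — then components under 0.3 ml are
dropped. The erosion is in-plane because head-CT slices are 3–5 mm thick:
a 3D erosion would delete every structure under three slices tall,
ventricles included. Widening the window can only grow the output (each
stage is monotone in the candidate set). Known limitation, as for any
fixed-window method: severely edematous infarct on real follow-up CTs can
enter the window; the window is configurable and a learned segmenter can
replace the whole callable.

**Infarct**: the detector looks for a spatially coherent hypodensity
relative to the mirrored hemisphere. Steps, in order:

- *Evidence image*: voxels more than 5 HU above the infarct ceiling
  (hemorrhage, contrast, calcification) are capped at the brain in-window
  median — hyperdense content is not evidence against a surrounding
  lesion. The margin leaves the upper noise tail of normal parenchyma
  untouched.
- *Smoothed contralateral difference*: 2 mm Gaussian smoothing pools the
  coherent uptake signal out of voxel noise; the mirrored intensity is
  sampled with cubic splines (linear interpolation cannot undershoot at
  local minima and would bias the mirror bright near dark structures).
  Candidates must be ≥ `delta_hu` = 1.5 HU darker than their mirror —
  ~3σ of the smoothed-difference noise at 2 HU scanner noise, and below
  the weakest signal of interest (5% uptake ≈ 1.9 HU).
- *Half-maximum adaptive cut*: smoothing turns the lesion edge into a ramp
  crossing half its plateau exactly at the true boundary, so the working
  threshold is `max(delta_hu, plateau/2)` with the plateau estimated as
  the 95th percentile of suprathreshold differences. This stops the
  detector from annexing the blurred halo around strong lesions.
- *Geometric eligibility*: brain eroded by one in-plane voxel, CSF dilated
  by one — steep density gradients at those rims turn sub-degree midline
  error into large coherent left-right differences.
- *Cleanup and refinement*: in-plane closing, minimum component size 1 ml,
  then the largest 26-connected 3D component is kept (ties broken by lower
  mean HU, then lowest linear index — deterministic).
- *Solidity gate and fill*: a genuine infarct is a solid blob while
  pure-noise "components" are thin 26-connected chains; an in-plane
  erosion removes chains entirely (→ *no visible infarct*), and the convex
  hull of the surviving core, re-clipped to eligibility, readmits interior
  voxels that noise pushed below threshold. This decouples the density
  measurement from detection noise, which would otherwise bias NWU upward
  at low contrast. A final mean-deficit check (≥ `delta_hu`/2 over the
  filled territory) rejects assembled noise.

On the standard phantom this recovers the constructed uptake to ≤ 1
point across `w ∈ {0.05, …, 0.35}` and returns *no visible infarct* at
`w = 0`. Convexity of the hull step is an idealization appropriate for the
phantom's ellipsoidal lesions; real infarcts are only locally convex, and
a learned segmenter should replace this detector for clinical material.

## CT perfusion

The indicator-dilution model: each voxel's baseline-subtracted curve is
`CBF · (AIF ⊛ R)(t − delay)` with residue `R(t) = e^{−t/MTT}`. The AIF is
the mean baseline-subtracted curve of the 20 voxels ranking best on (high
peak, early peak, narrow width) — a score invariant to global rescaling of
the data. Deconvolution inverts the **block-circulant** convolution matrix
(zero-padding to twice the series length), whose SVD is the DFT, so
truncating singular values below 0.1 of the maximum is exactly truncating
small Fourier coefficients of the AIF. The delay-insensitive formulation
matters: ischemic tissue lags the AIF by seconds, and the non-circulant
matrix systematically underestimates CBF in exactly the tissue the core
rule must classify (we measured ~20% CBF loss at a 6 s delay before
switching). CBF = max of the recovered residue, Tmax = its argmax;
truncation smooths the residue's leading edge, shifting Tmax by about one
frame (a recovered 7 s for a constructed 6 s delay at 1 s framing).

Core rule: brain voxels with CBF strictly below 30% of the reference,
where the reference is the **median** CBF of tissue with Tmax < 4 s
(median, not mean: robust to residual lesion voxels; the aggregator is
otherwise unspecified in the protocol). Only ratios enter, so the rule is
invariant to curve rescaling and no absolute ml/100 g/min calibration is
attempted. An empty core is a legitimate outcome and surfaces as *no
measurable core*.

## Agreement statistics

Dice is `2|A∩B|/(|A|+|B|)` with both-empty defined as 1 (perfect agreement
on absence). ICC(2,1) — single-measure, absolute-agreement, two-way random
effects — is computed from the two-way ANOVA mean squares, with the
Shrout–Fleiss F-based 95% CI (Satterthwaite df); it is cross-checked in
the tests against both a sums-of-squares brute force and pingouin's
ICC(A,1). Bland–Altman uses the classical fixed 1.96 multiplier with the
n−1 standard deviation.

## The phantom: what it does and does not emulate

The phantom exists to make every stage falsifiable against construction
truth. It emulates: parenchyma at 38 ± 2 HU, CSF at 8 ± 3 HU in enlarged
lateral ventricles and an interhemispheric fissure, a ~700 HU skull shell
on air, partial-volume blur (1.5 mm Gaussian — about a soft reconstruction
kernel; a kernel specified in voxels would be 5 mm axially and unphysical),
2 HU scanner noise, a unilateral ellipsoidal infarct whose density deficit
factor `(1 − w)` is applied *after* the anatomical blur with a sharp edge —
so the mean over the ground-truth mask is exactly `(1 − w)` times the
homologous tissue mean, making `100·w` the oracle — plus optional
hyperdense HT foci (uniform 50–80 HU replacing a fraction of lesion
voxels) and axial head tilt. The CTP forward model convolves a
gamma-variate AIF (bolus at 8 s, 4 s rise) with exponential residues, at
reduced flow and added delay in the core, on top of the NCCT baseline,
with a dedicated arterial vessel region carrying the undiluted AIF.

It does **not** emulate: gyral/sulcal anatomy, grey–white contrast,
beam-hardening or metal artifacts, non-convex or multifocal infarcts,
midline shift from mass effect, slice-boxcar (vs Gaussian) z-averaging, or
contrast recirculation. Passing tests therefore demonstrate that the
pipeline's geometry, densitometry, deconvolution and statistics are
correct under controlled conditions — not that the classical segmenters
match trained models on clinical scans.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `infarct_hu` | [0, 40] | HU | follow-up infarct window (protocol) |
| `baseline_core_hu`, `normal_hu` | [20, 80] | HU | standard brain window (protocol) |
| `min_region_voxels` | 50 | voxels | mean over fewer is noise-dominated |
| `csf_hu_low/high` | −5 / 15 | HU | brackets water with noise margin |
| `delta_hu` | 1.5 | HU | ~3σ smoothed-diff noise floor |
| `smoothing_mm` | 2.0 | mm | pools coherent uptake out of voxel noise |
| `min_component_ml` | 1.0 | ml | speckle suppression before refinement |
| `svd_threshold_fraction` | 0.1 | — | regularization vs Tmax fidelity (0.2 shifts Tmax by 2 frames) |
| `cbf_core_fraction` | 0.30 | — | core rule (protocol) |
| `tmax_normal_s` | 4.0 | s | normal-tissue definition (protocol) |
| patch edge | 20 | mm | standard square patch |
| ROI diameter | 10 | mm | manual protocol disc |

Problem sizes: the standard phantom is a 72×88×32 grid at 2.5×2.5×5 mm
(≈1.2 l head volume, ~47 ml infarct), and CTP series run 50 frames at 1 s
— sizes chosen so a full pipeline run takes about a second and the whole
validation suite stays interactive on a laptop.

## Known limitations

- The classical infarct detector assumes a single, roughly convex,
  unilateral lesion; bilateral or strongly non-convex infarcts need the
  pluggable learned segmenter.
- A fixed CSF window cannot distinguish severely edematous infarct from
  CSF on real follow-up scans.
- ROI-mode NWU applies no HU windows (the manual protocol avoids
  hemorrhage and CSF by placement); single small ROIs on noisy data
  scatter by several points — the protocol's own sampling noise.
- Tmax carries a one-frame regularization offset; the core rule is
  unaffected (it uses Tmax only as a < 4 s gate).
- With extensive parenchymal hematoma replacing most of the lesion, NWU is
  not measurable by any thresholding method; the pipeline errors out once
  the ischemic region falls below the voxel floor.
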