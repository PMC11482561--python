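# Methods

## The counting problem

A CSF sample is stained (a nucleic-acid dye marks WBCs in the green
fluorescence channel, an anti-glycophorin-A conjugate marks RBCs in the
cyan/far-red channel), loaded into a 100 µm deep microfluidic chip, and
photographed field by field. Counting reduces to: find the circular objects
in each field, decide which are WBCs, RBCs or debris, and convert the
accepted counts into an absolute concentration through the imaged volume and
the dilution bookkeeping.

## Synthetic fields

`FieldSpec` defaults describe one chip field: 488 × 488 px at 1.0 µm/px over
a 100 µm channel depth, i.e. 488² × 1² × 100 µm³ × 10⁻⁶ = **23.8144 nL per
field**, the imager's volume per image. Cell numbers per field are Poisson
with mean `concentration × volume`; positions are uniform (rejection-sampled
to prevent overlap unless `overlap_allowed`); radii are uniform in the class
interval — WBC 3.5–6 µm, RBC 2.5–4 µm (typical leukocyte/erythrocyte radii
at this optical scale). Each cell is a filled disc with a 1-px linear edge
falloff: enough to make Hough gradients well defined without modelling
optics. Per-cell peak amplitudes are log-normal (median 900 counts over a
background of 100, log-SD 0.2); each class signals in exactly one
fluorescence channel and faintly (amplitude 80) in bright field. Debris
artifacts are rendered below or above the cell size range with dual-channel
intensity. Channels receive additive Gaussian noise (SD 5) and are clipped
at zero.

What the generator does **not** emulate: point-spread blur, illumination
gradients, autofocus error, staining kinetics, non-circular or deformed
cells, and real debris morphology. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and its statistics on
idealised imagery — not detection performance on real microscopy.

Determinism: a `FieldSpec` (including its seed) renders bit-identically;
multi-field runs derive per-field seeds from `(master seed, field index)` so
generation order cannot matter.

### Measurement simulators

Replicate measurements for the three modalities share one structure —
Poisson sampling of the counted volume followed by the modality's
concentration formula — plus modality-specific noise:

* **Hemocytometer**: Poisson counts in `squares × 0.1 µL` per read (the
  standard 1 mm × 1 mm × 0.1 mm large square; the chamber geometry fixes
  this volume), two reads averaged, then a mean-one log-normal examiner
  factor with CV `examiner_cv`. A single multiplicative examiner parameter
  reproduces the large, concentration-flat CVs characteristic of manual
  counting; 0.35 is used in the precision studies.
* **Chip imager**: Poisson count over `n_images × 23.8144 nL` of stained
  (2.1× diluted) sample, pushed through the chip formula, times a mean-one
  log-normal instrument factor (`instrument_cv`). A `min_count` floor
  reports 0 when fewer events than the floor are seen, emulating the
  instrument's rejection of sparse event sets as artifacts; it defaults to 0
  (the generic model is exactly unbiased) and is enabled only in the
  detection-limit study configuration.
* **Flow cytometer**: independent Poisson draws of bead and cell events
  (bead events expected ≈ 5000) pushed through the counting-bead ratio
  formula. Zero drawn beads flags the measurement invalid rather than
  producing a silent zero.

**Calibration of the validation studies.** The detection-limit and precision
studies use the chip-imager model with effective sampled volume 5.2 µL of
original sample (`n_images = 459`), `instrument_cv = 0.25` and
`min_count = 10`. These three numbers were calibrated once against the
verification study's replicate tables: they reproduce the reported
per-replicate SDs to ~±30%, the all-zero replicate rows at 0.66–1.0
cells/µL (impossible under pure Poisson sampling, and the clearest evidence
of a sparse-event floor), and the suppressed means just above the floor.
With them, the estimated LOD falls in the published windows with ~99%
probability per series.

## Detection

A circle Hough transform with gradient-direction voting: Sobel gradients
(scaled to intensity/pixel), edge pixels above `edge_threshold` (default 50,
an order of magnitude above the noise floor and well below cell-edge
gradients), each voting along ± its gradient direction at every radius in
2–8 px. The (x, y, r) accumulator is pooled over a 3 × 3 center
neighbourhood (absorbing rounding scatter), normalised by circumference
`2πr`, and thresholded at `accumulator_threshold = 1.5` — on rendered cells
true centers score ≈ 2.7–3.1 (two edge rings vote) while the brightest
spurious peaks stay below ≈ 0.8. Greedy non-maximum suppression keeps the
higher score, ties broken toward smaller (y, x), making runs exactly
reproducible. Centers and radii are integer-pixel; 1 px accuracy is the
declared tolerance and no sub-pixel refinement is attempted.

Size filtering converts radii to µm and keeps the union of the class
intervals, padded by a 1 µm measurement tolerance (the detector's radius
quantisation would otherwise clip true RBCs at the 2.5 µm class boundary)
and capped at the doublet cutoff.

Intensity per channel is the disc mean minus the **median** of a concentric
annulus (gap 2 px, width 3 px); the median, plus exclusion of annulus pixels
under any other detection's disc, keeps touching neighbours from biasing the
background estimate. Discs clipped by the border are measured on the clipped
region and flagged `edge`.

## Gating

Quadrant cuts on (GF, CF) intensity, with on-cut events going to the
non-positive side so assignment is total. Default fixed cuts of 150 sit
roughly midway (log scale) between the corrected background (≈0 ± a few
counts) and the signal population (≈900). Auto mode uses Otsu's threshold on
`log1p` intensity per channel, then re-centers the cut midway between the
two Otsu class means — plain Otsu settles at the edge of a wide background
mode, leaving no margin; the re-centred cut is robust for separated
populations. Degenerate channels fall back to the median positive intensity
and are flagged.

Double-positive (C4) events are resolved by ordered deterministic rules in
place of the instrument's image classifier: radius below every cell class →
artifact; radius at or above 1.5× the largest single-cell radius → doublet
(one WBC **and** one RBC); otherwise the class with the larger
cut-normalised intensity wins, exact ties → artifact. The 1.5× cutoff and
both class size ranges are configuration, not constants. Bookkeeping puts
C1 events with C4-artifacts into `artifact_count`, so
`wbc + rbc + artifacts − doublets = events`.

## Quantification

All concentrations are cells × 10⁶/L ≡ cells/µL, stored at full precision
(reports round to 2 dp, correlations to 4 dp). The chip formula multiplies
`count × 1000 / (23.8144 nL × n_images)` by the sample dilution factor and
the stain dilution factor 84/40 = 2.1. The known-bead-count tube formula
divides the bead concentration by the tested sample volume, as the assay
write-up states it; the conventional kit formula uses beads per tube — the
discrepancy is deliberate and preserved here. The hemocytometer five-square
low-count protocol is expressed through `squares_counted`, not hard-coded.

## Validation statistics

* **Linearity** uses the replicate means per level, not pooled raws.
* **LOB** uses the CLSI nonparametric rank `0.5 + (p/100)·N` with linear
  interpolation, clipped to the observed range; the convention is exposed as
  an option. Blanks from both cell-free samples are pooled by default.
* **LOD** applies "more than 95%" strictly: an exceedance fraction of
  exactly 0.95 (19/20) does not qualify.
* **Precision** reports per-level mean, SD (n−1) and CV%; a zero mean flags
  the CV undefined instead of dividing by zero.

## Comparison statistics

Passing–Bablok excludes pairs with equal x and slopes exactly −1, shifts
the median by the number of slopes below −1, and takes 95% CIs from the
normal-approximation rank bounds with variance `n(n−1)(2n+5)/18`; the
intercept is `median(y − bx)` with its CI evaluated at the slope CI
endpoints. The test suite checks the estimator exactly against a literal
enumerate-everything implementation. Bland–Altman uses the t distribution
for the bias CI (the common clinical-software convention; configurable) and
fixed 1.96 SD limits of agreement. Subrange re-analysis defaults to the
comparator method's value as the window reference.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 200 fields for the Poisson-law check, 2000
seeds for measurement unbiasedness (3 SE), 50 runs × 8 levels × 20
replicates for the LOD windows, 20 seeds × 6 levels × 6 replicates per
modality for the precision ordering (CVs compared after averaging over
seeds — a single six-replicate CV estimate has ~29% relative noise, so the
ordering claim is about the level-wise mean CV), 20 fields for detector
recall/precision, and 100 four-field measurements for end-to-end recovery.

## Known limitations

* The detector assumes near-circular cells and fails gracefully (lower
  recall) on heavy overlap; overlapping pairs merge into C4 doublets only
  when the merged detection is oversized.
* The C4 rules are an auditable stand-in for a learned classifier, not a
  reproduction of one.
* Auto-thresholding needs both populations present; a sample with only one
  cell class should use fixed cuts.
* The measurement simulators model counting statistics and operator/
  instrument dispersion, not systematic matrix effects (lysis, aggregation,
  carry-over), so between-method biases of real studies are out of reach.
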