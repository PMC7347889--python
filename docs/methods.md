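# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ccvoid`. It is written for someone who wants to understand
*why* the package computes what it computes, and what passing its test suite
does and does not demonstrate about real scans.

## The measurement problem

En-face swept-source OCTA renders blood flow as a decorrelation signal.
In the choriocapillaris (CC) slab — a thin en-face projection just below the
retinal pigment epithelium — regions whose flow falls below the detection
floor appear dark and are interpreted as *flow voids* (flow deficits). The
package quantifies, per scan:

- **flow-void density** — void area as a percentage of the analyzed area,
- **flow-void number** — count of connected void components,
- **mean void size** — total void area / number (µm²),
- **retinal perfusion densities** — large-vessel, superficial-plexus and
  deep-plexus vessel area as a percentage of *total* image area,
- **subfoveal retinal and choroidal thickness** (µm) from structural
  B-scans,

and, across a longitudinal design (subjects × visits × timepoints),
tests for diurnal variation of each variable with a repeated-measures
ANOVA, with grader reliability summarized by intraclass correlation.

## Flow-void quantification

1. **Exclusion mask.** Large superficial vessels cast projection/shadow
   artifacts onto the CC slab; the foveal avascular zone (FAZ) is
   physiologically capillary-free. Both are excluded. The large-vessel mask
   is segmented from the superficial-plexus angiogram: Gaussian smoothing
   (σ = 2 px), Otsu threshold, removal of connected components < 50 px,
   dilation by 1 px. All four knobs live in `MaskingConfig`. The source
   method gives only "an intensity-based threshold"; Otsu is the natural
   parameter-free choice because large vessels form the bright mode of a
   near-bimodal histogram, and it makes the mask invariant to affine
   intensity rescaling. Whether the original mask was dilated is unstated;
   the 1-px default covers partial-volume fringes and is configurable. The
   FAZ is an *input* polygon (manual demarcation is standard practice);
   rasterization uses the even–odd rule at pixel centers (c + 0.5, r + 0.5),
   which is deterministic and stays well defined for self-intersecting
   outlines. A circle-from-center-and-radius helper supports synthetic work.
2. **Threshold.** The void threshold is `mean − 1·SD` of the intensities of
   the *analyzed* (non-excluded) pixels. The SD is the population SD
   (divisor N); the source method does not specify the divisor, and the
   choice is recorded in the result metadata. Statistics are restricted to
   the analyzed region because the excluded bright vessels would bias the
   mean upward. A void pixel is *strictly below* threshold, so a constant
   image (SD = 0) has zero voids.
3. **Morphometry.** A single void is a connected component of the binarized
   void mask; connectivity defaults to 8 (configurable — the convention is
   not stated in the source). No minimum-size filter is applied by default
   (`min_void_px` exists in config). Density uses the analyzed area as
   denominator; the identity `density · analyzed_area / 100 = count ·
   mean_size` is asserted at result construction. Note that mean void size
   is an *area* and is reported in µm², even though clinical tables often
   label the same quantity "µm".

Perfusion densities intentionally differ: vessels are enhanced with a
multiscale Frangi filter, binarized with one global threshold (Otsu by
default), and divided by the **total** image area with no exclusions — so
flow-void density and perfusion density are not directly comparable numbers.

## Frangi vesselness

For Hessian eigenvalues |λ₁| ≤ |λ₂| at scale s (γ = 2 normalization, i.e.
the Hessian is multiplied by s²):

    V = 0                                   if λ₂ > 0  (bright vessels)
    V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²)) otherwise,

with R_B = λ₁/λ₂ (blobness), S = √(λ₁² + λ₂²) (structureness), maximized
over scales. Defaults: scales {1, 2, 3, 4} px, β = 0.5, c = "auto" = half
the maximum Frobenius norm of the Hessian at that scale. The original
clinical pipeline tuned its filter against anatomy, which is not
reproducible; these defaults follow the original filter formulation and are
fully configurable.

The Hessian is computed with separable sampled-Gaussian derivative kernels
whose DC response is explicitly zeroed. Two numerical consequences matter:
vesselness is exactly invariant to additive intensity offsets and exactly
zero on constant images, and the operator commutes with 90° rotations to
float precision. With γ = 2 normalization a Gaussian ridge of profile SD
σ_r responds maximally at scale √2·σ_r.

## Thickness

The foveal B-scan is the one minimizing the ILM→RPE separation (ties to the
lowest index); the two flanking B-scans can be averaged to improve contrast
of the choroidal–scleral interface (CSI) before tracing (whether the
central scan joins the average is an option, `include_center`, default
off). Thickness is read vertically at the foveal column — at the fovea the
RPE is locally horizontal, so the vertical caliper coincides with the
perpendicular one — and converted at 1.95 µm/pixel axial sampling (the
device's digital sampling; configurable): retina = ILM→outer RPE, choroid =
outer RPE→CSI. Boundaries come per column from a trace file; a simple
bright-band detector (`detect_boundaries`) recovers them on synthetic or
high-contrast scans to about one pixel.

## Diurnal statistics

Each visit is analyzed separately with a one-way within-subject ANOVA:
F = MS_time / MS_(subject×time). Sphericity is checked with Mauchly's W
(orthonormal-contrast covariance; chi-square approximation with
df = k(k−1)/2 − 1), and the Greenhouse–Geisser ε (eigenvalue form, clamped
to [1/(k−1), 1]) deflates both dfs. The reported p follows the policy:
*conditional* (default) uses the GG-adjusted p only when Mauchly rejects at
0.05; *always* applies it unconditionally. Degenerate inputs are flagged
rather than erroring: zero within-subject variance gives F = 0, p = 1; a
perfect time effect gives F = ∞, p = 0; k = 2 makes sphericity trivial
(W = 1, ε = 1).

One caveat worth stating precisely: the folklore "the GG-adjusted p is
always ≥ the unadjusted p" holds only in the decision-relevant regime. The
two F survival curves cross once, far above conventional significance
levels, so for small F (large p) the adjusted p can be *smaller*. The
adjustment never creates a rejection the unadjusted test would not also
make; the test suite asserts exactly that.

ICC defaults to ICC(2,1) — two-way random effects, absolute agreement,
single measurement — because graders are treated as interchangeable and a
constant grader offset should count as disagreement. ICC(3,1) (consistency)
is available. Confidence intervals follow the standard F-based
(Shrout–Fleiss) construction. Zero between-subject variance leaves the ICC
undefined and flagged. Missing timepoints are handled by listwise subject
deletion before the ANOVA.

## Synthetic data: what it emulates and what it does not

The generator exists to provide ground truth. Its defaults *are* the
reference study conditions: 14 subjects × 2 visits × 5 timepoints (09:00 to
17:00 at 2-h spacing), 3 × 3-mm fields sampled at 300 px (10 µm/px — the
device's nominal 300-A-scan pattern; the en-face pixel count is otherwise
undocumented), 16% dropout with a 360 µm² target blob size (the regime
reported for healthy maculae, where ~16% density and ~3,600 voids over the
~7.8 mm² analyzed field imply ~360 µm² per void), choroidal thickness
297.7 ± 92.1 µm with diurnal deltas (0, −2, −4.1, −2, −3.9) µm, retinal
thickness 222.4 ± 29 µm with null deltas, null void deltas, and
within-subject thickness noise of 1.5 µm (chosen so the reported diurnal
significance is reproducible at n = 14; the source does not state a
residual SD). Reported diurnal amplitudes for choroidal thickness vary
between ~4 and ~8 µm depending on how they are summarized; the deltas are
therefore plain parameters, with the per-timepoint table values as
defaults. Grader noise is additive Gaussian on thickness readings (default
9 µm, giving ICC ≈ 0.99 against a 92-µm between-subject SD).

**CC slab.** Dropout blobs are random ellipses with jittered radii placed
until the target fraction is reached (stopping within one blob); overlap is
allowed, and truth (density, count, mean size) is recomputed from the final
mask — exactly what a perfect segmenter would see. At 16% coverage merging
makes the realized mean component size larger than the per-blob target;
this is intended, and the recorded truth is always the realized one.
Speckle is multiplicative: raw per-pixel exponential speckle (fully
developed speckle intensity), smoothed by a PSF-sized Gaussian grain
(default 1 px ≈ the device's 20-µm transverse resolution at 10 µm/px), then
renormalized to mean 1 and SD = `speckle_contrast` (default 0.2). The
smoothing reproduces the spatial grain of real angiograms, and the
surviving right skew gives perfused tissue a thin lower intensity tail —
the regime in which mean−1SD thresholding is approximately unbiased, as it
must be for a method that is used clinically at face value. Intensity
levels default to background 160 and void 10 (8-bit): voids sit near the
noise floor, and 160 keeps the speckled bright tail below the 8-bit clip.

**SVP/DVP slabs.** Large vessels are smooth sinusoidal ribbons carved from
the distance transform of random centerlines at the quantile matching the
requested footprint (default 10% of image area, matching reported
large-vessel densities); capillaries are thresholded band-pass noise; a
central circular FAZ (default 300 µm radius ≈ 0.28 mm² area) is kept
avascular and recorded as a 64-gon polygon. The deep slab is the capillary
mesh without large vessels (projection artifacts are assumed removed
upstream, as device software does). Synthetic perfusion densities depend
on these texture parameters and are *not* calibrated to clinical values —
OCTA perfusion metrics are not comparable across processing pipelines, and
reproducing any particular instrument's absolute numbers is a non-goal.

**B-scans.** Bright bands at ILM/RPE/CSI over layered tissue levels, with a
Gaussian foveal pit in the ILM; truth rows are exact. Thickness targets are
converted to integer band rows, so pipeline-measured thickness differs from
continuous truth by at most one pixel (1.95 µm) of rounding.

**Not emulated:** projection artifacts (removed upstream in the reference
workflow), motion artifacts, 3-D volumes, drusen or other pathology, signal
attenuation, and inter-scan registration error. Passing the recovery tests
therefore shows the *algorithmic* chain is correct and calibrated on the
stated texture model — not that the 1-SD threshold is unbiased on any real
instrument's output.

## Problem sizes and runtime choices

Statistical acceptance checks run at the reference design (n = 14, k = 5;
2,000 replicates for type-I calibration). The end-to-end replicate runs
(50 seeded full-pipeline studies) use 128-px grids, a single visit and a
reduced B-scan height so that a complete run of the suite stays cheap on a
single core; subject count, timepoint count, trend size (4 µm) and noise
(1.5 µm) are kept at the reference values. The grid size matters for test
calibration, not just speed: a record's mean void size averages over the
void clusters it contains, and on very small grids (≤ ~96 px) too few
clusters remain for the average to normalize, leaving heavy-tailed record
noise that measurably inflates the ANOVA's type-I rate (pooled estimates
across several hundred replicate 96-px studies put flow-void density and
count near 6–7% and mean void size near 8–9% at α = 0.05). 128 px is the
smallest size at which this artifact stops dominating; at the reference
300-px field each record averages several times more clusters still.

## Known limitations

- The FAZ must be supplied; there is no automatic FAZ segmentation.
- No compensation for drusen- or media-related signal attenuation.
- The CSI is taken from supplied traces; automatic choroidal segmentation
  of real scans is out of scope.
- Mean void size inherits the heavy tail of merged-component size
  distributions; its significance tests are the least well calibrated of
  the eight variables (see above).
- No multiplicity correction across the eight variables (deliberate,
  matching common practice in the diurnal-variation literature).
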