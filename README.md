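# ccvoid

Quantification of **choriocapillaris flow voids**, retinal perfusion
densities and subfoveal retinal/choroidal thickness from en-face OCTA
angiograms, together with the diurnal-variation statistics used to judge
whether these biomarkers are stable across the day.

Flow deficits of the choriocapillaris are a candidate imaging biomarker in
age-related macular degeneration, myopia, diabetic retinopathy and
hypertension. A biomarker is only useful if it is robust to diurnal
physiology, so the core analysis here is: quantify flow voids per scan,
then test a subjects × timepoints design with a repeated-measures ANOVA.
Because clinical OCTA datasets are rarely shareable, the package includes a
first-class synthetic-data module that generates angiograms, B-scans and
complete longitudinal studies with known ground truth, so every stage of
the pipeline is verifiable end to end.

## The method in brief

Per scan (3 × 3-mm macular field, three en-face slabs + structural B-scan):

1. From the superficial-plexus slab, segment the **large-vessel mask**
   (smooth → Otsu → small-object removal → dilation) and rasterize the
   manually demarcated **FAZ polygon**; their union is the exclusion mask.
2. On the choriocapillaris slab, threshold at **mean − 1·SD** of the
   analyzed (non-excluded) intensities. Pixels strictly below are voids.
   Report density = 100·void/analyzed area, the number of connected
   components, and mean size = total area / number (µm²). The identity
   `density × analyzed_area / 100 = count × mean_size` is enforced on
   every result.
3. **Perfusion densities**: Frangi vesselness (Hessian eigenvalues
   |λ₁| ≤ |λ₂|; `exp(−R_B²/2β²)(1 − e^{−S²/2c²})`, zero where λ₂ > 0),
   global Otsu binarization, vessel area over *total* image area, for the
   superficial and deep plexuses plus the large-vessel mask.
4. **Thickness**: locate the foveal pit (minimal ILM–RPE separation),
   average the neighboring B-scans for CSI contrast, and convert pixel
   separations at 1.95 µm/px (retina: ILM→RPE; choroid: RPE→CSI).
5. **Statistics**: per visit and variable, a one-way within-subject ANOVA
   (F = MS_time/MS_subject×time) with Mauchly's sphericity test and
   conditional Greenhouse–Geisser adjustment; grader reliability via
   ICC(2,1) with F-based confidence intervals.

Details, defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
from ccvoid import (CCSpec, StudySpec, generate_diurnal_study,
                    RunConfig, run_study)

# a small synthetic diurnal study: 5 subjects, 1 visit, 5 timepoints
spec = StudySpec(n_subjects=5, n_visits=1, cc_spec=CCSpec(grid_size=128),
                 seed=7)
manifest = generate_diurnal_study(spec, "demo_study")

result = run_study(manifest, RunConfig(), out_dir="demo_results")
rows = result.records.rows
print(rows[["void_density_pct", "void_count", "void_mean_size_um2"]].mean())
r = result.anova["choroidal_thickness_um"][1]
print(f"choroid: F={r.F:.2f}, GG eps={r.gg_epsilon:.3f}, p={r.p_reported:.4f}")
```

prints (exact values depend only on the seed):

```
void_density_pct       15.649631
void_count            268.000000
void_mean_size_um2    603.815254
dtype: float64
choroid: F=4.96, GG eps=0.681, p=0.0086
```

The mean void density recovers the generator's 16% dropout target; the
choroidal thickness ANOVA detects the injected diurnal pattern (thickest in
the morning, ~4 µm shallower by afternoon), while the flow-void metrics
show no diurnal effect — the qualitative signature expected for healthy
eyes. `demo_results/` then contains `records.csv` (one row per
subject/visit/timepoint with all eight variables), `summary.csv`
(mean ± SD per timepoint) and `anova.json` (full test results per variable
and visit).

A command-line interface mirrors the library:

```bash
ccvoid simulate --spec study.yaml --out study/
ccvoid run --manifest study/manifest.csv --out results/
ccvoid quantify --cc cc.tiff --svp svp.tiff --faz faz.json --scale-um 10
ccvoid rm-anova --input results/records.csv --variable choroidal_thickness_um --visit 1
```

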