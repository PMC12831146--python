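# Methods

## The measurement problem

Perforating scleral vessels (PSVs) — presumed short posterior ciliary
arteries — enter the choroid through discrete scleral channels. Whether
choriocapillaris (CC) perfusion immediately around these entry sites
differs from the surrounding macula is a question about *local* flow
deficits measured against *global* deficit burden, in eyes whose axial
elongation simultaneously changes image magnification, choroidal
thickness, and global CC perfusion. This package implements the
quantification chain and the statistics needed to pose that question, and
a synthetic-data layer that makes every stage verifiable against known
truth.

## Image chain

**Slab convention.** Inputs are en-face slabs of a 16-µm CC layer starting
4 µm below Bruch's membrane, from fovea-centered 6 × 6 mm scans. Slab
extraction from volumes is upstream of this package; the data model
(`EnFaceImage`) carries only the 2-D raster, its isotropic pixel pitch and
a modality tag. The default raster is 1024 px for a 6-mm scan (pitch
5.859 µm), at which the 23.4-µm Phansalkar radius is exactly 4 px; raster
size is configurable and all physical parameters are specified in µm/mm,
not pixels.

**Compensation.** OCTA flow signal under attenuating structures (vessels,
media opacity, vignetting) is depressed multiplicatively, and the
structural OCT slab of the same layer is depressed alike. The compensated
image is flow / max(structure, ε), rescaled to [0, 1]; ε defaults to 1% of
the structural maximum so that near-zero structural signal cannot blow up
the ratio. Wherever the structural signal stays above ε the shared
multiplicative field cancels exactly.

**Binarization.** Phansalkar local thresholding, built for low-contrast
granular images, over a *circular* window (the parameter is a radius) with
reflective border padding:

t = μ_w · (1 + p·e^(−q·μ_w) + k·(σ_w/r − 1))

on [0, 1]-normalized input, constants k = 0.25, r = 0.5, p = 2, q = 10
(the parameterization in common use; only the algorithm and the 23.4-µm
radius are fixed by the source convention, so the constants are
configurable). Pixels at or below the local threshold are flow deficits.
Local mean and standard deviation are computed by convolution with the
normalized disk; an explicit per-pixel loop oracle in the test suite
checks bit-identical agreement.

**Vessel exclusion.** How "large" retinal vessels were delineated is not
standardized; the package's stated default is Otsu global thresholding of
the superficial-plexus slab, removal of connected components smaller than
a 36-µm square (capillary speckle), and isotropic dilation by 30 µm
(configurable) to cover shadow margins. Excluded pixels are removed from
the denominator of every flow-deficit percentage; the metrics are provably
insensitive to anything underneath them.

**Per-vessel metrics.** FDPSV is the deficit percentage of the evaluable
area inside the traced ROI; FD250 is the same over the ring of pixels with
Euclidean distance to the ROI in (0, 250] µm. The ring uses a distance
transform with the physical pitch as sampling, so its width is isotropic
in µm and matches the set definition exactly (tested against brute force).
Rings clipped by the frame border are computed on the in-frame portion and
flagged.

**VFD.** The frame is overlaid with a square grid of 0.1-mm² cells
(side ≈ 0.316 mm) anchored so the foveal center sits on a grid node; for
each cell intersecting the ROI the centroid of the intersection is taken,
and the VFD is the mean Euclidean centroid-to-fovea distance, with the
mean X and Y offsets as its decomposition. Taking "0.1 mm² units"
literally as an *area* makes a cell larger than the typical PSV
(≈ 0.05 mm²), so most real ROIs land in one cell and the VFD degenerates
to a single centroid distance — the result is then flagged
(`single_cell=True`) rather than silently reinterpreted; the cell area is
configurable, and setting it to one pixel's area reproduces the per-pixel
mean distance exactly. Anchoring the grid at the fovea makes the metric
exactly invariant under joint whole-pixel translations of ROI and fovea.
The fovea defaults to the frame center (fovea-centered scans) and can be
overridden.

**Magnification.** All quantities are computed in nominal image units and
corrected post hoc: linear measures × F, areas × F², with
F = 3.48 × 0.01306 × (AXL − 1.82) (≈ 1.066 at AXL 25.28 mm). F is
undefined for AXL ≤ 1.82 mm and this is an error, not a clamp.
Percentages are ratios of pixel counts and need no correction.

## Statistics

Observations are PSVs nested in eyes nested in subjects. Every regression
is a linear mixed model with a random intercept per subject and a
variance-component intercept per eye within subject, fitted by maximum
likelihood (statsmodels `MixedLM`). Fixed effects are reported with Wald
95% CIs and p-values; likelihood-ratio testing is available through the ML
fits. "R²" is marginal R² — var(Xβ̂) over var(Xβ̂) + σ²_subject + σ²_eye +
σ²_residual — the single-number convention adopted here since the
reporting convention upstream is not explicit. A singular fit (variance
component at zero) is flagged on the result object, not raised: it is the
expected behaviour on data that genuinely lack a variance component, and
in that limit the fixed effects agree with OLS (tested to 1e-4 relative).

Spearman screens use tie-corrected p-values; constant columns are reported
as missing rather than dropped. VIF_j = 1/(1−R²_j) from OLS of each
predictor on the rest; perfect collinearity reports ∞. Repeatability uses
the two-way, absolute-agreement, single-measurement ICC (ICC(A,1), the
standard choice for intra-grader agreement; computed via pingouin), with
its F-based 95% CI. Post-hoc power for one coefficient uses the noncentral
t-distribution with ncp = β̂/se, df = n_eff − k − 1, where n_eff is the
*subject-level* effective sample size — eyes and PSVs of one subject are
not independent evidence; se may be recovered from a 95% CI as
half-width/1.96. At extreme noncentrality, where scipy's noncentral t
loses accuracy, the asymptotic normal shift is used.

## The synthetic-data layer

**What the scene generator emulates.** (i) A quasi-regular granular flow
texture: band-pass-filtered Gaussian noise with a 50-µm correlation
length, thresholded at the exact quantile of the requested deficit
fraction, so ground-truth flow voids are contiguous blobs at a controlled
area fraction (default 0.18, the scale reported for healthy myopic eyes).
Void edges are softened by a 0.8-px Gaussian, as on real compensated
slabs; perfused and void intensities (0.85 / 0.12) carry mild smooth
modulation. (ii) One smooth multiplicative attenuation field — a sum of
2–3 broad Gaussians scaled to [1−amplitude, 1] — applied to flow and
structure alike: exactly the artifact class compensation targets, and the
reason the uncompensated estimate degrades while the compensated one does
not. (iii) A superficial slab with a bright large-vessel tree (curved
walks from the frame edges, 60–110 µm calibers) whose ground-truth
footprint is returned. (iv) Disjoint elliptical PSV ROIs (semi-axes
60–220 µm, giving areas on the reported 0.05-mm² scale) placed uniformly
in a 0.8–2.4 mm annulus around the fovea, avoiding the vessel tree, with
bounded retries and an explicit packing error. Images are float64 in
[0, 1] in memory; writing quantizes to the 16-bit file grid.

**What it does not emulate.** OCT speckle statistics, projection
artifacts, motion lines, segmentation error, staphyloma/tilt geometry, or
genuinely altered perfusion at PSV sites (FDPSV ≈ FD250 ≈ global CCFD% by
construction). Passing tests therefore demonstrate correctness of the
measurement chain under controlled conditions, not clinical performance on
device images.

**Cohort generator.** Per-PSV records from
response = β₀ + Σβ_j·x_j + b_subject + b_eye + ε, with b and ε independent
Gaussians (default SDs 5, 3, 7 — chosen so the total response SD matches
the reported ≈ 12% scale). Covariates are drawn at the reported cohort
means/SDs (age 28.3 ± 7.0 y, AXL 25.28 ± 1.09 mm with a fellow-eye-shared
component, SE and CT mildly collinear with AXL, global CCFD 17.9 ± 10.6%),
and the AXL–CCFD correlation is set by a Gaussian copula on standardized
scales (default 0.47, the observed association; 0.8 in the confounding
demonstrations). Default fixed effects take the adjusted-model magnitudes
(β_AXL = −2.37, β_CCFD = +1.02, ...), which is what produces the
univariable-positive / multivariable-negative AXL behaviour when the
confound is strong. The simulated response is *not* clipped to [0, 100]:
clipping would break the linearity on which CI-coverage calibration
rests; the [0, 100] invariant applies to image-derived percentages.

## Numerical and design choices

- Deficit polarity: pixels ≤ threshold are deficits (dark pixels).
- Radius conversion: radius_px = round(radius_um / pitch_um); a radius
  below one pixel is an error.
- Ring distance: Euclidean distance transform, not iterated dilation, so
  ring width is isotropic in physical units.
- Grid tie-breaks: grid cells are half-open; pixel centers are never
  exactly on cell boundaries in the default geometries.
- Compensation guard: ε = 1% of the structural maximum (the source recipe
  is silent on division guards).
- Empty evaluable area raises an explicit error — never a silent zero.
- Degenerate inputs: empty ROIs, constant superficial images, single-cell
  VFDs, and boundary variance fits all have defined, flagged behaviour.

## Problem sizes used in validation

The test suite validates the image chain at 256–1024 px rasters (oracle
equivalences at 64–128 px, where brute force is exact and fast), mask
recovery and compensation benefit over 20 seeded scenes at 512/256 px, CI
coverage over 200 cohorts of 400 subjects, and the confounding sign flip
over 100 cohorts of 150 subjects. The acceptance script uses six
1024-px scenes and one 31-subject cohort — the published study's scale.

## Known limitations

- The vessel-masking recipe (Otsu + caliber filter + dilation) is a stated
  default, not a community standard; Dice against the synthetic truth is
  ≈ 0.99, but real superficial slabs are harder.
- Wald CIs from ML fits are slightly anticonservative in small cohorts;
  coverage is calibrated at 400 subjects, not at 31.
- The VFD grid origin follows the fovea; a device grid anchored elsewhere
  would shift cell boundaries and change N slightly (the formulas are
  unaffected).
- CT/AXL is carried as a covariate (ct_um / axl_mm, µm/mm); no attempt is
  made to model choroidal thinning mechanistically.
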