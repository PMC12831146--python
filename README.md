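# ccpsv

Quantification of choriocapillaris (CC) flow deficits at perforating
scleral vessel (PSV) entry sites from en-face OCTA slabs, with the
downstream cohort statistics, exercisable end to end on synthetic data
with known ground truth.

## Who this is for

Ophthalmic image-analysis researchers who want a tested, reusable
implementation of the standard compensated-binarization recipe for
swept-source OCTA choriocapillaris slabs and the per-vessel metrics built
on top of it — without needing patient data to validate any stage.

## What it computes

Given a co-registered pair of en-face slabs of the same 16-µm CC layer
(flow OCTA + structural OCT) and a superficial-plexus image:

1. **Compensation** — the flow slab is multiplied pixel-wise by the inverse
   of the structural slab, removing shared multiplicative signal
   attenuation, and rescaled to [0, 1].
2. **Binarization** — Phansalkar local adaptive thresholding over a
   circular window of radius 23.4 µm,

   t = μ_w · (1 + p·e^(−q·μ_w) + k·(σ_w/r − 1)),  k = 0.25, r = 0.5, p = 2, q = 10,

   with pixels ≤ t marked as flow deficits.
3. **Large-vessel exclusion** — Otsu binarization of the superficial slab,
   restricted to large-caliber structures and dilated, masks shadowed CC.
4. **Metrics** — global CCFD% (dark-pixel fraction of evaluable area);
   per PSV: FDPSV (CCFD% inside the traced entry ROI), FD250 (CCFD% in a
   concentric 250-µm-wide ring), the ROI area, and the vessel-to-fovea
   distance VFD = (1/N)·Σᵢ √((Xᵢ−X₀)² + (Yᵢ−Y₀)²) over the centroids of a
   calibrated square grid of 0.1-mm² cells, decomposed into X/Y offsets.
   Linear measures scale by the Bennett–Littmann magnification factor
   F = 3.48 × 0.01306 × (AXL − 1.82) and areas by F².
5. **Statistics** — Spearman screens, univariable and multivariable linear
   mixed-effects models with nested random intercepts (subject, eye within
   subject, fitted by ML), marginal R², variance inflation factors,
   intraclass correlation for repeatability, and post-hoc power from the
   noncentral t-distribution.

The `ccpsv.synthetic` module generates scenes (granular CC texture with a
controlled deficit fraction, a shared smooth attenuation field, a
large-vessel tree, elliptical PSV ROIs) and per-PSV cohorts (nested random
intercepts plus a controllable axial-length–CCFD confound) with full
ground truth, so every stage is testable offline.

## Worked example

```sh
python examples/quantify_scene.py
```

```
ground-truth deficit fraction :  18.00 %
estimated global CCFD%        :  18.15 %
pixel agreement with truth    :  99.88 %
evaluable / excluded pixels   : 233813 / 28331
```

The scene was generated with an 18% deficit fraction and a 35% attenuation
artifact; after compensation and local thresholding the estimate lands
within 0.15 percentage points and 99.9% of pixels match the ground-truth
mask. The confounding demonstration:

```sh
python examples/cohort_statistics.py
```

```
univariable AXL beta   = +4.73 [+3.92, +5.54]
multivariable AXL beta = -2.20 [-3.10, -1.29]  (truth -2.37)
```

A truly negative axial-length effect appears positive when screened alone,
because axial length is correlated (ρ = 0.8 here) with global deficit
burden; adjusting for global CCFD% recovers the negative truth. The other
examples cover per-vessel metrics (`examples/psv_site_metrics.py`) and the
config-driven pipeline (`examples/full_pipeline.py`). A thin CLI wraps the
same pipeline: `ccpsv simulate|quantify|stats|all` (see `ccpsv --help`).

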