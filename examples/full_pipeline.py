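"""Run the whole pipeline — simulate, quantify, model — from one config.

Writes a scene bundle (TIFF slabs, PSV label masks, cohort CSV, manifest),
quantifies it into per-PSV metrics, and fits the full statistical report,
all under ./pipeline_demo/.  Identical seeds give byte-identical outputs.
"""

from ccpsv import CohortSimParams, PipelineConfig, SyntheticSceneParams, run_all

config = PipelineConfig(
    scene=SyntheticSceneParams(raster_px=512, n_psv=3, seed=42),
    cohort=CohortSimParams(n_subjects=31, seed=42),
)
result = run_all(config, "pipeline_demo")

print("multivariable mixed model (FDPSV ~ candidate predictors):")
print(result["multivariable"].to_frame().round(3).to_string(index=False))
print(f"\nmarginal R2 = {result['multivariable'].r2:.3f}")
print(f"post-hoc power for the AXL term = {result['posthoc_power']:.3f}")
print("report bundle written under pipeline_demo/ (scene/, stats/)")
# With the default simulation the cohort mirrors the published study's scale:
# 31 subjects, ~52 eyes, ~110 PSVs, global CCFD ~18%, and an AXL-CCFD
# correlation of 0.47.
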