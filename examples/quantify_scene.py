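"""Quantify global choriocapillaris flow deficits on a synthetic scene.

Generates a 6x6 mm en-face scene with a known 18% flow-deficit fraction and
a smooth attenuation artifact, runs inverse-structure compensation and
Phansalkar binarization, excludes large retinal vessels, and compares the
estimated global CCFD% against the generator's ground truth.
"""

from ccpsv import (
    SyntheticSceneParams,
    compensate,
    fd_percent,
    generate_cc_scene,
    phansalkar_binarize,
    vessel_exclusion_mask,
)

scene = generate_cc_scene(
    SyntheticSceneParams(raster_px=512, attenuation_amplitude=0.35, noise_sd=0.0, seed=1)
)
compensated = compensate(scene.flow, scene.structure)
deficit = phansalkar_binarize(compensated)
exclusion = vessel_exclusion_mask(scene.superficial, dilation_um=30.0)
result = fd_percent(deficit, exclusion)

truth_pct = 100.0 * scene.truth_deficit.pixels.mean()
agreement = 100.0 * (deficit.pixels == scene.truth_deficit.pixels).mean()

print(f"ground-truth deficit fraction : {truth_pct:6.2f} %")
print(f"estimated global CCFD%        : {result.ccfd_percent:6.2f} %")
print(f"pixel agreement with truth    : {agreement:6.2f} %")
print(f"evaluable / excluded pixels   : {result.evaluable_px} / {result.excluded_px}")
# CCFD% should land within a fraction of a percentage point of the truth:
# compensation removes the attenuation exactly, and the local threshold
# recovers the soft-edged flow voids almost pixel for pixel.
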