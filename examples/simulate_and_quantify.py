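"""Generate one synthetic embryo volume and quantify it.

Builds a noiseless gastrula-stage embryo with mosaic GFP reporter
expression and a half-activated effector channel, then runs the full
per-sample measurement: Otsu thresholds, 3D region masks, voxelwise GFP
normalization, the six region medians and the QC gates.
"""

import numpy as np

from optoquant import EmbryoTruth, generate_volume, quantify_sample

truth = EmbryoTruth(seed=42, shape=(32, 96, 96), n_nuclei=80, noise_sd=30.0)
volume, masks = generate_volume(truth, activation_level=0.5)

record = quantify_sample(volume)

print(f"embryo voxels:          {masks['embryo'].sum()}")
print(f"GFP coverage of embryo: {record.gfp_coverage:.2f}")
print(f"QC passed:              {record.qc.passed}")
print(f"median raw effector (DAPI region):       {record.raw_dapi:.1f} AU")
print(f"median normalized effector (GFP region): {record.norm_gfp:.3f} AU/AU")
print(f"median normalized effector (DAPI+GFP):   {record.norm_dapi_gfp:.3f} AU/AU")

# The normalized GFP-region median approximates gain * activation plus a
# baseline/reporter ratio term: with gain 2 and activation 0.5 the driven
# component is ~1.0 AU/AU; the mosaic makes the raw medians heterogeneous
# while the normalized medians stay calibrated.
expected = truth.effector_gain * 0.5
print(f"programmed gain x activation:            {expected:.3f} AU/AU")
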