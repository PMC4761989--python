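"""Train on a few phantoms, segment a held-out one, and print its metrics.

A phantom is a 128 x 16 x 160 voxel synthetic SD-OCT volume with one
serous PED (an arch-shaped hypo-reflective dome between the lifted RPE
floor and Bruch's membrane) plus one confounding fluid pocket above the
RPE floor and multiplicative speckle. The pipeline denoises, segments the
retinal surfaces, filters candidate regions with AdaBoost, and runs the
shape-constrained graph cut with morphological refinement.
"""

import numpy as np

from pedseg import generate_phantom, segment_volume, train_model
from pedseg.phantom import random_phantom_params

train_set = []
for i in range(4):
    volume, truth = generate_phantom(random_phantom_params(100 + i))
    train_set.append((volume, truth.ped_mask))
clf, params = train_model(train_set, tune_weights=True)
print(f"classifier: {len(clf.stumps)} stumps; "
      f"energy weights (R, S, B) = ({params.weights.lambda_r:.2f}, "
      f"{params.weights.lambda_s:.2f}, {params.weights.lambda_b:.2f})")

volume, truth = generate_phantom(random_phantom_params(999))
result = segment_volume(volume, clf, params, truth=truth.ped_mask,
                        retina=truth.retina_mask)
m = result.metrics
print(f"truth PED voxels:     {truth.ped_mask.count()}")
print(f"segmented PED voxels: {result.final_mask.count()}")
print(f"TPVF {100 * m.tpvf:.2f}%  FPVF {100 * m.fpvf:.3f}%  "
      f"DSC {100 * m.dsc:.2f}%  PPV {100 * m.ppv:.2f}%")
# TPVF = fraction of the true PED recovered; FPVF = false positives as a
# fraction of the non-PED retina; DSC/PPV = overlap and precision.
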