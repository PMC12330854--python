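"""First-level GLM on a phantom and overlap with a reference mask.

Builds the 10-regressor design (Random/Okay/Suppress boxcars, parametric
urge, blinks, plus temporal derivatives), plants an urge-tracking voxel set
in white noise, fits the voxelwise GLM, thresholds the Urge > Random
contrast at Z >= 3.2, and reports conjunction and overlap metrics against
the planted mask.
"""

import numpy as np

from urgepfm import behaviour, glm, synthgen

schedule = synthgen.make_block_schedule()
urge, blinks = synthgen.simulate_urge_and_blinks(schedule, seed=2)
z = behaviour.downsample_standardise(urge)
design = glm.build_design_matrix(schedule, z, blinks)
print("design columns:", ", ".join(design.columns))

rng = np.random.default_rng(2)
grid = (12, 12, 4)
n_vols = design.matrix.shape[0]
data = rng.standard_normal(grid + (n_vols,))
planted = np.zeros(grid, bool)
planted[4:8, 4:8, 1:3] = True
urge_col = design.column("Urge")
data[planted] += 2.0 / urge_col.std() * urge_col  # per-voxel CNR 2

contrast = design.contrast_vector(["Urge"], ["Random"])
res = glm.fit_glm(data, design, contrast)
print(f"\nUrge > Random: {int(res.binary.sum())} voxels above Z = 3.2 "
      f"({int(planted.sum())} planted)")

conj = glm.conjunction(res.binary, planted)
rep = glm.overlap_metrics(res.binary, planted)
print(f"conjunction with planted mask: {int(conj.sum())} voxels")
print(f"overlap: {rep.percent_of_b:.1f}% of the planted mask, "
      f"Jaccard {rep.jaccard:.2f}, Dice {rep.dice:.2f}")
# High Dice/Jaccard means the thresholded contrast found the planted
# urge-tracking voxels with few false positives (the Z >= 3.2 threshold
# admits ~7 noise voxels per 10,000 under the null).
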