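"""Build Gaussian age-weighted activation templates from a synthetic cohort.

Every participant contributes to the template at every target age,
weighted by how close their baseline age lies to it (sigma = 4 years).
"""

import numpy as np

import agekernel as ak

cfg = ak.SyntheticConfig(n_participants=120, grid_shape=(8, 8, 8), seed=0)
cohort, truth = ak.generate_cohort(cfg)
betas = ak.generate_activation(cohort, truth, "MEM", "baseline")

w = ak.gaussian_weights(cohort.baseline_ages, target_age=35.0)
print(f"kernel weights at target age 35: max {w.weights.max():.5f} "
      f"(a 35-year-old would get {1 / (4 * np.sqrt(2 * np.pi)):.5f}), "
      f"min {w.weights.min():.2e}")

series = ak.weighted_series(betas, cohort.baseline_ages)
print(f"weighted template series: {series.n_ages} target ages "
      f"({series.target_ages[0]}..{series.target_ages[-1]}) x {series.values.shape[1]} voxels")

# each template is a convex combination of participant maps, so it stays
# inside the per-voxel range of the cohort
v0 = betas.values[:, 0]
print(f"voxel 0: cohort range [{v0.min():.2f}, {v0.max():.2f}], "
      f"template range [{series.values[:, 0].min():.2f}, {series.values[:, 0].max():.2f}]")
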