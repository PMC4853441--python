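"""Generate a synthetic stroke cohort and inspect its structure.

Builds the default 93-subject cohort on the 32^3 toy template: contiguous
unilateral lesions with a territory-like prevalence core, fluency and
auxiliary test scores driven by ground-truth lesion weights plus
demographics and noise.
"""

import numpy as np

from fluencymap import lesion_prevalence, make_cohort

cohort = make_cohort(seed=1)
prev = lesion_prevalence(cohort)

print(f"subjects: {cohort.n_subjects}")
print(f"grid: {cohort.grid.dims}, voxel {cohort.grid.voxel_size} mm")
volumes = [m.volume_ml for m in cohort.lesion_maps]
print(f"lesion volume: median {np.median(volumes):.2f} ml, "
      f"range {min(volumes):.2f}-{max(volumes):.2f} ml")
print(f"max per-voxel lesion count: {prev.counts.max()} "
      f"(voxels damaged in >=3 subjects: {(prev.counts >= 3).sum()})")
print("missing per test:", cohort.missingness())

# The per-voxel counts say how often each template location is lesioned;
# voxels below the display threshold (3) are hidden in prevalence figures
# but kept exactly in `prev.counts`.
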