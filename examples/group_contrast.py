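"""Patch-level group contrast, patients versus controls.

Averages thickness into patches for every subject, residualizes age and sex
across the cohort, and tests patients < controls with a seeded label
permutation and max-statistic correction.
"""

import numpy as np

from mosaicmap import SimulationConfig, group_permutation_test, simulate_cohort
from mosaicmap.group_stats import residualize_covariates
from mosaicmap.parcellate import patch_means

cfg = SimulationConfig(seed=5, n_controls=25, n_patients=25, V=600, N=60,
                       atrophy_effect=4.0, atrophy_patch_fraction=0.15)
cohort = simulate_cohort(cfg)

ids = cohort.control_ids + cohort.patient_ids
profiles = [patch_means(cohort.vertex_maps[s], cohort.scheme) for s in ids]
covars = cohort.cohort.frame.set_index("subject_id").loc[ids].reset_index()
profiles = residualize_covariates(profiles, covars)

n_ctrl = len(cohort.control_ids)
res = group_permutation_test(profiles[n_ctrl:], profiles[:n_ctrl],
                             n_perm=5000, seed=11, correction="maxstat")

sig = np.flatnonzero(res.significant) + 1
print(f"{res.n_permutations} permutations "
      f"({'exhaustive' if res.exhaustive else 'Monte Carlo'})")
print(f"significant patches (patients thinner): {sig.size} of {cfg.N}")
print(f"strongest contrast: patch {int(np.nanargmin(res.patch_stat)) + 1}, "
      f"mean difference {np.nanmin(res.patch_stat):.3f} mm, "
      f"p = {res.p[np.nanargmin(res.patch_stat)]:.4f}")
# Patches injected with atrophy in ~15% of patients drop the group mean by a
# fraction of the injected effect; the max-statistic correction keeps the
# family-wise error over the 60 patches at the nominal level.
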