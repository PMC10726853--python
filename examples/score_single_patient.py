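"""Score one patient's cortical thickness map with the mosaic approach.

Builds a small synthetic cohort (89 healthy controls, one patient with
6-reference-SD atrophy injected into ~10% of 100 patches), runs the full
MAP pipeline and prints what it finds.
"""

import numpy as np

from mosaicmap import SimulationConfig, run_map_subject, simulate_cohort, true_burden

cfg = SimulationConfig(seed=7, n_controls=89, n_patients=1, V=2000, N=100,
                       atrophy_effect=6.0, atrophy_patch_fraction=0.1)
cohort = simulate_cohort(cfg)

patient = cohort.maps_for(cohort.patient_ids)[0]
controls = cohort.maps_for(cohort.control_ids)

result = run_map_subject(patient, controls, cohort.scheme, cohort.mask,
                         alpha=0.05, correction="per-patch")

truth = cohort.ground_truth[patient.subject_id]
detected = np.flatnonzero(result.thin) + 1

print(f"patient {result.subject_id}: {result.n_patches} patches, "
      f"{result.n_ref} reference controls")
print(f"thin-patch fraction: {result.thin_patch_fraction:.3f} "
      f"(true injected burden {true_burden(cohort, patient.subject_id):.3f})")
print(f"injected patches: {truth.tolist()}")
print(f"detected patches: {detected.tolist()}")
print(f"smallest attainable p with {result.n_ref} controls: "
      f"{1 / result.n_permutations:.4f} (all p lie on the grid k/{result.n_permutations})")
# The thin-patch fraction is the scalar biomarker: the share of evaluable
# cortical patches whose thickness is significantly below the reference
# cohort at the chosen alpha.
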