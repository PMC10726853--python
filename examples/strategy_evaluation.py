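"""Which analysis strategy correlates best with clinical disease burden?

Simulates a cohort whose lesion volume (LV) is coupled to true atrophy
burden more strongly than the EDSS disability score, computes each
patient's burden scalar under several strategies (MAP at two parcellation
resolutions, vertexwise Crawford-Howell + FDR), correlates the scalars
with LV and EDSS, and runs the strategy-comparison ANOVAs.
"""

import numpy as np
from scipy import stats

from mosaicmap import (
    SimulationConfig, compare_strategies, fit_reference, make_parcellation,
    patch_means, pearson_r, simulate_cohort, threshold_map,
)
from mosaicmap.baselines import fdr_bh
from mosaicmap.map_core import exhaustive_null, patch_pvalues, zscore_patches

cfg = SimulationConfig(seed=3, n_controls=89, n_patients=120, V=1000, N=100,
                       atrophy_effect=6.0, atrophy_patch_fraction=0.1,
                       clinical_coupling=0.6, edss_coupling=0.35)
cohort = simulate_cohort(cfg)
controls = cohort.maps_for(cohort.control_ids)
ctrl_mat = np.vstack([m.values for m in controls])
mu, sd = ctrl_mat.mean(axis=0), ctrl_mat.std(axis=0, ddof=1)

schemes = {100: cohort.scheme, 50: make_parcellation(cfg.V, 50)}
refs = {n: fit_reference([patch_means(m, s) for m in controls])
        for n, s in schemes.items()}

fractions = {("MAP", n): [] for n in schemes} | {("CT", 0): []}
for sid in cohort.patient_ids:
    vm = cohort.vertex_maps[sid]
    for n, scheme in schemes.items():
        prof = patch_means(vm, scheme)
        z = zscore_patches(prof, refs[n])
        p = patch_pvalues(z, exhaustive_null(prof, refs[n]))
        thin = threshold_map(p, 0.05)
        fractions[("MAP", n)].append(thin[np.isfinite(p)].mean())
    t = (vm.values - mu) / (sd * np.sqrt(1 + 1 / len(controls)))
    p_vert = stats.t.cdf(t, len(controls) - 1)
    fractions[("CT", 0)].append(fdr_bh(p_vert, 0.05).mean())

pats = cohort.cohort.patients
records = []
for (metric, resolution), frac in fractions.items():
    for outcome, col in (("LV", "lesion_volume"), ("EDSS", "edss")):
        r = pearson_r(frac, pats[col].to_numpy())
        records.append({"outcome": outcome, "metric": metric,
                        "correction": "Perm" if metric == "MAP" else "FDR",
                        "smoothing_or_parcellation": resolution, "r": r})
        print(f"{metric}-{resolution:<4} vs {outcome:4s}: r = {r:+.3f}")

report = compare_strategies(records)
print("\noutcome ANOVA (LV vs EDSS): "
      f"F = {report['outcome_anova']['F']:.1f}, "
      f"p = {report['outcome_anova']['p']:.4f}")
print("best strategy:", report["ranked"].iloc[0].to_dict())
# LV correlations exceed EDSS correlations for every strategy because the
# generator couples LV to atrophy burden more strongly -- the qualitative
# ordering the evaluation layer is built to detect.
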