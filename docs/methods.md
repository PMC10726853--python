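# Methods

## The MAP statistic

For a patient with patch-mean thickness `x` and an HC reference cohort of
n profiles on the same parcellation, the per-patch z-score is
`z_k = (x_k − m_k) / s_k` with `m_k`, `s_k` the reference mean and sample
SD (n−1 denominator). A Crawford–Howell variant dividing additionally by
`sqrt(1 + 1/n)` is available behind a flag but off by default: the plain z
is the statistic of the mosaic approach, and the permutation step below —
not the normal approximation — carries the inference.

"Exhaustive permutation" is realized as the n+1 leave-one-as-singleton
relabelings of the pooled {patient} ∪ HC set: that is the complete
relabeling space of a singleton-versus-group design, and the only reading
consistent with discretely gridded p-values at k/(n+1). Each relabeling
recomputes z per patch against the remaining n subjects. The p-value is
the tie-inclusive fraction of relabelings with z at or below the observed
z, so the observed relabeling always counts and `p ≥ 1/(n+1)`. Only low
thickness is tested (one-sided, atrophy direction).

Two thresholding modes exist because "per-patch permutation p" and
"family-wise error control" are distinct readings of the same inferential
step: `per-patch` thresholds each p at α directly (default, α = .05);
`max-stat` compares each observed z against the null distribution of the
per-relabeling *minimum* z across patches, which controls the probability
of any false call. At N = 1 the two coincide (a tested reduction); with
many patches max-stat is strictly more conservative. Neither mode is
asserted to be the historical computation — both are provided and the
default is the per-patch rule.

Degenerate patches (reference SD exactly 0, or empty after masking) carry
NaN z and NaN p, are never silently ±inf, and are excluded from both the
numerator and the denominator of the thin-patch fraction. An alternative
convention would assign p = 1 when all pooled values tie; we prefer "not
evaluable" over fabricating certainty from zero variance.

Implementation note: the leave-one-out z matrix is computed vectorized from
column sums, but row 0 (the observed labeling) is recomputed with the exact
expression used by the z-scoring function so the `≤` tie with itself holds
bit-for-bit; without this, round-off can push the observed p below the
attainable floor.

## Baselines

- **σ→FWHM**: FWHM = σ·2√(2 ln 2) ≈ σ·2.35482.
- **Smoothing** is iterated mass-conserving diffusion on the mesh graph:
  `new[v] = w·v + (1−w)·Σ_{u∈N(v)} old[u]/deg(u)` with w = 0.5, restricted
  to in-mask vertices. The iteration count matches the accumulated
  random-walk variance `(1−w)·edge²` per step to σ². This conserves the
  global mean on any mesh, contracts variance, and preserves constants on
  regular (closed) meshes; it is *not* a geodesic Gaussian (true geodesic
  smoothing needs full surface geometry, out of scope here), but it honors
  the contracts downstream comparisons rely on: identity at σ = 0,
  monotone contraction in σ, no bleeding across the mask.
- **Singleton-versus-group GLM**: per vertex, regress control thickness on
  [1, age, sex], score the patient by the prediction-interval t
  `t = (y₀ − x₀β̂) / (s·sqrt(1 + x₀ᵀ(XᵀX)⁻¹x₀))`, df = n − rank, one-sided
  p for thinness. With no covariates this is exactly the Crawford–Howell
  single-case t (verified against the closed form to 1e−10).
- **Corrections**: Benjamini–Hochberg step-up (delegated to statsmodels)
  and max-statistic permutation FWE over the exhaustive singleton
  relabelings. Threshold-free cluster enhancement is deliberately not
  implemented — it is an external tool's algorithm, and max-stat preserves
  the FWE-vs-FDR comparison the evaluation layer needs. The max-stat
  baseline path operates on unadjusted thickness (covariate refitting per
  relabeling is not performed).
- **Burden fraction**: significant vertices / mask size, the vertexwise
  analogue of the thin-patch fraction.

## Group contrast and evaluation

The group-level patch statistic is the difference of group means of patch
thickness (patient − control), tested one-sided by label permutation:
exhaustive enumeration when ≤ 10 subjects (pure tie-inclusive ratio),
otherwise seeded Monte-Carlo with +1 smoothing, `p = (1 + #{null ≤ obs}) /
(n_perm + 1)`, default 5000 permutations. Covariates are handled by
residualizing patch means on [1, age, sex] across all subjects before the
permutation. The statistic runs on thickness means — not on z-maps or
binary thin-calls — because that is the only variant fully determined by
the GLM framing; the alternatives would be equally defensible.

The evaluation layer reduces each strategy to one Pearson r per clinical
outcome (raw LV in mL and raw EDSS; no transformation) and tests three
hypotheses with clean one-way ANOVAs: (1) LV vs EDSS as outcome, (2) the
GM metric / approach (MAP vs each standard metric, Tukey HSD follow-up),
(3) none-vs-any smoothing within the standard approaches and none-vs-any
parcellation within MAP. The original study's exact factor coding for its
printed F statistics is not reconstructable from its text, so those F
values are documented as non-targets; the package's ANOVAs answer the same
three questions on whatever strategy table they are given.

Demographic utilities operate on printed summaries: Welch t with
Welch–Satterthwaite df from (n, mean, SD) pairs, and the Yates-corrected
χ² on a 2×2 table (continuity term floored at zero only when |O−E| < 0.5,
matching common implementations).

## Synthetic cohorts

The generator emulates the study conditions the method targets: 89 HC and
465 patients by default, thickness anchored at 2.41 ± 0.11 mm (HC regional
mean ± between-subject SD), patient LV lognormal with mean 5.39 mL / SD
8.41 mL, EDSS on the half-point 0–10 grid with median 1.50 / IQR 2.00.

Per subject and patch, the patch-level mean is `base_mean + patch_offset_k
+ N(0, base_sd_between)`, with patch offsets (SD 0.03 mm) drawn once per
cohort for regional variation, plus vertex noise N(0, 0.3 mm). Patients
draw an individual atrophy probability from a Beta distribution with mean
`atrophy_patch_fraction` and concentration 20 — patient-to-patient burden
heterogeneity is what makes burden–clinical correlations meaningful — and
each atrophic patch loses `atrophy_effect` × the generative SD of its
patch mean, `sqrt(base_sd_between² + vertex_noise_sd²/patch_size)`.
Default effect 4 SD; the recovery studies use 6 SD.

Clinical coupling is a Gaussian copula on the standardized true burden.
For LV, the latent correlation is inflated by the lognormal attenuation
factor `sqrt(e^{σ²}−1)/σ` so that the *raw-scale* Pearson correlation
matches `clinical_coupling` (default 0.6); couplings above ≈ 0.71 are
infeasible under this marginal and raise an error. EDSS uses a weaker
rank coupling (default 0.35), mirroring the empirical observation that
structural burden tracks lesion load more closely than disability.

Reproducibility: every subject has a substream keyed by (seed, subject
index), with patient indices offset by 10⁶, so control maps are
bit-identical across runs and under changes of the patient count.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: cortical geometry and the real topography of
atrophy; the *shared* between-subject component of thickness (here
base_sd_between is independent across patches, so a subject who is
globally thin everywhere does not occur, which real normative pipelines
must handle by covariate modeling or global scaling); scanner and
sequence effects; spatial autocorrelation of vertex noise beyond patch
structure; and lesion topography.

## Numerical and design choices

- All statistics treat parcellation label 0 (medial wall / unassigned) as
  outside the analysis; empty patches propagate NaN rather than a value.
- Patch means are unweighted vertex averages (no area weighting — vertex
  areas are unavailable in CSV mode, and patch averaging is defined over
  vertices).
- Hemispheres are one concatenated vertex vector; per-hemisphere files
  concatenate at load.
- GIFTI scalars are written float32 (the surface-format norm); CSV paths
  round-trip at full double precision.
- Problem sizes in the test and acceptance studies — 100–2000 vertices,
  50–100 patches, 120–2000 simulated patients — are chosen so each study
  gives stable statistics at desk scale; MAP itself is O((n_ref+1)·N) per
  patient and runs at the full 59k-vertex, 1000-patch scale without
  difficulty.
- Known limitations: no longitudinal modeling, no age/sex-matched
  reference subgrouping, no external normative databases, and the
  covariate-adjusted max-stat baseline noted above.
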