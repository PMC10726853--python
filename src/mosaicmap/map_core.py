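"""The mosaic-approach (MAP) statistic.

For one patient and a healthy-control (HC) reference cohort, each cortical
patch gets

1. a z-score: the patient's patch-mean thickness rated against the HC
   patch means, ``z_k = (x_k - mean_ref_k) / sd_ref_k`` (sample SD, n-1);
2. an exhaustive-permutation p-value: the patient is pooled with the n_ref
   controls, every pooled subject is in turn treated as the singleton and
   re-scored against the remaining n_ref, and ``p_k`` is the fraction of the
   n_ref + 1 relabelings whose z is <= the observed patient z.  This is the
   only exhaustive relabeling scheme for a singleton-versus-group design, so
   p-values live on the discrete grid k / (n_ref + 1);
3. a thin/not-thin call at level alpha (default .05), either per patch
   directly on the permutation p, or with a max-statistic step across
   patches (family-wise error control in the Nichols-Holmes sense).

The scalar biomarker is the *thin-patch fraction*: the fraction of evaluable
patches called thin.  Only abnormally LOW thickness is called (one-sided,
atrophy direction).  The whole procedure is deterministic: no sampling
enters anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConsistencyError, ValidationError
from .io import CorticalMask, ParcellationScheme, VertexMap
from .parcellate import PatchProfile, patch_means

__all__ = [
    "ReferenceModel",
    "AtrophyResult",
    "fit_reference",
    "zscore_patches",
    "exhaustive_null",
    "patch_pvalues",
    "threshold_map",
    "thin_patch_fraction",
    "run_map_subject",
    "residualize_profiles",
]


@dataclass
class ReferenceModel:
    """Per-patch normative statistics of the HC cohort.

    The full control profile matrix is retained because the exhaustive
    permutation re-derives leave-one-out references from it.
    """

    patch_mean_ref: np.ndarray
    patch_sd_ref: np.ndarray
    reference_profiles: np.ndarray  # n_ref x N
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.reference_profiles = np.asarray(self.reference_profiles, dtype=float)
        if self.reference_profiles.ndim != 2:
            raise ValidationError("reference_profiles must be n_ref x N")
        if self.n_ref < 2:
            raise ValidationError(
                f"need >= 2 control profiles, got {self.n_ref}"
            )

    @property
    def n_ref(self) -> int:
        return int(self.reference_profiles.shape[0])

    @property
    def n_patches(self) -> int:
        return int(self.reference_profiles.shape[1])

    @property
    def degenerate(self) -> np.ndarray:
        """Patches where the reference SD is 0 or undefined (z not computable)."""
        with np.errstate(invalid="ignore"):
            return ~(self.patch_sd_ref > 0)


@dataclass
class AtrophyResult:
    """Per-patch z, permutation p, thin calls and the thin-patch fraction."""

    subject_id: str
    z: np.ndarray
    p: np.ndarray
    thin: np.ndarray
    patch_sizes: np.ndarray
    alpha: float
    n_ref: int
    n_permutations: int
    thin_patch_fraction: float
    correction: str = "per-patch"

    @property
    def evaluable(self) -> np.ndarray:
        return np.isfinite(self.p)

    @property
    def n_patches(self) -> int:
        return int(self.z.size)


def fit_reference(profiles: Sequence[PatchProfile]) -> ReferenceModel:
    """Per-patch mean and sample SD (n-1) across control profiles.

    Patches with SD exactly 0 are flagged degenerate; patches empty in any
    control propagate NaN and are likewise degenerate.
    """
    if len(profiles) < 2:
        raise ValidationError(f"need >= 2 control profiles, got {len(profiles)}")
    sizes = {p.n_patches for p in profiles}
    if len(sizes) != 1:
        raise ConsistencyError(f"mixed parcellation sizes among controls: {sorted(sizes)}")
    mat = np.vstack([p.patch_means for p in profiles])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    return ReferenceModel(
        patch_mean_ref=mean,
        patch_sd_ref=sd,
        reference_profiles=mat,
        subject_ids=[p.subject_id for p in profiles],
    )


def zscore_patches(
    patient: PatchProfile, ref: ReferenceModel, crawford_howell: bool = False
) -> np.ndarray:
    """z per patch; NaN (never silent infinity) where the reference SD is 0
    or either side is undefined.

    ``crawford_howell=True`` divides additionally by sqrt(1 + 1/n_ref),
    the single-case prediction-interval correction; off by default since the
    plain z is the MAP statistic.
    """
    if patient.n_patches != ref.n_patches:
        raise ConsistencyError(
            f"patient has {patient.n_patches} patches, reference {ref.n_patches}"
        )
    denom = ref.patch_sd_ref.copy()
    if crawford_howell:
        denom = denom * np.sqrt(1.0 + 1.0 / ref.n_ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (patient.patch_means - ref.patch_mean_ref) / denom
    z[ref.degenerate] = np.nan
    return z


def _loo_zscores(pooled: np.ndarray) -> np.ndarray:
    """Leave-one-as-singleton z for every row of ``pooled`` ((n+1) x N).

    Row i is scored against the mean/SD (n-1 denominator) of the other n
    rows, column by column.  Cells where the leave-one-out SD is 0, or any
    value involved is NaN, are NaN.
    """
    m, n_patches = pooled.shape
    n = m - 1
    col_sum = np.nansum(pooled, axis=0)
    col_sumsq = np.nansum(pooled**2, axis=0)
    any_nan = np.any(np.isnan(pooled), axis=0)
    loo_mean = (col_sum[None, :] - pooled) / n
    # sum of squared deviations of the leave-one-out set
    ss = col_sumsq[None, :] - pooled**2 - n * loo_mean**2
    ss = np.maximum(ss, 0.0)  # guard tiny negative round-off
    with np.errstate(invalid="ignore", divide="ignore"):
        loo_sd = np.sqrt(ss / (n - 1))
        z = (pooled - loo_mean) / loo_sd
    z[~np.isfinite(z)] = np.nan
    z[:, any_nan] = np.nan
    return z


def exhaustive_null(patient: PatchProfile, ref: ReferenceModel) -> np.ndarray:
    """All n_ref + 1 leave-one-as-singleton relabelings of the pooled set.

    Row 0 is the true patient as singleton (identical to
    :func:`zscore_patches`); rows 1..n_ref are the controls in reference
    order, each scored against the other n_ref pooled subjects (which then
    include the patient).  Each patch is scored separately, preserving the
    physiological thickness differences across the cortex.
    """
    if patient.n_patches != ref.n_patches:
        raise ConsistencyError(
            f"patient has {patient.n_patches} patches, reference {ref.n_patches}"
        )
    pooled = np.vstack([patient.patch_means[None, :], ref.reference_profiles])
    null = _loo_zscores(pooled)
    # row 0 must equal zscore_patches bit-for-bit so the observed relabeling
    # always satisfies the <= tie rule (guaranteeing p >= 1/(n_ref+1)); the
    # streaming-sum formulation above differs by round-off, so recompute it
    # with the reference model's own statistics.
    null[0] = zscore_patches(patient, ref)
    return null


def patch_pvalues(observed_z: np.ndarray, null_z: np.ndarray) -> np.ndarray:
    """p_k = #{rows r: null_z[r, k] <= observed_z[k]} / n_rows.

    Ties count as <=, and the observed relabeling is itself one row, so
    p >= 1/n_rows always.  Undefined (NaN) null cells count as NOT smaller;
    an undefined observed z gives an undefined p.
    """
    observed_z = np.asarray(observed_z, dtype=float)
    null_z = np.asarray(null_z, dtype=float)
    if null_z.ndim != 2 or null_z.shape[1] != observed_z.size:
        raise ConsistencyError("null matrix width must match observed z length")
    with np.errstate(invalid="ignore"):
        counts = np.sum(null_z <= observed_z[None, :], axis=0)
    p = counts / null_z.shape[0]
    p = np.where(np.isfinite(observed_z), p, np.nan)
    return p


def _maxstat_pfwe(observed_z: np.ndarray, null_z: np.ndarray) -> np.ndarray:
    """FWE-corrected p by the min-across-patches null distribution
    (one-sided low: the extreme statistic is the per-row minimum z)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_min = np.nanmin(null_z, axis=1)
    with np.errstate(invalid="ignore"):
        counts = np.sum(row_min[:, None] <= observed_z[None, :], axis=0)
    p_fwe = counts / null_z.shape[0]
    return np.where(np.isfinite(observed_z), p_fwe, np.nan)


def threshold_map(
    p: np.ndarray,
    alpha: float = 0.05,
    correction: str = "per-patch",
    observed_z: np.ndarray | None = None,
    null_z: np.ndarray | None = None,
) -> np.ndarray:
    """Binary thin calls at level alpha.

    ``per-patch`` thresholds each permutation p directly (p_k <= alpha).
    ``max-stat`` additionally controls the family-wise error across patches:
    a patch is thin iff its observed z falls at or below the alpha-quantile
    of the null distribution of per-relabeling minimum z (requires
    ``observed_z`` and ``null_z``).
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(p, dtype=float)
    if null_z is not None and alpha < 1.0 / null_z.shape[0]:
        warnings.warn(
            f"alpha={alpha} is below the smallest attainable permutation "
            f"p-value 1/{null_z.shape[0]}; no patch can be called thin"
        )
    if correction == "per-patch":
        with np.errstate(invalid="ignore"):
            return (p <= alpha) & np.isfinite(p)
    if correction == "max-stat":
        if observed_z is None or null_z is None:
            raise ValidationError("max-stat correction needs observed_z and null_z")
        p_fwe = _maxstat_pfwe(np.asarray(observed_z, dtype=float), null_z)
        with np.errstate(invalid="ignore"):
            return (p_fwe <= alpha) & np.isfinite(p_fwe)
    raise ValidationError(f"unknown correction {correction!r}")


def thin_patch_fraction(thin: np.ndarray, evaluable: np.ndarray) -> float:
    """#(thin and evaluable) / #evaluable."""
    thin = np.asarray(thin, dtype=bool)
    evaluable = np.asarray(evaluable, dtype=bool)
    if thin.size != evaluable.size:
        raise ConsistencyError("thin and evaluable lengths differ")
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValidationError("no evaluable patch")
    return float(np.sum(thin & evaluable) / n_eval)


def residualize_profiles(
    profiles: Sequence[PatchProfile],
    covariates: np.ndarray,
    fit_rows: np.ndarray | None = None,
) -> list[PatchProfile]:
    """Residualize patch means on covariates (design [1 | covariates]).

    Coefficients are estimated on ``fit_rows`` only (e.g. controls) and the
    fitted effect is removed from every profile, so a patient's deviation
    from the normative age/sex trend is preserved.
    """
    mat = np.vstack([p.patch_means for p in profiles])
    X = np.column_stack([np.ones(len(profiles)), np.asarray(covariates, dtype=float)])
    rows = np.arange(len(profiles)) if fit_rows is None else np.asarray(fit_rows)
    if np.linalg.matrix_rank(X[rows]) < X.shape[1]:
        raise ValidationError("covariate design is rank deficient")
    beta, *_ = np.linalg.lstsq(X[rows], mat[rows], rcond=None)
    resid = mat - X @ beta
    out = []
    for i, prof in enumerate(profiles):
        out.append(
            PatchProfile(
                subject_id=prof.subject_id,
                patch_means=np.where(prof.evaluable, resid[i], np.nan),
                patch_sizes=prof.patch_sizes,
            )
        )
    return out


def run_map_subject(
    patient: VertexMap,
    controls: Sequence[VertexMap],
    scheme: ParcellationScheme,
    mask: CorticalMask | None = None,
    alpha: float = 0.05,
    correction: str = "per-patch",
) -> AtrophyResult:
    """End-to-end MAP for one patient.

    Composes patch averaging, reference fitting, the exhaustive permutation
    null, p-values, thresholding and the thin-patch fraction.  Fully
    deterministic.
    """
    patient_prof = patch_means(patient, scheme, mask)
    control_profs = [patch_means(c, scheme, mask) for c in controls]
    ref = fit_reference(control_profs)
    z = zscore_patches(patient_prof, ref)
    null = exhaustive_null(patient_prof, ref)
    p = patch_pvalues(z, null)
    thin = threshold_map(p, alpha=alpha, correction=correction,
                         observed_z=z, null_z=null)
    frac = thin_patch_fraction(thin, np.isfinite(p))
    return AtrophyResult(
        subject_id=patient.subject_id,
        z=z,
        p=p,
        thin=thin,
        patch_sizes=patient_prof.patch_sizes,
        alpha=alpha,
        n_ref=ref.n_ref,
        n_permutations=null.shape[0],
        thin_patch_fraction=frac,
        correction=correction,
    )
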