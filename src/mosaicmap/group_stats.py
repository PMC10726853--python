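"""Nonparametric group-level patch contrast (patients vs. controls).

The per-patch statistic is the difference of group means of patch thickness
(patient - control), tested one-sided in the atrophy direction by permuting
group labels.  When the total number of subjects is <= 10 every label
assignment is enumerated and p is the exact tie-inclusive ratio; otherwise
n_perm seeded Monte-Carlo draws are used with +1 smoothing,
p = (1 + #{null <= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError, ConsistencyError
from .baselines import fdr_bh
from .parcellate import PatchProfile

__all__ = ["GroupContrastResult", "group_permutation_test", "residualize_covariates"]

EXHAUSTIVE_MAX_SUBJECTS = 10


@dataclass
class GroupContrastResult:
    patch_stat: np.ndarray   # mean(patient) - mean(control) per patch
    p: np.ndarray            # one-sided, patient < control
    significant: np.ndarray  # after the chosen correction
    n_permutations: int
    exhaustive: bool
    correction: str

    @property
    def evaluable(self) -> np.ndarray:
        return np.isfinite(self.p)


def _stack(profiles: Sequence[PatchProfile]) -> np.ndarray:
    sizes = {p.n_patches for p in profiles}
    if len(sizes) != 1:
        raise ConsistencyError(f"mixed parcellation sizes: {sorted(sizes)}")
    return np.vstack([p.patch_means for p in profiles])


def group_permutation_test(
    patients: Sequence[PatchProfile],
    controls: Sequence[PatchProfile],
    n_perm: int = 5000,
    seed: int | None = None,
    correction: str = "maxstat",
    alpha: float = 0.05,
) -> GroupContrastResult:
    """Permutation test of mean patch thickness, patients vs. controls."""
    if len(patients) < 2 or len(controls) < 2:
        raise ValidationError("need >= 2 subjects per group")
    data = _stack(list(patients) + list(controls))
    n_pat = len(patients)
    n_tot = data.shape[0]
    evaluable = ~np.any(np.isnan(data), axis=0)

    def stat_for(pat_idx: np.ndarray) -> np.ndarray:
        sel = np.zeros(n_tot, dtype=bool)
        sel[pat_idx] = True
        return data[sel].mean(axis=0) - data[~sel].mean(axis=0)

    observed = stat_for(np.arange(n_pat))

    exhaustive = n_tot <= EXHAUSTIVE_MAX_SUBJECTS
    if exhaustive:
        null = np.vstack([stat_for(np.asarray(idx))
                          for idx in combinations(range(n_tot), n_pat)])
        n_draws = null.shape[0]
        with np.errstate(invalid="ignore"):
            p = np.sum(null <= observed[None, :], axis=0) / n_draws
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, data.shape[1]))
        for i in range(n_perm):
            idx = rng.permutation(n_tot)[:n_pat]
            null[i] = stat_for(idx)
        n_draws = n_perm
        with np.errstate(invalid="ignore"):
            p = (1.0 + np.sum(null <= observed[None, :], axis=0)) / (n_perm + 1.0)
    p = np.where(evaluable, p, np.nan)

    if correction == "fdr":
        significant = fdr_bh(p, alpha)
    elif correction == "maxstat":
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row_min = np.nanmin(null[:, evaluable], axis=1) if evaluable.any() else null.min(axis=1)
        if exhaustive:
            p_fwe = np.sum(row_min[:, None] <= observed[None, :], axis=0) / n_draws
        else:
            p_fwe = (1.0 + np.sum(row_min[:, None] <= observed[None, :], axis=0)) / (n_perm + 1.0)
        significant = (p_fwe <= alpha) & evaluable
    else:
        raise ValidationError(f"unknown correction {correction!r}")

    return GroupContrastResult(
        patch_stat=np.where(evaluable, observed, np.nan),
        p=p,
        significant=significant & evaluable,
        n_permutations=n_draws,
        exhaustive=exhaustive,
        correction=correction,
    )


def residualize_covariates(
    profiles: Sequence[PatchProfile], covariates: pd.DataFrame
) -> list[PatchProfile]:
    """Regress patch means on [1 | age | sex] across ALL subjects and return
    residual profiles (group labels untouched).

    ``covariates`` rows align with ``profiles`` by position, or by
    ``subject_id`` when that column is present.
    """
    df = covariates.copy()
    if "subject_id" in df.columns:
        df = df.set_index(df["subject_id"].astype(str))
        try:
            df = df.loc[[p.subject_id for p in profiles]]
        except KeyError as exc:
            raise ValidationError(f"covariates missing for a profile: {exc}") from exc
    if len(df) != len(profiles):
        raise ConsistencyError("covariate rows do not align with profiles")
    sex = df["sex"].astype(str).str.upper().str[0].map({"F": 0.0, "M": 1.0})
    if sex.isna().any():
        raise ValidationError("sex must be F or M")
    X = np.column_stack([
        np.ones(len(profiles)),
        df["age"].to_numpy(dtype=float),
        sex.to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient covariate design (age/sex)")
    data = _stack(profiles)
    evaluable = ~np.any(np.isnan(data), axis=0)
    resid = np.full_like(data, np.nan)
    if evaluable.any():
        beta, *_ = np.linalg.lstsq(X, data[:, evaluable], rcond=None)
        resid[:, evaluable] = data[:, evaluable] - X @ beta
    return [
        PatchProfile(
            subject_id=prof.subject_id,
            patch_means=np.where(prof.evaluable & evaluable, resid[i], np.nan),
            patch_sizes=np.where(evaluable, prof.patch_sizes, 0),
        )
        for i, prof in enumerate(profiles)
    ]
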