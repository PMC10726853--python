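"""The "standard approaches" at desk scale.

Vertexwise single-subject inference the way surface-based morphometry
pipelines usually do it: optional smoothing on the mesh, a singleton-versus-
group GLM with age/sex covariates (which without covariates reduces to the
Crawford-Howell single-case t-test), one-sided in the atrophy direction
(patient < controls), followed by either Benjamini-Hochberg FDR or
max-statistic permutation FWE correction, and finally the burden fraction
(share of significant vertices inside the cortical mask).

Smoothing is iterated mass-conserving neighbor diffusion on the mesh graph,
calibrated so the accumulated kernel variance matches the requested Gaussian
sigma; it conserves the global mean on any mesh and preserves constant maps
on regular (closed) meshes.  Sigma 0 is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, ValidationError
from .io import CorticalMask, VertexMap
from .map_core import _loo_zscores  # shared leave-one-out machinery

__all__ = [
    "Mesh",
    "SmoothingSpec",
    "GAUSSIAN_SIGMA_TO_FWHM",
    "sigma_to_fwhm",
    "smooth_on_mesh",
    "singleton_vs_group",
    "singleton_null_stats",
    "fdr_bh",
    "maxstat_fwe",
    "burden_fraction",
    "run_standard_subject",
]

#: FWHM = sigma * 2 sqrt(2 ln 2)
GAUSSIAN_SIGMA_TO_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class Mesh:
    """Vertex adjacency carrier for smoothing.

    ``neighbors`` maps each vertex to its neighbor indices (symmetric);
    ``edge_length`` is the nominal edge length in mm.
    """

    neighbors: list[np.ndarray]
    edge_length: float = 1.0

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(n, dtype=int) for n in self.neighbors]
        if self.edge_length <= 0:
            raise ValidationError("edge_length must be positive")
        # symmetry check
        for v, nbrs in enumerate(self.neighbors):
            for u in nbrs:
                if v not in self.neighbors[u]:
                    raise ValidationError(f"asymmetric adjacency: {v} -> {u}")

    @property
    def vertex_count(self) -> int:
        return len(self.neighbors)

    def adjacency(self) -> sp.csr_matrix:
        rows, cols = [], []
        for v, nbrs in enumerate(self.neighbors):
            rows.extend([v] * len(nbrs))
            cols.extend(nbrs.tolist())
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)),
                             shape=(self.vertex_count, self.vertex_count))


@dataclass
class SmoothingSpec:
    """Gaussian-equivalent smoothing width. sigma in mm; sigma 0 = identity."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def fwhm(self) -> float:
        return sigma_to_fwhm(self.sigma)


def sigma_to_fwhm(sigma: float) -> float:
    """Convert a Gaussian sigma (mm) to full width at half maximum (mm)."""
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    return float(sigma * GAUSSIAN_SIGMA_TO_FWHM)


def smooth_on_mesh(
    vmap: VertexMap,
    mesh: Mesh,
    spec: SmoothingSpec | float,
    mask: CorticalMask | None = None,
    w: float = 0.5,
) -> VertexMap:
    """Diffusion smoothing on the mesh graph.

    Each iteration applies ``new[v] = w*v + (1-w) * sum_u in N(v) old[u]/deg(u)``
    restricted to in-mask vertices (masked-out vertices neither send nor
    receive and are returned unchanged).  The iteration count is chosen so
    the accumulated random-walk variance (1-w) * edge_length^2 per step
    matches sigma^2.  Isolated in-mask vertices are left unchanged with a
    warning.
    """
    if not isinstance(spec, SmoothingSpec):
        spec = SmoothingSpec(sigma=float(spec))
    if mesh.vertex_count != vmap.vertex_count:
        raise ConsistencyError(
            f"mesh has {mesh.vertex_count} vertices, map has {vmap.vertex_count}"
        )
    if spec.sigma == 0:
        return VertexMap(subject_id=vmap.subject_id, values=vmap.values.copy())
    include = np.ones(vmap.vertex_count, dtype=bool) if mask is None else mask.include
    if mask is not None and mask.vertex_count != vmap.vertex_count:
        raise ConsistencyError("mask length does not match map")

    adj = mesh.adjacency()
    # restrict adjacency to the mask
    keep = sp.diags(include.astype(float))
    adj = keep @ adj @ keep
    deg = np.asarray(adj.sum(axis=1)).ravel()
    isolated = include & (deg == 0)
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated in-mask vertices left unchanged"
        )
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    # column-normalized transition: receives (1-w) * value_u / deg_u from neighbors
    spread = adj @ sp.diags(inv_deg)

    n_iter = max(1, int(np.ceil(spec.sigma**2 / ((1.0 - w) * mesh.edge_length**2))))
    vals = vmap.values.copy()
    movable = include & (deg > 0)
    cur = vals.copy()
    for _ in range(n_iter):
        nxt = w * cur + (1.0 - w) * (spread @ cur)
        cur = np.where(movable, nxt, cur)
    out = np.where(include, cur, vmap.values)
    return VertexMap(subject_id=vmap.subject_id, values=out)


def _design_from_covariates(
    covariates: pd.DataFrame, subject_ids: Sequence[str]
) -> np.ndarray:
    """Build [1 | age | sex(M=1)] rows matched to subject_ids."""
    df = covariates.copy()
    if "subject_id" in df.columns:
        df = df.set_index(df["subject_id"].astype(str))
    missing = [s for s in subject_ids if s not in df.index]
    if missing:
        raise ValidationError(f"covariates missing for subjects {missing}")
    rows = df.loc[list(subject_ids)]
    sex = rows["sex"].astype(str).str.upper().str[0].map({"F": 0.0, "M": 1.0})
    if sex.isna().any():
        raise ValidationError("sex must be F or M in the covariate table")
    X = np.column_stack([
        np.ones(len(subject_ids)),
        rows["age"].to_numpy(dtype=float),
        sex.to_numpy(dtype=float),
    ])
    return X


def _singleton_glm(
    Y: np.ndarray, y0: np.ndarray, X: np.ndarray, x0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Prediction-interval t for one new observation against a fitted GLM.

    Y: n x V control responses; y0: patient response per vertex;
    X: n x p design; x0: patient design row.
    t = (y0 - x0 b) / (s sqrt(1 + x0' (X'X)^-1 x0)), df = n - rank(X).
    """
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify a collinear column for the error message
        bad = []
        for j in range(1, p):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j)
        raise ValidationError(f"rank-deficient design; collinear column(s) {bad}")
    df = n - rank
    if df < 1:
        raise ValidationError(f"no residual degrees of freedom (n={n}, rank={rank})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    s2 = np.sum(resid**2, axis=0) / df
    lever = 1.0 + float(x0 @ xtx_inv @ x0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (y0 - x0 @ beta) / np.sqrt(s2 * lever)
    t[~np.isfinite(t)] = np.nan
    return t, s2, df


def singleton_vs_group(
    patient: VertexMap,
    controls: Sequence[VertexMap],
    covariates: pd.DataFrame | None = None,
    mask: CorticalMask | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vertexwise singleton-versus-group GLM, one-sided for thinness.

    Returns ``(t, p, df)`` with NaN outside the mask.  With no covariates
    this is exactly the Crawford-Howell single-case t-test
    ``t = (x - mean) / (SD sqrt(1 + 1/n))`` with df = n - 1.
    """
    n = len(controls)
    if covariates is not None and n < 3:
        raise ValidationError("need >= 3 controls when covariates are used")
    if n < 2:
        raise ValidationError("need >= 2 controls")
    V = patient.vertex_count
    for c in controls:
        if c.vertex_count != V:
            raise ConsistencyError(f"control {c.subject_id} has different vertex count")
    include = np.ones(V, dtype=bool) if mask is None else mask.include
    Y = np.vstack([c.values for c in controls])[:, include]
    y0 = patient.values[include]
    if covariates is None:
        X = np.ones((n, 1))
        x0 = np.ones(1)
    else:
        ids = [c.subject_id for c in controls]
        X = _design_from_covariates(covariates, ids)
        x0 = _design_from_covariates(covariates, [patient.subject_id])[0]
    t_in, _, df = _singleton_glm(Y, y0, X, x0)
    p_in = stats.t.cdf(t_in, df)  # one-sided, patient < controls
    t = np.full(V, np.nan)
    p = np.full(V, np.nan)
    t[include] = t_in
    p[include] = p_in
    return t, p, df


def singleton_null_stats(
    patient: VertexMap,
    controls: Sequence[VertexMap],
    mask: CorticalMask | None = None,
) -> np.ndarray:
    """Exhaustive relabeling null for the singleton design (no covariates).

    Returns an (n+1) x V_masked matrix of leave-one-as-singleton z maps over
    the pooled patient + controls set, row 0 being the observed labeling.
    """
    V = patient.vertex_count
    include = np.ones(V, dtype=bool) if mask is None else mask.include
    pooled = np.vstack([patient.values[None, :]] +
                       [c.values[None, :] for c in controls])[:, include]
    return _loo_zscores(pooled)


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level alpha (NaNs never
    rejected)."""
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if not finite.any():
        return out
    rej, *_ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
    out[finite] = rej
    return out


def maxstat_fwe(
    observed_stat: np.ndarray, null_stats: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Max-statistic (here: min, one-sided low) permutation FWE rejections.

    Vertex k is rejected iff the fraction of null replicates whose minimum
    statistic across the map is <= observed_stat[k] is itself <= alpha.
    """
    observed_stat = np.asarray(observed_stat, dtype=float)
    null_stats = np.asarray(null_stats, dtype=float)
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    n_rows = null_stats.shape[0]
    if n_rows < 1.0 / alpha:
        warnings.warn(
            f"only {n_rows} permutation replicates for alpha={alpha}; "
            "the critical quantile is unreliable"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_min = np.nanmin(null_stats, axis=1)
    with np.errstate(invalid="ignore"):
        p_fwe = np.sum(row_min[:, None] <= observed_stat[None, :], axis=0) / n_rows
    return (p_fwe <= alpha) & np.isfinite(observed_stat)


def burden_fraction(rejections: np.ndarray, mask: CorticalMask) -> float:
    """#(rejected inside mask) / #(mask); the vertexwise burden scalar."""
    rejections = np.asarray(rejections, dtype=bool)
    if rejections.size != mask.vertex_count:
        raise ConsistencyError("rejections length does not match mask")
    denom = int(mask.include.sum())
    return float(np.sum(rejections & mask.include) / denom)


def run_standard_subject(
    patient: VertexMap,
    controls: Sequence[VertexMap],
    mesh: Mesh | None = None,
    sigma: float = 0.0,
    covariates: pd.DataFrame | None = None,
    mask: CorticalMask | None = None,
    alpha: float = 0.05,
    correction: str = "fdr",
) -> dict:
    """One patient through the standard vertexwise pipeline.

    Smooth (if sigma > 0 and a mesh is given), run the singleton GLM, apply
    the chosen correction ('fdr' on parametric one-sided p, or 'maxstat' on
    the exhaustive relabeling null), and report the burden fraction.
    """
    if sigma > 0:
        if mesh is None:
            raise ValidationError("smoothing requires a mesh")
        spec = SmoothingSpec(sigma=sigma)
        patient = smooth_on_mesh(patient, mesh, spec, mask)
        controls = [smooth_on_mesh(c, mesh, spec, mask) for c in controls]
    if mask is None:
        mask = CorticalMask.full(patient.vertex_count)
    t, p, df = singleton_vs_group(patient, controls, covariates, mask)
    if correction == "fdr":
        rejections = fdr_bh(p, alpha)
    elif correction == "maxstat":
        null = singleton_null_stats(patient, controls, mask)
        rej_masked = maxstat_fwe(null[0], null, alpha)
        rejections = np.zeros(patient.vertex_count, dtype=bool)
        rejections[mask.include] = rej_masked
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return {
        "t": t,
        "p": p,
        "df": df,
        "rejections": rejections,
        "burden_fraction": burden_fraction(rejections, mask),
        "sigma": sigma,
        "alpha": alpha,
        "correction": correction,
    }
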