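"""Synthetic study-condition generator.

Emulates the study setup that the method targets: a healthy-control (HC)
reference cohort (default 89 subjects) and a relapsing-remitting MS patient
cohort (default 465), bilateral thickness maps summarized by patches, with
patch-level atrophy injected in patients and clinical covariates (lesion
volume, EDSS) statistically coupled to the injected atrophy burden.

Generative model, per subject s and patch k:

    thickness[s, v] = base_mean + patch_offset[k] + b[s, k] + eps[s, v]

with patch_offset ~ N(0, patch_offset_sd) drawn once per cohort (regional
thickness differences), b[s, k] ~ N(0, base_sd_between) independent across
subjects and patches (between-subject variation of the regional mean, the
"2.41 +/- 0.11 mm"-scale quantity), and vertex noise eps ~ N(0,
vertex_noise_sd).  Patients draw an individual atrophy probability from a
Beta distribution with mean ``atrophy_patch_fraction`` (heterogeneous
disease burden), each patch is then independently atrophic, and atrophic
patches lose ``atrophy_effect`` reference-SDs of thickness, where the
reference patch SD is the generative SD of a patch mean,
sqrt(base_sd_between^2 + vertex_noise_sd^2 / patch_size).

Lesion volume is lognormal (mean 5.39 mL, SD 8.41 mL) with its raw-scale
Pearson correlation to true burden calibrated to ``clinical_coupling``;
EDSS lives on the 0-10 half-point grid with a deliberately weaker rank
coupling.  Everything is reproducible: one master seed, with per-subject
substreams keyed by (seed, subject index) so cohorts are stable under
changes of the cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .baselines import Mesh
from .io import CohortTable, CorticalMask, ParcellationScheme, VertexMap

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "make_mesh",
    "make_parcellation",
    "simulate_cohort",
    "true_burden",
]

# lognormal LV marginal calibrated to the printed cohort summary
LV_MEAN_ML = 5.39
LV_SD_ML = 8.41
# EDSS marginal: median 1.50, IQR 2.00 on the half-point grid
EDSS_MEDIAN = 1.50
EDSS_IQR = 2.00

_PATIENT_STREAM_OFFSET = 1_000_000  # keeps control/patient substreams disjoint
_COHORT_STREAM = 2_000_000          # cohort-level draws (patch offsets, clinical)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_controls: int = 89
    n_patients: int = 465
    V: int = 2000
    N: int = 100
    base_mean: float = 2.41
    base_sd_between: float = 0.11
    patch_offset_sd: float = 0.03
    vertex_noise_sd: float = 0.3
    atrophy_patch_fraction: float = 0.1
    atrophy_effect: float = 4.0
    clinical_coupling: float = 0.6
    edss_coupling: float = 0.35
    burden_concentration: float = 20.0
    vertex_level_atrophy: bool = False

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 0:
            raise ValidationError("need >= 2 controls and >= 0 patients")
        if not (0 <= self.atrophy_patch_fraction <= 1):
            raise ValidationError("atrophy_patch_fraction must be in [0, 1]")
        for name in ("base_mean", "base_sd_between", "vertex_noise_sd",
                     "patch_offset_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("clinical_coupling", "edss_coupling"):
            c = getattr(self, name)
            if not (0 <= c <= 1):
                raise ValidationError(f"{name}={c} outside [0, 1]")
        if self.N > self.V:
            raise ValidationError(f"N={self.N} patches exceed V={self.V} vertices")


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    vertex_maps: dict[str, VertexMap]
    cohort: CohortTable
    scheme: ParcellationScheme
    mask: CorticalMask
    ground_truth: dict[str, np.ndarray]  # patient id -> atrophic patch labels (1-based)

    @property
    def control_ids(self) -> list[str]:
        return self.cohort.controls["subject_id"].tolist()

    @property
    def patient_ids(self) -> list[str]:
        return self.cohort.patients["subject_id"].tolist()

    def maps_for(self, ids: Sequence[str]) -> list[VertexMap]:
        return [self.vertex_maps[i] for i in ids]


def make_mesh(V: int, topology: str = "grid") -> Mesh:
    """Deterministic test meshes: a 4-connected rectangle or a cycle."""
    if V < 3:
        raise ValidationError(f"need >= 3 vertices, got {V}")
    if topology == "ring":
        neighbors = [np.array([(v - 1) % V, (v + 1) % V]) for v in range(V)]
    elif topology == "grid":
        ncols = int(np.ceil(np.sqrt(V)))
        neighbors = []
        for v in range(V):
            r, c = divmod(v, ncols)
            nbrs = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                u = rr * ncols + cc
                if rr >= 0 and cc >= 0 and cc < ncols and 0 <= u < V:
                    nbrs.append(u)
            neighbors.append(np.array(sorted(nbrs), dtype=int))
    else:
        raise ValidationError(f"unknown topology {topology!r}")
    return Mesh(neighbors=neighbors, edge_length=1.0)


def make_parcellation(V: int, N: int, seed: int | None = None) -> ParcellationScheme:
    """Contiguous blocks of near-equal size (sizes differ by at most 1).

    With a seed, which blocks carry the extra vertex is randomized; without,
    the leading blocks do (the numpy array_split convention).
    """
    if N > V:
        raise ValidationError(f"N={N} > V={V}")
    if N < 1:
        raise ValidationError("need N >= 1")
    base, rem = divmod(V, N)
    sizes = np.full(N, base, dtype=int)
    if rem:
        if seed is None:
            sizes[:rem] += 1
        else:
            rng = np.random.default_rng(seed)
            sizes[rng.choice(N, size=rem, replace=False)] += 1
    labels = np.repeat(np.arange(1, N + 1), sizes)
    return ParcellationScheme(labels=labels)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _latent_coupling(target_r: float, sigma: float) -> float:
    """Latent Gaussian correlation that yields raw-scale Pearson ``target_r``
    against a lognormal(mu, sigma) marginal (attenuation sigma/sqrt(e^s2-1))."""
    atten = sigma / np.sqrt(np.expm1(sigma**2))
    latent = target_r / atten
    if latent > 1.0:
        raise ValidationError(
            f"coupling {target_r:.3f} infeasible under the lognormal LV marginal "
            f"(maximum attainable raw-scale correlation is {atten:.3f})"
        )
    return latent


def _subject_values(cfg: SimulationConfig, stream_index: int,
                    patch_offset: np.ndarray, labels: np.ndarray) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, stream_index])
    b = rng.normal(0.0, cfg.base_sd_between, size=cfg.N)
    patch_level = cfg.base_mean + patch_offset + b
    vals = patch_level[labels - 1] + rng.normal(0.0, cfg.vertex_noise_sd, size=cfg.V)
    return np.clip(vals, 0.0, None)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full HC + patient cohort with ground-truth atrophy."""
    cfg = config
    scheme = make_parcellation(cfg.V, cfg.N)
    labels = scheme.labels
    mask = CorticalMask.full(cfg.V)
    patch_sizes = scheme.patch_sizes

    cohort_rng = np.random.default_rng([cfg.seed, _COHORT_STREAM])
    patch_offset = cohort_rng.normal(0.0, cfg.patch_offset_sd, size=cfg.N)
    # generative SD of a patch mean in the reference population
    ref_patch_sd = np.sqrt(cfg.base_sd_between**2 +
                           cfg.vertex_noise_sd**2 / np.maximum(patch_sizes, 1))

    vertex_maps: dict[str, VertexMap] = {}
    rows = []

    for i in range(cfg.n_controls):
        sid = f"HC{i + 1:03d}"
        vals = _subject_values(cfg, i, patch_offset, labels)
        rng = np.random.default_rng([cfg.seed, i, 7])
        rows.append({
            "subject_id": sid, "group": "control",
            "age": float(np.clip(rng.normal(37.36, 15.06), 18, 80)),
            "sex": "F" if rng.random() < 59 / 89 else "M",
            "lesion_volume": np.nan, "edss": np.nan, "disease_duration": np.nan,
        })
        vertex_maps[sid] = VertexMap(subject_id=sid, values=vals)

    ground_truth: dict[str, np.ndarray] = {}
    burdens = np.zeros(cfg.n_patients)
    for j in range(cfg.n_patients):
        sid = f"MS{j + 1:03d}"
        idx = _PATIENT_STREAM_OFFSET + j
        vals = _subject_values(cfg, idx, patch_offset, labels)
        rng = np.random.default_rng([cfg.seed, idx, 11])
        f = cfg.atrophy_patch_fraction
        if f > 0:
            kappa = cfg.burden_concentration
            f_i = rng.beta(kappa * f, kappa * (1.0 - f))
            atrophic = np.flatnonzero(rng.random(cfg.N) < f_i) + 1  # 1-based
        else:
            atrophic = np.array([], dtype=int)
        if atrophic.size:
            if cfg.vertex_level_atrophy:
                # per-vertex injection (for baseline comparisons)
                hit = np.isin(labels, atrophic)
                vals = vals - hit * cfg.atrophy_effect * ref_patch_sd[labels - 1]
            else:
                drop = np.zeros(cfg.N)
                drop[atrophic - 1] = cfg.atrophy_effect * ref_patch_sd[atrophic - 1]
                vals = vals - drop[labels - 1]
        vals = np.clip(vals, 0.0, None)
        ground_truth[sid] = atrophic
        burdens[j] = atrophic.size / cfg.N
        rows.append({
            "subject_id": sid, "group": "patient",
            "age": float(np.clip(rng.normal(40.14, 9.94), 18, 80)),
            "sex": "F" if rng.random() < 305 / 465 else "M",
            "lesion_volume": np.nan, "edss": np.nan,
            "disease_duration": float(np.clip(rng.normal(8.65, 5.16), 0, None)),
        })
        vertex_maps[sid] = VertexMap(subject_id=sid, values=vals)

    # clinical variables coupled to true burden through a Gaussian copula
    if cfg.n_patients > 0:
        z_burden = (burdens - burdens.mean())
        sd = z_burden.std()
        z_burden = z_burden / sd if sd > 0 else np.zeros_like(z_burden)

        mu_lv, sg_lv = _lognormal_params(LV_MEAN_ML, LV_SD_ML)
        c_lv = _latent_coupling(cfg.clinical_coupling, sg_lv)
        eps = cohort_rng.normal(size=cfg.n_patients)
        lv = np.exp(mu_lv + sg_lv * (c_lv * z_burden + np.sqrt(1 - c_lv**2) * eps))

        mu_e = np.log(EDSS_MEDIAN)
        sg_e = float(np.arcsinh((EDSS_IQR / 2.0) / EDSS_MEDIAN) / 0.67449)
        c_e = cfg.edss_coupling
        eps2 = cohort_rng.normal(size=cfg.n_patients)
        edss_raw = np.exp(mu_e + sg_e * (c_e * z_burden + np.sqrt(1 - c_e**2) * eps2))
        edss = np.clip(np.round(edss_raw * 2.0) / 2.0, 0.0, 10.0)

        frame = pd.DataFrame(rows)
        pat = frame["group"] == "patient"
        frame.loc[pat, "lesion_volume"] = lv
        frame.loc[pat, "edss"] = edss
    else:
        frame = pd.DataFrame(rows)

    return SimulatedCohort(
        config=cfg,
        vertex_maps=vertex_maps,
        cohort=CohortTable(frame=frame),
        scheme=scheme,
        mask=mask,
        ground_truth=ground_truth,
    )


def true_burden(cohort: SimulatedCohort, subject_id: str) -> float:
    """Realized ground-truth burden: #atrophic patches / N for one patient."""
    if subject_id not in cohort.ground_truth:
        raise ValidationError(f"{subject_id} is not a patient of this cohort")
    return float(cohort.ground_truth[subject_id].size / cohort.config.N)
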