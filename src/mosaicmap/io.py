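"""Readers and writers for the formats the tool touches.

Surface scalar maps (per-vertex cortical thickness) and parcellation label
maps are stored either as GIFTI files (``.shape.gii`` / ``.label.gii``,
read and written through nibabel) or as plain single-column CSV files.
Cohort metadata and per-patch result tables are CSV.

Conventions
-----------
* Both hemispheres are handled as one concatenated vertex vector (left then
  right); per-hemisphere files are concatenated at load time.
* Parcellation label 0 is reserved for unassigned / medial-wall vertices and
  is excluded from every statistic.
* CSV dialect: comma-separated, UTF-8, "." decimal separator.  Scalar-map and
  label CSVs are a single column with an optional one-line header.
* Vertex order is never permuted by any reader or writer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import nibabel as nib

from .errors import ConsistencyError, FormatError, ValidationError

__all__ = [
    "VertexMap",
    "ParcellationScheme",
    "CorticalMask",
    "CohortTable",
    "read_vertex_map",
    "write_vertex_map",
    "read_parcellation",
    "write_parcellation",
    "read_mask",
    "read_cohort",
    "write_result_table",
    "read_result_table",
]

UNASSIGNED = 0  # reserved parcellation label (medial wall / outside mask)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VertexMap:
    """One subject's per-vertex cortical thickness values, in millimetres."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValidationError(f"{self.subject_id}: empty vertex map")
        bad = np.flatnonzero(~np.isfinite(self.values))
        if bad.size:
            raise ValidationError(
                f"{self.subject_id}: non-finite thickness at vertex indices "
                f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
            )
        if np.any(self.values < 0):
            neg = np.flatnonzero(self.values < 0)
            raise ValidationError(
                f"{self.subject_id}: negative thickness at vertex indices "
                f"{neg[:10].tolist()}"
            )

    @property
    def vertex_count(self) -> int:
        return int(self.values.size)


@dataclass
class ParcellationScheme:
    """Integer patch label per vertex; 0 means unassigned.

    ``n_patches`` is the maximum label N; every patch 1..N either has at
    least one vertex or is flagged in ``empty_patches``.
    """

    labels: np.ndarray
    patch_names: list[str] | None = None
    n_patches: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise ValidationError("parcellation labels must be integers")
            self.labels = as_int
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("labels must be a nonempty 1-d vector")
        if self.labels.min() < 0:
            raise ValidationError(
                "negative parcellation labels at indices "
                f"{np.flatnonzero(self.labels < 0)[:10].tolist()}"
            )
        self.n_patches = int(self.labels.max())
        if self.n_patches == 0:
            raise ValidationError("parcellation assigns no vertex to any patch")
        if self.patch_names is not None and len(self.patch_names) != self.n_patches:
            raise ValidationError(
                f"{len(self.patch_names)} patch names for {self.n_patches} patches"
            )

    @property
    def vertex_count(self) -> int:
        return int(self.labels.size)

    @property
    def patch_sizes(self) -> np.ndarray:
        """Vertex count per patch 1..N (before any masking)."""
        return np.bincount(self.labels, minlength=self.n_patches + 1)[1:]

    @property
    def empty_patches(self) -> np.ndarray:
        """Boolean vector, True where a patch label has no vertex."""
        return self.patch_sizes == 0

    def check_matches(self, other_len: int, what: str = "companion array") -> None:
        if other_len != self.vertex_count:
            raise ConsistencyError(
                f"parcellation has {self.vertex_count} vertices but "
                f"{what} has {other_len}"
            )


@dataclass
class CorticalMask:
    """Boolean include/exclude vector over the vertex set."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include).astype(bool).ravel()
        if self.include.size == 0 or not self.include.any():
            raise ValidationError("cortical mask includes no vertex")

    @property
    def vertex_count(self) -> int:
        return int(self.include.size)

    @classmethod
    def full(cls, n_vertices: int) -> "CorticalMask":
        return cls(np.ones(n_vertices, dtype=bool))


REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "age", "sex")
OPTIONAL_COHORT_COLUMNS = ("lesion_volume", "edss", "disease_duration")


@dataclass
class CohortTable:
    """Subject metadata: group, age, sex and (for patients) LV / EDSS.

    ``frame`` is a pandas DataFrame with normalized, typed columns; the
    clinical columns are NaN for controls.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        df["subject_id"] = df["subject_id"].astype(str)
        dup = df["subject_id"][df["subject_id"].duplicated()].unique()
        if dup.size:
            raise ValidationError(f"duplicate subject_id: {dup.tolist()}")
        group = df["group"].astype(str).str.strip().str.lower()
        ok = group.isin(["patient", "control"])
        if not ok.all():
            raise ValidationError(
                f"unrecognized group values: {sorted(group[~ok].unique())} "
                "(expected 'patient' or 'control', case-insensitive)"
            )
        df["group"] = group
        sex = df["sex"].astype(str).str.strip().str.upper().str[0]
        if not sex.isin(["F", "M"]).all():
            raise ValidationError(
                f"unrecognized sex values: {sorted(df['sex'][~sex.isin(['F','M'])].unique())}"
            )
        df["sex"] = sex
        df["age"] = pd.to_numeric(df["age"])
        for col in OPTIONAL_COHORT_COLUMNS:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        if "edss" in df.columns:
            edss = df["edss"].dropna()
            bad = edss[(edss < 0) | (edss > 10)]
            if not bad.empty:
                raise ValidationError(
                    f"EDSS outside [0, 10] for subjects "
                    f"{df.loc[bad.index, 'subject_id'].tolist()}"
                )
        self.frame = df.reset_index(drop=True)

    @property
    def patients(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] == "patient"]

    @property
    def controls(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] == "control"]

    @property
    def counts(self) -> dict[str, int]:
        return {"control": len(self.controls), "patient": len(self.patients)}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gii") or name.endswith(".gii.gz"):
        return "gifti"
    return "csv"


def _read_scalar_csv(path: Path) -> np.ndarray:
    """Single-column CSV with an optional one-line non-numeric header."""
    try:
        raw = pd.read_csv(path, header=None, dtype=str, comment="#",
                          keep_default_na=False)
    except Exception as exc:  # malformed file
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    if raw.shape[1] != 1:
        raise FormatError(f"{path}: expected a single column, got {raw.shape[1]}")
    col = raw.iloc[:, 0]
    start = 0
    try:
        float(col.iloc[0])
    except (TypeError, ValueError):
        start = 1  # header row
    data = col.iloc[start:].str.strip()
    numeric = pd.to_numeric(data, errors="coerce")
    # entries that are NaN *strings* flow through as NaN values and are caught
    # by VertexMap validation (which names the vertex index); anything else
    # unparseable is a format problem
    is_nan_token = data.str.lower().isin(["nan", "+nan", "-nan"])
    unparsed = np.flatnonzero(numeric.isna().to_numpy() & ~is_nan_token.to_numpy())
    if unparsed.size:
        raise FormatError(
            f"{path}: non-numeric entries at data rows {unparsed[:10].tolist()}"
        )
    # reparse at full precision for lossless round trips
    return np.array([float(v) if not n else np.nan
                     for v, n in zip(data, is_nan_token)], dtype=float)


def _read_gifti_array(path: Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as GIFTI ({exc})") from exc
    if not isinstance(img, nib.gifti.GiftiImage) or not img.darrays:
        raise FormatError(f"{path}: not a GIFTI file with data arrays")
    return np.concatenate([d.data.ravel() for d in img.darrays])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_vertex_map(
    path: str | Path | Sequence[str | Path],
    format: str | None = None,
    subject_id: str | None = None,
) -> VertexMap:
    """Read a per-vertex thickness map from GIFTI shape or CSV.

    ``path`` may be a sequence of per-hemisphere files, concatenated in the
    order given (left then right by convention).  Non-finite entries raise a
    :class:`ValidationError` naming the offending vertex indices.
    """
    if isinstance(path, (str, Path)):
        paths = [Path(path)]
    else:
        paths = [Path(p) for p in path]
    parts = []
    for p in paths:
        fmt = format or _infer_format(p)
        if fmt in ("gifti", "gifti-shape"):
            parts.append(_read_gifti_array(p).astype(float))
        elif fmt == "csv":
            parts.append(_read_scalar_csv(p))
        else:
            raise FormatError(f"unknown vertex-map format {fmt!r}")
    sid = subject_id or paths[0].stem.split(".")[0]
    return VertexMap(subject_id=sid, values=np.concatenate(parts))


def write_vertex_map(vmap: VertexMap, path: str | Path, format: str | None = None) -> None:
    """Write a vertex map as GIFTI shape (float32, the surface-format norm)
    or single-column CSV (full precision)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("gifti", "gifti-shape"):
        darr = nib.gifti.GiftiDataArray(
            vmap.values.astype(np.float32), intent="NIFTI_INTENT_SHAPE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))
    elif fmt == "csv":
        pd.DataFrame({"thickness": vmap.values}).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown vertex-map format {fmt!r}")


def read_parcellation(
    path: str | Path | Sequence[str | Path], format: str | None = None
) -> ParcellationScheme:
    """Read a parcellation label map (GIFTI label or CSV of integers).

    ``n_patches`` is the maximum label; label-0 vertices are unassigned and
    intermediate labels with no vertex are flagged empty.
    """
    if isinstance(path, (str, Path)):
        paths = [Path(path)]
    else:
        paths = [Path(p) for p in path]
    parts = []
    names: list[str] | None = None
    for p in paths:
        fmt = format or _infer_format(p)
        if fmt in ("gifti", "gifti-label"):
            img = nib.load(str(p))
            parts.append(_read_gifti_array(p))
            try:
                table = img.labeltable.get_labels_as_dict()
                if table and names is None:
                    nmax = max(table)
                    names = [table.get(k, f"patch_{k}") for k in range(1, nmax + 1)]
            except Exception:
                pass
        elif fmt == "csv":
            vals = _read_scalar_csv(p)
            if np.any(~np.isfinite(vals)):
                raise ValidationError(f"{p}: non-finite parcellation labels")
            if np.any(vals != np.round(vals)):
                raise ValidationError(f"{p}: parcellation labels must be integers")
            parts.append(vals.astype(int))
        else:
            raise FormatError(f"unknown parcellation format {fmt!r}")
    labels = np.concatenate(parts).astype(int)
    return ParcellationScheme(labels=labels, patch_names=names)


def write_parcellation(scheme: ParcellationScheme, path: str | Path,
                       format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("gifti", "gifti-label"):
        darr = nib.gifti.GiftiDataArray(
            scheme.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))
    elif fmt == "csv":
        pd.DataFrame({"label": scheme.labels}).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown parcellation format {fmt!r}")


def read_mask(path: str | Path | Sequence[str | Path],
              format: str | None = None) -> CorticalMask:
    """Read a cortical mask stored as a 0/1 scalar map (GIFTI or CSV)."""
    vm_vals = read_vertex_map(path, format=format, subject_id="mask").values
    return CorticalMask(include=vm_vals > 0.5)


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate the cohort CSV (subject_id, group, age, sex, + clinical)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    return CohortTable(frame=df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_result_table(result, path: str | Path) -> None:
    """Write one patient's per-patch result as CSV.

    Leading ``#`` metadata lines carry the patch count, alpha, reference size
    and correction mode; the table has one row per patch with full float
    precision so that a round trip is lossless.
    """
    path = Path(path)
    n = result.z.size
    meta = (
        f"# subject_id={result.subject_id},n_patches={n},alpha={result.alpha!r},"
        f"n_ref={result.n_ref},n_permutations={result.n_permutations},"
        f"correction={result.correction},"
        f"thin_patch_fraction={result.thin_patch_fraction!r}\n"
    )
    df = pd.DataFrame(
        {
            "patch_id": np.arange(1, n + 1),
            "n_vertices": result.patch_sizes,
            "z": result.z,
            "p": result.p,
            "thin": result.thin.astype(int),
        }
    )
    if n == 0:
        warnings.warn("writing an empty result table (no patches)")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(meta)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_result_table(path: str | Path):
    """Reread a result table written by :func:`write_result_table`."""
    from .map_core import AtrophyResult  # local import to avoid a cycle

    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing metadata header line")
    meta = dict(item.split("=", 1) for item in first[1:].strip().split(","))
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    thin = df["thin"].to_numpy(dtype=bool)
    return AtrophyResult(
        subject_id=meta["subject_id"],
        z=df["z"].to_numpy(dtype=float),
        p=df["p"].to_numpy(dtype=float),
        thin=thin,
        patch_sizes=df["n_vertices"].to_numpy(dtype=int),
        alpha=float(meta["alpha"]),
        n_ref=int(meta["n_ref"]),
        n_permutations=int(meta["n_permutations"]),
        correction=meta["correction"],
        thin_patch_fraction=float(meta["thin_patch_fraction"]),
    )
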