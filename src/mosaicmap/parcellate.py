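"""Reduce vertexwise thickness to patch means under a parcellation scheme.

A *patch* (mosaic) is one parcel of the cortical parcellation; its summary
is the unweighted arithmetic mean of the masked vertices it contains.
Patches left empty after masking carry NaN and are excluded from all
downstream fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, ValidationError
from .io import CorticalMask, ParcellationScheme, VertexMap

__all__ = ["PatchProfile", "patch_means", "identity_parcellation"]


@dataclass
class PatchProfile:
    """Per-patch mean thickness for one subject.

    ``patch_means[k-1]`` is the mean over vertices with label k inside the
    mask; NaN where ``patch_sizes[k-1] == 0`` (patch empty after masking).
    """

    subject_id: str
    patch_means: np.ndarray
    patch_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.patch_means = np.asarray(self.patch_means, dtype=float).ravel()
        self.patch_sizes = np.asarray(self.patch_sizes, dtype=int).ravel()
        if self.patch_means.size != self.patch_sizes.size:
            raise ValidationError("patch_means and patch_sizes lengths differ")
        nonempty = self.patch_sizes > 0
        if not np.all(np.isfinite(self.patch_means[nonempty])):
            raise ValidationError("non-finite patch mean at a nonempty patch")

    @property
    def n_patches(self) -> int:
        return int(self.patch_means.size)

    @property
    def evaluable(self) -> np.ndarray:
        return self.patch_sizes > 0


def patch_means(
    vmap: VertexMap,
    scheme: ParcellationScheme,
    mask: CorticalMask | None = None,
) -> PatchProfile:
    """Average all masked vertices for each patch.

    Label-0 (unassigned) vertices never contribute.  Patches with no masked
    vertex get mean NaN and size 0.
    """
    scheme.check_matches(vmap.vertex_count, "vertex map")
    if mask is None:
        mask = CorticalMask.full(vmap.vertex_count)
    if mask.vertex_count != vmap.vertex_count:
        raise ConsistencyError(
            f"mask has {mask.vertex_count} vertices, map has {vmap.vertex_count}"
        )
    labels = np.where(mask.include, scheme.labels, 0)
    n = scheme.n_patches
    counts = np.bincount(labels, minlength=n + 1)[1:]
    sums = np.bincount(labels, weights=vmap.values, minlength=n + 1)[1:]
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PatchProfile(subject_id=vmap.subject_id, patch_means=means,
                        patch_sizes=counts)


def identity_parcellation(mask: CorticalMask) -> ParcellationScheme:
    """Each masked vertex becomes its own patch (the "no parcellation" case).

    Masked vertices are labeled 1..M in vertex order; unmasked vertices get 0.
    """
    labels = np.zeros(mask.vertex_count, dtype=int)
    labels[mask.include] = np.arange(1, int(mask.include.sum()) + 1)
    return ParcellationScheme(labels=labels)
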