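"""Searchlight neighborhoods and model-brain Spearman similarity maps.

A searchlight sweeps a sphere of radius ``r`` voxels across the brain
mask; within each sphere the concepts' multi-voxel patterns yield a neural
RDM, which is compared to a model RDM by Spearman rank correlation over
the off-diagonal cells.  The resulting coefficient is assigned to the
sphere's center voxel.  Centers whose sphere covers less than a minimum
fraction of the full sphere with in-mask voxels (a condition arising at
brain boundaries) are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import stats

from .glm import TrialBetaSet
from .rdm import RDM, upper_triangle

log = logging.getLogger(__name__)

__all__ = [
    "ConstantPatternError",
    "SearchlightSet",
    "RsaMap",
    "sphere_offsets",
    "searchlight_centers",
    "neural_rdm",
    "rsa_map",
    "partial_rsa_map",
]


class ConstantPatternError(ValueError):
    """A concept's pattern is constant over the searchlight voxels."""


#: decimals RDM cells are rounded to before rank transformation, so exact
#: representational ties (identical patterns) survive floating-point noise;
#: 1e-10 is far below the resolution of any measured correlation distance
TIE_DECIMALS = 10


def sphere_offsets(radius_vox: float) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with squared norm <= radius^2.

    Inclusive boundary, radius counted in voxels; at radius 3 the sphere
    contains 123 voxels.
    """
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius_vox**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass(frozen=True)
class SearchlightSet:
    """Retained searchlight centers with their in-mask neighbor voxels.

    ``centers`` are (n, 3) voxel coordinates; ``neighbors[i]`` holds the
    in-mask voxel column indices (into the C-order in-mask vector) inside
    center i's sphere, always including the center itself.
    """

    centers: np.ndarray = field(repr=False)
    neighbors: list = field(repr=False)
    radius_vox: float
    min_fraction: float
    mask_shape: tuple

    @property
    def n_centers(self) -> int:
        return len(self.neighbors)


def searchlight_centers(
    mask: np.ndarray,
    radius_vox: float = 3.0,
    min_fraction: float = 0.5,
) -> SearchlightSet:
    """Compute searchlight centers and neighborhoods over a binary mask.

    A mask voxel is retained as a center iff at least ``min_fraction`` of
    the full geometric sphere (123 voxels at radius 3) is made of in-mask
    voxels; the denominator is the full sphere size, so spheres protruding
    beyond the volume or the mask count as incomplete.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = sphere_offsets(radius_vox)
    sphere_size = len(offsets)
    vox_index = np.full(mask.shape, -1, dtype=np.int64)
    vox_index[mask] = np.arange(int(mask.sum()))
    coords = np.argwhere(mask)  # (m, 3), C-order == column order
    m = coords.shape[0]
    hit_cols = np.full((m, sphere_size), -1, dtype=np.int64)
    for k, off in enumerate(offsets):
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < mask.shape), axis=1)
        idx = vox_index[shifted[ok, 0], shifted[ok, 1], shifted[ok, 2]]
        rows = np.flatnonzero(ok)
        hit_cols[rows[idx >= 0], k] = idx[idx >= 0]
    counts = np.sum(hit_cols >= 0, axis=1)
    retained = counts >= min_fraction * sphere_size - 1e-9
    centers = coords[retained]
    neighbors = [row[row >= 0] for row in hit_cols[retained]]
    return SearchlightSet(
        centers=centers,
        neighbors=neighbors,
        radius_vox=radius_vox,
        min_fraction=min_fraction,
        mask_shape=mask.shape,
    )


def _restricted(betas, voxel_idx) -> tuple:
    if isinstance(betas, TrialBetaSet):
        return betas.concepts, betas.betas[:, voxel_idx]
    raise TypeError("betas must be a TrialBetaSet")


def _corr_cells(p: np.ndarray, context: str = "") -> np.ndarray:
    """Upper-triangle correlation-distance cells of pattern rows."""
    z = p - p.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", z, z))
    if np.any(norms == 0):
        raise ConstantPatternError(
            f"constant pattern over searchlight voxels{context}"
        )
    c = (z @ z.T) / np.outer(norms, norms)
    np.clip(c, -1.0, 1.0, out=c)
    return upper_triangle(1.0 - c)


def neural_rdm(betas, voxel_idx) -> RDM:
    """Correlation-distance RDM of concept patterns over given voxels.

    Each concept's pattern restricted to ``voxel_idx`` is centered and
    scaled to unit variance (a no-op for the subsequent Pearson
    correlation) before pairwise correlation distances are taken.
    """
    voxel_idx = np.asarray(voxel_idx, dtype=int)
    if voxel_idx.size < 2:
        raise ValueError("need at least 2 voxels for a pattern correlation")
    concepts, p = _restricted(betas, voxel_idx)
    cells = _corr_cells(p)
    k = len(concepts)
    d = np.zeros((k, k))
    i, j = np.triu_indices(k, k=1)
    d[i, j] = cells
    d[j, i] = cells
    return RDM(labels=concepts, d=d)


@dataclass(frozen=True)
class RsaMap:
    """3-D grid of Spearman coefficients at searchlight centers.

    NaN everywhere except retained (and non-skipped) centers.
    """

    values: np.ndarray = field(repr=False)
    model_label: str = ""

    def to_nifti(self, affine=None):
        if affine is None:
            affine = np.eye(4)
        return nib.Nifti1Image(self.values.astype(np.float32), affine)


def _check_labels(betas, model: RDM) -> None:
    if tuple(betas.concepts) != tuple(model.labels):
        raise ValueError(
            "beta concept labels must equal model RDM labels, in order"
        )


def _map_from_ranks(betas, sls: SearchlightSet, model_ranks: np.ndarray,
                    residualize=None, model_label: str = "") -> RsaMap:
    values = np.full(sls.mask_shape, np.nan)
    mr = model_ranks - model_ranks.mean()
    if residualize is not None:
        mr = residualize(mr)
    mr_norm = np.sqrt(mr @ mr)
    skipped = 0
    for center, idx in zip(sls.centers, sls.neighbors):
        _, p = _restricted(betas, idx)
        try:
            cells = _corr_cells(p, context=f" at center {tuple(center)}")
        except ConstantPatternError:
            skipped += 1
            continue
        nr = stats.rankdata(np.round(cells, TIE_DECIMALS))
        nr = nr - nr.mean()
        if residualize is not None:
            nr = residualize(nr)
        denom = np.sqrt(nr @ nr) * mr_norm
        if denom == 0:
            skipped += 1
            continue
        values[tuple(center)] = (nr @ mr) / denom
    if skipped:
        log.info("skipped %d searchlights with undefined neural RDM cells",
                 skipped)
    return RsaMap(values=values, model_label=model_label)


def rsa_map(betas, model: RDM, sls: SearchlightSet) -> RsaMap:
    """Spearman rho between each searchlight's neural RDM and a model RDM.

    The value at each retained center is the Spearman rank correlation
    (average ranks for ties) between the neural and model RDM cells;
    searchlights with an undefined neural RDM (a constant pattern) are
    skipped and logged, leaving NaN.
    """
    _check_labels(betas, model)
    model_ranks = stats.rankdata(np.round(model.cells(), TIE_DECIMALS))
    return _map_from_ranks(betas, sls, model_ranks, model_label="model")


def partial_rsa_map(betas, model: RDM, nuisance, sls: SearchlightSet) -> RsaMap:
    """Searchlight RSA with nuisance RDMs partialled out.

    Spearman partial correlation: the model and neural RDM cells are rank
    transformed, linearly residualized on the nuisance RDMs' ranks (plus an
    intercept), and the residuals correlated.  An empty nuisance list
    reduces to :func:`rsa_map`.  Nuisance sets that are collinear with the
    model (after ranking) are rejected.
    """
    nuisance = list(nuisance)
    if not nuisance:
        return rsa_map(betas, model, sls)
    _check_labels(betas, model)
    for nu in nuisance:
        if tuple(nu.labels) != tuple(model.labels):
            raise ValueError("nuisance RDM labels must match the model's")
    model_ranks = stats.rankdata(np.round(model.cells(), TIE_DECIMALS))
    z = np.column_stack(
        [np.ones(model_ranks.size)]
        + [stats.rankdata(np.round(nu.cells(), TIE_DECIMALS)) for nu in nuisance]
    )
    full = np.column_stack([z, model_ranks])
    if np.linalg.matrix_rank(full) <= np.linalg.matrix_rank(z):
        raise ValueError("nuisance RDMs are collinear with the model RDM")
    q, _ = np.linalg.qr(z)

    def residualize(x):
        return x - q @ (q.T @ x)

    return _map_from_ranks(betas, sls, model_ranks, residualize=residualize,
                           model_label="model|nuisance")
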