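"""First-level GLM estimation for event-related and block fMRI designs.

Implements the standard mass-univariate machinery: canonical double-gamma
HRF convolution on an oversampled time grid, discrete-cosine high-pass
drift regressors, ordinary least squares with optional single-pass AR(1)
prewhitening, trial-wise Least-Squares-Single (LSS) beta estimation, block
contrasts with t statistics, and Gaussian spatial smoothing.

LSS fits one GLM per trial of interest: a regressor for that single word
trial, one aggregate regressor for all other word trials, and one for all
pseudoword trials; the trial-of-interest coefficient per in-mask voxel is
that trial's activation estimate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats

log = logging.getLogger(__name__)

__all__ = [
    "canonical_hrf",
    "sampled_hrf",
    "dct_drifts",
    "DesignMatrix",
    "build_design_matrix",
    "task_regressors",
    "estimate_ar1",
    "whiten",
    "TrialBetaSet",
    "StatMap",
    "lss_betas",
    "block_glm_contrast",
    "smooth_volume",
]

#: oversampling bins per TR used for HRF convolution (fixed convention)
OVERSAMPLE = 16
#: HRF support in seconds
HRF_LENGTH_S = 32.0


def canonical_hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response evaluated at times ``t``.

    Difference of two gamma densities: a positive response peaking about
    5 s after the event and a late undershoot, with the conventional
    parameterization (delays 6 s and 16 s, unit dispersions, undershoot
    ratio 1/6).  Not normalized; see :func:`sampled_hrf`.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, a=peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, a=undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    return peak - undershoot_ratio * under


def sampled_hrf(tr: float, oversample: int = OVERSAMPLE) -> np.ndarray:
    """HRF sampled on the oversampled grid, normalized to unit sum."""
    dt = tr / oversample
    t = np.arange(0.0, HRF_LENGTH_S, dt)
    h = canonical_hrf(t)
    return h / h.sum()


def task_regressors(
    design,
    conditions: Sequence,
    n_vols: int,
    tr: float,
    oversample: int = OVERSAMPLE,
) -> np.ndarray:
    """HRF-convolved regressors (volumes x conditions), one per condition.

    Event boxcars (sticks, for zero durations) are laid out on a grid of
    ``oversample`` bins per TR, convolved with the canonical HRF, and
    sampled at the volume acquisition midpoints ``(i + 0.5) * TR``.  This
    handles onsets jittered by sub-TR fractions.
    """
    dt = tr / oversample
    n_fine = n_vols * oversample
    h = sampled_hrf(tr, oversample)
    onsets = np.asarray(design.onsets, dtype=float)
    durations = np.asarray(design.durations, dtype=float)
    labels = np.asarray(design.conditions, dtype=object)
    if onsets.size and onsets.max() + durations[np.argmax(onsets)] > n_vols * tr + dt:
        raise ValueError("design events extend beyond the acquired volumes")
    cols = np.zeros((n_vols, len(conditions)))
    sample_idx = np.arange(n_vols) * oversample + oversample // 2
    for c, cond in enumerate(conditions):
        fine = np.zeros(n_fine)
        for on, du in zip(onsets[labels == cond], durations[labels == cond]):
            a = int(round(on / dt))
            b = max(a + 1, int(round((on + du) / dt)))
            fine[a : min(b, n_fine)] = 1.0
        conv = np.convolve(fine, h)[:n_fine]
        cols[:, c] = conv[sample_idx]
    return cols


def dct_drifts(n_vols: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (volumes x K), unit-norm columns.

    ``K = floor(2 * n_vols * tr / cutoff_s)`` cosines, one for every period
    longer than the cutoff; the constant (k = 0) term is excluded.  Columns
    are mutually orthogonal.
    """
    k_max = int(math.floor(2.0 * n_vols * tr / cutoff_s))
    n = np.arange(n_vols)
    cols = [
        np.cos(np.pi * k * (2 * n + 1) / (2 * n_vols)) * np.sqrt(2.0 / n_vols)
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.zeros((n_vols, 0))
    return np.column_stack(cols)


@dataclass(frozen=True)
class DesignMatrix:
    """Time x regressor design matrix with labelled columns."""

    x: np.ndarray = field(repr=False)
    names: tuple
    tr: float

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        if self.x.shape[1] != len(self.names):
            raise ValueError("one name per design column required")


def _condition_order(design) -> list:
    return list(dict.fromkeys(design.conditions))


def build_design_matrix(
    design,
    n_vols: int,
    tr: float | None = None,
    hpf_cutoff_s: float | None = 128.0,
    nuisance: np.ndarray | None = None,
    conditions: Sequence | None = None,
) -> DesignMatrix:
    """Assemble a first-level design matrix.

    Column order: one HRF-convolved column per task condition (order of
    first appearance unless ``conditions`` is given), discrete-cosine drift
    columns for every period above ``hpf_cutoff_s``, nuisance columns
    (e.g. realignment parameters), and a constant column last.
    """
    tr = float(design.tr if tr is None else tr)
    if conditions is None:
        conditions = _condition_order(design)
    tasks = task_regressors(design, conditions, n_vols, tr)
    blocks = [tasks]
    names = [str(c) for c in conditions]
    if hpf_cutoff_s is not None:
        drifts = dct_drifts(n_vols, tr, hpf_cutoff_s)
        blocks.append(drifts)
        names += [f"drift_{k + 1}" for k in range(drifts.shape[1])]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_vols:
            raise ValueError("nuisance matrix must have one row per volume")
        blocks.append(nuisance)
        names += [f"nuis_{k + 1}" for k in range(nuisance.shape[1])]
    blocks.append(np.ones((n_vols, 1)))
    names.append("constant")
    x = np.column_stack(blocks)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn(
            "design matrix is rank deficient; estimation uses the "
            "pseudoinverse",
            stacklevel=2,
        )
    return DesignMatrix(x=x, names=names, tr=tr)


def estimate_ar1(residuals: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of residuals (time x voxels)."""
    r = np.atleast_2d(residuals.T).T  # ensure 2-D, time first
    num = np.sum(r[1:] * r[:-1])
    den = np.sum(r * r)
    if den == 0:
        return 0.0
    return float(np.clip(num / den, -0.99, 0.99))


def whiten(m: np.ndarray, phi: float) -> np.ndarray:
    """AR(1) prewhitening transform along the first (time) axis.

    Cochrane-Orcutt style: ``y'_t = y_t - phi * y_{t-1}`` with the first
    sample scaled by ``sqrt(1 - phi^2)`` so the transform is full rank.
    """
    m = np.asarray(m, dtype=float)
    out = np.empty_like(m)
    out[0] = math.sqrt(1.0 - phi * phi) * m[0]
    out[1:] = m[1:] - phi * m[:-1]
    return out


@dataclass(frozen=True)
class StatMap:
    """3-D statistic grid (t or z), finite in-mask, NaN outside."""

    values: np.ndarray = field(repr=False)
    df: float
    kind: str = "t"

    def __post_init__(self):
        if self.kind not in ("t", "z"):
            raise ValueError("kind must be 't' or 'z'")


@dataclass(frozen=True)
class TrialBetaSet:
    """Per-concept activation estimates stacked as concepts x in-mask voxels.

    Row order matches the (sorted) concept label order used for the model
    RDMs.  ``mask`` is the 3-D boolean grid the voxel axis refers to, in
    C-order of ``np.flatnonzero(mask)``.
    """

    concepts: tuple
    betas: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "concepts", tuple(self.concepts))
        if self.betas.shape[0] != len(self.concepts):
            raise ValueError("one beta row per concept required")
        if self.betas.shape[1] != int(np.count_nonzero(self.mask)):
            raise ValueError("beta columns must match in-mask voxel count")
        if self.affine is None:
            object.__setattr__(self, "affine", np.eye(4))

    def to_nifti(self):
        """4-D NIfTI (x, y, z, concept) plus a label table (DataFrame)."""
        shape = self.mask.shape + (len(self.concepts),)
        data = np.full(shape, np.nan, dtype=np.float32)
        flat = np.flatnonzero(self.mask)
        for i in range(len(self.concepts)):
            vol = np.full(self.mask.size, np.nan, dtype=np.float32)
            vol[flat] = self.betas[i]
            data[..., i] = vol.reshape(self.mask.shape)
        img = nib.Nifti1Image(data, self.affine)
        labels = pd.DataFrame({"index": range(len(self.concepts)),
                               "concept": list(self.concepts)})
        return img, labels


def _masked_series(vol) -> np.ndarray:
    """Time x in-mask-voxel data matrix from a VolumeSeries."""
    data = np.asarray(vol.data, dtype=float)
    mask = np.asarray(vol.mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape must equal the spatial shape of the data")
    return data[mask].T  # (t, v)


def _ols_fit(x: np.ndarray, y: np.ndarray):
    beta = np.linalg.pinv(x) @ y
    resid = y - x @ beta
    return beta, resid


def lss_betas(
    vol,
    design,
    word_labels: Sequence | None = None,
    pseudoword_label: str = "pseudoword",
    ar1: bool = True,
    hpf_cutoff_s: float | None = 128.0,
    nuisance: np.ndarray | None = None,
) -> TrialBetaSet:
    """Least-Squares-Single trial-wise beta estimation.

    For each real-word trial a separate GLM is fitted whose task block has
    exactly three columns: the trial of interest, all other word trials
    aggregated, and all pseudoword trials aggregated (omitted when there
    are none); drift, nuisance and constant columns are appended.  With
    ``ar1=True`` a single pooled lag-1 autocorrelation is estimated from
    the residuals of a reference model (all words as one regressor) and
    applied as a prewhitening transform to data and design.

    Returns the trial-of-interest coefficients per in-mask voxel, rows
    sorted alphabetically by concept label (the order model RDMs use).
    """
    tr = float(vol.tr)
    y = _masked_series(vol)
    n_vols = y.shape[0]

    labels = np.asarray(design.conditions, dtype=object)
    if word_labels is None:
        word_labels = [c for c in dict.fromkeys(labels) if c != pseudoword_label]
    word_labels = list(word_labels)
    if not word_labels:
        raise ValueError("design contains no real-word trials")
    counts = {w: int(np.sum(labels == w)) for w in word_labels}
    repeated = [w for w, n in counts.items() if n != 1]
    if repeated:
        raise ValueError(
            f"each word label must tag exactly one trial; offending: {repeated}"
        )

    # single-event regressors, one per word trial
    word_cols = task_regressors(design, word_labels, n_vols, tr)
    all_words = word_cols.sum(axis=1, keepdims=True)
    has_pseudo = bool(np.sum(labels == pseudoword_label))
    pseudo = (
        task_regressors(design, [pseudoword_label], n_vols, tr)
        if has_pseudo
        else np.zeros((n_vols, 0))
    )

    confounds = []
    if hpf_cutoff_s is not None:
        confounds.append(dct_drifts(n_vols, tr, hpf_cutoff_s))
    if nuisance is not None:
        confounds.append(np.atleast_2d(np.asarray(nuisance, dtype=float)))
    confounds.append(np.ones((n_vols, 1)))
    c_block = np.column_stack(confounds)

    n_regressors = 2 + pseudo.shape[1] + c_block.shape[1]
    if n_vols < n_regressors:
        raise ValueError(
            f"{n_vols} volumes cannot support {n_regressors} regressors"
        )

    if ar1:
        x_ref = np.column_stack([all_words, pseudo, c_block])
        _, resid = _ols_fit(x_ref, y)
        phi = estimate_ar1(resid)
        y_w = whiten(y, phi)
        word_w = whiten(word_cols, phi)
        all_w = whiten(all_words, phi)
        pseudo_w = whiten(pseudo, phi) if has_pseudo else pseudo
        c_w = whiten(c_block, phi)
    else:
        y_w, word_w, all_w, pseudo_w, c_w = y, word_cols, all_words, pseudo, c_block

    order = sorted(range(len(word_labels)), key=lambda i: str(word_labels[i]))
    betas = np.empty((len(word_labels), y.shape[1]))
    for row, i in enumerate(order):
        target = word_w[:, i : i + 1]
        others = all_w - target
        x = np.column_stack([target, others, pseudo_w, c_w])
        beta, _ = _ols_fit(x, y_w)
        betas[row] = beta[0]
    concepts = [word_labels[i] for i in order]
    return TrialBetaSet(
        concepts=concepts,
        betas=betas,
        mask=np.asarray(vol.mask, dtype=bool),
        affine=getattr(vol, "affine", None),
    )


def block_glm_contrast(
    vol,
    design,
    contrast: Sequence[float],
    hpf_cutoff_s: float | None = 128.0,
    nuisance: np.ndarray | None = None,
    ar1: bool = False,
):
    """Block-design GLM with a contrast: returns (StatMap, contrast image).

    Boxcar regressors (one per task condition) are convolved with the
    canonical HRF; the per-voxel contrast estimate ``c'beta`` and its t
    statistic ``c'beta / SE`` are computed, with ``df = T - rank(X)``.
    """
    conditions = _condition_order(design)
    contrast = np.asarray(contrast, dtype=float)
    if contrast.size != len(conditions):
        raise ValueError(
            f"contrast length {contrast.size} != {len(conditions)} task conditions"
        )
    if not np.any(contrast):
        raise ValueError("contrast of all zeros is not a contrast")
    y = _masked_series(vol)
    n_vols = y.shape[0]
    dm = build_design_matrix(
        design, n_vols, tr=vol.tr, hpf_cutoff_s=hpf_cutoff_s,
        nuisance=nuisance, conditions=conditions,
    )
    x = dm.x
    if ar1:
        _, resid0 = _ols_fit(x, y)
        phi = estimate_ar1(resid0)
        x = whiten(x, phi)
        y = whiten(y, phi)
    beta, resid = _ols_fit(x, y)
    rank = np.linalg.matrix_rank(x)
    df = n_vols - rank
    c_full = np.zeros(x.shape[1])
    c_full[: contrast.size] = contrast
    con = c_full @ beta
    sigma2 = np.sum(resid * resid, axis=0) / df
    xtx_inv = np.linalg.pinv(x.T @ x)
    c_var = float(c_full @ xtx_inv @ c_full)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = con / np.sqrt(sigma2 * c_var)
    n_degenerate = int(np.sum(~np.isfinite(t)))
    if n_degenerate:
        log.info("block_glm_contrast: %d voxels with undefined t", n_degenerate)
    mask = np.asarray(vol.mask, dtype=bool)
    t_grid = np.full(mask.shape, np.nan)
    t_grid[mask] = t
    con_grid = np.full(mask.shape, np.nan)
    con_grid[mask] = con
    return StatMap(values=t_grid, df=df, kind="t"), con_grid


def smooth_volume(img: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D image.

    ``sigma = fwhm / (2 * sqrt(2 * ln 2))`` per axis, converted from mm to
    voxel units.  The kernel is truncated at 6 sigma so the interior profile
    matches the analytic Gaussian to better than 1e-6.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel_size
    return ndimage.gaussian_filter(np.asarray(img, dtype=float),
                                   sigma=sigma_vox, truncate=6.0)
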