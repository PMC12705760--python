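"""Group-level inference on subject maps.

Per-voxel normality screening (Shapiro-Wilk with FDR correction), one- and
two-sample and paired t-maps, minimum-statistic conjunction, and
cluster-level family-wise-error control by permutation: clusters of
contiguous suprathreshold voxels (18-connectivity) are compared against
the permutation null distribution of the maximum cluster size, obtained by
sign-flipping subjects (one-sample/paired) or permuting group labels
(two-sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .glm import StatMap

log = logging.getLogger(__name__)

__all__ = [
    "GroupSample",
    "Cluster",
    "ClusterResult",
    "normality_screen",
    "group_t_map",
    "conjunction_map",
    "cluster_inference",
    "t_to_z",
]

#: 18-connectivity structuring element (faces + edges) for cluster labelling
_CONN18 = ndimage.generate_binary_structure(3, 2)


@dataclass(frozen=True)
class GroupSample:
    """Subject x voxel matrix over a common mask.

    ``groups`` (optional) holds a two-level label per subject for
    two-sample tests; ``pairs`` (optional) a pairing id per row for paired
    tests, where each pair id occurs exactly twice, once per group level.
    """

    maps: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    affine: np.ndarray = field(default=None, repr=False)
    groups: np.ndarray = field(default=None, repr=False)
    pairs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        maps = np.asarray(self.maps, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if maps.ndim != 2:
            raise ValueError("maps must be subjects x voxels")
        if maps.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if maps.shape[1] != int(mask.sum()):
            raise ValueError("map columns must match in-mask voxel count")
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "mask", mask)
        if self.affine is None:
            object.__setattr__(self, "affine", np.eye(4))
        if self.groups is not None:
            g = np.asarray(self.groups)
            if g.size != maps.shape[0]:
                raise ValueError("one group label per subject required")
            if np.unique(g).size != 2:
                raise ValueError("exactly two group levels required")
            object.__setattr__(self, "groups", g)
        if self.pairs is not None:
            object.__setattr__(self, "pairs", np.asarray(self.pairs))

    @classmethod
    def from_stack(cls, stack4d: np.ndarray, mask: np.ndarray, **kw
                   ) -> "GroupSample":
        """Build from a 4-D (x, y, z, subject) array and a mask."""
        mask = np.asarray(mask, dtype=bool)
        maps = np.asarray(stack4d, dtype=float)[mask].T
        return cls(maps=maps, mask=mask, **kw)

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]


def normality_screen(gs: GroupSample, alpha: float = 0.05) -> float:
    """Fraction of in-mask voxels rejecting Shapiro-Wilk normality after FDR.

    Each voxel's across-subject sample is tested with Shapiro-Wilk;
    p-values are Benjamini-Hochberg corrected at ``alpha`` across voxels.
    Voxels that are constant across subjects (or contain NaN) are excluded
    from testing and logged.
    """
    if gs.n_subjects < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 subjects")
    maps = gs.maps
    usable = np.isfinite(maps).all(axis=0) & (maps.std(axis=0) > 0)
    n_excluded = int(np.sum(~usable))
    if n_excluded:
        log.info("normality_screen: excluded %d constant/NaN voxels",
                 n_excluded)
    cols = np.flatnonzero(usable)
    if cols.size == 0:
        raise ValueError("no testable voxels")
    pvals = np.array([stats.shapiro(maps[:, j]).pvalue for j in cols])
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return float(reject.mean())


def _t_one_sample(maps: np.ndarray) -> tuple[np.ndarray, int]:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t, n - 1


def _t_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1)
           + (nb - 1) * b.var(axis=0, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(
            sp2 * (1.0 / na + 1.0 / nb))
    return t, df


def _paired_diffs(gs: GroupSample) -> np.ndarray:
    if gs.groups is None or gs.pairs is None:
        raise ValueError("paired mode needs groups and pairs")
    levels = np.unique(gs.groups)
    diffs = []
    for pid in dict.fromkeys(gs.pairs.tolist()):
        sel = gs.pairs == pid
        if sel.sum() != 2 or np.unique(gs.groups[sel]).size != 2:
            raise ValueError(f"pair {pid!r} must have one row per group level")
        ia = np.flatnonzero(sel & (gs.groups == levels[0]))[0]
        ib = np.flatnonzero(sel & (gs.groups == levels[1]))[0]
        diffs.append(gs.maps[ia] - gs.maps[ib])
    return np.asarray(diffs)


def group_t_map(gs: GroupSample, mode: str = "one_sample") -> StatMap:
    """Voxel-wise t-map across subjects.

    ``one_sample``: mean against zero (df = n-1); ``two_sample``: pooled
    t between the two group levels (df = n1+n2-2); ``paired``: one-sample
    t on within-pair differences.  Voxels with zero variance get NaN and
    are logged.
    """
    if mode == "one_sample":
        t, df = _t_one_sample(gs.maps)
    elif mode == "two_sample":
        if gs.groups is None:
            raise ValueError("two_sample mode needs group labels")
        levels = np.unique(gs.groups)
        a = gs.maps[gs.groups == levels[0]]
        b = gs.maps[gs.groups == levels[1]]
        if min(a.shape[0], b.shape[0]) < 2:
            raise ValueError("each group needs at least 2 subjects")
        t, df = _t_two_sample(a, b)
    elif mode == "paired":
        diffs = _paired_diffs(gs)
        if diffs.shape[0] < 2:
            raise ValueError("need at least 2 pairs")
        t, df = _t_one_sample(diffs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_bad = int(np.sum(~np.isfinite(t)))
    if n_bad:
        log.info("group_t_map: %d voxels with undefined t (zero variance)",
                 n_bad)
    t = np.where(np.isfinite(t), t, np.nan)
    grid = np.full(gs.mask.shape, np.nan)
    grid[gs.mask] = t
    return StatMap(values=grid, df=df, kind="t")


def conjunction_map(t_a: StatMap, t_b: StatMap) -> StatMap:
    """Minimum-statistic conjunction of two t-maps.

    The voxel-wise minimum exceeds the cluster-forming threshold exactly
    when both conjuncts do (conjunction null, the conservative
    formulation).  Maps must share grid and degrees of freedom.
    """
    if t_a.values.shape != t_b.values.shape:
        raise ValueError("conjunction maps must share the same grid")
    if t_a.df != t_b.df or t_a.kind != t_b.kind:
        raise ValueError("conjunction maps must share the same df basis")
    return StatMap(values=np.minimum(t_a.values, t_b.values),
                   df=t_a.df, kind=t_a.kind)


def t_to_z(t, df: float):
    """Probability-matching transform of t statistics to z-scores."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
    return z if z.ndim else float(z)


@dataclass(frozen=True)
class Cluster:
    """One suprathreshold cluster with its peak and corrected p-value."""

    size: int
    peak_ijk: tuple
    peak_mm: tuple
    peak_stat: float
    peak_z: float
    p_corrected: float
    significant: bool
    voxel_labels: int = 0  # label id in the cluster image


@dataclass(frozen=True)
class ClusterResult:
    """Cluster list, significance mask, and the underlying statistic map."""

    clusters: list
    sig_mask: np.ndarray = field(repr=False)
    stat: StatMap = None
    label_img: np.ndarray = field(default=None, repr=False)
    affine: np.ndarray = field(default=None, repr=False)
    t_threshold: float = float("nan")


def _max_cluster_size(t_vec: np.ndarray, mask: np.ndarray, t_crit: float
                      ) -> int:
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = t_vec > t_crit
    if not supra.any():
        return 0
    labels, n = ndimage.label(supra, structure=_CONN18)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(supra, labels, range(1, n + 1))))


def cluster_inference(
    gs: GroupSample,
    mode: str = "one_sample",
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-level FWE-corrected inference by permutation.

    The observed t-map is thresholded at the one-sided cluster-forming
    threshold ``t_{df}(1 - voxel_p)``; contiguous suprathreshold clusters
    (18-connectivity) are measured, and each cluster's corrected p-value is
    ``(1 + #{null max size >= observed size}) / (1 + n_perm)`` under the
    permutation null of the maximum cluster size: random sign flips of
    subjects for one-sample/paired (valid under a symmetric null), random
    relabelings for two-sample.  Clusters with corrected p < cluster_alpha
    form the significance mask.  No suprathreshold voxels is an empty
    result, not an error.
    """
    if n_perm < 100:
        raise ValueError("n_perm >= 100 required for stable tail estimates")
    rng = np.random.default_rng(seed)
    if mode == "paired":
        maps = _paired_diffs(gs)
        flip_mode = True
    elif mode == "one_sample":
        maps = gs.maps
        flip_mode = True
    elif mode == "two_sample":
        if gs.groups is None:
            raise ValueError("two_sample mode needs group labels")
        maps = gs.maps
        flip_mode = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    maps = np.nan_to_num(maps, nan=0.0)

    if flip_mode:
        t_obs, df = _t_one_sample(maps)
    else:
        levels = np.unique(gs.groups)
        ga = gs.groups == levels[0]
        t_obs, df = _t_two_sample(maps[ga], maps[~ga])
    t_crit = float(stats.t.isf(voxel_p, df))
    t_obs = np.where(np.isfinite(t_obs), t_obs, -np.inf)

    # observed clusters
    supra = np.zeros(gs.mask.shape, dtype=bool)
    supra[gs.mask] = t_obs > t_crit
    label_img, n_clusters = ndimage.label(supra, structure=_CONN18)

    # permutation null of the maximum cluster size
    null_max = np.empty(n_perm, dtype=int)
    if flip_mode:
        n = maps.shape[0]
        ss = np.sum(maps * maps, axis=0)  # invariant under sign flips
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        means = signs @ maps / n
        var = np.clip((ss - n * means**2) / (n - 1), 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = means / np.sqrt(var / n)
        t_perm = np.where(np.isfinite(t_perm), t_perm, -np.inf)
        for i in range(n_perm):
            null_max[i] = _max_cluster_size(t_perm[i], gs.mask, t_crit)
    else:
        n_a = int(np.sum(ga))
        idx = np.arange(maps.shape[0])
        for i in range(n_perm):
            perm = rng.permutation(idx)
            t_p, _ = _t_two_sample(maps[perm[:n_a]], maps[perm[n_a:]])
            t_p = np.where(np.isfinite(t_p), t_p, -np.inf)
            null_max[i] = _max_cluster_size(t_p, gs.mask, t_crit)

    stat_grid = np.full(gs.mask.shape, np.nan)
    stat_grid[gs.mask] = np.where(np.isfinite(t_obs), t_obs, np.nan)
    stat = StatMap(values=stat_grid, df=df, kind="t")

    clusters = []
    sig = np.zeros(gs.mask.shape, dtype=bool)
    for lab in range(1, n_clusters + 1):
        members = label_img == lab
        size = int(members.sum())
        p_corr = float((1 + np.sum(null_max >= size)) / (1 + n_perm))
        masked_stat = np.where(members, stat_grid, -np.inf)
        peak_flat = int(np.argmax(masked_stat))
        peak_ijk = np.unravel_index(peak_flat, gs.mask.shape)
        peak_mm = tuple(
            (gs.affine @ np.array([*peak_ijk, 1.0]))[:3].tolist())
        peak_stat = float(stat_grid[peak_ijk])
        significant = p_corr < cluster_alpha
        if significant:
            sig |= members
        clusters.append(Cluster(
            size=size,
            peak_ijk=tuple(int(v) for v in peak_ijk),
            peak_mm=peak_mm,
            peak_stat=peak_stat,
            peak_z=t_to_z(peak_stat, df),
            p_corrected=p_corr,
            significant=significant,
            voxel_labels=lab,
        ))
    clusters.sort(key=lambda c: -c.size)
    return ClusterResult(clusters=clusters, sig_mask=sig, stat=stat,
                         label_img=label_img, affine=gs.affine,
                         t_threshold=t_crit)
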