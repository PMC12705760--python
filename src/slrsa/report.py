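"""Result tabulation: localizer overlap percentages and cluster tables.

Overlap is reported as the percentage of voxels of a significance map (or
of a single cluster) that fall inside a localizer activation mask; cluster
tables list, per cluster, its size, its local maxima in world coordinates,
the peak statistic, and the per-localizer overlap percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import StatMap
from .inference import ClusterResult, t_to_z

__all__ = ["OverlapReport", "overlap_percent", "cluster_table"]


def overlap_percent(a: np.ndarray, b: np.ndarray) -> float:
    """Percentage of voxels of binary mask ``a`` that also lie in ``b``.

    ``100 * |a and b| / |a|``; undefined (raises) when ``a`` is empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the same grid")
    na = int(a.sum())
    if na == 0:
        raise ValueError("overlap is undefined for an empty reference mask")
    return 100.0 * int(np.logical_and(a, b).sum()) / na


@dataclass(frozen=True)
class OverlapReport:
    """Whole-map and per-cluster localizer overlap percentages (1 decimal).

    ``map_overlap[name]`` is the percentage of all significant voxels
    inside localizer ``name``; ``cluster_overlap[i][name]`` the same for
    cluster i.  ``None`` when the significance map is empty.
    """

    map_overlap: dict
    cluster_overlap: list = field(default_factory=list)


def _local_maxima(stat: np.ndarray, members: np.ndarray, affine: np.ndarray,
                  peak_sep_mm: float, max_peaks: int) -> list:
    """Greedy selection of cluster local maxima separated in world space."""
    vals = np.where(members, stat, -np.inf)
    is_max = vals >= ndimage.maximum_filter(vals, size=3, mode="constant",
                                            cval=-np.inf)
    cand = np.argwhere(is_max & members)
    cand = cand[np.argsort(-vals[tuple(cand.T)])]
    picked = []
    picked_mm = []
    for ijk in cand:
        mm = (affine @ np.array([*ijk, 1.0]))[:3]
        if picked_mm and np.min(
            np.linalg.norm(np.array(picked_mm) - mm, axis=1)
        ) < peak_sep_mm:
            continue
        picked.append(tuple(int(v) for v in ijk))
        picked_mm.append(mm)
        if len(picked) >= max_peaks:
            break
    return picked


def cluster_table(
    result: ClusterResult,
    localizers: Mapping[str, np.ndarray],
    stat: StatMap | None = None,
    peak_sep_mm: float = 8.0,
    max_peaks: int = 16,
    significant_only: bool = True,
) -> tuple[pd.DataFrame, OverlapReport]:
    """Tabulate clusters with peaks and localizer overlaps.

    One row per local maximum (peaks at least ``peak_sep_mm`` apart, at
    most ``max_peaks`` per cluster); cluster-level fields (size, corrected
    p, overlaps) are repeated on each of its rows.  Whole-map overlaps use
    the significance mask as reference.
    """
    if stat is None:
        stat = result.stat
    grid_shape = result.sig_mask.shape
    for name, m in localizers.items():
        if np.asarray(m).shape != grid_shape:
            raise ValueError(f"localizer {name!r} grid does not match")
    if stat.values.shape != grid_shape:
        raise ValueError("statistic map grid does not match the clusters")
    affine = result.affine if result.affine is not None else np.eye(4)
    stat_vals = np.nan_to_num(stat.values, nan=-np.inf)

    if result.sig_mask.any():
        map_overlap = {
            name: round(overlap_percent(result.sig_mask, m), 1)
            for name, m in localizers.items()
        }
    else:
        map_overlap = {name: None for name in localizers}

    rows = []
    cluster_overlaps = []
    for ci, cl in enumerate(result.clusters):
        if significant_only and not cl.significant:
            continue
        members = result.label_img == cl.voxel_labels
        overlaps = {
            name: round(overlap_percent(members, m), 1)
            for name, m in localizers.items()
        }
        cluster_overlaps.append(overlaps)
        peaks = _local_maxima(stat_vals, members, affine,
                              peak_sep_mm, max_peaks)
        for ijk in peaks:
            mm = (affine @ np.array([*ijk, 1.0]))[:3]
            t_peak = float(stat.values[ijk])
            rows.append({
                "cluster": ci,
                "size_vox": cl.size,
                "p_corrected": cl.p_corrected,
                **{f"overlap_{n}_pct": v for n, v in overlaps.items()},
                "x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
                "peak_stat": t_peak,
                "peak_z": t_to_z(t_peak, stat.df) if stat.kind == "t"
                else t_peak,
            })
    columns = (
        ["cluster", "size_vox", "p_corrected"]
        + [f"overlap_{n}_pct" for n in localizers]
        + ["x_mm", "y_mm", "z_mm", "peak_stat", "peak_z"]
    )
    table = pd.DataFrame(rows, columns=columns)
    return table, OverlapReport(map_overlap=map_overlap,
                                cluster_overlap=cluster_overlaps)
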