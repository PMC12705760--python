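"""Representational dissimilarity matrices (RDMs) and their comparison.

An RDM stores, for every pair of conditions (here: word concepts), the
correlation distance ``1 - Pearson r`` between the conditions' feature
vectors or activation patterns.  RDMs are the common currency of
representational similarity analysis: model RDMs built from semantic
vectors or behavioural feature norms are compared against neural RDMs
computed from multi-voxel patterns, using Spearman rank correlation over
the off-diagonal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RDM",
    "RdmComparison",
    "correlation_distance_rdm",
    "build_experience_matrix",
    "semantic_rdm",
    "compare_rdms",
    "save_rdm",
    "load_rdm",
    "upper_triangle",
]

#: numerical slack for symmetry / range checks on construction
_TOL = 1e-8


def upper_triangle(d: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix, row-major.

    The same helper is used for model and neural RDMs so both sides of a
    comparison vectorize their cells in an identical order.
    """
    d = np.asarray(d)
    i, j = np.triu_indices(d.shape[0], k=1)
    return d[i, j]


@dataclass(frozen=True)
class RDM:
    """Symmetric matrix of correlation distances with condition labels.

    Invariants (checked on construction): the matrix is symmetric with an
    exactly zero diagonal, entries lie in ``[0, 2]`` (the range of
    ``1 - r``), and the label count equals the matrix order.
    """

    labels: tuple
    d: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        d = np.array(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("RDM matrix must be square")
        if len(self.labels) != d.shape[0]:
            raise ValueError(
                f"label count {len(self.labels)} != matrix order {d.shape[0]}"
            )
        if not np.allclose(d, d.T, atol=_TOL, equal_nan=False):
            raise ValueError("RDM matrix must be symmetric")
        d = 0.5 * (d + d.T)
        if np.any(np.abs(np.diag(d)) > _TOL):
            raise ValueError("RDM diagonal must be zero")
        np.fill_diagonal(d, 0.0)
        if d.min() < -_TOL or d.max() > 2.0 + _TOL:
            raise ValueError("correlation distances must lie in [0, 2]")
        np.clip(d, 0.0, 2.0, out=d)
        d.flags.writeable = False
        object.__setattr__(self, "d", d)

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    def cells(self) -> np.ndarray:
        """Off-diagonal upper-triangle cells, row-major."""
        return upper_triangle(self.d)


@dataclass(frozen=True)
class RdmComparison:
    """Spearman comparison of two RDMs' off-diagonal cells."""

    rho: float
    p: float
    n_pairs: int


def correlation_distance_rdm(m, labels: Sequence | None = None) -> RDM:
    """Convert a conditions x features matrix to a correlation-distance RDM.

    ``d[i, j] = 1 - Pearson(row_i, row_j)``.  Rows with zero variance have
    no defined correlation and are rejected with the offending row named.
    """
    if isinstance(m, pd.DataFrame):
        if labels is None:
            labels = list(m.index)
        m = m.to_numpy(dtype=float)
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 condition rows")
    if labels is None:
        labels = [f"cond_{i:03d}" for i in range(m.shape[0])]
    if len(labels) != m.shape[0]:
        raise ValueError("label count does not match row count")
    sd = m.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"row(s) with zero variance have undefined correlation: "
            f"{[labels[i] for i in bad]}"
        )
    d = 1.0 - np.corrcoef(m)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 2.0, out=d)
    return RDM(labels=labels, d=d)


def build_experience_matrix(pl, concepts: Sequence | None = None) -> pd.DataFrame:
    """Average per-participant category proportions into a concepts x 11 matrix.

    For every participant and concept the category counts are first turned
    into proportions of that cell's total listed properties; proportions are
    then averaged across the participants for whom the cell is not missing.
    Cells flagged missing contribute nothing (they are not treated as zero).

    Parameters
    ----------
    pl:
        A :class:`slrsa.synth.PropertyListings` (or any object with
        ``participants``, ``concepts``, ``categories``, ``counts`` and
        ``missing`` attributes).
    concepts:
        Row order of the output; defaults to ``pl.concepts``.  Must be a
        subset of the listing's concepts.
    """
    if concepts is None:
        concepts = list(pl.concepts)
    concept_idx = {c: i for i, c in enumerate(pl.concepts)}
    unknown = [c for c in concepts if c not in concept_idx]
    if unknown:
        raise ValueError(f"concepts not present in listings: {unknown}")
    counts = np.asarray(pl.counts, dtype=float)  # P x C x K
    n_part, _, n_cat = counts.shape
    missing = {(p, c) for p, c in pl.missing}
    out = np.zeros((len(concepts), n_cat))
    for r, concept in enumerate(concepts):
        ci = concept_idx[concept]
        rows = []
        for pi, participant in enumerate(pl.participants):
            if (participant, concept) in missing:
                continue
            cell = counts[pi, ci]
            total = cell.sum()
            if total == 0:
                # a listed cell always has >=1 property; an all-zero cell is
                # only legal when flagged missing
                raise ValueError(
                    f"cell ({participant!r}, {concept!r}) has zero counts "
                    "but is not flagged missing"
                )
            rows.append(cell / total)
        if not rows:
            raise ValueError(f"concept {concept!r} is missing for all participants")
        out[r] = np.mean(rows, axis=0)
    return pd.DataFrame(out, index=list(concepts), columns=list(pl.categories))


def semantic_rdm(space, concepts: Sequence) -> tuple[RDM, list]:
    """Build the language RDM from a semantic space, dropping absent concepts.

    Concepts without a vector in the space are dropped (the study dropped 6
    of its 64 words because they were absent from the word2vec vocabulary);
    the dropped labels are returned so the caller can report them.
    """
    have = {c: i for i, c in enumerate(space.concepts)}
    kept = [c for c in concepts if c in have]
    dropped = [c for c in concepts if c not in have]
    if len(kept) < 2:
        raise ValueError("fewer than 2 concepts present in the semantic space")
    vecs = np.asarray(space.vectors)[[have[c] for c in kept]]
    return correlation_distance_rdm(vecs, labels=kept), dropped


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return np.nan
    return float((rx @ ry) / denom)


def compare_rdms(
    a: RDM,
    b: RDM,
    n_perm: int = 0,
    seed: int | None = None,
    alternative: str = "greater",
) -> RdmComparison:
    """Spearman rank correlation between two RDMs' off-diagonal cells.

    Labels must match exactly, in order: no silent reordering is performed.
    With ``n_perm == 0`` the asymptotic p-value of the Spearman statistic is
    returned; otherwise a permutation p-value is computed by jointly
    relabeling the conditions of ``b`` (permuting its rows and columns with
    the same permutation) ``n_perm`` times.
    """
    if tuple(a.labels) != tuple(b.labels):
        raise ValueError("RDM labels differ (no silent reordering is done)")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    xa, xb = a.cells(), b.cells()
    rho = _spearman(xa, xb)
    n_pairs = xa.size
    if n_perm == 0:
        res = stats.spearmanr(xa, xb, alternative=alternative)
        p = float(res.pvalue)
    else:
        rng = np.random.default_rng(seed)
        k = a.n_conditions
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(k)
            d_perm = b.d[np.ix_(perm, perm)]
            r = _spearman(xa, upper_triangle(d_perm))
            if alternative == "greater":
                count += r >= rho
            else:
                count += abs(r) >= abs(rho)
        p = (1 + count) / (1 + n_perm)
    return RdmComparison(rho=rho, p=p, n_pairs=int(n_pairs))


def save_rdm(rdm: RDM, path) -> None:
    """Write an RDM to an HDF5 file with datasets ``labels`` and ``d``."""
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "labels",
            data=np.array([str(x) for x in rdm.labels], dtype=object),
            dtype=h5py.string_dtype("utf-8"),
        )
        f.create_dataset("d", data=rdm.d)


def load_rdm(path) -> RDM:
    """Read an RDM from HDF5; invariants are re-checked on load."""
    with h5py.File(path, "r") as f:
        if "labels" not in f:
            raise ValueError(f"{path}: missing 'labels' dataset")
        if "d" not in f:
            raise ValueError(f"{path}: missing 'd' dataset")
        labels = [
            x.decode("utf-8") if isinstance(x, bytes) else str(x)
            for x in f["labels"][()]
        ]
        d = np.asarray(f["d"][()], dtype=float)
    return RDM(labels=labels, d=d)
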