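"""Inter-rater agreement for property-category codings.

Two independent raters assign each listed property to modal feature
categories; agreement per category is quantified with the two-way
random-effects, absolute-agreement, single-measure intraclass correlation
ICC(A,1), and the per-category coefficients are summarized by a mean
weighted by each category's classification frequency.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "icc_agreement",
    "weighted_mean_icc",
    "category_rating_table",
    "read_rating_table",
]


def _as_table(rt) -> np.ndarray:
    if isinstance(rt, pd.DataFrame):
        rt = rt.to_numpy(dtype=float)
    rt = np.asarray(rt, dtype=float)
    if rt.ndim != 2 or rt.shape[1] != 2:
        raise ValueError("rating table must be items x 2 raters")
    if rt.shape[0] < 2:
        raise ValueError("need at least 2 items")
    return rt


def icc_agreement(rt) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    From the items x raters mean-squares decomposition with n items and
    k = 2 raters::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the row (item), column (rater), and residual
    mean squares.  Undefined (raises) when the table has zero variance.
    """
    x = _as_table(rt)
    n, k = x.shape
    grand = x.mean()
    if np.all(x == x.flat[0]):
        raise ValueError("ICC undefined: rating table has zero variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def weighted_mean_icc(iccs: Sequence[float], freqs: Sequence[float]) -> float:
    """Frequency-weighted mean of per-category ICCs.

    ``sum(icc_i * w_i) / sum(w_i)`` with weights the categories' mean
    classification frequencies over both raters; invariant to rescaling
    all weights by a positive constant.
    """
    iccs = np.asarray(iccs, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if iccs.shape != freqs.shape:
        raise ValueError("iccs and freqs must have equal length")
    if np.any(freqs < 0):
        raise ValueError("frequencies must be nonnegative")
    total = freqs.sum()
    if total == 0:
        raise ValueError("frequencies must not all be zero")
    return float(np.sum(iccs * freqs) / total)


def category_rating_table(pl_a, pl_b, category: str) -> pd.DataFrame:
    """Items x 2 table of one category's classification frequency per rater.

    Items are concepts; the rating is each rater's mean count of the
    category across the participants with a non-missing cell.  ``pl_a`` and
    ``pl_b`` are two raters' codings of the same listings (see
    :class:`slrsa.synth.PropertyListings`).
    """
    if tuple(pl_a.concepts) != tuple(pl_b.concepts):
        raise ValueError("raters must code the same concepts")
    try:
        ki_a = pl_a.categories.index(category)
        ki_b = pl_b.categories.index(category)
    except ValueError:
        raise ValueError(f"unknown category {category!r}") from None

    def freq(pl, ki):
        out = np.empty(len(pl.concepts))
        for ci, c in enumerate(pl.concepts):
            vals = [
                pl.counts[pi, ci, ki]
                for pi, p in enumerate(pl.participants)
                if (p, c) not in pl.missing
            ]
            if not vals:
                raise ValueError(f"concept {c!r} missing for all participants")
            out[ci] = np.mean(vals)
        return out

    return pd.DataFrame(
        {"rater1": freq(pl_a, ki_a), "rater2": freq(pl_b, ki_b)},
        index=list(pl_a.concepts),
    )


def read_rating_table(path) -> pd.DataFrame:
    """Read an (item, rater1, rater2) TSV into an items x 2 table."""
    df = pd.read_csv(path, sep="\t")
    need = {"item", "rater1", "rater2"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: columns {sorted(need)} required")
    return df.set_index("item")[["rater1", "rater2"]]
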