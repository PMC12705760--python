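import numpy as np
import pytest

from slrsa import rdm, synth


@pytest.fixture
def small_mask():
    """Compact ellipsoid mask in a 14^3 grid (~1000 voxels)."""
    return synth.ellipsoid_mask((14, 14, 14))


@pytest.fixture
def toy_rdm():
    """Valid 6-condition RDM with distinct continuous cells."""
    rng = np.random.default_rng(11)
    m = rng.standard_normal((6, 20))
    return rdm.correlation_distance_rdm(m, labels=list("abcdef"))


def brute_force_corr_rdm(m):
    """Independent pairwise correlation-distance oracle (explicit loops)."""
    m = np.asarray(m, dtype=float)
    k = m.shape[0]
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            xi = m[i] - m[i].mean()
            xj = m[j] - m[j].mean()
            r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            d[i, j] = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def rank_average(x):
    """Average ranks, written independently of scipy for oracle use."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    """Rank-then-Pearson Spearman oracle with average ranks for ties."""
    ra, rb = rank_average(a), rank_average(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))
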