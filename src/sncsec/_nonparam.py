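"""Shared nonparametric machinery: exact small-sample Mann-Whitney.

The group comparisons throughout the pipeline run on handfuls of
culture-medium samples (3-7 per group), where the normal approximation
to the Mann-Whitney null is poor.  The exact path enumerates every
assignment of the pooled observations to the two groups, which is also
correct under ties (it is the permutation test on the observed
multiset).  Larger samples fall back to scipy's tie-corrected normal
approximation.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

#: Largest pooled sample size for which the exact null is enumerated.
EXACT_LIMIT = 12


def mann_whitney_u(a, b) -> float:
    """U statistic of side ``a`` (number of (a, b) pairs with a > b,
    counting ties as 1/2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)


def exact_mw_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group splits.

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled values to
    the two groups and counts splits whose U is at least as far from the
    null mean n_a*n_b/2 as the observed U.  Valid with ties.

    Returns ``(U, p)`` with U the statistic of side ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2
    mu = n_a * n_b / 2
    u_obs = float(ranks[:n_a].sum() - offset)
    d_obs = abs(u_obs - mu)
    hits = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= d_obs - 1e-9:
            hits += 1
    return u_obs, hits / comb(n_a + n_b, n_a)


def mann_whitney(a, b, exact_limit: int = EXACT_LIMIT) -> tuple[float, float]:
    """Two-sided Mann-Whitney test.

    Exact enumeration when the pooled sample size is at most
    ``exact_limit``; tie-corrected normal approximation (with continuity
    correction) otherwise.

    Returns ``(U, p)`` with U the statistic of side ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) + len(b) <= exact_limit:
        return exact_mw_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
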