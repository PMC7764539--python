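"""Clinical/embryology statistics for couple-level ART outcome tables.

Implements the nonparametric toolkit used to relate IVF/ICSI protocol
parameters, gametogenesis measures, and embryo outcomes: Spearman rank
correlation matrices with Fisher-transform 95% confidence intervals,
two-sided Mann-Whitney comparisons of numeric variables between
outcome groups, and chi-square / Fisher exact tests for 2x2 outcome
tables.  Missing values are tolerated pairwise; the n actually used is
reported per correlation cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from sncsec._nonparam import exact_mw_p, mann_whitney, mann_whitney_u  # noqa: F401

#: Largest n for which the exact Spearman permutation null is enumerated.
SPEARMAN_EXACT_LIMIT = 9


@dataclass
class CorrelationResult:
    var_a: str
    var_b: str
    rho: float
    p: float
    ci95: tuple[float, float]
    n: int


def fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a correlation."""
    if n <= 3:
        return (float("nan"), float("nan"))
    with np.errstate(divide="ignore"):  # |rho| = 1 -> degenerate CI at +-1
        z = np.arctanh(rho)
    crit = stats.norm.ppf(0.5 + level / 2)
    half = crit / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def spearman(
    x, y, exact_limit: int = SPEARMAN_EXACT_LIMIT
) -> tuple[float, float]:
    """Spearman rho and two-sided p for one variable pair.

    rho is the Pearson correlation of average ranks.  The p-value uses
    the t approximation, except at very small n where the permutation
    null is enumerated exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_limit:
        perms = np.array(list(permutations(ry)))
        sx = rx - rx.mean()
        sp = perms - ry.mean()
        rhos = (sp @ sx) / np.sqrt((sx**2).sum() * (sp**2).sum(axis=1))
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).sum() / factorial(n))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p


def spearman_matrix(
    table: pd.DataFrame, variables: list[str] | None = None, min_pairs: int = 4
) -> list[CorrelationResult]:
    """All-pairs Spearman correlations with pairwise-complete deletion.

    Pairs with fewer than ``min_pairs`` complete observations or with a
    constant variable are reported with NaN rho (flagged, not fatal).
    """
    cols = variables if variables is not None else list(table.columns)
    out = []
    for ia, a in enumerate(cols):
        for b in cols[ia + 1 :]:
            sub = table[[a, b]].dropna()
            n = len(sub)
            if n < min_pairs:
                out.append(CorrelationResult(a, b, float("nan"), float("nan"), (float("nan"), float("nan")), n))
                continue
            rho, p = spearman(sub[a], sub[b])
            out.append(CorrelationResult(a, b, rho, p, fisher_ci(rho, n), n))
    return out


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "var_a": [r.var_a for r in results],
            "var_b": [r.var_b for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "ci_lo": [r.ci95[0] for r in results],
            "ci_hi": [r.ci95[1] for r in results],
            "n": [r.n for r in results],
        }
    )


def chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (Yates correction optional).

    A zero row or column margin makes the test degenerate; (nan, nan)
    is returned in that case.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (sum of tables as or less probable)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def format_p(p: float, floor: float = 0.001) -> str:
    """Report-style p formatting: values below 0.001 become "<0.001"."""
    if np.isnan(p):
        return "NA"
    return f"<{floor}" if p < floor else f"{p:.4g}"


def plot_correlation_matrix(results: list[CorrelationResult], path, alpha: float = 0.05):
    """Dot-matrix correlation plot: blue positive, red negative, dot
    size growing with significance; non-significant cells crossed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = []
    for r in results:
        for v in (r.var_a, r.var_b):
            if v not in names:
                names.append(v)
    idx = {v: i for i, v in enumerate(names)}
    fig, ax = plt.subplots(figsize=(0.4 * len(names) + 2,) * 2)
    for r in results:
        for (i, j) in ((idx[r.var_a], idx[r.var_b]), (idx[r.var_b], idx[r.var_a])):
            if np.isnan(r.rho):
                continue
            color = "tab:blue" if r.rho >= 0 else "tab:red"
            if r.p < alpha:
                size = 20 + 60 * min(-np.log10(max(r.p, 1e-10)) / 4, 1)
                ax.scatter(j, i, s=size, c=color)
            else:
                ax.scatter(j, i, marker="x", s=25, c=color)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    ax.set_xlim(-0.5, len(names) - 0.5)
    ax.set_ylim(len(names) - 0.5, -0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
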