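"""Count-matrix normalization and nonparametric group comparison.

Normalization is the median-of-ratios method: each sample's size factor
is the median, over features, of the ratio of that sample's count to
the feature's geometric mean across samples, computed on features with
strictly positive counts everywhere.  Group contrasts are tested per
feature with a two-sided Mann-Whitney test on normalized counts, exact
by enumeration at the pooled sample sizes this assay produces.

A negative-binomial Wald analysis is deliberately not provided: the
shipped comparison is the exact rank test, which matches the small-n
nonparametric treatment used everywhere else in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sncsec._nonparam import mann_whitney

GROUPS = ("I", "II", "III", "IV", "Reference")


@dataclass
class CountMatrix:
    """Integer feature x sample count table with sample group labels."""

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self):
        self.counts = self.counts.copy()
        self.counts.columns = self.counts.columns.astype(str)
        self.groups = self.groups.copy()
        self.groups.index = self.groups.index.astype(str)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.counts.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, groups: set[str] | list[str]) -> list[str]:
        wanted = set(groups)
        return [s for s in self.sample_ids if self.groups[s] in wanted]


@dataclass
class GroupComparison:
    feature_id: str
    contrast: str
    u: float
    p: float
    median_log2_ratio: float
    p_adj: float | None = None


def size_factors(m: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only features with strictly positive counts in every sample enter
    the geometric-mean reference and the per-sample ratio medians.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no feature with positive counts in all samples")
    log_ref = np.log(arr[all_pos])
    log_geomean = log_ref.mean(axis=1)
    # median taken on the log scale (geometric interpolation between the
    # two middle ratios when the feature count is even)
    factors = np.exp(np.median(log_ref - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(m: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if factors is None:
        factors = size_factors(m)
    return m.counts / factors


def compare_groups(
    m: CountMatrix,
    a: set[str] | list[str],
    b: set[str] | list[str],
    factors: pd.Series | None = None,
    bh: bool = False,
) -> list[GroupComparison]:
    """Per-feature two-sided Mann-Whitney on normalized counts.

    ``a`` and ``b`` are sets of group labels (e.g. {"I"} vs
    {"III", "IV"}).  Exact enumeration is used when the pooled sample
    count is small (see :mod:`sncsec._nonparam`); raw p-values are
    reported unless ``bh`` requests Benjamini-Hochberg adjustment.
    """
    sa, sb = m.samples_in(a), m.samples_in(b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each side of the contrast needs >=2 samples")
    norm = normalize(m, factors)
    contrast = "+".join(sorted(a)) + " vs " + "+".join(sorted(b))
    out = []
    for fid in m.feature_ids:
        xa = norm.loc[fid, sa].to_numpy(dtype=float)
        xb = norm.loc[fid, sb].to_numpy(dtype=float)
        u, p = mann_whitney(xa, xb)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(np.median(xa)) - np.log2(np.median(xb))
        out.append(GroupComparison(fid, contrast, u, p, float(ratio)))
    if bh:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([c.p for c in out], method="fdr_bh")[1]
        for c, q in zip(out, adj):
            c.p_adj = float(q)
    return out


def comparisons_to_frame(comps: list[GroupComparison]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sncRNA": [c.feature_id for c in comps],
            "contrast": [c.contrast for c in comps],
            "U": [c.u for c in comps],
            "p": [c.p for c in comps],
            "median_log2_ratio": [c.median_log2_ratio for c in comps],
        }
    )
    if comps and comps[0].p_adj is not None:
        df["p_adj"] = [c.p_adj for c in comps]
    return df


def read_counts_tsv(counts_path, groups_path) -> CountMatrix:
    """Load a counts TSV (features x samples) and a sample->group TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str).set_index("sample")["group"]
    return CountMatrix(counts, groups)
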