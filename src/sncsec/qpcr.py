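"""ddCt relative quantification of qPCR Ct tables.

Fold change of a target sncRNA in a sample is 2^-ddCt with

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,refmedium - Ct_ref,refmedium)

where the reference RNA (default hsa_piR_023338, constant across
samples) normalizes per-well input and the embryo-free reference
medium anchors the fold change at 1.  Per-group summaries report the
median and quartiles of the per-sample fold changes, in linear and
log2 form; group contrasts use the exact Mann-Whitney test (fold
changes are a strictly monotone transform of -ddCt, so ranks are
shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sncsec._nonparam import mann_whitney
from sncsec.datasets import REFERENCE_RNA


@dataclass
class QpcrTable:
    """Long-format Ct table: one row per (sample, sncRNA) measurement.

    Required columns: sample, group, sncRNA, ct.  Technical replicates
    (duplicate rows) are collapsed by mean Ct.  ``reference_sample``
    names the no-embryo medium; several wells of it are allowed and are
    averaged on the dCt scale.
    """

    data: pd.DataFrame
    reference_rna: str = REFERENCE_RNA
    reference_sample: str = "REFMEDIUM"

    def __post_init__(self):
        required = {"sample", "group", "sncRNA", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        self.data = (
            self.data.groupby(["sample", "group", "sncRNA"], as_index=False)["ct"]
            .mean()
        )
        samples = set(self.data["sample"])
        if self.reference_sample not in samples:
            raise ValueError(f"reference sample {self.reference_sample!r} absent")
        has_ref = set(self.data.loc[self.data["sncRNA"] == self.reference_rna, "sample"])
        if samples - has_ref:
            raise ValueError(
                f"samples lacking reference RNA Ct: {sorted(samples - has_ref)}"
            )


def fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_refmedium: float,
    ct_ref_refmedium: float,
) -> float:
    """2^-ddCt for a single sample against the reference medium."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_refmedium, ct_ref_refmedium):
        if v is None or not np.isfinite(v):
            raise ValueError("all four Ct values are required")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_refmedium - ct_ref_refmedium
    )
    return float(2.0 ** -ddct)


def sample_fold_changes(table: QpcrTable) -> pd.DataFrame:
    """Per-sample fold change for every assayed sncRNA.

    Returns long format: sample, group, sncRNA, fold_change.  The
    reference medium itself and the reference RNA are excluded from the
    output (their fold change is 1 by construction).
    """
    df = table.data
    ref_ct = df[df["sncRNA"] == table.reference_rna].set_index("sample")["ct"]
    refmed = df[df["sample"] == table.reference_sample].set_index("sncRNA")["ct"]
    ref_dct = refmed - ref_ct[table.reference_sample]

    rows = []
    for (sample, group), sub in df.groupby(["sample", "group"]):
        if sample == table.reference_sample:
            continue
        for _, r in sub.iterrows():
            rna = r["sncRNA"]
            if rna == table.reference_rna or rna not in ref_dct.index:
                continue
            ddct = (r["ct"] - ref_ct[sample]) - ref_dct[rna]
            rows.append((sample, group, rna, float(2.0 ** -ddct)))
    return pd.DataFrame(rows, columns=["sample", "group", "sncRNA", "fold_change"])


@dataclass
class FoldChangeSummary:
    sncRNA: str
    group: str
    me: float
    q1: float
    q3: float

    @property
    def log2_me(self) -> float:
        return float(np.log2(self.me))

    @property
    def log2_q1(self) -> float:
        return float(np.log2(self.q1))

    @property
    def log2_q3(self) -> float:
        return float(np.log2(self.q3))


def summarize_groups(fc: pd.DataFrame) -> list[FoldChangeSummary]:
    """Median and quartiles of fold changes per (sncRNA, group).

    Quartiles use linear interpolation between order statistics
    (numpy's default), so a single sample gives Me = Q1 = Q3.
    """
    out = []
    for (rna, group), sub in fc.groupby(["sncRNA", "group"], sort=True):
        v = sub["fold_change"].to_numpy(dtype=float)
        if len(v) == 0:
            raise ValueError(f"empty group {group} for {rna}")
        q1, me, q3 = np.percentile(v, [25, 50, 75])
        out.append(FoldChangeSummary(rna, group, float(me), float(q1), float(q3)))
    return out


def summary_to_frame(summaries: list[FoldChangeSummary]) -> pd.DataFrame:
    """Report table: 4-dp linear fold changes, 2-dp log2 columns."""
    return pd.DataFrame(
        {
            "sncRNA": [s.sncRNA for s in summaries],
            "group": [s.group for s in summaries],
            "Me": [round(s.me, 4) for s in summaries],
            "log2_Me": [round(s.log2_me, 2) for s in summaries],
            "log2_Q1": [round(s.log2_q1, 2) for s in summaries],
            "log2_Q3": [round(s.log2_q3, 2) for s in summaries],
        }
    )


def compare_fold_changes(
    fc: pd.DataFrame, rna: str, a: set[str] | list[str], b: set[str] | list[str]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney on per-sample fold changes of one sncRNA.

    ``a`` and ``b`` are group-label sets; returns (U, p).
    """
    sub = fc[fc["sncRNA"] == rna]
    xa = sub[sub["group"].isin(set(a))]["fold_change"].to_numpy(dtype=float)
    xb = sub[sub["group"].isin(set(b))]["fold_change"].to_numpy(dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each side of the contrast needs >=2 samples")
    return mann_whitney(xa, xb)


def read_ct_tsv(path, reference_rna: str = REFERENCE_RNA, reference_sample: str = "REFMEDIUM") -> QpcrTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "sncRNA": str})
    return QpcrTable(df, reference_rna=reference_rna, reference_sample=reference_sample)
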