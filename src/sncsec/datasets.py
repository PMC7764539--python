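"""Bundled reference datasets.

Small plain-text tables from a published qPCR/small-RNA-seq study of
spent culture medium collected from individual human morulae on day 4
after fertilization.  Samples fall into groups by the embryo's day-5
outcome: I (good/excellent blastocyst, live birth), II (poor/fair
blastocyst), III (degenerated), IV (arrested), plus an embryo-free
Reference medium incubated alongside.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

#: piRNAs secreted by group-I morulae above the embryo-free background
#: (2.8-28 fold), per the qPCR fold-change summary.
SECRETED_PIRNAS = (
    "hsa_piR_011291",
    "hsa_piR_001311",
    "hsa_piR_015462",
    "hsa_piR_016735",
    "hsa_piR_019675",
    "hsa_piR_020381",
    "hsa_piR_004880",
)

#: Published database target-gene counts for the two miRNAs (annotation
#: only; the lists themselves are consumed as user-supplied inputs).
MIRNA_TARGET_GENE_COUNTS = {"hsa-let-7i-5p": 119, "hsa-let-7b-5p": 158}

#: Endogenous reference RNA used for ddCt normalization.
REFERENCE_RNA = "hsa_piR_023338"


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = importlib.resources.files("sncsec.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def load_scm_counts() -> tuple[pd.DataFrame, pd.Series]:
    """Sequencing read counts for 26 sncRNAs in 14 spent-medium samples.

    Returns
    -------
    counts : DataFrame
        Integer matrix, sncRNA ids as index, sample ids as columns.
    groups : Series
        Sample id -> group label (I, II, III, IV, Reference).
    """
    counts = _read("scm_counts.tsv", index_col=0, dtype={0: str})
    counts.columns = counts.columns.astype(str)
    groups = _read("scm_groups.tsv", dtype=str).set_index("sample")["group"]
    return counts, groups


def load_scm_count_pvalues() -> pd.DataFrame:
    """Published per-sncRNA group-comparison p-values for the count table.

    These come from a negative-binomial Wald analysis of the full
    (unpublished) feature matrix and are carried as annotations only;
    they are not recomputable from the 26 bundled rows.
    """
    return _read("scm_counts_pvalues.tsv", index_col=0)


def load_qpcr_summary() -> pd.DataFrame:
    """Published qPCR fold-change summary per (sncRNA, group).

    Fold changes are ddCt ratios relative to the embryo-free reference
    medium, normalized to the reference RNA hsa_piR_023338.  Columns:
    Me (median fold change), log2_Me, log2_Q1, log2_Q3, and printed
    Mann-Whitney p-values per contrast (strings; "<0.001" preserved).
    """
    return _read(
        "qpcr_foldchange_summary.tsv",
        dtype={
            "p_I_vs_III_IV": str,
            "p_I_vs_II": str,
            "p_II_vs_III_IV": str,
        },
    )


def load_mzt_gene_lists() -> pd.DataFrame:
    """Stage-wise downregulated genes that are predicted sncRNA targets.

    Long-format table: target_set (hsa-let-7b-5p, hsa-let-7i-5p, or the
    pooled nine-piRNA set), contrast (down_D3_vs_D2, down_D3_vs_D5,
    down_D5_vs_D3 -- days after fertilization), symbol.
    """
    return _read("mzt_downregulated_targets.tsv")


def load_sncrna_sequences() -> pd.DataFrame:
    """Published sense-primer sequences for the assayed piRNAs.

    DNA alphabet as printed; callers that need RNA should normalize
    T->U (see :func:`sncsec.targets.normalize_rna`).
    """
    return _read("sncrna_sequences.tsv", index_col=0)
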