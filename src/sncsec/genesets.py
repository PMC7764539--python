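"""Intersection of predicted target-gene sets with stage gene lists.

Gene symbols are matched exactly after uppercasing; no alias
resolution is attempted, and symbols present on only one side are
simply not in the overlap (a sidecar of unmatched symbols can be
derived from the reports).  An optional hypergeometric tail probability
quantifies overrepresentation given a user-supplied universe size.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GeneListSet:
    name: str
    symbols: frozenset[str]

    def __init__(self, name: str, symbols):
        object.__setattr__(self, "name", name)
        up = frozenset(str(s).upper() for s in symbols)
        if not up:
            raise ValueError(f"gene list {name!r} is empty")
        object.__setattr__(self, "symbols", up)


@dataclass
class IntersectionReport:
    rna_id: str
    list_name: str
    overlap: set[str]
    p: float | None = None

    @property
    def size(self) -> int:
        return len(self.overlap)


def intersect(
    targets: dict[str, set[str]], lists: list[GeneListSet]
) -> list[IntersectionReport]:
    """Exact set intersections of per-RNA target symbols with each list.

    Case-insensitive on symbols; output sorted by (RNA id, list name).
    """
    if not targets or not lists:
        raise ValueError("need non-empty targets and lists")
    out = []
    for rna_id in sorted(targets):
        up = {str(s).upper() for s in targets[rna_id]}
        for gl in sorted(lists, key=lambda g: g.name):
            out.append(IntersectionReport(rna_id, gl.name, up & gl.symbols))
    return out


def hypergeom_enrich(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts the common elements of a random ``set_a``-subset and a
    fixed ``set_b``-subset of a ``universe``-element background.
    """
    if not 0 <= overlap <= min(set_a, set_b) <= universe:
        raise ValueError("need 0 <= overlap <= min(set_a, set_b) <= universe")
    if max(set_a, set_b) > universe:
        raise ValueError("set sizes exceed the universe")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_b, set_a))


def reports_to_frame(reports: list[IntersectionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rna_id": [r.rna_id for r in reports],
            "list_name": [r.list_name for r in reports],
            "overlap_size": [r.size for r in reports],
            "overlap": [",".join(sorted(r.overlap)) for r in reports],
            "p": [r.p for r in reports],
        }
    )


def read_gene_lists_tsv(path) -> list[GeneListSet]:
    """Long-format TSV (columns: name/list, symbol) -> named gene sets."""
    df = pd.read_csv(path, sep="\t")
    name_col = "name" if "name" in df.columns else df.columns[0]
    sym_col = "symbol" if "symbol" in df.columns else df.columns[-1]
    return [
        GeneListSet(str(name), sub[sym_col].tolist())
        for name, sub in df.groupby(name_col, sort=True)
    ]
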