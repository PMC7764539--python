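"""Assignment of aligned small-RNA reads to annotated sncRNA features.

Reads are intervals from a genome alignment; features are annotated
miRNA/piRNA loci.  A read is counted toward a feature only if at least
a fixed fraction of the read's length (default 90%) overlaps the
feature, after discarding reads outside the retained length range
(default 16-50 nt).  Coordinates are BED-style 0-based half-open
throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

AmbiguousPolicy = Literal["drop", "count-all"]


@dataclass(frozen=True)
class ReadInterval:
    read_id: str
    reference: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.read_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureInterval:
    feature_id: str
    reference: str
    start: int
    end: int
    feature_class: str = "piRNA"
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.feature_id}"
            )


def filter_by_length(
    reads: Iterable[ReadInterval], min_len: int = 16, max_len: int = 50
) -> list[ReadInterval]:
    """Drop reads shorter than ``min_len`` or longer than ``max_len``.

    Bounds are inclusive: a 16-nt read and a 50-nt read are both kept.
    Input order is preserved.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= r.length <= max_len]


def count_reads(
    reads: Iterable[ReadInterval],
    features: Iterable[FeatureInterval],
    frac_overlap: float = 0.9,
    ambiguous: AmbiguousPolicy = "drop",
    stranded: bool = False,
) -> dict[str, int]:
    """Count reads per feature under the fractional-overlap rule.

    A read qualifies for a feature iff overlap_length / read_length >=
    ``frac_overlap`` (and strands match, when ``stranded``).  Under the
    default ``"drop"`` policy a read qualifying for two or more features
    is counted for none; ``"count-all"`` credits each.  Every feature id
    appears in the result, zero counts included.
    """
    if not 0 < frac_overlap <= 1:
        raise ValueError(f"frac_overlap must be in (0, 1], got {frac_overlap}")
    if ambiguous not in ("drop", "count-all"):
        raise ValueError(f"unknown ambiguous policy {ambiguous!r}")
    features = list(features)
    ids = [f.feature_id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("feature ids must be unique")
    by_ref: dict[str, list[FeatureInterval]] = defaultdict(list)
    for f in features:
        by_ref[f.reference].append(f)
    counts = dict.fromkeys(ids, 0)
    for read in reads:
        hits = []
        for f in by_ref.get(read.reference, ()):
            if stranded and "." not in (read.strand, f.strand):
                if read.strand != f.strand:
                    continue
            overlap = min(read.end, f.end) - max(read.start, f.start)
            if overlap > 0 and overlap / read.length >= frac_overlap:
                hits.append(f.feature_id)
        if len(hits) == 1 or (hits and ambiguous == "count-all"):
            for fid in hits:
                counts[fid] += 1
    return counts


def read_bed(path, as_features: bool = False) -> list:
    """Read a BED6 (or BED4+) file into read or feature intervals.

    Columns: chrom, start, end, name, score, strand; score is ignored,
    missing strand defaults to ".".  With ``as_features`` the name field
    becomes the feature id.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    out = []
    for row in df.itertuples(index=False):
        strand = str(row[5]) if len(row) > 5 else "."
        if as_features:
            out.append(
                FeatureInterval(str(row[3]), str(row[0]), int(row[1]), int(row[2]), strand=strand)
            )
        else:
            out.append(
                ReadInterval(str(row[3]), str(row[0]), int(row[1]), int(row[2]), strand=strand)
            )
    return out


def counts_to_frame(counts: dict[str, int], sample_id: str) -> pd.DataFrame:
    """One-column count matrix (features x one sample)."""
    return pd.DataFrame({sample_id: pd.Series(counts, dtype=int)}).rename_axis("sncRNA")
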