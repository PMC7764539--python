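"""miRanda-style small-RNA target prediction on transcript sequences.

A small RNA (piRNA or miRNA, 5'->3') is aligned against the reverse of
a transcript window, so that alignment columns read as an antiparallel
duplex.  The aligner is a Smith-Waterman local alignment with affine
gaps and complementarity scoring (Watson-Crick +5, G:U wobble +1,
mismatch -3, gap open -9, gap extend -4), with pair scores multiplied
by 4 at small-RNA positions 2-8 -- the weighting that emphasizes the
seed, as in the miRanda family of tools.  Candidate sites must clear an
alignment-score threshold (sc >= 170), a nearest-neighbor duplex
free-energy threshold (en <= -20 kcal/mol), perfect Watson-Crick
pairing at small-RNA positions 2-11 (primary seed), and at most four
non-Watson-Crick positions at 12-21 (secondary seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sncsec.nn_tables import INITIATION_DG, LOOP_PENALTY_DG, stack_dg

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


RNA_ALPHABET = "ACGU"
_CODE = {b: i for i, b in enumerate(RNA_ALPHABET)}
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}

#: Pairing-state glyphs for the compact per-position string.
PAIRING_GLYPHS = {"WC": "|", "GU": ":", "mismatch": ".", "gap": "-", "unaligned": "~"}


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; reject other letters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"invalid RNA letters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    return "".join(comp[b] for b in reversed(seq))


@dataclass(frozen=True)
class SmallRNA:
    id: str
    sequence: str
    accession: str = ""
    rna_class: str = "piRNA"

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 16:
            raise ValueError(f"{self.id}: small RNA shorter than 16 nt")


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    gene_symbol: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 30:
            raise ValueError(f"{self.id}: transcript shorter than 30 nt")


@dataclass(frozen=True)
class ScoringScheme:
    match_wc: float = 5.0
    match_gu: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    scale: float = 4.0
    scale_start: int = 2  # 1-based small-RNA position range scaled
    scale_end: int = 8
    sc_min: float = 170.0
    en_max: float = -20.0
    seed_allow_gu: bool = False
    max_secondary_mismatches: int = 4

    def __post_init__(self):
        if self.sc_min <= 0 and np.isfinite(self.sc_min):
            raise ValueError("sc_min must be positive")
        if self.en_max >= 0:
            raise ValueError("en_max must be negative")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")


@dataclass
class DuplexHit:
    rna_id: str
    transcript_id: str
    start: int  # 0-based half-open site on the transcript sense strand
    end: int
    sc: float
    en: float
    pairing: list[str]  # per small-RNA position, 5'->3'
    primary_seed_ok: bool
    secondary_mismatches: int
    passes: bool

    @property
    def pairing_string(self) -> str:
        return "".join(PAIRING_GLYPHS[s] for s in self.pairing)


NEG = -1e18


@njit(cache=True)
def _gotoh(x, y, pair, scale, s_lo, s_hi, gap_open, gap_extend):
    """Gotoh local-alignment matrices for x against y.

    ``pair`` is the 4x4 base-pair score matrix; pair scores at x
    positions in [s_lo, s_hi] (0-based, inclusive) are multiplied by
    ``scale``.  A gap of length L costs -(open + (L-1) * extend) with
    open/extend passed as negative numbers.  Returns (M, X, Y): M[i, j]
    is the best score of a local alignment ending with x[i-1] paired to
    y[j-1]; X ends with a gap in y (x consumed), Y with a gap in x.
    """
    m, n = len(x), len(y)
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    for i in range(1, m + 1):
        w = scale if s_lo <= i - 1 <= s_hi else 1.0
        for j in range(1, n + 1):
            s = pair[x[i - 1], y[j - 1]] * w
            best_prev = 0.0
            if M[i - 1, j - 1] > best_prev:
                best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + s
            a = M[i - 1, j] + gap_open
            b = X[i - 1, j] + gap_extend
            X[i, j] = a if a > b else b
            a = M[i, j - 1] + gap_open
            b = Y[i, j - 1] + gap_extend
            Y[i, j] = a if a > b else b
    return M, X, Y


def _pair_matrix(s: ScoringScheme) -> np.ndarray:
    pair = np.full((4, 4), s.mismatch)
    for a, b in _WC:
        pair[_CODE[a], _CODE[b]] = s.match_wc
    for a, b in _GU:
        pair[_CODE[a], _CODE[b]] = s.match_gu
    return pair


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.int64)


def align_duplex(
    rna: str | SmallRNA, window: str, scheme: ScoringScheme = ScoringScheme()
) -> tuple[float, list[tuple[int | None, int | None]], tuple[int, int]]:
    """Best local duplex alignment of a small RNA against one window.

    The window is a transcript subsequence on the sense strand; it is
    reversed internally so that columns pair the RNA 5'->3' with the
    site 3'->5' (antiparallel).  Returns ``(sc, columns, (j_lo, j_hi))``
    where ``columns`` is a list of (rna_index, reversed_window_index)
    with None marking a gap, and ``(j_lo, j_hi)`` is the 0-based
    half-open aligned span on the *reversed* window.  An all-mismatch
    or empty alignment yields sc = 0 and no columns.
    """
    r = rna.sequence if isinstance(rna, SmallRNA) else normalize_rna(rna)
    w = normalize_rna(window)
    if len(w) < len(r) / 2:
        raise ValueError("window shorter than half the small RNA")
    y = w[::-1]
    M, X, Y = _gotoh(
        _encode(r),
        _encode(y),
        _pair_matrix(scheme),
        scheme.scale,
        scheme.scale_start - 1,
        scheme.scale_end - 1,
        scheme.gap_open,
        scheme.gap_extend,
    )
    sc = float(M.max())
    if sc <= 0:
        return 0.0, [], (0, 0)
    i, j = np.unravel_index(int(M.argmax()), M.shape)
    cols: list[tuple[int | None, int | None]] = []
    pair = _pair_matrix(scheme)
    state = "M"
    eps = 1e-6
    while i > 0 and j > 0:
        if state == "M":
            cols.append((i - 1, j - 1))
            w_i = scheme.scale if scheme.scale_start - 1 <= i - 1 <= scheme.scale_end - 1 else 1.0
            prev = M[i, j] - pair[_CODE[r[i - 1]], _CODE[y[j - 1]]] * w_i
            i, j = i - 1, j - 1
            if abs(prev) < eps:
                break
            if abs(M[i, j] - prev) < eps:
                state = "M"
            elif abs(X[i, j] - prev) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            cols.append((i - 1, None))
            if abs(M[i - 1, j] + scheme.gap_open - X[i, j]) < eps:
                state = "M"
            i -= 1
        else:
            cols.append((None, j - 1))
            if abs(M[i, j - 1] + scheme.gap_open - Y[i, j]) < eps:
                state = "M"
            j -= 1
    cols.reverse()
    j_vals = [c[1] for c in cols if c[1] is not None]
    return sc, cols, (min(j_vals), max(j_vals) + 1)


def pairing_states(
    cols: list[tuple[int | None, int | None]], rna_seq: str, y_seq: str
) -> list[str]:
    """Per-RNA-position pairing state (5'->3') from alignment columns."""
    states = ["unaligned"] * len(rna_seq)
    for i, j in cols:
        if i is None:
            continue
        if j is None:
            states[i] = "gap"
        else:
            duo = (rna_seq[i], y_seq[j])
            states[i] = "WC" if duo in _WC else "GU" if duo in _GU else "mismatch"
    return states


def duplex_energy(
    cols: list[tuple[int | None, int | None]], rna_seq: str, y_seq: str
) -> float:
    """Nearest-neighbor free energy of the aligned duplex, kcal/mol.

    Initiation plus stack terms over consecutive paired columns; each
    internal run of unpaired columns (mismatch or gap) between paired
    stretches breaks the helix and adds a fixed loop penalty.  Zero
    paired positions means no duplex: energy 0 by convention.
    """
    paired_flags = []
    pairs = []
    for i, j in cols:
        if i is not None and j is not None:
            duo = (rna_seq[i], y_seq[j])
            ok = duo in _WC or duo in _GU
            paired_flags.append(ok)
            pairs.append(rna_seq[i] + y_seq[j] if ok else None)
        else:
            paired_flags.append(False)
            pairs.append(None)
    if not any(paired_flags):
        return 0.0
    en = INITIATION_DG
    first = paired_flags.index(True)
    last = len(paired_flags) - 1 - paired_flags[::-1].index(True)
    in_break = False
    prev_pair = None
    for k in range(first, last + 1):
        if paired_flags[k]:
            if prev_pair is not None and not in_break:
                en += stack_dg(prev_pair, pairs[k])
            if in_break:
                en += LOOP_PENALTY_DG
                in_break = False
            prev_pair = pairs[k]
        else:
            in_break = True
    return float(en)


def transcript_bulges(cols: list[tuple[int | None, int | None]]) -> frozenset[int]:
    """Small-RNA positions (1-based) followed by a transcript-side bulge.

    A run of gap-in-RNA columns between the columns of small-RNA
    positions p and p+1 means unpaired transcript bases interrupt the
    helix there; the run is recorded under p.
    """
    out = set()
    last_i = None
    pending = False
    for i, j in cols:
        if i is None:
            pending = True
        else:
            if pending and last_i is not None:
                out.add(last_i + 1)  # 1-based position before the bulge
            pending = False
            last_i = i
    return frozenset(out)


def classify_seed(
    pairing: list[str],
    scheme: ScoringScheme = ScoringScheme(),
    bulges: frozenset[int] = frozenset(),
) -> tuple[bool, int]:
    """Seed-region verdict from per-position pairing states.

    Positions are 1-based from the small-RNA 5' end.  The primary seed
    (2-11) must be contiguous Watson-Crick pairing: every position WC
    (G:U counts as a mismatch unless ``scheme.seed_allow_gu``) and no
    transcript-side bulge between seed positions.  Secondary mismatches
    are counted at positions 12-min(21, length): every state other than
    WC (and GU when allowed) -- mismatch, gap, unaligned overhang --
    plus one per transcript bulge interrupting that region.
    """
    if len(pairing) < 11:
        raise ValueError("small RNA shorter than 11 nt has no seed region")
    accepted = {"WC", "GU"} if scheme.seed_allow_gu else {"WC"}
    primary_ok = all(s in accepted for s in pairing[1:11]) and not any(
        2 <= p <= 10 for p in bulges
    )
    hi = min(21, len(pairing))
    secondary = pairing[11:hi]
    mismatches = sum(s not in accepted for s in secondary)
    mismatches += sum(12 <= p <= hi - 1 for p in bulges)
    return primary_ok, mismatches


def _window_starts(length: int, width: int, step: int) -> list[int]:
    if length <= width:
        return [0]
    starts = list(range(0, length - width + 1, step))
    if starts[-1] != length - width:
        starts.append(length - width)
    return starts


def scan(
    rnas: list[SmallRNA],
    transcripts: list[Transcript],
    scheme: ScoringScheme = ScoringScheme(),
    step: int = 5,
    window_margin: int = 10,
) -> list[DuplexHit]:
    """Scan transcripts for candidate binding sites of each small RNA.

    A window of length (RNA length + ``window_margin``) slides with the
    given step over each transcript sense strand; each window is
    aligned, overlapping candidates are deduplicated keeping the
    highest sc (ties: smaller start), and the four filters (sc, en,
    primary seed, secondary mismatches) set each hit's ``passes`` flag.
    Output is sorted by (rna id, transcript id, site start).
    """
    if not rnas or not transcripts:
        raise ValueError("need at least one small RNA and one transcript")
    hits: list[DuplexHit] = []
    for rna in sorted(rnas, key=lambda r: r.id):
        width = len(rna.sequence) + window_margin
        for tr in sorted(transcripts, key=lambda t: t.id):
            cand: list[DuplexHit] = []
            for ws in _window_starts(len(tr.sequence), width, step):
                window = tr.sequence[ws : ws + width]
                sc, cols, (j_lo, j_hi) = align_duplex(rna, window, scheme)
                if sc <= 0:
                    continue
                y = window[::-1]
                states = pairing_states(cols, rna.sequence, y)
                en = duplex_energy(cols, rna.sequence, y)
                primary_ok, sec_mm = classify_seed(states, scheme, transcript_bulges(cols))
                start = ws + len(window) - j_hi
                end = ws + len(window) - j_lo
                passes = (
                    sc >= scheme.sc_min
                    and en <= scheme.en_max
                    and primary_ok
                    and sec_mm <= scheme.max_secondary_mismatches
                )
                cand.append(
                    DuplexHit(
                        rna.id, tr.id, start, end, sc, en, states,
                        primary_ok, sec_mm, passes,
                    )
                )
            hits.extend(_dedup_overlapping(cand))
    hits.sort(key=lambda h: (h.rna_id, h.transcript_id, h.start))
    return hits


def _dedup_overlapping(cand: list[DuplexHit]) -> list[DuplexHit]:
    """Keep the max-sc hit among mutually overlapping candidates."""
    kept: list[DuplexHit] = []
    for h in sorted(cand, key=lambda h: (-h.sc, h.start, h.end)):
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    return kept


def passing_hits(hits: list[DuplexHit]) -> list[DuplexHit]:
    return [h for h in hits if h.passes]


def hits_to_genes(
    hits: list[DuplexHit],
    mapping: dict[str, str],
    passing_only: bool = True,
) -> tuple[dict[str, set[str]], set[str]]:
    """Collapse hits to per-small-RNA gene-symbol sets.

    ``mapping`` maps transcript ids to gene symbols (uppercased on
    output).  Returns (rna id -> symbol set, unmapped transcript ids);
    unmapped transcripts are reported, not fatal.
    """
    genes: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for h in hits:
        if passing_only and not h.passes:
            continue
        symbol = mapping.get(h.transcript_id)
        if symbol is None:
            unmapped.add(h.transcript_id)
            continue
        genes.setdefault(h.rna_id, set()).add(symbol.upper())
    return genes, unmapped


def hits_to_frame(hits: list[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rna_id": [h.rna_id for h in hits],
            "transcript_id": [h.transcript_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "sc": [h.sc for h in hits],
            "en": [h.en for h in hits],
            "primary_seed_ok": [h.primary_seed_ok for h in hits],
            "secondary_mismatches": [h.secondary_mismatches for h in hits],
            "passes": [h.passes for h in hits],
            "pairing": [h.pairing_string for h in hits],
        }
    )


def read_fasta(path, kind: str = "smallrna") -> list:
    """Read a FASTA file of small RNAs or transcripts (T normalized to U)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if kind == "smallrna":
            out.append(SmallRNA(rec.id, str(rec.seq)))
        else:
            out.append(Transcript(rec.id, str(rec.seq)))
    return out
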