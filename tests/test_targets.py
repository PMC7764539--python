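"""Duplex aligner, energy model, seed filter, and transcript scan."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sncsec.nn_tables import INITIATION_DG, stack_dg
from sncsec.targets import (
    ScoringScheme,
    SmallRNA,
    Transcript,
    align_duplex,
    classify_seed,
    duplex_energy,
    hits_to_genes,
    pairing_states,
    passing_hits,
    reverse_complement,
    scan,
)

SCHEME = ScoringScheme()


def _pair_score(a, b, scheme=SCHEME):
    if (a, b) in {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}:
        return scheme.match_wc
    if (a, b) in {("G", "U"), ("U", "G")}:
        return scheme.match_gu
    return scheme.mismatch


def enumerate_alignments_score(r, y, scheme=SCHEME):
    """Exhaustive DFS over every gapped local alignment of r vs y.

    Walks all monotone paths of pair / gap-in-y / gap-in-x operations
    from every start cell, allowing the alignment to end anywhere, and
    returns the maximum score (floored at 0).  Exponential; tiny
    sequences only.
    """
    best = 0.0

    def step(i, j, score, last):
        nonlocal best
        if last == "p":
            best = max(best, score)
        if i < len(r) and j < len(y):
            w = scheme.scale if scheme.scale_start - 1 <= i <= scheme.scale_end - 1 else 1.0
            step(i + 1, j + 1, score + _pair_score(r[i], y[j], scheme) * w, "p")
        if last == "p" or last == "x":
            if i < len(r):
                pen = scheme.gap_extend if last == "x" else scheme.gap_open
                step(i + 1, j, score + pen, "x")
        if last == "p" or last == "y":
            if j < len(y):
                pen = scheme.gap_extend if last == "y" else scheme.gap_open
                step(i, j + 1, score + pen, "y")

    for i0 in range(len(r)):
        for j0 in range(len(y)):
            step(i0, j0, 0.0, "start")
            # force a first pair at (i0, j0) as well
            w = scheme.scale if scheme.scale_start - 1 <= i0 <= scheme.scale_end - 1 else 1.0
            step(i0 + 1, j0 + 1, _pair_score(r[i0], y[j0], scheme) * w, "p")
    return best


def cubic_dp_score(r, y, scheme=SCHEME):
    """Independent O(n^3) local-alignment DP trying every gap length.

    H[i][j] is the best score of an alignment ending with r[i-1] paired
    to y[j-1]; gaps of length L cost open + (L-1)*extend in one shot.
    """
    m, n = len(r), len(y)
    H = np.zeros((m + 1, n + 1))
    for i in range(1, m + 1):
        w = scheme.scale if scheme.scale_start - 1 <= i - 1 <= scheme.scale_end - 1 else 1.0
        for j in range(1, n + 1):
            s = _pair_score(r[i - 1], y[j - 1], scheme) * w
            cand = [0.0, H[i - 1, j - 1]]
            for L in range(1, i - 1 + 1):
                cand.append(H[i - 1 - L, j - 1] + scheme.gap_open + (L - 1) * scheme.gap_extend)
            for L in range(1, j - 1 + 1):
                cand.append(H[i - 1, j - 1 - L] + scheme.gap_open + (L - 1) * scheme.gap_extend)
            H[i, j] = max(cand) + s
    return float(max(H.max(), 0.0))


def test_hand_scored_perfect_pentamer():
    """5'-UGCGA-3' against a site reading A-C-G-C-U antiparallel:
    position 1 unscaled (+5), positions 2-5 scaled (4 * 4 * 5)."""
    window = "ACGCU"[::-1]
    sc, cols, span = align_duplex("UGCGA", window)
    assert sc == 85.0
    assert [c for c in cols] == [(i, i) for i in range(5)]


def test_all_mismatch_floors_at_zero():
    sc, cols, _ = align_duplex("GGGG", "GGGG")
    assert sc == 0.0 and cols == []


@pytest.mark.parametrize("seed", range(8))
def test_dp_equals_exhaustive_enumeration_small(seed):
    rng = np.random.default_rng(seed)
    r = "".join(rng.choice(list("ACGU"), size=rng.integers(3, 7)))
    y = "".join(rng.choice(list("ACGU"), size=rng.integers(3, 7)))
    sc, _, _ = align_duplex(r, y[::-1])  # align_duplex reverses internally
    assert sc == pytest.approx(enumerate_alignments_score(r, y))


@pytest.mark.parametrize("seed", range(12))
def test_dp_equals_independent_cubic_dp(seed):
    rng = np.random.default_rng(100 + seed)
    r = "".join(rng.choice(list("ACGU"), size=12))
    y = "".join(rng.choice(list("ACGU"), size=12))
    sc, _, _ = align_duplex(r, y[::-1])
    assert sc == pytest.approx(cubic_dp_score(r, y))


def test_invalid_alphabet_rejected():
    with pytest.raises(ValueError):
        align_duplex("ACGX", "ACGU")


def test_energy_hand_example_gc_helix():
    """5'-GGG-3'/3'-CCC-5': initiation + two GG/CC stacks."""
    sc, cols, _ = align_duplex("GGG", "CCC")
    en = duplex_energy(cols, "GGG", "CCC"[::-1])
    assert en == pytest.approx(4.09 + 2 * (-3.26))


def test_energy_empty_duplex_is_zero():
    assert duplex_energy([], "GGG", "CCC") == 0.0


def test_energy_interruption_penalty():
    """A central mismatch splits the helix: stacks only within the two
    arms plus one fixed loop penalty."""
    r = "GGGAGGG"
    site_rev = "CCCACCC"  # A-A mismatch in the middle
    cols = [(i, i) for i in range(7)]
    en = duplex_energy(cols, r, site_rev)
    expected = INITIATION_DG + 4 * stack_dg("GC", "GC") + 3.0
    assert en == pytest.approx(expected)


def test_long_gc_duplex_clears_energy_threshold(rng):
    pir = "".join(rng.choice(list("GCAU"), p=[0.4, 0.4, 0.1, 0.1], size=30))
    site = reverse_complement(pir)
    sc, cols, _ = align_duplex(pir, site)
    assert duplex_energy(cols, pir, site[::-1]) <= -20.0
    assert sc >= 170.0


def test_stack_table_reverse_reading_consistency():
    pairs = ["AU", "UA", "CG", "GC", "GU", "UG"]
    for p1, p2 in itertools.product(pairs, pairs):
        assert stack_dg(p1, p2) == pytest.approx(stack_dg(p2[::-1], p1[::-1]))


class TestSeedClassification:
    def test_perfect_duplex(self):
        assert classify_seed(["WC"] * 21) == (True, 0)

    def test_five_secondary_mismatches_fail_rule(self):
        states = ["WC"] * 21
        for pos in (13, 15, 17, 19, 21):  # 1-based
            states[pos - 1] = "mismatch"
        ok, mm = classify_seed(states)
        assert (ok, mm) == (True, 5)
        assert mm > ScoringScheme().max_secondary_mismatches

    def test_gu_in_primary_seed_strict_vs_permissive(self):
        states = ["WC"] * 21
        states[4] = "GU"  # position 5
        assert classify_seed(states)[0] is False
        assert classify_seed(states, ScoringScheme(seed_allow_gu=True))[0] is True

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            classify_seed(["WC"] * 10)

    def test_unaligned_overhang_counts_in_secondary(self):
        states = ["WC"] * 15 + ["unaligned"] * 6
        assert classify_seed(states) == (True, 6)

    def test_transcript_bulge_inside_primary_seed_breaks_it(self):
        from sncsec.targets import transcript_bulges

        # bulge between small-RNA positions 5 and 6 (transcript base
        # skipped), all positions themselves WC
        cols = [(i, i) for i in range(5)] + [(None, 5)] + [
            (i, i + 1) for i in range(5, 21)
        ]
        bulges = transcript_bulges(cols)
        assert bulges == frozenset({5})
        assert classify_seed(["WC"] * 21, bulges=bulges)[0] is False
        # a bulge in the secondary region counts as one mismatch instead
        cols2 = [(i, i) for i in range(15)] + [(None, 15)] + [
            (i, i + 1) for i in range(15, 21)
        ]
        ok, mm = classify_seed(["WC"] * 21, bulges=transcript_bulges(cols2))
        assert (ok, mm) == (True, 1)


def test_reverse_complement_site_gives_clean_seed(rng):
    pir = "".join(rng.choice(list("ACGU"), size=28))
    site = reverse_complement(pir)
    sc, cols, _ = align_duplex(pir, site)
    states = pairing_states(cols, pir, site[::-1])
    assert classify_seed(states) == (True, 0)


@pytest.fixture(scope="module")
def planted():
    from sncsec.synthetic import SimConfig, simulate_transcriptome

    cfg = SimConfig(seed=7, n_transcripts=5, transcript_length=700, n_planted_sites=4)
    return simulate_transcriptome(cfg)


class TestScan:
    def test_planted_sites_recovered_at_exact_coordinates(self, planted):
        pirnas, txs, truth = planted
        ph = passing_hits(scan(pirnas, txs))
        found = {(h.rna_id, h.transcript_id, h.start) for h in ph}
        for pid, (tid, start) in truth.items():
            assert (pid, tid, start) in found
        assert len(ph) == len(truth)

    def test_infinite_sc_min_empties_passes_but_not_raw_hits(self, planted):
        pirnas, txs, _ = planted
        base = scan(pirnas, txs)
        strict = scan(pirnas, txs, ScoringScheme(sc_min=float("inf")))
        assert len(passing_hits(strict)) == 0
        assert [(h.rna_id, h.transcript_id, h.start, h.sc) for h in strict] == [
            (h.rna_id, h.transcript_id, h.start, h.sc) for h in base
        ]

    def test_transcript_order_invariance(self, planted):
        pirnas, txs, _ = planted
        a = scan(pirnas, txs)
        b = scan(pirnas, list(reversed(txs)))
        assert [(h.rna_id, h.transcript_id, h.start) for h in a] == [
            (h.rna_id, h.transcript_id, h.start) for h in b
        ]

    def test_filter_monotonicity(self, planted):
        pirnas, txs, _ = planted
        loose = passing_hits(scan(pirnas, txs, ScoringScheme(sc_min=100, en_max=-10)))
        tight = passing_hits(scan(pirnas, txs, ScoringScheme(sc_min=200, en_max=-30)))
        loose_keys = {(h.rna_id, h.transcript_id, h.start) for h in loose}
        assert all((h.rna_id, h.transcript_id, h.start) in loose_keys for h in tight)

    def test_seed_mutation_degrades_recall_monotonically(self):
        """Mutating more primary-seed positions of the planted site can
        only lose sites, never gain them."""
        from sncsec.synthetic import SimConfig, simulate_transcriptome

        cfg = SimConfig(seed=5, n_transcripts=3, transcript_length=500, n_planted_sites=3)
        pirnas, txs, truth = simulate_transcriptome(cfg)
        flip = {"A": "C", "C": "A", "G": "U", "U": "G"}
        recalls = []
        for n_mut in (0, 3, 8):
            mutated = []
            for t in txs:
                seq = list(t.sequence)
                for pid, (tid, start) in truth.items():
                    if tid != t.id:
                        continue
                    site_len = len(next(p for p in pirnas if p.id == pid).sequence)
                    # primary seed nt 2-11 sits at the 3' end of the site
                    for k in range(n_mut):
                        pos = start + site_len - 2 - k  # positions 2, 3, ...
                        seq[pos] = flip[seq[pos]]
                mutated.append(Transcript(t.id, "".join(seq)))
            ph = passing_hits(scan(pirnas, mutated))
            hit_ids = {h.rna_id for h in ph}
            recalls.append(sum(p in hit_ids for p in truth) / len(truth))
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[2] == 0.0  # a heavily mutated seed cannot pass


def test_hits_to_genes_dedup_and_unmapped(planted_hits=None):
    from sncsec.synthetic import SimConfig, simulate_transcriptome

    cfg = SimConfig(seed=7, n_transcripts=4, transcript_length=500, n_planted_sites=3)
    pirnas, txs, truth = simulate_transcriptome(cfg)
    hits = passing_hits(scan(pirnas, txs))
    mapping = {tid: f"GENE{i % 2}" for i, tid in enumerate(sorted({t for t, _ in truth.values()}))}
    genes, unmapped = hits_to_genes(hits, mapping)
    for pid, (tid, _) in truth.items():
        if tid in mapping:
            assert mapping[tid] in genes[pid]
        else:
            assert tid in unmapped
    assert hits_to_genes([], {})[0] == {}


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGU", min_size=16, max_size=24))
def test_perfect_complement_always_passes_seed(seq):
    site = reverse_complement(seq)
    sc, cols, _ = align_duplex(seq, site)
    states = pairing_states(cols, seq, site[::-1])
    assert classify_seed(states) == (True, 0)
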