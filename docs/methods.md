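# Methods notes

This note records the models, parameter choices, and numerical
decisions behind `sncsec`, in the order the pipeline runs.

## Study design emulated by the synthetic module

The generators emulate a spent-culture-medium small-RNA study of human
morulae: four outcome groups of embryos — I (developed into a
good/excellent blastocyst, live birth), II (poor/fair blastocyst),
III (degenerated), IV (arrested) — plus one embryo-free Reference
medium incubated alongside. The default sequencing arm has 3/3/4/3
embryo samples and one reference sample; the default feature space is
459 sncRNAs, matching the magnitude of a combined miRNA+piRNA
detection set, with counts at a common baseline mean of 200 reads
(the bundled published count rows span tens to thousands; a common
baseline keeps the group-shift contract exact, at the cost of not
modeling between-feature abundance spread — see Limitations).

**Counts.** Negative binomial with mean/dispersion parameterization,
`Var = μ + φμ²`, the standard RNA-seq convention. Default `φ = 0.3`, a
typical biological dispersion for low-input small-RNA libraries.
"Secreted" features (default 24, the size of the significant piRNA set
in the emulated design) have group-I mean `baseline · 2^effect_log2fc`
(default log2FC = 2, inside the observed 1.5–4.8 log2 secretion
range); every other feature/group combination, including the Reference
medium, sits at baseline.

**qPCR.** `Ct = a − log2(abundance) + N(0, σ)` with intercept
`a = 35` cycles at unit abundance and `σ = 0.25` cycles (typical
technical replicate SD). The reference RNA sits at constant baseline
abundance in all samples, so ΔΔCt inverts the simulation exactly at
`σ = 0`: the fold change recovered for a secreted feature in group I
is exactly `2^effect_log2fc`. With one reference-medium well per
feature the reference ΔCt error is shared across samples, so recovery
guarantees are stated on the pooled median, not per feature.

**Transcriptome.** Uniform-random A/C/G/U transcripts (default 10 ×
1500 nt); each simulated piRNA (26–31 nt) gets one site — its exact
Watson–Crick reverse complement — written onto the sense strand at a
recorded position, with overlaps rejected by retry. The truth map
drives recall scoring.

**Clinical table.** One row per couple (default 27) with the variables
of a correlation-matrix analysis of an IVF/ICSI cohort: a latent
ovarian-reserve factor declines with female age and drives AMH, oocyte
and MII yields up, and gonadotropin dose, stimulation length, and HMG
(vs rFSH) use down; delivery odds rise with reserve and an HCG
trigger. Percentages are clipped to [0, 100], binaries are 0/1.

## Read assignment

BED-style 0-based half-open coordinates throughout. Length filter
16–50 nt inclusive (reads *shorter than* 16 or *longer than* 50 are
removed). A read counts toward a feature iff
`overlap / read_length ≥ 0.9`; reads qualifying for two or more
features are dropped by default (the behavior of counting tools
without multi-overlap assignment), with a `count-all` policy
available. Strand is ignored unless `--stranded` is given. Gapped
(CIGAR-aware) overlap and multimapper redistribution are out of scope.

## Normalization and group comparison

Size factors are median-of-ratios: the geometric-mean reference uses
only features with strictly positive counts in every sample, and the
median is taken on the log scale, so an even number of usable features
interpolates geometrically between the two middle ratios. This matches
the R implementation of the method to machine precision (cross-checked
against an independent Python port in the tests). Note the algebra:
scaling a single sample by c multiplies its factor by `c^(1−1/m)` and
every other factor by `c^(−1/m)`; scaling the whole matrix by c leaves
all factors unchanged (the scalar cancels in every ratio), so
normalized counts are equivariant — not invariant — under global
rescaling. All rank-based results are unaffected either way.

Group contrasts use a two-sided Mann–Whitney test on normalized
counts. With pooled n ≤ 12 the null is enumerated exactly over all
`C(n_a+n_b, n_a)` group assignments of the observed values — correct
under ties, where it is the permutation test on the observed multiset;
larger samples use the tie-corrected normal approximation with
continuity correction. No negative-binomial Wald test is provided:
at 3–7 samples per group the exact rank test matches the
nonparametric treatment used for every other comparison in the
pipeline, and published NB p-values depend on full feature matrices
that are not reconstructible from a printed excerpt. Raw p-values are
reported by default; `--bh` adds Benjamini–Hochberg adjustment.

## ΔΔCt quantification

`FC = 2^−ΔΔCt` with `ΔΔCt = (Ct_T,s − Ct_R,s) − (Ct_T,ref −
Ct_R,ref)`; amplification efficiency is assumed to be 2 exactly (no
efficiency correction). Technical replicates are collapsed by mean Ct
before ΔΔCt; multiple reference-medium wells are likewise averaged.
Group summaries report the median and quartiles of per-sample fold
changes using linear interpolation between order statistics
(numpy/R type-7, the most common default; the quartile rule of the
emulated study is not stated, so quartile agreement is asserted
loosely in tests while medians and their log2s are asserted at
printed precision). Report formatting: 4 dp linear, 2 dp log2.
Because fold changes are a strictly monotone transform of −ΔΔCt,
group comparisons on either scale share all ranks and p-values.

## Target prediction

The scanner is a documented re-implementation of the miRanda-family
approach — a complementarity-weighted local alignment plus an energy
filter — not a byte-compatible port of the C tool.

**Alignment.** Smith–Waterman with affine gaps (Gotoh three-state DP)
of the small RNA (5′→3′) against the reverse of a transcript window,
so columns read as an antiparallel duplex. Pair scores: Watson–Crick
+5, G:U wobble +1, mismatch −3; gap open −9, extend −4 (a length-L gap
costs `9 + 4(L−1)`); pair scores (of either sign) are multiplied by
4.0 at small-RNA positions 2–8, concentrating score in the seed. The
default threshold sc ≥ 170 is retained on this scale: a perfect 30-nt
complement scores 255, a perfect 22-mer 215, and random sequence
essentially never reaches 170 (the scrambled-null suite measures
this). Alignments end on a paired column; trailing gaps can never
raise a score. The DP is verified against an exhaustive enumeration
of all gapped local alignments on tiny instances and against an
independently written cubic explicit-gap-length DP at 12 nt.

**Energy.** `en = +4.09 (duplex initiation) + Σ nearest-neighbor
stacks + 3.0 per internal helix interruption`, in kcal/mol at 37 °C.
Watson–Crick stack parameters are the Xia-1998 ΔG°37 values; G:U
stacks use the Turner-set wobble values at 0.1 kcal precision. Stored
stacks are canonicalized over the two strand readings
(`(p1,p2) ≡ (rev p2, rev p1)`), which the tests verify exhaustively.
Terminal AU penalties and the self-complementarity symmetry term are
omitted — this is a stack-sum screen, not a full secondary-structure
fold, and its absolute values approximate (not reproduce) a
partition-function tool. Zero paired positions give en = 0 by
convention. The default threshold en ≤ −20 kcal/mol is retained; a
perfect ≥ 20-nt duplex passes it comfortably.

**Seed filter.** Positions are 1-based from the small-RNA 5′ end.
The primary seed (2–11) must be *contiguous* Watson–Crick pairing:
every position WC and no transcript-side bulge between seed
positions. The contiguity clause matters — a local aligner can
otherwise "rescue" a mutated seed by bulging transcript bases out
while every small-RNA position still pairs, which is not perfect seed
matching in any biological sense. G:U in the seed counts as a
mismatch by default (strict reading of "perfect matching");
`seed_allow_gu` relaxes this, since the original description leaves
wobble treatment open. Secondary mismatches at 12–21 count every
non-WC state — mismatch, small-RNA gap, unaligned overhang, G:U when
strict — plus one per transcript bulge; ≤ 4 pass. RNAs shorter than
21 nt truncate the secondary window; shorter than 11 nt are rejected.

**Scanning.** Window length = RNA length + 10, step 5 (no site longer
than the window margin can be missed; the final window is clipped to
the transcript end). Overlapping candidate sites for the same
RNA/transcript are deduplicated keeping the maximal sc, ties broken
toward the smaller start. Output is sorted by (RNA, transcript,
start), so results are invariant to input order. All four filters set
a `passes` flag rather than discarding hits, keeping filter
monotonicity inspectable.

## Gene-set intersection

Symbols are matched exactly after uppercasing; no alias resolution.
Enrichment, when requested, is the upper-tail hypergeometric
`P(X ≥ k)` and requires an explicit universe size — no default genome
size is assumed.

## Clinical statistics

Spearman ρ is the Pearson correlation of average ranks;
pairwise-complete deletion handles missing values, with the n used
reported per cell and cells with < 4 complete pairs or a constant
variable flagged as NaN rather than fatal. p-values use the
t-approximation, with exact permutation enumeration below n = 10.
The 95% CI is the Fisher transform `tanh(atanh ρ ± 1.96/√(n−3))`; on
bivariate-normal data at n = 27 its measured coverage of the
population Spearman correlation is ≈ 94%, the slight undercoverage
expected because the rank correlation's z-variance exceeds
`1/(n−3)`. Chi-square on 2×2 tables is uncorrected Pearson by default
(Yates optional); Fisher's exact test (two-sided, summing tables no
more probable than observed) is provided separately — the two can
legitimately disagree by factors of ~2 at these sample sizes, which
is why both are exposed. p-values below 0.001 render as "<0.001" in
reports.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on the bundled
published tables plus synthetic data at deliberately modest sizes
chosen to exercise every code path with stable statistics: alignment
oracles at 5–12 nt, planted-site scans over 4–6 transcripts of
500–800 nt, power estimation over 200 secreted-feature tests at 10
samples per side (NB dispersion 0.2, log2FC 3), 500–1000 replicates
for CI coverage, and 12–40 replicate simulations for error rates.

## Known limitations

- Between-feature abundance heterogeneity and library-size variation
  are not simulated; the NB baseline is common to all features.
- The duplex energy ignores loop-sequence dependence, terminal
  penalties, and competing intramolecular structure.
- The aligner's score scale is internally consistent but not
  comparable to other tools' score scales except through the planted
  and null suites.
- No multimapper handling or cross-database reconciliation in read
  assignment.
- Gene-symbol matching has no alias table; renamed symbols simply
  fail to intersect and are visible in the reports.
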