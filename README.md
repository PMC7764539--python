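# sncsec — small noncoding RNA secretome analysis for pre-implantation embryos

Human embryos cultured individually for IVF release small noncoding
RNAs (miRNAs and PIWI-interacting RNAs) into the droplet of culture
medium around them. The abundance of specific piRNAs and miRNAs in
this *spent culture medium*, sampled at the morula stage (day 4 after
fertilization), tracks whether the embryo will go on to form a
good-quality blastocyst — a non-invasive window on the
maternal-to-zygotic transition (MZT). `sncsec` implements the full
computational pipeline for this kind of study:

- **`sncsec.reads`** — assignment of aligned small-RNA reads (BED
  intervals) to annotated miRNA/piRNA features. Reads of 16–50 nt are
  retained and counted toward a feature only if ≥ 90% of the read
  overlaps it (`fracOverlap`-style counting); ambiguous reads are
  dropped by default.
- **`sncsec.counts`** — median-of-ratios normalization
  (`s_j = median_f (k_fj / (∏_j' k_fj')^{1/m})`, computed over features
  positive in every sample) and per-feature two-sided Mann–Whitney
  group contrasts, exact by full enumeration of group splits at the
  pooled sample sizes this assay produces (n ≤ 12).
- **`sncsec.qpcr`** — ΔΔCt relative quantification: fold change
  `2^−[(Ct_T,s − Ct_R,s) − (Ct_T,ref − Ct_R,ref)]` against a reference
  piRNA (`hsa_piR_023338`) and an embryo-free reference medium, with
  median/quartile group summaries in linear and log2 form.
- **`sncsec.targets`** — the core bespoke computation: a miRanda-style
  scan of transcript sequences for piRNA/miRNA binding sites. A
  weighted Smith–Waterman local alignment (WC +5, G:U +1, mismatch −3,
  gap open −9 / extend −4, scores ×4 at small-RNA positions 2–8)
  produces a score *sc*; a nearest-neighbor stack sum (Xia-1998
  Watson–Crick parameters plus a wobble table) gives the duplex free
  energy *en*; sites must satisfy sc ≥ 170, en ≤ −20 kcal/mol, perfect
  contiguous WC pairing at positions 2–11 (primary seed), and ≤ 4
  non-WC positions at 12–21 (secondary seed).
- **`sncsec.genesets`** — intersection of predicted target-gene sets
  with stage-specific downregulated gene lists, plus an upper-tail
  hypergeometric overrepresentation test.
- **`sncsec.clinical`** — couple-level statistics: Spearman rank
  correlation matrices with Fisher-transform 95% CIs
  (`tanh(atanh ρ ± 1.96/√(n−3))`), Mann–Whitney comparisons, and
  chi-square / Fisher exact tests on 2×2 outcome tables.
- **`sncsec.synthetic`** — generators for every input the pipeline
  consumes: negative-binomial count matrices with a group-I secretion
  effect, Ct tables linked to latent abundances (`Ct = 35 −
  log2(abundance)`), transcripts with planted complementary piRNA
  sites, and a clinical couples table.

Small published reference tables (a 26 × 14 sncRNA count matrix from
morula spent-medium sequencing, the qPCR fold-change summary, and
stage-wise downregulated target-gene lists) ship with the package
under `sncsec.datasets`.

## Worked example

```python
from sncsec.synthetic import SimConfig, simulate_transcriptome
from sncsec.targets import scan, passing_hits

cfg = SimConfig(seed=7, n_transcripts=6, transcript_length=800, n_planted_sites=5)
pirnas, transcripts, truth = simulate_transcriptome(cfg)
for hit in passing_hits(scan(pirnas, transcripts)):
    print(hit.rna_id, hit.transcript_id, hit.start, hit.sc, round(hit.en, 1))
```

prints

```
piR_sim_001 tx_004 663 245.0 -46.9
piR_sim_002 tx_003 604 255.0 -61.1
piR_sim_003 tx_004 492 235.0 -42.9
piR_sim_004 tx_002 736 245.0 -56.3
piR_sim_005 tx_002 50 240.0 -58.4
```

— each planted site recovered at its exact coordinates with an
alignment score well above the sc ≥ 170 threshold and a duplex free
energy far below −20 kcal/mol. Scrambling the piRNAs and rescanning
yields zero passing hits.

The same pipeline is available from the shell:

```bash
sncsec simulate --outdir bundle/ --seed 7
sncsec diffcounts --counts bundle/counts.tsv --groups bundle/groups.tsv \
       --contrast I:III+IV --out diff.tsv
sncsec predict-targets --rnas bundle/pirnas.fa --transcripts bundle/transcripts.fa \
       --out hits.tsv
sncsec correlate --clinical bundle/clinical.tsv --out corr.tsv --plot corr.png
```

## Layout

```
src/sncsec/        library modules (+ bundled data/ tables)
tests/             pytest suite, including enumeration oracles
scripts/           acceptance script
docs/methods.md    modeling and numerical notes
```
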