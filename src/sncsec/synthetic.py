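"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates a spent-culture-medium small-RNA study design: four embryo
outcome groups (I, II, III, IV) plus one embryo-free Reference medium;
negative-binomial sequencing counts in which designated "secreted"
features are shifted upward in group I; qPCR Ct values linked to the
latent abundances through Ct = a - log2(abundance) with a constant
reference RNA, so ddCt inverts the simulation exactly at zero noise;
random transcripts with planted perfectly complementary piRNA sites and
a truth map for recall scoring; and a couple-level clinical table with
the correlation structure typical of ovarian-reserve data.

Counts use the mean/dispersion NB parameterization, Var = mu + phi*mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sncsec.counts import CountMatrix
from sncsec.datasets import REFERENCE_RNA
from sncsec.qpcr import QpcrTable
from sncsec.targets import SmallRNA, Transcript, reverse_complement


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


def _default_groups() -> dict[str, int]:
    # Sequencing arm of the emulated design: 3/3/4/3 embryo samples
    # plus one embryo-free reference medium.
    return {"I": 3, "II": 3, "III": 4, "IV": 3, "Reference": 1}


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Counts: ``n_features`` sncRNA features at a common ``baseline_mean``
    (reads per sample), of which the first ``n_secreted`` are secreted
    by group-I embryos with a ``effect_log2fc`` log2 shift.  Dispersion
    is the NB phi in Var = mu + phi*mu^2.  qPCR: Ct noise SD in cycles,
    intercept ``ct_intercept`` cycles at unit abundance.  Transcriptome:
    ``n_planted_sites`` piRNAs, each with one perfectly complementary
    site planted in a random transcript.
    """

    n_features: int = 459
    n_secreted: int = 24
    n_samples_per_group: dict[str, int] = field(default_factory=_default_groups)
    nb_dispersion: float = 0.3
    baseline_mean: float = 200.0
    effect_log2fc: float = 2.0
    ct_noise_sd: float = 0.25
    ct_intercept: float = 35.0
    n_transcripts: int = 10
    transcript_length: int = 1500
    n_planted_sites: int = 5
    n_couples: int = 27
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 1 or self.n_transcripts < 1 or self.transcript_length < 1:
            raise ConfigError("counts must be >= 1")
        if not 0 <= self.n_secreted <= self.n_features:
            raise ConfigError("n_secreted must be within [0, n_features]")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigError("nb_dispersion and baseline_mean must be positive")
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd must be non-negative")
        if any(n < 1 for n in self.n_samples_per_group.values()):
            raise ConfigError("every group needs >= 1 sample")
        if self.n_planted_sites < 0:
            raise ConfigError("n_planted_sites must be >= 0")


@dataclass
class SyntheticBundle:
    counts: CountMatrix
    ct_table: QpcrTable
    pirnas: list[SmallRNA]
    transcripts: list[Transcript]
    truth: dict[str, tuple[str, int]]
    clinical: pd.DataFrame


def feature_ids(cfg: SimConfig) -> list[str]:
    """Feature naming: secreted features carry the ``sec_`` prefix."""
    width = len(str(cfg.n_features))
    return [
        (f"sec_{i:0{width}d}" if i < cfg.n_secreted else f"bg_{i:0{width}d}")
        for i in range(cfg.n_features)
    ]


def secreted_ids(cfg: SimConfig) -> list[str]:
    return [f for f in feature_ids(cfg) if f.startswith("sec_")]


def _sample_table(cfg: SimConfig) -> tuple[list[str], pd.Series]:
    samples, groups = [], []
    for g, n in cfg.n_samples_per_group.items():
        for k in range(n):
            samples.append(f"{g}_{k + 1}")
            groups.append(g)
    return samples, pd.Series(groups, index=samples, name="group")


def group_mean(cfg: SimConfig, feature: str, group: str) -> float:
    """Deterministic latent abundance of a feature in a group."""
    if feature.startswith("sec_") and group == "I":
        return cfg.baseline_mean * 2.0 ** cfg.effect_log2fc
    return cfg.baseline_mean


def _nb_draw(rng: np.random.Generator, mean: float, phi: float, size) -> np.ndarray:
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(cfg: SimConfig) -> CountMatrix:
    """NB count matrix; group-I mean of secreted features is
    baseline_mean * 2^effect_log2fc, everything else at baseline."""
    rng = np.random.default_rng(cfg.seed)
    samples, groups = _sample_table(cfg)
    feats = feature_ids(cfg)
    mat = np.empty((cfg.n_features, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        g = groups[s]
        means = np.array([group_mean(cfg, f, g) for f in feats])
        mat[:, j] = _nb_draw(rng, means, cfg.nb_dispersion, cfg.n_features)
    counts = pd.DataFrame(mat, index=pd.Index(feats, name="sncRNA"), columns=samples)
    return CountMatrix(counts, groups)


def simulate_qpcr(cfg: SimConfig, counts: CountMatrix) -> QpcrTable:
    """Ct table for every feature/sample in ``counts``.

    Ct = ct_intercept - log2(latent group abundance) + N(0, ct_noise_sd);
    the reference RNA sits at constant baseline abundance in every
    sample, and the first Reference-group sample serves as the
    no-embryo reference medium.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ref_samples = counts.samples_in({"Reference"})
    if not ref_samples:
        raise ConfigError("counts must include a Reference-group sample")
    rows = []
    for s in counts.sample_ids:
        g = counts.groups[s]
        for f in counts.feature_ids:
            mu = group_mean(cfg, f, g)
            ct = cfg.ct_intercept - np.log2(mu) + rng.normal(0, cfg.ct_noise_sd)
            rows.append((s, g, f, float(ct)))
        ct_ref = (
            cfg.ct_intercept
            - np.log2(cfg.baseline_mean)
            + rng.normal(0, cfg.ct_noise_sd)
        )
        rows.append((s, g, REFERENCE_RNA, float(ct_ref)))
    df = pd.DataFrame(rows, columns=["sample", "group", "sncRNA", "ct"])
    return QpcrTable(df, reference_rna=REFERENCE_RNA, reference_sample=ref_samples[0])


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def simulate_transcriptome(
    cfg: SimConfig, pirna_length_range: tuple[int, int] = (26, 31)
) -> tuple[list[SmallRNA], list[Transcript], dict[str, tuple[str, int]]]:
    """Random transcripts with one planted site per simulated piRNA.

    Each planted site is the Watson-Crick reverse complement of its
    piRNA written onto the transcript sense strand; sites never overlap.
    Returns (piRNAs, transcripts, truth) with truth mapping piRNA id to
    (transcript id, 0-based site start).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    lo, hi = pirna_length_range
    if cfg.transcript_length <= hi + 10:
        raise ConfigError("transcript_length must exceed piRNA length + margin")
    seqs = [
        list(_random_rna(rng, cfg.transcript_length)) for _ in range(cfg.n_transcripts)
    ]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(cfg.n_transcripts)}
    pirnas, truth = [], {}
    for k in range(cfg.n_planted_sites):
        pid = f"piR_sim_{k + 1:03d}"
        pir = _random_rna(rng, int(rng.integers(lo, hi + 1)))
        site = reverse_complement(pir)
        placed = False
        for _ in range(200):
            t = int(rng.integers(cfg.n_transcripts))
            start = int(rng.integers(0, cfg.transcript_length - len(site) + 1))
            span = (start, start + len(site))
            if all(span[1] <= a or span[0] >= b for a, b in occupied[t]):
                seqs[t][span[0] : span[1]] = list(site)
                occupied[t].append(span)
                truth[pid] = (f"tx_{t + 1:03d}", start)
                placed = True
                break
        if not placed:
            raise GenerationError("could not place a non-overlapping site")
        pirnas.append(SmallRNA(pid, pir))
    transcripts = [
        Transcript(f"tx_{i + 1:03d}", "".join(s)) for i, s in enumerate(seqs)
    ]
    return pirnas, transcripts, truth


def scramble(rna: SmallRNA, rng: np.random.Generator) -> SmallRNA:
    """Shuffle a small RNA's letters (null model for target scans)."""
    seq = list(rna.sequence)
    rng.shuffle(seq)
    return SmallRNA(rna.id + "_scr", "".join(seq))


def simulate_clinical(cfg: SimConfig) -> pd.DataFrame:
    """Couple-level clinical table with ovarian-reserve correlations.

    One row per couple.  Female age drives ovarian reserve (AMH, OCC,
    MII counts) downward; low reserve pushes protocols toward HMG with
    higher gonadotropin doses and longer stimulation; delivery odds
    increase with reserve.  Percentages are bounded to [0, 100],
    binary variables are 0/1.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n = cfg.n_couples
    age = np.clip(rng.normal(33, 4, n), 24, 44).round(0)
    reserve = -0.6 * (age - 33) / 4 + 0.8 * rng.normal(size=n)  # latent
    amh = np.clip(np.exp(0.6 + 0.5 * reserve + 0.2 * rng.normal(size=n)), 0.1, 10)
    occ = np.clip(np.round(9 + 3.5 * reserve + 2.5 * rng.normal(size=n)), 1, 25)
    mii_frac = np.clip(0.68 + 0.2 * rng.normal(size=n), 0.2, 1.0)
    mii = np.clip(np.round(occ * mii_frac), 0, occ)
    hmg = (reserve + 0.5 * rng.normal(size=n) < -0.4).astype(int)
    rfsh = 1 - hmg
    dose = np.clip(1900 + 450 * hmg - 220 * reserve + 250 * rng.normal(size=n), 900, 3600).round(-1)
    days = np.clip(np.round(10 + 1.1 * hmg - 0.6 * reserve + 1.2 * rng.normal(size=n)), 7, 15)
    decap = (rng.random(n) < 0.15).astype(int)
    hcg = 1 - decap
    qual = 0.5 * reserve + 0.3 * hcg + 0.5 * rng.normal(size=n)  # embryo quality
    pct_exc = np.clip(40 + 25 * qual + 12 * rng.normal(size=n), 0, 100).round(0)
    rest = 100 - pct_exc
    frac_deg = np.clip(0.5 + 0.15 * rng.normal(size=n), 0, 1)
    pct_deg = (rest * frac_deg).round(0)
    pct_arr = np.clip((rest - pct_deg) * np.clip(0.5 + 0.2 * rng.normal(size=n), 0, 1), 0, 100).round(0)
    pct_bad = np.clip(rest - pct_deg - pct_arr, 0, 100)
    pct_fair = np.zeros(n)
    not_suitable = np.clip(pct_deg + pct_arr + pct_bad, 0, 100)
    p_delivery = 1 / (1 + np.exp(-(0.9 * reserve + 0.5 * hcg - 0.3)))
    delivery = (rng.random(n) < p_delivery).astype(int)
    sperm_conc = np.clip(rng.lognormal(np.log(55), 0.5, n), 2, 250).round(0)
    motility = np.clip(55 + 0.1 * (sperm_conc - 55) + 12 * rng.normal(size=n), 2, 95).round(0)
    morph = np.clip(2.3 + 0.01 * (sperm_conc - 55) + 0.03 * (motility - 55) + rng.normal(size=n), 0, 8).round(1)
    return pd.DataFrame(
        {
            "couple": np.arange(1, n + 1),
            "female_age": age,
            "male_age": np.clip(age + rng.normal(2, 3, n), 24, 55).round(0),
            "bmi": np.clip(rng.normal(23.4, 2.5, n), 17, 35).round(1),
            "amh_ng_ml": amh.round(2),
            "occ": occ,
            "mii": mii,
            "mii_occ_pct": np.where(occ > 0, 100 * mii / occ, np.nan).round(1),
            "sperm_concentration": sperm_conc,
            "progressive_motility_pct": motility,
            "morph_normal_pct": morph,
            "rfsh": rfsh,
            "hmg": hmg,
            "gonadotropin_dose_iu": dose,
            "stimulation_days": days,
            "hcg_trigger": hcg,
            "decapeptyl": decap,
            "pct_excellent_blastocysts": pct_exc,
            "pct_fair_blastocysts": pct_fair,
            "pct_bad_blastocysts": pct_bad,
            "pct_degenerated_morula": pct_deg,
            "pct_arrested_morula": pct_arr,
            "pct_not_suitable": not_suitable,
            "delivery": delivery,
        }
    )


def simulate_bundle(cfg: SimConfig) -> SyntheticBundle:
    counts = simulate_counts(cfg)
    ct = simulate_qpcr(cfg, counts)
    pirnas, transcripts, truth = simulate_transcriptome(cfg)
    clinical = simulate_clinical(cfg)
    return SyntheticBundle(counts, ct, pirnas, transcripts, truth, clinical)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write every bundle component as plain-text TSV/FASTA files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.counts.counts.to_csv(out / "counts.tsv", sep="\t")
    bundle.counts.groups.rename("group").rename_axis("sample").to_csv(
        out / "groups.tsv", sep="\t"
    )
    bundle.ct_table.data.to_csv(out / "ct.tsv", sep="\t", index=False)
    with open(out / "pirnas.fa", "w") as fh:
        for r in bundle.pirnas:
            fh.write(f">{r.id}\n{r.sequence}\n")
    with open(out / "transcripts.fa", "w") as fh:
        for t in bundle.transcripts:
            fh.write(f">{t.id}\n{t.sequence}\n")
    pd.DataFrame(
        [(p, t, s) for p, (t, s) in bundle.truth.items()],
        columns=["pirna", "transcript", "start"],
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    bundle.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
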