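"""Synthetic study generator with known ground truth.

Emulates the inputs of a cold-stress resequencing study: in-ear temperature
series for a cohort of ~200 animals over two winter weeks containing a
five-day extreme-cold spell; a 12-animal (two groups of six, two breeds)
multi-sample VCF of genome-wide biallelic SNPs in which most sites share
allele frequencies between the groups while a configured set of "planted"
loci is strongly divergent; a per-SNP functional (FAETH-style) score table
enriched at planted loci; and a toy GTF + FASTA gene model for consequence
annotation. Every output is a pure function of (config, seed).

Planted loci model true biological signals, so caller-artifact features
(hard-filter-failing INFO values, INDEL status, absence from the FAETH
table) are applied to background records only; planted loci keep ordinary
genotype missingness. One extra "causal" truth locus drives the temperature
phenotype: its VCF genotypes are the sequenced animals' actual dosages, so
its between-group divergence emerges from the extreme-group selection
instead of being planted directly.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .io import VariantRecord, write_temperature_csv
from .phenotype import (
    GroupSpec,
    TemperatureSeries,
    compute_phenotypes,
    select_coldest_interval,
    select_extreme_groups,
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.array(["A", "C", "G", "T"])
_STOPS = {"TAA", "TAG", "TGA"}


def _default_info_distributions() -> dict:
    """Passing-value distributions plus failing-value ranges per INFO key."""
    return {
        "QD": {"pass": ("normal", 25.0, 6.0, 2.0, None), "fail": (0.0, 1.99)},
        "MQ": {"pass": ("normal", 58.0, 3.0, 40.0, None), "fail": (20.0, 39.9)},
        "FS": {"pass": ("exponential", 8.0, None, 0.0, 60.0), "fail": (60.1, 200.0)},
        "MQRankSum": {"pass": ("normal", 0.0, 1.5, -12.5, 12.5),
                      "fail": (-20.0, -12.6)},
        "ReadPosRankSum": {"pass": ("normal", 0.0, 1.5, -8.0, 8.0),
                           "fail": (-15.0, -8.1)},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study. Defaults follow the study conditions:
    ~200 animals over 14 winter days with a five-day spell down to −32 °C,
    six sequenced animals per contrast group drawn from two breeds (7/12 and
    5/12 of the cohort), and genome-wide biallelic SNPs at ~1 per 25 kb with
    20 strongly divergent planted loci."""

    # cohort / phenotype
    n_animals: int = 200
    n_sequenced_per_group: int = 6
    breeds: tuple[tuple[str, float], ...] = (
        ("hereford", 7 / 12),
        ("kazakh_whiteheaded", 5 / 12),
    )
    n_days: int = 14
    sampling_interval_min: int = 60
    start_date: str = "2021-01-10"
    baseline_temp_c: float = 38.5
    in_ear_noise_sd: float = 0.25
    ambient_base_c: float = -12.0
    diurnal_amplitude_c: float = 6.0
    ambient_noise_sd: float = 1.5
    cold_spell_days: int = 5
    cold_spell_min_c: float = -32.0
    stress_threshold_c: float = -10.0
    # cold-sensitivity coefficient: base + per-allele * dosage + noise (°C/°C)
    sensitivity_base: float = 0.004
    sensitivity_per_allele: float = 0.006
    sensitivity_sd: float = 0.002
    causal_allele_freq: float = 0.5
    # genome / genotypes
    n_chromosomes: int = 2
    chrom_length: int = 125_000_000
    n_background_snps: int = 10_000
    n_planted_snps: int = 20
    planted_afd: float = 0.8
    missing_genotype_rate: float = 0.05
    fraction_failing_filters: float = 0.10
    indel_fraction: float = 0.05
    transition_prob: float = 2 / 3
    info_field_distributions: dict = field(
        default_factory=_default_info_distributions
    )
    # FAETH table
    faeth_enrichment: float = 0.9
    faeth_missing_rate: float = 0.45
    # gene models
    genes_per_chromosome: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        props = [
            self.planted_afd, self.missing_genotype_rate,
            self.fraction_failing_filters, self.indel_fraction,
            self.faeth_enrichment, self.faeth_missing_rate,
            self.causal_allele_freq, self.transition_prob,
        ] + [p for _, p in self.breeds]
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise InvalidConfigError("all proportions must lie in [0, 1]")
        counts = [
            self.n_animals, self.n_sequenced_per_group, self.n_days,
            self.sampling_interval_min, self.n_chromosomes, self.chrom_length,
            self.n_background_snps,
        ]
        if any(c <= 0 for c in counts):
            raise InvalidConfigError("counts must be positive")
        if self.n_planted_snps < 0:
            raise InvalidConfigError("n_planted_snps must be non-negative")
        if abs(sum(p for _, p in self.breeds) - 1.0) > 1e-9:
            raise InvalidConfigError("breed proportions must sum to 1")

    @classmethod
    def demo(cls, **overrides) -> "SimulationConfig":
        """A reduced-genome preset (SNP density preserved at ~1/25 kb) small
        enough to carry the gene-model FASTA through the full pipeline."""
        base = dict(
            n_chromosomes=2,
            chrom_length=1_250_000,
            n_background_snps=100,
            n_planted_snps=4,
            genes_per_chromosome=2,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SimulatedCohort:
    animals: pd.DataFrame  # animal_id, breed, causal_dosage, sensitivity
    series: dict[str, TemperatureSeries]
    ambient: TemperatureSeries


@dataclass
class StudyBundle:
    """Everything one synthetic study emits, plus its ground truth."""

    config: SimulationConfig
    cohort: SimulatedCohort
    interval: tuple
    phenotypes: list
    groups: GroupSpec
    records: list[VariantRecord]
    truth: pd.DataFrame
    faeth: pd.DataFrame
    gtf_text: Optional[str] = None
    fasta: Optional[dict[str, str]] = None


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# temperature series


def simulate_temperature_series(
    config: SimulationConfig,
    seed: int,
    dosages: Optional[np.ndarray] = None,
) -> SimulatedCohort:
    """Ambient + per-animal in-ear temperature series.

    The ambient series is diurnal noise around a winter baseline with one
    contiguous cold spell whose minimum reaches ``cold_spell_min_c`` exactly.
    Each animal's in-ear series is
    ``baseline − s_i · max(0, threshold − ambient) + noise`` where the
    cold-sensitivity coefficient ``s_i`` is linear in the animal's causal
    dosage plus a polygenic term.
    """
    if config.n_days < 6:
        raise InvalidConfigError(
            "n_days must be ≥ 6 to contain a five-day cold spell"
        )
    rng_amb, rng_animal, rng_noise = _spawn(seed, 3)

    n_per_day = (24 * 60) // config.sampling_interval_min
    n_points = config.n_days * n_per_day
    t0 = pd.Timestamp(config.start_date)
    timestamps = pd.date_range(
        t0, periods=n_points, freq=pd.Timedelta(minutes=config.sampling_interval_min)
    )
    hours = np.arange(n_points) * (config.sampling_interval_min / 60.0)

    # coldest around 03:00, warmest mid-afternoon
    diurnal = -config.diurnal_amplitude_c * np.cos(2 * np.pi * (hours % 24 - 3) / 24)
    base = (
        config.ambient_base_c
        + diurnal
        + rng_amb.normal(0.0, config.ambient_noise_sd, n_points)
    )
    spell_start_day = int(
        rng_amb.integers(0, config.n_days - config.cold_spell_days + 1)
    )
    spell_len_h = config.cold_spell_days * 24.0
    rel = (hours - spell_start_day * 24.0) / spell_len_h
    weight = np.where(
        (rel >= 0) & (rel <= 1), np.sin(np.pi * np.clip(rel, 0, 1)) ** 2, 0.0
    )
    in_spell = weight > 0.05
    if in_spell.any():
        # largest dip that keeps every point ≥ the configured extreme, with
        # equality attained: the spell minimum hits cold_spell_min_c exactly
        depth = np.min(
            (base[in_spell] - config.cold_spell_min_c) / weight[in_spell]
        )
        depth = max(depth, 0.0)
    else:
        depth = 0.0
    ambient_values = base - depth * weight

    ambient = TemperatureSeries(
        subject_id="ambient", timestamps=timestamps.to_numpy(), values=ambient_values
    )

    breed_names = [b for b, _ in config.breeds]
    breed_probs = [p for _, p in config.breeds]
    breed_assign = rng_animal.choice(
        breed_names, size=config.n_animals, p=breed_probs
    )
    if dosages is None:
        dosages = rng_animal.binomial(
            2, config.causal_allele_freq, config.n_animals
        )
    dosages = np.asarray(dosages, dtype=int)
    sensitivity = np.clip(
        config.sensitivity_base
        + config.sensitivity_per_allele * dosages
        + rng_animal.normal(0.0, config.sensitivity_sd, config.n_animals),
        0.0,
        None,
    )

    deficit = np.maximum(0.0, config.stress_threshold_c - ambient_values)
    width = len(str(config.n_animals))
    series = {}
    ids = [f"A{i + 1:0{width}d}" for i in range(config.n_animals)]
    for i, aid in enumerate(ids):
        values = (
            config.baseline_temp_c
            - sensitivity[i] * deficit
            + rng_noise.normal(0.0, config.in_ear_noise_sd, n_points)
        )
        series[aid] = TemperatureSeries(
            subject_id=aid, timestamps=timestamps.to_numpy(), values=values
        )
    animals = pd.DataFrame(
        {
            "animal_id": ids,
            "breed": breed_assign,
            "causal_dosage": dosages,
            "sensitivity": sensitivity,
        }
    )
    return SimulatedCohort(animals=animals, series=series, ambient=ambient)


# ---------------------------------------------------------------------------
# genotypes


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct 1-based positions on a chromosome, without materializing a
    full-length permutation (chromosomes can be 10^8 bp)."""
    if n > length:
        raise InvalidConfigError("more SNPs than positions on a chromosome")
    pos = np.unique(rng.integers(1, length + 1, n))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos)


def _draw_alleles(rng: np.random.Generator, transition_prob: float) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    if rng.random() < transition_prob:
        return ref, _TRANSITION[ref]
    choices = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return ref, str(rng.choice(choices))


def _genotypes_from_dosages(
    dosages: np.ndarray, missing: np.ndarray
) -> list:
    out = []
    for d, m in zip(dosages, missing):
        if m:
            out.append(None)
        elif d == 0:
            out.append((0, 0))
        elif d == 1:
            out.append((0, 1))
        else:
            out.append((1, 1))
    return out


def _draw_info(
    rng: np.random.Generator, dists: dict, failing: bool
) -> dict[str, float]:
    info = {}
    fail_key = str(rng.choice(sorted(dists))) if failing else None
    for key in sorted(dists):
        spec = dists[key]
        if key == fail_key:
            lo, hi = spec["fail"]
            info[key] = float(rng.uniform(lo, hi))
            continue
        kind, p1, p2, lo, hi = spec["pass"]
        if kind == "normal":
            val = rng.normal(p1, p2)
        elif kind == "exponential":
            val = rng.exponential(p1)
        else:
            raise InvalidConfigError(f"unknown INFO distribution kind {kind!r}")
        if lo is not None:
            val = max(val, lo)
        if hi is not None:
            val = min(val, hi)
        info[key] = float(val)
    return {k: round(v, 3) for k, v in info.items()}


def simulate_genotypes(
    config: SimulationConfig,
    groups: GroupSpec,
    seed: int,
    causal_dosages: Optional[dict[str, int]] = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Emit VCF records for the sequenced samples plus the planted-locus
    truth table.

    Background SNPs share one allele frequency between groups; planted SNPs
    draw per-group reference-allele frequencies at least ``planted_afd``
    apart. INFO values straddle the hard-filter thresholds for a configured
    fraction of background records, and a configured fraction of background
    records are INDELs.
    """
    labels = groups.labels
    if len(labels) != 2:
        raise InvalidConfigError("need exactly two group labels")
    for label in labels:
        if len(groups.samples(label)) != config.n_sequenced_per_group:
            raise InvalidConfigError(
                f"group {label!r} must have {config.n_sequenced_per_group} samples"
            )
    samples = tuple(sorted(groups.group_of))
    group_idx = {
        label: np.array([groups.group_of[s] == label for s in samples])
        for label in labels
    }

    rng_pos, rng_allele, rng_geno, rng_info = _spawn(seed, 4)

    n_indels = int(round(config.indel_fraction * config.n_background_snps))
    n_causal = 1 if causal_dosages is not None else 0
    n_sites = config.n_background_snps + config.n_planted_snps + n_indels + n_causal

    chroms = rng_pos.integers(1, config.n_chromosomes + 1, n_sites)
    positions = np.empty(n_sites, dtype=np.int64)
    for c in range(1, config.n_chromosomes + 1):
        idx = np.where(chroms == c)[0]
        positions[idx] = _unique_positions(rng_pos, len(idx), config.chrom_length)

    kinds = np.array(
        ["background"] * config.n_background_snps
        + ["planted"] * config.n_planted_snps
        + ["indel"] * n_indels
        + ["causal"] * n_causal
    )
    rng_pos.shuffle(kinds)

    order = np.lexsort((positions, chroms))
    records: list[VariantRecord] = []
    truth_rows = []
    n_samples = len(samples)
    for i in order:
        kind = kinds[i]
        chrom = str(chroms[i])
        pos = int(positions[i])
        ref, alt = _draw_alleles(rng_allele, config.transition_prob)
        missing = rng_geno.random(n_samples) < config.missing_genotype_rate

        if kind == "indel":
            ins = rng_allele.random() < 0.5
            if ins:
                alt_allele = ref + str(rng_allele.choice(_BASES))
                ref_allele = ref
            else:
                ref_allele = ref + str(rng_allele.choice(_BASES))
                alt_allele = ref
            q = rng_geno.uniform(0.05, 0.95)
            dosages = rng_geno.binomial(2, q, n_samples)
            info = _draw_info(
                rng_info,
                config.info_field_distributions,
                rng_info.random() < config.fraction_failing_filters,
            )
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref_allele, alts=(alt_allele,),
                    info=info, genotypes=_genotypes_from_dosages(dosages, missing),
                    samples=samples,
                )
            )
            continue

        if kind == "background":
            p_ref = rng_geno.uniform(0.05, 0.95)
            p_by_group = {label: p_ref for label in labels}
            failing = rng_info.random() < config.fraction_failing_filters
        elif kind == "planted":
            d = rng_geno.uniform(config.planted_afd, 1.0)
            p_low = rng_geno.uniform(0.0, 1.0 - d)
            p_high = p_low + d
            if rng_geno.random() < 0.5:
                p_by_group = {labels[0]: p_low, labels[1]: p_high}
            else:
                p_by_group = {labels[0]: p_high, labels[1]: p_low}
            failing = False
        else:  # causal
            p_by_group = None
            failing = False

        dosages = np.zeros(n_samples, dtype=int)
        if kind == "causal":
            for j, s in enumerate(samples):
                dosages[j] = causal_dosages[s]
        else:
            for label in labels:
                mask = group_idx[label]
                q_alt = 1.0 - p_by_group[label]
                dosages[mask] = rng_geno.binomial(2, q_alt, int(mask.sum()))
        info = _draw_info(rng_info, config.info_field_distributions, failing)
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alts=(alt,), info=info,
                genotypes=_genotypes_from_dosages(dosages, missing),
                samples=samples,
            )
        )
        if kind in ("planted", "causal"):
            if kind == "causal":
                freqs = {}
                for label in labels:
                    mask = group_idx[label]
                    freqs[label] = 1.0 - dosages[mask].sum() / (2.0 * mask.sum())
                p_by_group = freqs
            truth_rows.append(
                {
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "role": kind,
                    f"p_{labels[0]}": p_by_group[labels[0]],
                    f"p_{labels[1]}": p_by_group[labels[1]],
                    "effect_size": (
                        config.sensitivity_per_allele if kind == "causal" else 0.0
                    ),
                }
            )
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(
        drop=True
    )
    return records, truth


# ---------------------------------------------------------------------------
# FAETH table


def simulate_faeth_table(
    records: list[VariantRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP functional score table (chrom, pos, ref, alt, score).

    Background biallelic SNPs draw lognormal scores and are absent from the
    table at ``faeth_missing_rate``; truth loci are always present and, with
    probability ``faeth_enrichment``, receive a score drawn uniformly between
    the empirical 90th percentile and the maximum of the background scores.
    Returns the table and the truth table with assigned scores attached.
    """
    if not records:
        raise InvalidConfigError("no records to score")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    truth_keys = set(zip(truth["chrom"], truth["pos"])) if len(truth) else set()

    background, planted = [], []
    for rec in records:
        if not (rec.is_biallelic and rec.is_snp):
            continue
        key = (rec.chrom, rec.pos)
        (planted if key in truth_keys else background).append(rec)

    bg_scores = rng.lognormal(0.0, 1.0, len(background))
    bg_present = rng.random(len(background)) >= config.faeth_missing_rate
    rows = [
        {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
         "score": float(s)}
        for r, s, keep in zip(background, bg_scores, bg_present)
        if keep
    ]
    if len(bg_scores):
        q90 = float(np.quantile(bg_scores, 0.9))
        top = float(bg_scores.max())
    else:
        q90, top = 1.0, 2.0
    truth = truth.copy()
    truth["faeth_score"] = np.nan
    for rec in planted:
        if rng.random() < config.faeth_enrichment:
            score = float(rng.uniform(q90, top))
        else:
            score = float(rng.lognormal(0.0, 1.0))
        rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
             "score": score}
        )
        sel = (truth["chrom"] == rec.chrom) & (truth["pos"] == rec.pos)
        truth.loc[sel, "faeth_score"] = score
    faeth = (
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "score"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return faeth, truth


# ---------------------------------------------------------------------------
# gene models


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense (non-stop) codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_BASES, 3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def simulate_gene_models(
    config: SimulationConfig, seed: int
) -> tuple[str, dict[str, str]]:
    """Toy multi-exon protein-coding gene models plus a consistent genome.

    Each chromosome carries ``genes_per_chromosome`` three-exon genes with
    alternating strands, 5'/3' UTRs and a valid CDS (ATG start, no internal
    in-frame stop, terminal stop codon; the CDS intervals include the stop
    codon). Returns the GTF text and a chrom→sequence dict.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    gtf_lines = []
    fasta: dict[str, str] = {}
    gene_serial = 0
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        seq = rng.choice(_BASES, config.chrom_length)
        cursor = 12_000  # leave an intergenic margin before the first gene
        for g in range(config.genes_per_chromosome):
            gene_serial += 1
            strand = "+" if gene_serial % 2 else "-"
            utr5 = int(rng.integers(60, 150))
            utr3 = int(rng.integers(80, 200))
            exon_cds = [int(rng.integers(120, 300)) * 3 for _ in range(3)]
            introns = [int(rng.integers(200, 800)) for _ in range(2)]
            cds_len = sum(exon_cds)

            # genomic layout left→right; for '-' genes the 3'UTR comes first
            left_utr = utr5 if strand == "+" else utr3
            right_utr = utr3 if strand == "+" else utr5
            start = cursor
            exons = []
            p = start
            for i, ce in enumerate(exon_cds):
                elen = ce + (left_utr if i == 0 else 0) + (
                    right_utr if i == 2 else 0
                )
                exons.append((p, p + elen - 1))
                p = p + elen + (introns[i] if i < 2 else 0)
            gene_end = exons[-1][1]
            if gene_end + 12_000 > config.chrom_length:
                raise InvalidConfigError(
                    "chrom_length too small to place the configured genes"
                )
            cds = []
            for i, (s, e) in enumerate(exons):
                cs = s + (left_utr if i == 0 else 0)
                ce_ = e - (right_utr if i == 2 else 0)
                cds.append((cs, ce_))

            codons = "ATG" + _random_codons(rng, cds_len // 3 - 2) + "TAA"
            cds_positions = [p_ for s, e in cds for p_ in range(s, e + 1)]
            if strand == "-":
                cds_positions = cds_positions[::-1]
                bases = codons.translate(str.maketrans("ACGT", "TGCA"))
            else:
                bases = codons
            for p_, b in zip(cds_positions, bases):
                seq[p_ - 1] = b

            gid = f"GENE{gene_serial:04d}"
            tid = f"TX{gene_serial:04d}"
            attrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gid}"; '
                f'gene_biotype "protein_coding";'
            )
            gattrs = f'gene_id "{gid}"; gene_name "{gid}"; gene_biotype "protein_coding";'

            def line(feature, s, e, frame="."):
                return (
                    f"{chrom}\tcoldrank_sim\t{feature}\t{s}\t{e}\t.\t{strand}\t"
                    f"{frame}\t{attrs if feature != 'gene' else gattrs}"
                )

            gtf_lines.append(line("gene", start, gene_end))
            gtf_lines.append(line("transcript", start, gene_end))
            cds_in_tx_order = cds if strand == "+" else cds[::-1]
            consumed = 0
            frames = {}
            for s, e in cds_in_tx_order:
                frames[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for (s, e) in exons:
                gtf_lines.append(line("exon", s, e))
            for (s, e) in cds:
                gtf_lines.append(line("CDS", s, e, str(frames[(s, e)])))
            # UTR features (derived downstream too; emitted for completeness)
            first_exon, last_exon = exons[0], exons[-1]
            if left_utr:
                kind = "five_prime_utr" if strand == "+" else "three_prime_utr"
                gtf_lines.append(
                    line(kind, first_exon[0], first_exon[0] + left_utr - 1)
                )
            if right_utr:
                kind = "three_prime_utr" if strand == "+" else "five_prime_utr"
                gtf_lines.append(
                    line(kind, last_exon[1] - right_utr + 1, last_exon[1])
                )
            cursor = gene_end + 12_000 + int(rng.integers(0, 2_000))
        fasta[chrom] = "".join(seq)
    return "\n".join(gtf_lines) + "\n", fasta


def _reconcile_with_fasta(
    records: list[VariantRecord], truth: pd.DataFrame, fasta: dict[str, str]
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Rewrite record alleles so the VCF REF matches the emitted genome.

    Allele draws happen before the genome sequence exists; this pass swaps in
    the FASTA base as REF, carrying over the substitution type (a transition
    stays a transition, a transversion stays a transversion, an INDEL keeps
    its shape). Genotype allele indices are untouched.
    """
    fixed = []
    for rec in records:
        base = fasta[rec.chrom][rec.pos - 1].upper()
        if rec.ref[0] == base:
            fixed.append(rec)
            continue
        if len(rec.ref) == 1 and all(len(a) == 1 for a in rec.alts):
            old_ref, old_alt = rec.ref, rec.alts[0]
            if old_alt == _TRANSITION[old_ref]:
                new_alt = _TRANSITION[base]
            else:
                choices = [b for b in "ACGT"
                           if b != base and b != _TRANSITION[base]]
                old_choices = [b for b in "ACGT"
                               if b != old_ref and b != _TRANSITION[old_ref]]
                new_alt = choices[old_choices.index(old_alt)]
            new_ref, alts = base, (new_alt,)
        else:  # INDEL: keep the inserted/deleted tail, swap the anchor base
            new_ref = base + rec.ref[1:]
            alts = tuple(base + a[1:] for a in rec.alts)
        fixed.append(replace(rec, ref=new_ref, alts=alts))
    by_pos = {(r.chrom, r.pos): r for r in fixed}
    truth = truth.copy()
    for i in truth.index:
        rec = by_pos[(truth.at[i, "chrom"], truth.at[i, "pos"])]
        truth.at[i, "ref"] = rec.ref
        truth.at[i, "alt"] = rec.alt
    return fixed, truth


# ---------------------------------------------------------------------------
# output writers


def write_vcf(records: list[VariantRecord], path: str, config=None) -> None:
    """Write records as an uncompressed VCF v4.2 text file."""
    if not records:
        raise InvalidConfigError("no records to write")
    samples = records[0].samples
    contigs = sorted({r.chrom for r in records}, key=lambda c: (len(c), c))
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=coldrank-simulate\n")
    for c in contigs:
        length = config.chrom_length if config is not None else None
        buf.write(
            f"##contig=<ID={c}" + (f",length={length}" if length else "") + ">\n"
        )
    for key, desc in (
        ("QD", "Variant confidence normalized by depth"),
        ("MQ", "RMS mapping quality"),
        ("FS", "Phred-scaled strand-bias Fisher p-value"),
        ("MQRankSum", "Alt-vs-ref mapping quality rank-sum Z"),
        ("ReadPosRankSum", "Alt-vs-ref read position rank-sum Z"),
    ):
        buf.write(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n'
        )
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    for r in records:
        info = ";".join(f"{k}={r.info[k]:g}" for k in sorted(r.info))
        gts = "\t".join(
            "./." if gt is None else f"{gt[0]}/{gt[1]}" for gt in r.genotypes
        )
        buf.write(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{','.join(r.alts)}\t.\tPASS\t"
            f"{info or '.'}\tGT\t{gts}\n"
        )
    Path(path).write_text(buf.getvalue())


def write_fasta(fasta: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in fasta.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# full study


#: genome size above which simulate_study skips FASTA/GTF emission by default
MAX_FASTA_GENOME = 20_000_000


def simulate_study(
    config: SimulationConfig,
    seed: int,
    outdir: Optional[str] = None,
    gene_models: Optional[bool] = None,
) -> StudyBundle:
    """Run the whole generator: cohort → phenotypes → groups → VCF → FAETH
    (→ gene models), optionally writing every output file under ``outdir``.

    ``gene_models=None`` emits the toy GTF/FASTA only when the configured
    genome is small enough (≤ 20 Mb total) for a sequence file to be
    practical; the reduced :meth:`SimulationConfig.demo` preset qualifies.
    """
    if gene_models is None:
        gene_models = (
            config.n_chromosomes * config.chrom_length <= MAX_FASTA_GENOME
        )
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    cohort = simulate_temperature_series(config, int(seeds[0]))
    interval = select_coldest_interval(cohort.ambient, config.cold_spell_days)
    breed_of = dict(zip(cohort.animals["animal_id"], cohort.animals["breed"]))
    phenotypes = compute_phenotypes(cohort.series, interval, breed_of)
    groups = select_extreme_groups(phenotypes, config.n_sequenced_per_group)

    dosage_of = dict(
        zip(cohort.animals["animal_id"], cohort.animals["causal_dosage"])
    )
    causal = {s: int(dosage_of[s]) for s in groups.group_of}
    records, truth = simulate_genotypes(
        config, groups, int(seeds[1]), causal_dosages=causal
    )
    gtf_text = fasta = None
    if gene_models:
        gtf_text, fasta = simulate_gene_models(config, int(seeds[3]))
        records, truth = _reconcile_with_fasta(records, truth, fasta)
    faeth, truth = simulate_faeth_table(records, truth, config, int(seeds[2]))

    bundle = StudyBundle(
        config=config, cohort=cohort, interval=interval, phenotypes=phenotypes,
        groups=groups, records=records, truth=truth, faeth=faeth,
        gtf_text=gtf_text, fasta=fasta,
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_temperature_csv(
            list(cohort.series.values()), out / "in_ear_temperatures.csv"
        )
        write_temperature_csv([cohort.ambient], out / "ambient_temperature.csv")
        groups.to_frame().to_csv(out / "groups.csv", index=False)
        write_vcf(records, out / "variants.vcf", config=config)
        faeth.to_csv(out / "faeth_scores.csv", index=False)
        truth.to_csv(out / "truth_table.csv", index=False)
        pd.DataFrame(
            [
                {"animal_id": p.animal_id, "breed": p.breed, "auc": p.auc}
                for p in phenotypes
            ]
        ).to_csv(out / "phenotypes.csv", index=False)
        if gene_models:
            (out / "genes.gtf").write_text(gtf_text)
            write_fasta(fasta, out / "genome.fa")
    return bundle
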