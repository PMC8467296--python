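"""Synthetic-study generator: determinism, planted signal, format validity."""

import numpy as np
import pytest
from scipy.stats import binomtest

from coldrank.errors import InvalidConfigError
from coldrank.io import read_temperature_csv, read_vcf
from coldrank.phenotype import GroupSpec
from coldrank.simulate import (
    SimulationConfig,
    simulate_faeth_table,
    simulate_gene_models,
    simulate_genotypes,
    simulate_temperature_series,
    write_vcf,
)
from coldrank.variant_filter import FilterThresholds, apply_hard_filters, failing_rules

from conftest import SAMPLES


@pytest.fixture(scope="module")
def genotype_run(groups12):
    """One study-scale genotype + FAETH simulation shared by the statistical
    checks below."""
    cfg = SimulationConfig()
    records, truth = simulate_genotypes(cfg, groups12, seed=123)
    faeth, truth = simulate_faeth_table(records, truth, cfg, seed=456)
    return cfg, records, truth, faeth


def small_config(**kw):
    defaults = dict(
        n_animals=12, n_chromosomes=2, chrom_length=500_000,
        n_background_snps=60, n_planted_snps=4, genes_per_chromosome=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_temperature_series_shape_and_cold_spell():
    cfg = small_config(n_days=14, sampling_interval_min=60)
    cohort = simulate_temperature_series(cfg, seed=5)
    assert all(len(s.values) == 14 * 24 for s in cohort.series.values())
    assert len(cohort.series) == 12
    assert cohort.ambient.values.min() == pytest.approx(cfg.cold_spell_min_c)


def test_zero_noise_zero_sensitivity_gives_constant_baseline():
    cfg = small_config(
        in_ear_noise_sd=0.0, sensitivity_base=0.0, sensitivity_per_allele=0.0,
        sensitivity_sd=0.0,
    )
    cohort = simulate_temperature_series(cfg, seed=5)
    for s in cohort.series.values():
        assert np.allclose(s.values, cfg.baseline_temp_c)


def test_temperature_requires_six_days():
    with pytest.raises(InvalidConfigError):
        simulate_temperature_series(small_config(n_days=5), seed=1)


def test_temperature_csv_determinism(tmp_path):
    from coldrank.io import write_temperature_csv

    cfg = small_config()
    paths = []
    for tag in ("a", "b"):
        cohort = simulate_temperature_series(cfg, seed=99)
        p = tmp_path / f"temps_{tag}.csv"
        write_temperature_csv(list(cohort.series.values()), p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_dosage_lowers_auc(groups12):
    """Parameter recovery, sign only: planted-allele dosage raises cold
    sensitivity and so lowers the AUC phenotype when noise is low."""
    from coldrank.phenotype import compute_auc, compute_phenotypes, select_coldest_interval

    cfg = small_config(
        n_animals=60, in_ear_noise_sd=0.02, sensitivity_sd=0.0002
    )
    cohort = simulate_temperature_series(cfg, seed=21)
    interval = select_coldest_interval(cohort.ambient)
    phens = compute_phenotypes(cohort.series, interval, {})
    auc = {p.animal_id: p.auc for p in phens}
    dosage = dict(zip(cohort.animals["animal_id"], cohort.animals["causal_dosage"]))
    ids = sorted(auc)
    r = np.corrcoef([dosage[i] for i in ids], [auc[i] for i in ids])[0, 1]
    assert r < -0.9


def test_planted_afd_one_gives_fixed_opposite_groups(groups12):
    cfg = small_config(planted_afd=1.0, missing_genotype_rate=0.0)
    records, truth = simulate_genotypes(cfg, groups12, seed=3)
    truth_keys = set(zip(truth["chrom"], truth["pos"]))
    sens = [s for s in SAMPLES if groups12.group_of[s] == "sensitive"]
    for rec in records:
        if (rec.chrom, rec.pos) not in truth_keys:
            continue
        dosages = {
            s: rec.alt_dosage(i) for i, s in enumerate(rec.samples)
        }
        sens_d = {dosages[s] for s in sens}
        tol_d = {dosages[s] for s in SAMPLES if s not in sens}
        assert sens_d in ({0}, {2}) and tol_d in ({0}, {2})
        assert sens_d != tol_d


def test_zero_missing_rate_means_no_missing_calls(groups12):
    cfg = small_config(missing_genotype_rate=0.0)
    records, _ = simulate_genotypes(cfg, groups12, seed=3)
    assert all(gt is not None for rec in records for gt in rec.genotypes)


def test_failing_fraction_matches_binomial_expectation(genotype_run):
    cfg, records, truth, _ = genotype_run
    truth_keys = set(zip(truth["chrom"], truth["pos"]))
    background = [r for r in records if (r.chrom, r.pos) not in truth_keys]
    n_fail = sum(bool(failing_rules(r, FilterThresholds())) for r in background)
    assert binomtest(n_fail, len(background), cfg.fraction_failing_filters).pvalue > 1e-4


def test_planted_records_survive_hard_filters(genotype_run):
    _, records, truth, _ = genotype_run
    passing, _ = apply_hard_filters(records)
    surviving = {(r.chrom, r.pos) for r in passing}
    assert all((c, p) in surviving for c, p in zip(truth["chrom"], truth["pos"]))


def test_planted_signal_dominates_background(genotype_run, groups12):
    """At planted AFD ≥ 0.8 the planted loci's mean empirical |Δp| exceeds the
    background mean by at least 0.5 in the emitted VCF."""
    from coldrank.ranking import allele_freq_diff

    _, records, truth, _ = genotype_run
    truth_keys = set(zip(truth["chrom"], truth["pos"]))
    planted_afd, background_afd = [], []
    for rec in records:
        if not (rec.is_biallelic and rec.is_snp):
            continue
        afd = allele_freq_diff(rec, groups12)
        if afd is None:
            continue
        key = (rec.chrom, rec.pos)
        (planted_afd if key in truth_keys else background_afd).append(afd)
    assert np.mean(planted_afd) - np.mean(background_afd) >= 0.5


def test_faeth_enrichment_and_coverage(genotype_run, groups12):
    cfg, records, truth, faeth = genotype_run
    truth_keys = set(zip(truth["chrom"], truth["pos"]))
    covered = set(zip(faeth["chrom"], faeth["pos"]))
    assert truth_keys <= covered  # truth loci always scored
    n_bg_snps = sum(
        1 for r in records
        if r.is_biallelic and r.is_snp and (r.chrom, r.pos) not in truth_keys
    )
    n_bg_covered = len(covered) - len(truth_keys)
    assert binomtest(n_bg_covered, n_bg_snps, 1 - cfg.faeth_missing_rate).pvalue > 1e-4


def test_full_enrichment_puts_planted_scores_in_top_decile(groups12):
    cfg = small_config(faeth_enrichment=1.0, faeth_missing_rate=0.0,
                       n_background_snps=400)
    records, truth = simulate_genotypes(cfg, groups12, seed=8)
    faeth, truth = simulate_faeth_table(records, truth, cfg, seed=9)
    truth_keys = set(zip(truth["chrom"], truth["pos"]))
    bg = faeth[~faeth.set_index(["chrom", "pos"]).index.isin(truth_keys)]
    q90 = np.quantile(bg["score"], 0.9)
    assert (truth["faeth_score"] >= q90).all()
    # absent-fraction 0: every biallelic SNP in the VCF is covered
    n_snps = sum(r.is_biallelic and r.is_snp for r in records)
    assert len(faeth) == n_snps


def test_gene_models_translate_cleanly_on_both_strands():
    from Bio.Seq import Seq

    cfg = small_config(genes_per_chromosome=2)
    gtf_text, fasta = simulate_gene_models(cfg, seed=4)
    strands = set()
    for chrom, strand, cds in _cds_blocks(gtf_text):
        seq = "".join(fasta[chrom][s - 1 : e] for s, e in cds)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        protein = str(Seq(seq).translate())
        assert protein.startswith("M")
        assert protein.endswith("*")
        assert "*" not in protein[:-1]
        strands.add(strand)
    assert strands == {"+", "-"}


def _cds_blocks(gtf_text):
    blocks = {}
    for line in gtf_text.strip().split("\n"):
        f = line.split("\t")
        if f[2] != "CDS":
            continue
        tid = f[8].split('transcript_id "')[1].split('"')[0]
        blocks.setdefault((f[0], f[6], tid), []).append((int(f[3]), int(f[4])))
    return [(c, s, sorted(v)) for (c, s, _), v in blocks.items()]


def test_gene_models_deterministic():
    cfg = small_config()
    assert simulate_gene_models(cfg, seed=4) == simulate_gene_models(cfg, seed=4)


def test_vcf_round_trip(tmp_path, groups12):
    cfg = small_config()
    records, _ = simulate_genotypes(cfg, groups12, seed=3)
    path = tmp_path / "sim.vcf"
    write_vcf(records, path, config=cfg)
    back = read_vcf(str(path))
    assert len(back) == len(records)
    for orig, rt in zip(records, back):
        assert (rt.chrom, rt.pos, rt.ref, rt.alts) == (
            orig.chrom, orig.pos, orig.ref, orig.alts
        )
        assert rt.genotypes == orig.genotypes
        for k, v in orig.info.items():
            assert rt.info[k] == pytest.approx(v, abs=5e-4)


def test_demo_bundle_outputs_parse_with_standard_readers(demo_bundle):
    import gffutils
    from pyfaidx import Fasta

    bundle, outdir = demo_bundle
    records = read_vcf(str(outdir / "variants.vcf"))
    assert len(records) == len(bundle.records)
    series = read_temperature_csv(str(outdir / "in_ear_temperatures.csv"))
    assert len(series) == bundle.config.n_animals
    fasta = Fasta(str(outdir / "genome.fa"))
    assert set(fasta.keys()) == {"1", "2"}
    db = gffutils.create_db(
        str(outdir / "genes.gtf"), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    assert len(list(db.features_of_type("gene"))) == 4


def test_study_vcf_is_consistent_with_its_genome(demo_bundle):
    """Every emitted SNP's REF matches the emitted FASTA base, so candidates
    inside simulated genes annotate without consistency errors."""
    from pyfaidx import Fasta

    from coldrank.annotation import build_gene_index, classify_variant

    bundle, outdir = demo_bundle
    fasta = Fasta(str(outdir / "genome.fa"))
    for rec in bundle.records:
        assert str(fasta[rec.chrom][rec.pos - 1]).upper() == rec.ref[0]
    index = build_gene_index(str(outdir / "genes.gtf"))
    classes = set()
    for rec in bundle.records:
        if rec.is_biallelic and rec.is_snp:
            _, summary = classify_variant(rec, index, fasta)
            classes.add(summary.klass)
    assert "intergenic" in classes  # uniform placement: most SNPs are intergenic


def test_group_sizes_and_breed_balance_in_full_study(demo_bundle):
    bundle, _ = demo_bundle
    frame = bundle.groups.to_frame()
    assert frame.groupby("group").size().tolist() == [6, 6]
    counts = frame.groupby(["breed", "group"]).size().unstack(fill_value=0)
    assert (counts.max(axis=1) - counts.min(axis=1) <= 1).all()


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigError):
        SimulationConfig(planted_afd=1.5)
    with pytest.raises(InvalidConfigError):
        SimulationConfig(n_animals=0)
    with pytest.raises(InvalidConfigError):
        SimulationConfig(breeds=(("a", 0.7), ("b", 0.6)))
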