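# Methods

## Phenotype

The body-temperature-maintenance phenotype is the trapezoidal integral of an
animal's in-ear temperature (°C·h) over the coldest contiguous five-day
window of the ambient series. "Coldest" is the window with the lowest mean of
the raw ambient samples; candidate windows start at the midnight of each
observed calendar day (the contiguity and day alignment are modelling
choices — a sensor study reports whole cold days, and a sliding sub-day
window would shift the interval by at most hours). Ties break to the earliest
start. When samples straddle an interval boundary, the piecewise-linear
interpolant is evaluated at the boundary so the integral covers exactly the
interval. Series must hold at least two samples inside the interval; no gap
filling or sensor QC is attempted.

Higher AUC is read as better temperature maintenance, so the top-AUC animals
form the "tolerant" group and the bottom-AUC animals the "sensitive" group.
Breed balance (each breed's count differing by at most one between groups) is
enforced by a deterministic best-improvement swap search: starting from the
naive top/bottom split, the single member swap (with the unselected pool or
between groups) that reduces breed imbalance while sacrificing the least AUC
separation is applied until balanced. The search is greedy; tests compare it
against an exhaustive search over all balanced six-subsets at cohort sizes
where enumeration is feasible.

## Hard filtering

Five strict-inequality thresholds on caller-emitted INFO annotations
(QD < 2, MQ < 40, FS > 60, MQRankSum < −12.5, ReadPosRankSum < −8) remove
records; INDELs and multiallelic sites are then dropped. A record missing an
annotation never fails the corresponding rule — the rank-sum annotations are
undefined at sites without both allele classes, which carries no evidence of
a bad call. Removal counts attribute a record to every rule it violates.
Boundary values (e.g. QD = 2.0) pass. No MAF, Hardy–Weinberg or
genotype-level filtering is applied. The autosome restriction belongs to the
ranking stage, keeping the filter module general.

## F_ST

Per-site differentiation uses the two-population Weir–Cockerham (1984) moment
estimator. With r = 2 groups, nᵢ called individuals, pᵢ reference-allele
frequencies and hᵢ observed heterozygote proportions:

    n̄ = Σnᵢ/r        n_c = (r·n̄ − Σnᵢ²/(r·n̄))/(r−1)
    p̄ = Σnᵢpᵢ/(r·n̄)   s² = Σnᵢ(pᵢ−p̄)²/((r−1)·n̄)   h̄ = Σnᵢhᵢ/(r·n̄)
    a = (n̄/n_c)·[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))·[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
    c = h̄/2          θ = a/(a+b+c)

Negative components and negative θ are retained, not clamped — downstream
ranking consumes the estimator's raw values. θ is undefined (NaN, flagged)
when a+b+c = 0, i.e. at sites monomorphic across the pooled sample; such
sites are excluded from windows and single-site outputs. Only r = 2 is
supported; more groups are rejected rather than silently generalized. A
fixed difference with six diploids per group gives a = 0.5, b = c = 0, θ = 1
exactly.

Windows of 50 kb stepped by 25 kb are anchored at position 1 of each
chromosome (half-open arithmetic internally, reported 1-based inclusive), so
interior positions fall in exactly two tiles. A window's weighted θ is
Σa/Σ(a+b+c) over its sites — the ratio-of-sums form vcftools reports — and
its mean θ the average of defined per-site values; empty windows are
omitted, and no minimum SNP count per window is imposed. A SNP's window-level
F_ST value is the maximum weighted θ among the windows covering it.

## Rank integration

Each evidence source becomes a fractional rank: values sorted descending,
rank = (average ordinal position among ties − 1)/(N − 1), so the highest
value ranks exactly 0 and the lowest exactly 1 (a single value ranks 0).
Average-position tie handling and the (N−1) normalization were chosen so the
endpoints are attained exactly.

The three universes deliberately differ, mirroring how the evidence is
available in practice: AFD ranks are computed over all autosomal biallelic
SNPs with ≥ 3 called genotypes per group; the F_ST and functional-score
ranks, and the final table, are restricted to the subset of those SNPs that
carry a functional annotation. SNPs without an annotation therefore shape the
AFD denominator but drop out of the output. AFD is the absolute difference —
candidate deviations run in both directions. The F_ST rank normalizes by
default within the SNP universe (each SNP ranked by its best window's value);
a `fst_rank_universe="windows"` switch instead assigns each SNP its best
window's fractional rank among windows. The two normalizations order SNPs
identically and the SNP-universe form is the default because it yields one
rank scale shared by all three evidence sources. Selection is the strict
inequality rank sum < 0.1 (threshold exposed); selection count is
non-decreasing in the threshold, and any strictly increasing transform of the
functional scores leaves all ranks unchanged.

## Consequence annotation

A lightweight classifier over an Ensembl-dialect GTF and genome FASTA
assigns each SNP–transcript pair one most-severe class with severity order
stop_gained > stop_lost > missense > splice_region > synonymous > UTR >
intron > upstream/downstream > intergenic. Coding calls extract the codon in
translation order (strand- and splice-aware), verify the reference base
against the FASTA (a mismatch is an error naming the transcript), substitute
the alternate allele and translate. Splice regions follow the Ensembl
convention — 1–3 exonic or 3–8 intronic bases from a splice site — with the
2-base donor/acceptor sites collapsed into splice_region rather than reported
separately. UTRs are derived as exon minus CDS (explicit UTR features are not
required), 5′ vs 3′ resolved by strand. Gene flanks default to 5 kb on each
side. Only one annotation source (a single GTF) is used; transcript sets
from different providers can yield different classes for the same SNP.

## Synthetic data

The generator emulates the study conditions: 200 animals recorded for 14
winter days at 60-minute intervals, with one contiguous five-day spell whose
minimum reaches −32 °C exactly; two breeds at 7:5 proportions; six sequenced
animals per contrast group; genome-wide biallelic SNPs with a small fraction
of INDELs, INFO values straddling every hard-filter threshold, 5% missing
genotypes, and 20 planted loci whose group frequencies differ by at least
0.8. Every output is a pure function of (config, seed).

In-ear temperature is `baseline − sᵢ·max(0, threshold − ambient) + noise`
with the cold-sensitivity coefficient sᵢ linear in the animal's dosage at a
designated causal locus plus a polygenic term (defaults: baseline 38.5 °C,
stress threshold −10 °C, base sensitivity 0.004 °C/°C, 0.006 per allele,
polygenic SD 0.002, sensor noise SD 0.25 °C). These magnitudes make the
between-group AUC gap a few tens of °C·h over a five-day spell — comparable
to sensor noise per sample but well resolved after integration.

Genotypes are binomial draws from group allele frequencies (Hardy–Weinberg
within groups), the simplest model consistent with per-group frequencies;
sites are independent — no linkage disequilibrium is simulated. Because of
that, the default SNP density is ~1 per 25 kb (10,020 SNPs on two 125 Mb
chromosomes): a single divergent locus must dominate its 50 kb window the way
an LD block of divergent SNPs does in real data, which at realistic density a
lone independent SNP cannot. Consequently, passing tests demonstrate that
the windowed scan finds isolated strong signals, not that it would resolve
real LD structure. Caller-artifact features — filter-failing INFO values,
INDEL status and absence from the functional-score table — are applied to
background records only: planted loci model true biological signals, whereas
those features model technical noise. Functional scores are lognormal
(heavy-tailed, like per-variant heritability contributions); an enriched
planted SNP draws uniformly between the empirical 90th percentile and the
maximum of the background scores, and 45% of background SNPs lack a score,
mirroring the roughly half-annotated SNP universe such tables cover.

The causal phenotype locus is not planted: its VCF genotypes are the
sequenced animals' actual dosages, so its between-group divergence emerges
from the extreme-group selection itself. Recovery statistics are computed on
the planted loci only.

Toy gene models place three-exon protein-coding genes on alternating strands
with UTRs, intergenic gaps and a valid CDS (ATG start, no internal in-frame
stop, terminal stop codon); in this GTF dialect the CDS intervals include the
stop codon. The genome FASTA is emitted only for configurations totalling
≤ 20 Mb (the `demo()` preset: 2 × 1.25 Mb at unchanged SNP density), and the
emitted VCF is reconciled against it so REF always matches the genome.

## Numerical and scale choices

Analysis drivers run at the reduced demo scale so a full study, including
the genome FASTA, regenerates in seconds; the recovery property (≥ 90% of
planted loci selected at rank sum < 0.1, averaged over seeds 1–10) is
asserted at the full 10,000-background-SNP scale in the test suite. At demo
scale fractional ranks are coarse (~1/39 granularity), so the absolute 0.1
threshold is conservative even when all planted loci lead the ranking —
fractional thresholds interact with universe size, a caveat that applies to
any rank-sum selection on small SNP panels. Oracle agreement for the
estimator is asserted to 1e-12 against an independently transcribed
evaluation of the component formulas; AUC refinement agreement to 1e-6
relative. Determinism relies on seeded numpy generators with spawned
substreams per output; identical (config, seed) reproduce byte-identical
CSV/VCF/GTF/FASTA files.

## Limitations

- No LD, so window statistics behave like collections of independent sites.
- The phenotype model is a single major locus plus polygenic noise; it exists
  to make parameter-recovery testable, not to mimic quantitative-genetic
  architecture.
- The functional score is consumed as given; its construction is out of
  scope.
- The annotation module classifies consequences only (no regulatory classes,
  protein features or variant-identifier lookup).
- Group sizes of six diploids make per-site θ extremely noisy; this package
  deliberately preserves that behaviour (including negative estimates)
  rather than shrinking or clamping.
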