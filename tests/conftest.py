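"""Shared fixtures: a 2x6 group spec, a demo study bundle, and a hand-built
two-gene toy genome with an independently constructed consequence truth map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from Bio.Seq import Seq

from coldrank.phenotype import GroupSpec
from coldrank.simulate import SimulationConfig, simulate_study

SAMPLES = tuple(f"S{i:02d}" for i in range(12))

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


@pytest.fixture(scope="session")
def groups12() -> GroupSpec:
    return GroupSpec(
        group_of={
            s: ("sensitive" if i < 6 else "tolerant")
            for i, s in enumerate(SAMPLES)
        },
        breed_of={
            s: ("hereford" if i % 2 else "kazakh_whiteheaded") for i, s in enumerate(SAMPLES)
        },
    )


GOOD_INFO = {"QD": 25.0, "MQ": 55.0, "FS": 3.0, "MQRankSum": 0.5,
             "ReadPosRankSum": -0.2}

#: hard-filter survivors of the ten-record fixture, by position
FILTER_FIXTURE_SURVIVORS = [100, 600, 700, 800, 900, 1000]


def make_filter_fixture():
    """Ten VCF records with one hand-constructed violation per hard-filter
    rule, one boundary-value record, an INDEL, a multiallelic site and two
    records with (partially) missing INFO."""
    from coldrank.io import VariantRecord

    def rec(pos, ref="A", alts=("G",), info=None):
        return VariantRecord(chrom="1", pos=pos, ref=ref, alts=alts,
                             info=info or {}, genotypes=[(0, 1)] * 12,
                             samples=SAMPLES)

    return [
        rec(100, info=dict(GOOD_INFO)),                                # passes
        rec(200, info={**GOOD_INFO, "QD": 1.9}),                       # fails QD
        rec(300, info={**GOOD_INFO, "MQ": 39.0}),                      # fails MQ
        rec(400, info={**GOOD_INFO, "FS": 61.0}),                      # fails FS
        rec(500, info={**GOOD_INFO, "MQRankSum": -13.0,
                       "ReadPosRankSum": -9.0}),                       # fails 2
        rec(600, info={"QD": 2.0, "MQ": 40.0, "FS": 60.0,
                       "MQRankSum": -12.5, "ReadPosRankSum": -8.0}),   # boundary
        rec(700, ref="A", alts=("AT",), info=dict(GOOD_INFO)),         # INDEL
        rec(800, ref="C", alts=("T", "G"), info=dict(GOOD_INFO)),      # multiallelic
        rec(900, info={}),                                             # no INFO
        rec(1000, info={"QD": 30.0}),                                  # partial
    ]


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("demo_study")
    bundle = simulate_study(SimulationConfig.demo(), seed=7, outdir=str(outdir))
    return bundle, outdir


# ---------------------------------------------------------------------------
# hand-built toy genome: one forward and one reverse gene on chromosome "T"


@dataclass(frozen=True)
class ToyGene:
    gene_id: str
    strand: str
    exons: tuple  # 1-based inclusive
    cds: tuple
    utr5: tuple
    utr3: tuple

    @property
    def start(self):
        return self.exons[0][0]

    @property
    def end(self):
        return self.exons[-1][1]


GENE_A = ToyGene(
    gene_id="GA",
    strand="+",
    exons=((12001, 12100), (12401, 12520), (12901, 13100)),
    cds=((12031, 12100), (12401, 12520), (12901, 12992)),
    utr5=(12001, 12030),
    utr3=(12993, 13100),
)
GENE_B = ToyGene(
    gene_id="GB",
    strand="-",
    exons=((26001, 26200), (26701, 26900), (27201, 27400)),
    cds=((26101, 26200), (26701, 26900), (27201, 27341)),
    utr5=(27342, 27400),
    utr3=(26001, 26100),
)
TOY_CHROM = "T"
TOY_LENGTH = 34_000
TOY_FLANK = 5_000

SEVERITY_ORDER = (
    "stop_gained", "stop_lost", "missense", "splice_region", "synonymous",
    "5'UTR", "3'UTR", "intron", "upstream", "downstream", "intergenic",
)


def _sense_codons(rng: np.random.Generator, n: int) -> str:
    bases = np.array(list("ACGT"))
    out = []
    while len(out) < n:
        c = "".join(rng.choice(bases, 3))
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def cds_positions(gene: ToyGene) -> list[int]:
    pos = [p for s, e in gene.cds for p in range(s, e + 1)]
    return pos if gene.strand == "+" else pos[::-1]


def build_toy_sequence(seed: int = 42) -> str:
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(np.array(list("ACGT")), TOY_LENGTH)))
    for gene in (GENE_A, GENE_B):
        positions = cds_positions(gene)
        n_codons = len(positions) // 3
        codons = "ATG" + _sense_codons(rng, n_codons - 2) + "TAA"
        # write bases so that reading `positions` in translation order (and
        # complementing on '-') reproduces `codons`
        for p, b in zip(positions, codons):
            seq[p - 1] = b if gene.strand == "+" else b.translate(_COMP)
    return "".join(seq)


def toy_gtf_text() -> str:
    lines = []
    for gene in (GENE_A, GENE_B):
        attrs = (
            f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1"; '
            f'gene_name "{gene.gene_id}";'
        )
        gattrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_id}";'

        def row(feature, s, e, frame=".", a=attrs):
            return (
                f"{TOY_CHROM}\ttest\t{feature}\t{s}\t{e}\t.\t{gene.strand}\t"
                f"{frame}\t{a}"
            )

        lines.append(row("gene", gene.start, gene.end, a=gattrs))
        lines.append(row("transcript", gene.start, gene.end))
        for s, e in gene.exons:
            lines.append(row("exon", s, e))
        order = gene.cds if gene.strand == "+" else gene.cds[::-1]
        consumed = 0
        for s, e in order:
            frame = (3 - consumed % 3) % 3
            lines.append(row("CDS", s, e, str(frame)))
            consumed += e - s + 1
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy_genome")
    seq = build_toy_sequence()
    gtf = d / "toy.gtf"
    fasta = d / "toy.fa"
    gtf.write_text(toy_gtf_text())
    with open(fasta, "w") as fh:
        fh.write(f">{TOY_CHROM}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    return {"gtf": str(gtf), "fasta": str(fasta), "seq": seq}


# ---------------------------------------------------------------------------
# independent truth map for the toy genome


def _splice_positions(gene: ToyGene) -> set[int]:
    """Literal splice-region bands: 1-3 exonic / 1-8 intronic bases from each
    internal exon boundary."""
    out: set[int] = set()
    exons = gene.exons
    for i, (s, e) in enumerate(exons):
        if i > 0:  # boundary at exon start (intron precedes)
            out.update(range(s, s + 3))  # exonic 1-3
            out.update(range(s - 8, s))  # intronic 1-8
        if i < len(exons) - 1:  # boundary at exon end
            out.update(range(e - 2, e + 1))
            out.update(range(e + 1, e + 9))
    return out


def _coding_class(gene: ToyGene, pos: int, alt: str, seq: str) -> str:
    positions = cds_positions(gene)
    idx = positions.index(pos)
    codon_pos = positions[(idx // 3) * 3 : (idx // 3) * 3 + 3]
    ref_codon = "".join(seq[p - 1] for p in codon_pos)
    alt_codon = list(ref_codon)
    alt_codon[codon_pos.index(pos)] = alt
    alt_codon = "".join(alt_codon)
    if gene.strand == "-":
        ref_codon = ref_codon.translate(_COMP)
        alt_codon = alt_codon.translate(_COMP)
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*":
        return "stop_lost"
    return "missense"


def toy_truth_class(pos: int, alt: str, seq: str) -> str:
    """Expected summary consequence at a toy-genome position (independent of
    the package's annotation machinery)."""
    candidates = []
    for gene in (GENE_A, GENE_B):
        if gene.start <= pos <= gene.end:
            splice = pos in _splice_positions(gene)
            in_cds = any(s <= pos <= e for s, e in gene.cds)
            in_exon = any(s <= pos <= e for s, e in gene.exons)
            if in_cds:
                base = _coding_class(gene, pos, alt, seq)
            elif in_exon:
                if gene.utr5[0] <= pos <= gene.utr5[1]:
                    base = "5'UTR"
                else:
                    base = "3'UTR"
            else:
                base = "intron"
            if splice:
                candidates.append(
                    min(("splice_region", base), key=SEVERITY_ORDER.index)
                )
            else:
                candidates.append(base)
        elif gene.start - TOY_FLANK <= pos < gene.start:
            candidates.append("upstream" if gene.strand == "+" else "downstream")
        elif gene.end < pos <= gene.end + TOY_FLANK:
            candidates.append("downstream" if gene.strand == "+" else "upstream")
    if not candidates:
        return "intergenic"
    return min(candidates, key=SEVERITY_ORDER.index)
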