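"""Gene-context and coding-consequence classification of SNPs.

A lightweight consequence caller over an Ensembl-dialect GTF and a genome
FASTA: every SNP–transcript pair gets one most-severe class out of
missense / synonymous / stop_gained / stop_lost / splice_region / intron /
5'UTR / 3'UTR / upstream / downstream / intergenic, with the amino-acid
change reported for coding classes. Splice regions follow the Ensembl
convention (1–3 exonic or 1–8 intronic bases from a splice site, with the
2-base donor/acceptor collapsed into splice_region). UTRs are derived from
exon minus CDS so the GTF does not need explicit UTR features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import ConsistencyError, ParseError
from .io import VariantRecord

SEVERITY = (
    "stop_gained",
    "stop_lost",
    "missense",
    "splice_region",
    "synonymous",
    "5'UTR",
    "3'UTR",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {c: i for i, c in enumerate(SEVERITY)}

SPLICE_EXONIC = 3  # exonic bases from an internal splice site
SPLICE_INTRONIC = 8  # intronic bases from a splice site

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted
    cds: list[tuple[int, int]]  # sorted; includes the stop codon

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def spliced_cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in translation order."""
        pos = [p for s, e in self.cds for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass
class Consequence:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_name: Optional[str]
    transcript_id: Optional[str]
    klass: str
    aa_change: Optional[str] = None


class GeneIndex:
    """Interval index over gene spans (± flank) supporting point queries."""

    def __init__(self, genes: list[GeneModel], flank: int = 5000):
        self.flank = flank
        self.genes = genes
        self._trees: dict[str, IntervalTree] = {}
        for gene in genes:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            # half-open interval arithmetic over 1-based inclusive coordinates
            tree[max(1, gene.start - flank) : gene.end + flank + 1] = gene

    def query(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[pos]]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))


def build_gene_index(gtf_path: str, flank: int = 5000) -> GeneIndex:
    """Parse a GTF into GeneModel objects indexed for point queries."""
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"cannot parse GTF {gtf_path}: {exc}") from exc

    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="transcript"):
            exons = sorted(
                (f.start, f.end) for f in db.children(t, featuretype="exon")
            )
            cds = sorted(
                (f.start, f.end) for f in db.children(t, featuretype="CDS")
            )
            transcripts.append(
                Transcript(
                    transcript_id=t.id, strand=t.strand, exons=exons, cds=cds
                )
            )
        if not transcripts:
            continue
        gene_name = g.attributes.get("gene_name", [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                gene_name=gene_name,
                chrom=g.seqid,
                strand=g.strand,
                transcripts=transcripts,
            )
        )
    return GeneIndex(genes, flank=flank)


def _codon_consequence(
    tx: Transcript, chrom: str, pos: int, ref: str, alt: str, fasta
) -> tuple[str, str]:
    """Class and amino-acid change for a SNP inside the (stop-inclusive) CDS."""
    spliced = tx.spliced_cds_positions()
    offset = spliced.index(pos)
    codon_idx = offset // 3
    codon_pos = spliced[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_pos) < 3:
        raise ConsistencyError(
            f"CDS length of {tx.transcript_id} not a codon multiple"
        )

    def base_at(p: int) -> str:
        b = str(fasta[chrom][p - 1 : p]).upper()
        return b

    genome_ref = base_at(pos)
    if genome_ref != ref.upper():
        raise ConsistencyError(
            f"reference mismatch at {chrom}:{pos}: FASTA has {genome_ref}, "
            f"VCF has {ref} ({tx.transcript_id})"
        )
    codon = [base_at(p) for p in codon_pos]
    alt_codon = list(codon)
    alt_codon[codon_pos.index(pos)] = alt.upper()
    if tx.strand == "-":
        codon = [b.translate(_COMPLEMENT) for b in codon]
        alt_codon = [b.translate(_COMPLEMENT) for b in alt_codon]
    aa_ref = str(Seq("".join(codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    aa_change = f"{aa_ref}{codon_idx + 1}{aa_alt}"
    if aa_ref == aa_alt:
        return "synonymous", aa_change
    if aa_alt == "*":
        return "stop_gained", aa_change
    if aa_ref == "*":
        return "stop_lost", aa_change
    return "missense", aa_change


def _splice_region_hit(tx: Transcript, pos: int) -> bool:
    """True when pos lies within the splice-region bands of an internal
    exon/intron boundary."""
    for i, (s, e) in enumerate(tx.exons):
        if s <= pos <= e:
            if i > 0 and pos - s + 1 <= SPLICE_EXONIC:
                return True
            if i < len(tx.exons) - 1 and e - pos + 1 <= SPLICE_EXONIC:
                return True
    for (_, prev_end), (next_start, _) in zip(tx.exons, tx.exons[1:]):
        if prev_end < pos < next_start:
            dist = min(pos - prev_end, next_start - pos)
            if dist <= SPLICE_INTRONIC:
                return True
    return False


def _transcript_consequence(
    gene: GeneModel, tx: Transcript, chrom: str, pos: int, ref: str, alt: str,
    fasta, flank: int,
) -> Optional[Consequence]:
    mk = lambda klass, aa=None: Consequence(  # noqa: E731
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene_name=gene.gene_name,
        transcript_id=tx.transcript_id, klass=klass, aa_change=aa,
    )
    if tx.start <= pos <= tx.end:
        in_exon = any(s <= pos <= e for s, e in tx.exons)
        splice = _splice_region_hit(tx, pos)
        if in_exon:
            in_cds = any(s <= pos <= e for s, e in tx.cds)
            if in_cds:
                klass, aa = _codon_consequence(tx, chrom, pos, ref, alt, fasta)
                if splice and _RANK["splice_region"] < _RANK[klass]:
                    return mk("splice_region", aa)
                return mk(klass, aa)
            if splice:
                return mk("splice_region")
            # exonic non-CDS: UTR side determined by strand
            cds_lo = tx.cds[0][0]
            cds_hi = tx.cds[-1][1]
            if pos < cds_lo:
                return mk("5'UTR" if tx.strand == "+" else "3'UTR")
            if pos > cds_hi:
                return mk("3'UTR" if tx.strand == "+" else "5'UTR")
            return mk("intron")  # unreachable for well-formed models
        return mk("splice_region" if splice else "intron")
    # flanking
    if tx.start - flank <= pos < tx.start:
        return mk("upstream" if tx.strand == "+" else "downstream")
    if tx.end < pos <= tx.end + flank:
        return mk("downstream" if tx.strand == "+" else "upstream")
    return None


def classify_variant(
    record: VariantRecord, index: GeneIndex, fasta, flank: Optional[int] = None
) -> tuple[list[Consequence], Consequence]:
    """All per-transcript consequences plus the most severe summary call.

    Severity ties are resolved toward the transcript whose gene starts first
    (then by gene id), making the summary deterministic.
    """
    flank = index.flank if flank is None else flank
    chrom, pos, ref, alt = record.chrom, record.pos, record.ref, record.alt
    consequences: list[Consequence] = []
    for gene in index.query(chrom, pos):
        for tx in gene.transcripts:
            cons = _transcript_consequence(
                gene, tx, chrom, pos, ref, alt, fasta, flank
            )
            if cons is not None:
                consequences.append(cons)
    if not consequences:
        summary = Consequence(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene_name=None, transcript_id=None, klass="intergenic",
        )
        return [], summary
    summary = min(consequences, key=lambda c: _RANK[c.klass])
    return consequences, summary


def annotate_table(ranked, gtf_path: str, fasta_path: str, flank: int = 5000):
    """Add gene_name / consequence / aa_change columns to a ranked SNP table."""
    from pyfaidx import Fasta

    index = build_gene_index(gtf_path, flank=flank)
    fasta = Fasta(str(fasta_path))
    genes, classes, aa_changes = [], [], []
    for row in ranked.itertuples(index=False):
        rec = VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos),
            ref=row.ref, alts=(row.alt,),
        )
        _, summary = classify_variant(rec, index, fasta, flank=flank)
        genes.append(summary.gene_name or "")
        classes.append(summary.klass)
        aa_changes.append(summary.aa_change or "")
    out = ranked.copy()
    out["gene_name"] = genes
    out["consequence"] = classes
    out["aa_change"] = aa_changes
    return out
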