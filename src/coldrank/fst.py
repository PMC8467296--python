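"""Weir–Cockerham (1984) F_ST between two groups, per site and in windows.

The per-site estimator decomposes allele-frequency variance into three
moment components: ``a`` (between populations), ``b`` (between individuals
within populations) and ``c`` (within individuals, i.e. heterozygosity), with
θ = a / (a + b + c). Windowed values use the "weighted" ratio-of-sums form
Σa / Σ(a+b+c) over the sites in each window, which is how vcftools reports
windowed F_ST; negative per-site estimates are retained, not clamped.

Only the two-population case is supported (r = 2); the pipeline contrasts a
cold-sensitive with a cold-tolerant group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import DegenerateSampleError, InvalidConfigError, MissingWindowError
from .io import VariantRecord
from .phenotype import GroupSpec


@dataclass(frozen=True)
class SiteGroupCounts:
    """Per-group summary of one biallelic site.

    ``n`` individuals with called genotypes, ``p`` reference-allele frequency
    among called alleles, ``h`` observed heterozygote proportion.
    """

    n1: int
    p1: float
    h1: float
    n2: int
    p2: float
    h2: float

    def __post_init__(self) -> None:
        for n, p, h in ((self.n1, self.p1, self.h1), (self.n2, self.p2, self.h2)):
            if n < 1:
                raise DegenerateSampleError("each group needs ≥ 1 called genotype")
            if not (0.0 <= p <= 1.0 and 0.0 <= h <= 1.0):
                raise ValueError("p and h must lie in [0, 1]")


@dataclass(frozen=True)
class FstComponents:
    """Variance components and derived θ for one site (r = 2 populations)."""

    a: float
    b: float
    c: float
    theta: float  # NaN when a + b + c == 0
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta)

    @property
    def denom(self) -> float:
        return self.a + self.b + self.c


@dataclass(frozen=True)
class WindowFst:
    """Weighted and mean F_ST of one genomic window (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    weighted_theta: float
    mean_theta: float


def site_group_counts(record: VariantRecord, groups: GroupSpec) -> SiteGroupCounts:
    """Summarize called genotypes of a biallelic site per contrast group."""
    stats = {}
    for label in groups.labels:
        n = het = ref_alleles = 0
        for sample, gt in zip(record.samples, record.genotypes):
            if groups.group_of.get(sample) != label or gt is None:
                continue
            n += 1
            ref_alleles += (gt[0] == 0) + (gt[1] == 0)
            het += gt[0] != gt[1]
        if n == 0:
            raise DegenerateSampleError(
                f"group {label!r} fully missing at {record.chrom}:{record.pos}"
            )
        stats[label] = (n, ref_alleles / (2 * n), het / n)
    g1, g2 = groups.labels
    return SiteGroupCounts(
        n1=stats[g1][0], p1=stats[g1][1], h1=stats[g1][2],
        n2=stats[g2][0], p2=stats[g2][1], h2=stats[g2][2],
    )


def site_fst(counts: SiteGroupCounts) -> FstComponents:
    """Weir–Cockerham variance components and θ for one biallelic site."""
    r = 2
    n1, n2 = counts.n1, counts.n2
    p1, p2 = counts.p1, counts.p2
    h1, h2 = counts.h1, counts.h2

    n_bar = (n1 + n2) / r
    if n_bar <= 1:
        raise DegenerateSampleError("mean sample size must exceed 1")
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0.0 else math.nan
    return FstComponents(
        a=a, b=b, c=c, theta=theta,
        n_bar=n_bar, n_c=n_c, p_bar=p_bar, s2=s2, h_bar=h_bar,
    )


def fst_scan(
    records: list[VariantRecord], groups: GroupSpec, min_called: int = 1
) -> pd.DataFrame:
    """Per-site components over a VCF: columns chrom, pos, a, b, c, theta.

    Sites where a group has fewer than ``min_called`` called genotypes (or
    none at all) are skipped. θ is NaN at sites monomorphic across the pooled
    sample.
    """
    from .variant_filter import called_counts

    rows = []
    for rec in records:
        counts = called_counts(rec, groups)
        if any(v < max(min_called, 1) for v in counts.values()):
            continue
        comp = site_fst(site_group_counts(rec, groups))
        rows.append(
            {"chrom": rec.chrom, "pos": rec.pos,
             "a": comp.a, "b": comp.b, "c": comp.c, "theta": comp.theta}
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "a", "b", "c", "theta"])


def window_starts(pos: int, window_size: int, step: int) -> list[int]:
    """1-based start coordinates of every window containing ``pos``.

    Windows tile the chromosome from position 1 with the given step, so a
    position interior to the tiling is covered by ``window_size // step``
    overlapping windows.
    """
    first_idx = max(0, -(-(pos - window_size) // step))  # ceil division
    starts = []
    idx = first_idx
    while idx * step + 1 <= pos:
        starts.append(idx * step + 1)
        idx += 1
    return starts


def windowed_fst(
    site_components: pd.DataFrame,
    window_size: int = 50_000,
    step: int = 25_000,
) -> list[WindowFst]:
    """Sliding-window weighted F_ST from a per-site component table.

    Each site contributes its (a, a+b+c) pair to every window containing its
    position; ``weighted_theta`` is Σa / Σ(a+b+c) and ``mean_theta`` the
    average of defined per-site θ. Sites with undefined θ (monomorphic pooled
    sample) contribute to neither. Empty windows are omitted.
    """
    if step > window_size:
        raise InvalidConfigError("window step must not exceed window size")
    acc: dict[tuple[str, int], list[float]] = {}
    df = site_components.dropna(subset=["theta"])
    for row in df.itertuples(index=False):
        denom = row.a + row.b + row.c
        for start in window_starts(int(row.pos), window_size, step):
            key = (row.chrom, start)
            slot = acc.setdefault(key, [0.0, 0.0, 0.0, 0])
            slot[0] += row.a
            slot[1] += denom
            slot[2] += row.theta
            slot[3] += 1
    windows = []
    for (chrom, start), (sum_a, sum_d, sum_t, n) in sorted(acc.items()):
        windows.append(
            WindowFst(
                chrom=chrom,
                start=start,
                end=start + window_size - 1,
                n_sites=n,
                weighted_theta=sum_a / sum_d if sum_d != 0.0 else math.nan,
                mean_theta=sum_t / n,
            )
        )
    return windows


def windows_to_frame(windows: list[WindowFst]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": w.chrom, "start": w.start, "end": w.end,
             "n_sites": w.n_sites, "weighted_theta": w.weighted_theta,
             "mean_theta": w.mean_theta}
            for w in windows
        ],
        columns=["chrom", "start", "end", "n_sites", "weighted_theta", "mean_theta"],
    )


def snp_window_value(
    chrom: str, pos: int, windows: list[WindowFst]
) -> float:
    """The highest weighted θ among the windows covering a SNP position."""
    best: Optional[float] = None
    for w in windows:
        if w.chrom == chrom and w.start <= pos <= w.end:
            if not math.isnan(w.weighted_theta):
                if best is None or w.weighted_theta > best:
                    best = w.weighted_theta
    if best is None:
        raise MissingWindowError(f"no window with data covers {chrom}:{pos}")
    return best


def snp_window_values(
    positions: pd.DataFrame, windows: list[WindowFst]
) -> pd.Series:
    """Vectorized :func:`snp_window_value` for a (chrom, pos) frame.

    Returns NaN for SNPs covered by no window with data.
    """
    by_chrom: dict[str, list[WindowFst]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    out = []
    for row in positions.itertuples(index=False):
        ws = by_chrom.get(row.chrom, [])
        vals = [
            w.weighted_theta
            for w in ws
            if w.start <= row.pos <= w.end and not math.isnan(w.weighted_theta)
        ]
        out.append(max(vals) if vals else math.nan)
    return pd.Series(out, index=positions.index, dtype=float)
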