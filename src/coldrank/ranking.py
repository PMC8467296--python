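"""Three-way fractional-rank integration and candidate SNP selection.

Each SNP carries three pieces of evidence: the weighted F_ST of its
higher-valued overlapping window, the absolute allele-frequency difference
(AFD) between the contrast groups, and a per-SNP functional (FAETH-style)
score. Each is converted to a fractional rank in [0, 1] — the highest value
maps to 0, the lowest to 1 — within its own ranking universe, the three ranks
are summed, and SNPs with a rank sum below the threshold (default 0.1) are
selected as candidates.

The universes deliberately differ, mirroring how the evidence is available:
AFD ranks are computed over every autosomal SNP with at least ``min_called``
genotypes per group, while the final table (and the FAETH rank universe) is
restricted to the subset of those SNPs that have a FAETH annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidInputError
from .fst import WindowFst, snp_window_values
from .io import VariantRecord
from .phenotype import GroupSpec
from .variant_filter import called_counts


@dataclass(frozen=True)
class RankedSnp:
    chrom: str
    pos: int
    ref: str
    alt: str
    window_fst_value: float
    afd: float
    faeth: float
    r_fst: float
    r_afd: float
    r_faeth: float
    rank_sum: float
    selected: bool


def fractional_ranks(values) -> np.ndarray:
    """Descending fractional ranks in [0, 1]: highest value → 0, lowest → 1.

    Ties take the average ordinal position; a single value ranks 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot rank an empty value list")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("rank input must be finite")
    if arr.size == 1:
        return np.zeros(1)
    ordinal = rankdata(-arr, method="average")  # 1 = highest value
    return (ordinal - 1.0) / (arr.size - 1.0)


def is_autosome(chrom: str) -> bool:
    """True for numeric chromosome labels (with or without a 'chr' prefix)."""
    label = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return label.isdigit()


def allele_freq_diff(
    record: VariantRecord, groups: GroupSpec, min_called: int = 3
) -> Optional[float]:
    """|p_group1 − p_group2| over called reference alleles, or None.

    None (exclusion, not an error) when the chromosome is non-autosomal or
    either group has fewer than ``min_called`` called genotypes.
    """
    if not is_autosome(record.chrom):
        return None
    counts = called_counts(record, groups)
    if any(v < min_called for v in counts.values()):
        return None
    freqs = {}
    for label in groups.labels:
        ref = total = 0
        for sample, gt in zip(record.samples, record.genotypes):
            if groups.group_of.get(sample) != label or gt is None:
                continue
            ref += (gt[0] == 0) + (gt[1] == 0)
            total += 2
        freqs[label] = ref / total
    g1, g2 = groups.labels
    return abs(freqs[g1] - freqs[g2])


def assemble_ranks(
    records: list[VariantRecord],
    windows: list[WindowFst],
    faeth: pd.DataFrame,
    groups: GroupSpec,
    threshold: float = 0.1,
    min_called: int = 3,
    fst_rank_universe: str = "snps",
) -> pd.DataFrame:
    """Build the ranked candidate table.

    ``fst_rank_universe`` selects the denominator of the F_ST rank:
    ``"snps"`` (default) ranks every SNP by its higher-valued window's
    weighted θ within the SNP universe; ``"windows"`` ranks the windows
    themselves and gives each SNP its best window's fractional rank (so SNPs
    sharing a window share a rank value). Both orderings agree.

    Returns a DataFrame sorted by ascending rank_sum (ties by chrom, pos)
    with one row per autosomal, min-called, FAETH-annotated SNP.
    """
    if fst_rank_universe not in ("snps", "windows"):
        raise InvalidInputError(f"unknown fst_rank_universe {fst_rank_universe!r}")

    rows = []
    for rec in records:
        afd = allele_freq_diff(rec, groups, min_called=min_called)
        if afd is None:
            continue
        rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
             "afd": afd}
        )
    if not rows:
        raise InvalidInputError("no autosomal SNP passes the min-called filter")
    afd_universe = pd.DataFrame(rows)
    # AFD ranks are fractional within the full min-called autosomal universe,
    # before the FAETH restriction shrinks the table.
    afd_universe["r_afd"] = fractional_ranks(afd_universe["afd"].to_numpy())

    faeth = faeth.copy()
    faeth["chrom"] = faeth["chrom"].astype(str)
    merged = afd_universe.merge(
        faeth[["chrom", "pos", "score"]], on=["chrom", "pos"], how="inner"
    )
    if merged.empty:
        raise InvalidInputError("no ranked SNP has a FAETH annotation")
    merged = merged.rename(columns={"score": "faeth"})
    merged["r_faeth"] = fractional_ranks(merged["faeth"].to_numpy())

    merged["window_fst_value"] = snp_window_values(
        merged[["chrom", "pos"]], windows
    )
    covered = merged.dropna(subset=["window_fst_value"]).copy()
    if covered.empty:
        raise InvalidInputError("no ranked SNP is covered by an F_ST window")
    if fst_rank_universe == "snps":
        covered["r_fst"] = fractional_ranks(covered["window_fst_value"].to_numpy())
    else:
        wvals = np.array(
            [w.weighted_theta for w in windows if not np.isnan(w.weighted_theta)]
        )
        wranks = fractional_ranks(wvals)
        rank_of = dict(zip(wvals, wranks))  # equal values share a rank anyway
        covered["r_fst"] = [rank_of[v] for v in covered["window_fst_value"]]

    covered["rank_sum"] = covered["r_fst"] + covered["r_afd"] + covered["r_faeth"]
    covered["selected"] = covered["rank_sum"] < threshold
    covered = covered.sort_values(
        ["rank_sum", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    return covered[
        ["chrom", "pos", "ref", "alt", "window_fst_value", "afd", "faeth",
         "r_fst", "r_afd", "r_faeth", "rank_sum", "selected"]
    ]
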