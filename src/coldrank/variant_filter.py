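"""GATK-style hard filtering of VCF records and site-class filters.

Five fixed thresholds on caller-emitted site annotations remove likely
artifacts: low quality-by-depth (QD), low RMS mapping quality (MQ), strand
bias (FS), and strongly negative mapping-quality / read-position rank-sum
Z-scores. A record missing an annotation never fails that rule — the rank-sum
annotations are undefined at sites without heterozygotes, which is not
evidence of a bad call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedRatioError
from .io import VariantRecord
from .phenotype import GroupSpec

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs (GATK Best Practices defaults)."""

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0


def failing_rules(record: VariantRecord, thresholds: FilterThresholds) -> list[str]:
    """Names of the hard-filter rules this record violates (possibly several)."""
    info = record.info
    failed = []
    if info.get("QD") is not None and info["QD"] < thresholds.qd_min:
        failed.append("QD")
    if info.get("MQ") is not None and info["MQ"] < thresholds.mq_min:
        failed.append("MQ")
    if info.get("FS") is not None and info["FS"] > thresholds.fs_max:
        failed.append("FS")
    if (
        info.get("MQRankSum") is not None
        and info["MQRankSum"] < thresholds.mqranksum_min
    ):
        failed.append("MQRankSum")
    if (
        info.get("ReadPosRankSum") is not None
        and info["ReadPosRankSum"] < thresholds.readposranksum_min
    ):
        failed.append("ReadPosRankSum")
    return failed


def apply_hard_filters(
    records: list[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Drop records violating any hard-filter rule.

    Returns the surviving records and per-rule removal counts; a removed
    record is attributed to every rule it violates, so the counts can sum to
    more than the number of removed records.
    """
    counts = {k: 0 for k in ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum")}
    passing = []
    for rec in records:
        failed = failing_rules(rec, thresholds)
        if failed:
            for rule in failed:
                counts[rule] += 1
        else:
            passing.append(rec)
    return passing, counts


def keep_biallelic_snps(records: list[VariantRecord]) -> list[VariantRecord]:
    """Retain biallelic single-nucleotide substitutions (drop INDELs and
    multiallelic sites)."""
    return [r for r in records if r.is_biallelic and r.is_snp]


def ts_tv_ratio(records: list[VariantRecord]) -> float:
    """Transition/transversion ratio over biallelic SNP records."""
    ts = tv = 0
    for r in records:
        if not (r.is_biallelic and r.is_snp):
            continue
        if (r.ref.upper(), r.alt.upper()) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise UndefinedRatioError("no transversions; Ts/Tv undefined")
    return ts / tv


def called_counts(record: VariantRecord, groups: GroupSpec) -> dict[str, int]:
    """Number of non-missing genotypes per contrast group at this site."""
    counts = {label: 0 for label in groups.labels}
    for sample, gt in zip(record.samples, record.genotypes):
        label = groups.group_of.get(sample)
        if label is not None and gt is not None:
            counts[label] += 1
    return counts


def min_called_mask(
    records: list[VariantRecord], groups: GroupSpec, min_called: int = 3
) -> np.ndarray:
    """True where each group has ≥ ``min_called`` successfully called
    genotypes."""
    mask = np.zeros(len(records), dtype=bool)
    for i, rec in enumerate(records):
        counts = called_counts(rec, groups)
        mask[i] = all(c >= min_called for c in counts.values())
    return mask
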