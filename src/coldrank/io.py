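"""Input/output: VCF records, group tables, FAETH score tables.

The in-memory variant container is a light dataclass holding exactly what the
downstream statistics need (position, alleles, the five caller INFO
annotations, and per-sample diploid genotype calls). VCF parsing goes through
cyvcf2; writing synthetic VCFs is handled by :mod:`coldrank.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import ParseError

#: INFO keys consumed by the hard filters, in the order they are reported.
INFO_KEYS = ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum")

#: A diploid genotype call: a pair of allele indices, or None when missing.
Genotype = Optional[tuple[int, int]]


@dataclass
class VariantRecord:
    """One VCF site: alleles, caller annotations and genotype calls.

    ``alts`` keeps every ALT allele so multiallelic sites can be recognised
    and removed; ``alt`` is the first ALT for the (usual) biallelic case.
    ``genotypes[i]`` is the call for ``samples[i]``: a ``(a1, a2)`` pair of
    allele indices, or ``None`` for ``./.``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    info: dict = field(default_factory=dict)
    genotypes: list[Genotype] = field(default_factory=list)
    samples: tuple[str, ...] = ()

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def alt_dosage(self, i: int) -> Optional[int]:
        """Alt-allele count (0/1/2) for sample i, or None when missing."""
        gt = self.genotypes[i]
        if gt is None:
            return None
        return int(gt[0] > 0) + int(gt[1] > 0)


def _info_value(variant, key: str, chrom: str, pos: int):
    raw = variant.INFO.get(key)
    if raw is None:
        return None
    try:
        val = float(raw)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"non-numeric INFO field {key}={raw!r} at {chrom}:{pos}"
        ) from exc
    if math.isnan(val):
        return None
    return val


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a (plain or bgzipped) VCF into VariantRecord objects."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = tuple(vcf.samples)
    records = []
    for v in vcf:
        info = {}
        for key in INFO_KEYS:
            val = _info_value(v, key, v.CHROM, v.POS)
            if val is not None:
                info[key] = val
        genotypes: list[Genotype] = []
        for g in v.genotypes:  # [a1, a2, phased]
            a1, a2 = int(g[0]), int(g[1])
            genotypes.append(None if a1 < 0 or a2 < 0 else (a1, a2))
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=int(v.POS),
                ref=v.REF,
                alts=tuple(v.ALT),
                info=info,
                genotypes=genotypes,
                samples=samples,
            )
        )
    vcf.close()
    return records


def read_groups(path: str) -> "GroupSpec":
    """Read a sample→group/breed assignment CSV (sample_id, group, breed)."""
    from .phenotype import GroupSpec

    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group", "breed"}
    if not required.issubset(df.columns):
        raise ParseError(f"group table must have columns {sorted(required)}")
    return GroupSpec(
        group_of=dict(zip(df["sample_id"], df["group"])),
        breed_of=dict(zip(df["sample_id"], df["breed"])),
    )


def read_faeth(path: str) -> pd.DataFrame:
    """Read a per-SNP functional (FAETH-style) score table.

    Expected columns: chrom, pos, ref, alt, score.
    """
    df = pd.read_csv(path, dtype={"chrom": str})
    required = {"chrom", "pos", "score"}
    if not required.issubset(df.columns):
        raise ParseError(f"FAETH table must have columns {sorted(required)}")
    df["pos"] = df["pos"].astype(int)
    df["score"] = df["score"].astype(float)
    return df


def read_temperature_csv(path: str) -> dict[str, "TemperatureSeries"]:
    """Read long-format sensor CSV (animal_id, timestamp, temp_c) to series."""
    from .phenotype import TemperatureSeries

    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = {}
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("timestamp")
        out[str(animal_id)] = TemperatureSeries(
            subject_id=str(animal_id),
            timestamps=sub["timestamp"].to_numpy(),
            values=sub["temp_c"].to_numpy(float),
        )
    return out


def write_temperature_csv(series: Sequence["TemperatureSeries"], path: str) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": s.subject_id,
                    "timestamp": pd.DatetimeIndex(s.timestamps).strftime(
                        "%Y-%m-%dT%H:%M:%S"
                    ),
                    "temp_c": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
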