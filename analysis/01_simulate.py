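#!/usr/bin/env python
"""Generate the synthetic cold-stress study used by the downstream steps.

Emits, under results/study/: in-ear and ambient temperature CSVs for the
cohort, the 12-sample VCF (background + planted + causal loci, INDELs, and
INFO values straddling the hard-filter thresholds), the group and breed
table, the FAETH-style score table, the planted-locus truth table, and a toy
GTF + FASTA gene model. Uses the reduced-genome demo preset (2 x 1.25 Mb
chromosomes at the default ~1 SNP / 25 kb density) so the genome FASTA stays
small enough to carry through annotation.
"""

from pathlib import Path

from coldrank.simulate import SimulationConfig, simulate_study

OUT = Path(__file__).resolve().parents[1] / "results" / "study"
SEED = 1


def main() -> None:
    config = SimulationConfig.demo()
    bundle = simulate_study(config, SEED, outdir=OUT)
    planted = bundle.truth[bundle.truth["role"] == "planted"]
    print(f"wrote synthetic study to {OUT}")
    print(f"  animals: {config.n_animals} ({len(bundle.groups.group_of)} sequenced)")
    print(f"  VCF records: {len(bundle.records)}")
    print(f"  planted divergent loci: {len(planted)} (+1 causal locus)")
    print(f"  ambient minimum: {bundle.cohort.ambient.values.min():.1f} °C")
    print(f"  coldest interval: {bundle.interval[0]:%Y-%m-%d} .. "
          f"{bundle.interval[1]:%Y-%m-%d}")


if __name__ == "__main__":
    main()
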