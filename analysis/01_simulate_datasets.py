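#!/usr/bin/env python
"""Generate the synthetic three-taxon study data and write it to disk.

Emits one protein FASTA per taxon and the toy focal genome (FASTA + GFF3)
under scratch/data/ (bulky, fully regenerable from the seed), plus the
ground-truth ledger and a coverage summary under results/data/.  Everything
downstream is recomputable from these files (or, since generation is seeded,
from the study design in common.py alone).
"""

from __future__ import annotations

import json

from common import GENOME_SPEC, RESULTS, SCRATCH, SEED, family_specs

from phycomp.records import write_fasta
from phycomp.synthetic import (generate_genome, generate_proteomes,
                               simulate_coverage, write_genome_fasta,
                               write_gff3)


def main() -> None:
    outdir = RESULTS / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    seqdir = SCRATCH / "data"
    seqdir.mkdir(parents=True, exist_ok=True)

    proteomes, ledger = generate_proteomes(family_specs(), seed=SEED)
    for taxon, records in proteomes.items():
        write_fasta(records, seqdir / f"{taxon}.faa")
        print(f"{taxon}: {len(records)} proteins")
    ledger.to_json(outdir / "truth_ledger.json")

    genome, _ = generate_genome(GENOME_SPEC)
    write_genome_fasta(genome, seqdir / "focal_genome.fna")
    write_gff3(genome, seqdir / "focal_genome.gff3")
    total = sum(len(c) for c in genome.contigs)
    print(f"genome: {len(genome.contigs)} contigs, {total:,} bp, "
          f"{len(genome.genes)} genes")

    coverage = simulate_coverage(17_000_000, 62, 101, seed=SEED)
    with open(outdir / "coverage_summary.json", "w") as handle:
        json.dump({"n_reads": coverage.n_reads,
                   "read_length": coverage.read_length,
                   "total_mapped_bases": coverage.total_mapped_bases,
                   "mean_coverage": coverage.mean_coverage}, handle, indent=1)
    print(f"coverage summary: {coverage.n_reads:,} reads at "
          f"{coverage.mean_coverage:.1f}x")


if __name__ == "__main__":
    main()
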