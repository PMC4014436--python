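#!/usr/bin/env python
"""Compaction statistics of the toy focal genome, next to the published table.

Computes the assembly summary (N50, GC), realized gene density and exon/
intron geometry of the generated genome, the coverage-based genome-size
estimate, and the coding densities of the nine published green-algal genomes
from their printed gene counts and assembled sizes.
"""

from __future__ import annotations

import pandas as pd

from common import GENOME_SPEC, RESULTS, SEED

from phycomp.genome_stats import (assembly_summary, coding_density,
                                  estimate_genome_size, filter_contigs,
                                  gene_structure_stats)
from phycomp.synthetic import generate_genome, simulate_coverage

PUBLISHED = [  # (label, predicted genes, assembled size in Mbp)
    ("Ostreococcus tauri", 7892, 12.6),
    ("Ostreococcus lucimarinus", 7651, 13.2),
    ("Micromonas RCC299", 10109, 20.9),
    ("Micromonas pusilla", 10672, 22.0),
    ("Helicosporidium", 6035, 12.4),
    ("Chlorella variabilis", 9791, 46.2),
    ("Coccomyxa subellipsoidea", 9629, 49.0),
    ("Chlamydomonas reinhardtii", 16709, 112.0),
    ("Volvox carteri", 14971, 131.0),
]


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    genome, _ = generate_genome(GENOME_SPEC)
    contigs = filter_contigs(genome.contigs, min_len=500)
    summary = assembly_summary(contigs)
    structure = gene_structure_stats(genome)
    density = len(genome.genes) / (summary.total_bp / 1000.0)
    print(f"assembly: {summary.n_contigs} contigs >=500 bp, "
          f"{summary.total_bp:,} bp, N50 {summary.n50_bp:,} bp, "
          f"GC {summary.gc_percent:.1f}%")
    print(f"genes: {len(genome.genes)} ({density:.3f} gene/kbp), "
          f"{structure.mean_exons_per_gene} exons/gene "
          f"({structure.mean_exon_bp} bp/exon), "
          f"{structure.mean_introns_per_gene} introns/gene "
          f"({structure.mean_intron_bp} bp/intron)")

    coverage = simulate_coverage(17_000_000, 62, 101, seed=SEED)
    size = estimate_genome_size(coverage.total_mapped_bases,
                                coverage.mean_coverage)
    print(f"coverage-based size estimate: {size / 1e6:.2f} Mbp "
          f"from {coverage.n_reads:,} reads at {coverage.mean_coverage:.1f}x")

    table = pd.DataFrame(
        [{"genome": label, "genes": genes, "size_mbp": size_mbp,
          "gene_density": coding_density(genes, size_mbp)}
         for label, genes, size_mbp in PUBLISHED])
    table.to_csv(RESULTS / "published_densities.tsv", sep="\t", index=False)
    print("\npublished coding densities (gene/kbp):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
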