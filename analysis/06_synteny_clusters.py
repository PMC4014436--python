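#!/usr/bin/env python
"""Synteny clusters between the toy focal genome and a rearranged relative.

Derives the relative's gene order from the focal genome by deleting a third
of the genes (no ortholog), relocating some, and inverting one block per
contig; orthologs are then assigned by RBH on synthetic hit tables and
clusters detected from the two gene orders.  Reports the fraction of focal
genes on the ten largest contigs that sit in a conserved cluster.
"""

from __future__ import annotations

import random

import pandas as pd

from common import GENOME_SPEC, RESULTS, SEED

from phycomp.similarity import HitTable, SimilarityHit
from phycomp.synteny import (GenePosition, find_clusters,
                             gene_order_from_genome, largest_contig_genes,
                             rbh_orthologs, synteny_fraction)
from phycomp.synthetic import generate_genome


def rearranged_order(order_a, rng):
    """Gene order of a fictional relative: deletions, relocations, inversions."""
    by_contig: dict[str, list[str]] = {}
    for gene, pos in sorted(order_a.items(), key=lambda kv: (kv[1].contig,
                                                             kv[1].index)):
        by_contig.setdefault(pos.contig, []).append(gene)
    order_b: dict[str, GenePosition] = {}
    relocated: list[str] = []
    for contig, genes in by_contig.items():
        kept = [g for g in genes if rng.random() > 1 / 3]  # deletions
        for gene in list(kept):
            if rng.random() < 0.1:  # relocations to a far contig
                kept.remove(gene)
                relocated.append(gene)
        if len(kept) > 6:  # invert one internal block
            i = rng.randrange(1, len(kept) - 4)
            kept[i:i + 4] = reversed(kept[i:i + 4])
        for idx, gene in enumerate(kept):
            order_b[f"B_{gene}"] = GenePosition(f"scf_{contig}", idx)
    for idx, gene in enumerate(relocated):
        order_b[f"B_{gene}"] = GenePosition("scf_far", idx)
    return order_b


def hit_tables(order_a, order_b):
    """Mutual best hits between each focal gene and its B_ counterpart."""
    ab, ba = HitTable(), HitTable()
    for gene in order_a:
        partner = f"B_{gene}"
        if partner not in order_b:
            continue
        ab.add(SimilarityHit(gene, partner, 1e-50, 80.0, 80, 100, 200.0, 100, 100))
        ba.add(SimilarityHit(partner, gene, 1e-50, 80.0, 80, 100, 200.0, 100, 100))
    return ab, ba


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = random.Random(SEED)
    genome, _ = generate_genome(GENOME_SPEC)
    order_a = gene_order_from_genome(genome)
    order_b = rearranged_order(order_a, rng)
    ab, ba = hit_tables(order_a, order_b)
    orthologs = rbh_orthologs(ab, ba)
    print(f"{len(orthologs)} RBH orthologs from {len(order_a)} focal genes")

    clusters = find_clusters(orthologs, order_a, order_b, max_gap=2,
                             min_cluster_size=2)
    rows = [{"cluster": i + 1, "contig_a": c.contig_a, "contig_b": c.contig_b,
             "orientation": c.orientation, "n_pairs": c.size,
             "genes_a": ";".join(p.gene_a for p in c.pairs)}
            for i, c in enumerate(clusters)]
    pd.DataFrame(rows).to_csv(RESULTS / "synteny_clusters.tsv", sep="\t",
                              index=False)
    n_inverted = sum(c.orientation == "inverted" for c in clusters)
    print(f"{len(clusters)} clusters ({n_inverted} inverted), "
          f"{sum(c.size for c in clusters)} anchored gene pairs")

    selected = largest_contig_genes(genome, n_contigs=10)
    fraction = synteny_fraction(clusters, selected)
    print(f"{fraction:.0%} of the {len(selected)} genes on the ten largest "
          f"focal contigs lie in syntenic clusters")


if __name__ == "__main__":
    main()
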