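# phycomp

Comparative-genomic toolkit for asking whether a small parasite genome is
*reduced* (functions lost) or merely *compact* (same functions, less DNA).
The motivating system is the trebouxiophyte green algae: the obligate insect
parasite *Helicosporidium* has a ~12.4 Mbp genome, 2.5-fold smaller than its
free-living relatives *Chlorella variabilis* and *Coccomyxa subellipsoidea*,
yet retains nearly all ancestral metabolic pathways.  The toolkit implements
the analyses that support that kind of conclusion, end-to-end testable on
synthetic three-taxon data with a known ground truth.

## What it computes

- **Gene-family networks** (`similarity`, `family_network`): all-vs-all
  Smith–Waterman protein comparisons (BLOSUM62, gap open 11/extend 1,
  Karlin–Altschul E-values) or ingested BLASTP `-outfmt 6` tables.  An edge
  joins two proteins when *both* reciprocal hits satisfy
  E < 1e-10, identity > 20%, identical residues ≥ 20% of the shorter
  sequence, and alignment length > 20 aa.  Connected components are gene
  families; per-taxon counts yield `contracted` / `expanded` / `balanced` /
  `absent-in-focal` calls against a focal taxon, summarised per functional
  category.
- **Pathway retention** (`pathway`): presence/absence of reference gene sets
  (KEGG-style pathway maps, GreenCut2-style inventories) against proteome,
  genome and transcriptome hits with E-value thresholds 1e-10 (protein) and
  1e-5 (nucleotide); a gene is absent only if absent from all three.
  Retention fractions per pathway, genome/transcriptome congruence, and a
  two-sided Fisher exact test for whether losses concentrate in a focus set
  (e.g. photosynthesis).
- **Chitinase motifs** (`motifs`): GH18 catalytic motif DxxDxDxE with
  single-substitution variants at conserved positions (e.g. E→P), the three
  accessory motifs Kx6GG, MxYDx(x)G and Gx3Wx2DxD, motif order, start
  methionine, length and average-mass kDa per protein.
- **Compaction statistics** (`genome_stats`): contig filtering, N50, GC,
  coding density (genes/kbp of assembled Mbp), exon/intron geometry from
  GFF3-style gene models, and coverage-based genome sizing
  (mapped bases / mean coverage).
- **Synteny** (`synteny`): reciprocal-best-hit orthologs, maximal colinear
  anchor chains (forward or inverted, bounded gene gaps), and the fraction of
  genes on selected contigs lying in conserved clusters.
- **Synthetic data** (`synthetic`): seeded three-taxon proteomes built from
  per-family ancestral sequences with planted contractions/expansions and
  planted motifs, toy annotated genomes with configurable density/geometry/GC,
  and coverage summaries — each with a `TruthLedger` for scoring.

## Worked example

```python
from phycomp.synthetic import FamilySpec, generate_proteomes
from phycomp.similarity import all_vs_all
from phycomp.family_network import (EdgeCriteria, build_network,
                                    connected_components, classify_components)

specs = [FamilySpec(f"fam{i}", (1, 2, 2) if i < 10 else (2, 2, 2),
                    ancestral_length=120, within_divergence=0.1)
         for i in range(30)]
proteomes, ledger = generate_proteomes(specs, seed=1)
hits = all_vs_all(proteomes)
ids = [r.id for recs in proteomes.values() for r in recs]
graph = build_network(hits, ids, EdgeCriteria())
comps = connected_components(graph, ledger.member_taxon)
comps = classify_components(comps, "focal", ["relative1", "relative2"])
print("edges match ledger:",
      {frozenset(e) for e in graph.edges()} == ledger.within_family_pairs())
print("contracted:",
      sum(c.representation_call == "contracted" for c in comps))
```

prints

```
edges match ledger: True
contracted: 10
```

i.e. the 400 network edges are exactly the planted within-family pairs and
the ten families planted with fewer focal members than either comparator are
all (and only) the ones called contracted.

## Analysis scripts

`analysis/01_simulate_datasets.py` … `06_synteny_clusters.py` run the whole
study on the synthetic dataset: data generation, network + family calls,
pathway retention, the chitinase motif report, compaction statistics next to
the nine published green-algal coding densities, and synteny clusters.  Each
writes its tables under `results/` (bulky regenerable sequence files go to
`scratch/`).  Run them in order from `analysis/`.

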