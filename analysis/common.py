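"""Shared study design for the numbered analysis scripts.

One place defines the synthetic study conditions — the planted family census,
the sequence divergence, the genome geometry (matching the focal parasite's
published compaction statistics) and the master seed — so every script works
on the same dataset.
"""

from __future__ import annotations

from pathlib import Path

from phycomp.synthetic import FamilySpec, GenomeSpec

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
# bulky regenerable outputs (sequences, full hit tables) live outside results
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

# Planted family census: 10 contracted in the focal taxon, 3 expanded,
# 2 absent-in-focal, 15 balanced.
FAMILY_COUNTS = ([(1, 2, 2), (1, 3, 2), (2, 3, 4), (1, 2, 3), (2, 4, 3),
                  (1, 2, 2), (3, 4, 5), (1, 4, 4), (2, 3, 3), (1, 3, 3)]
                 + [(4, 1, 1), (3, 2, 1), (5, 2, 2)]
                 + [(0, 2, 1), (0, 1, 1)]
                 + [(2, 2, 2), (1, 1, 1), (1, 1, 2), (2, 1, 3), (3, 3, 3)] * 3)

CATEGORIES = ("transcription", "transport", "metabolism")

# Geometry of the toy focal genome: density 0.487 gene/kbp, 2.3 exons/gene,
# 366 bp exons, 168 bp introns, 62% GC — the published compaction profile.
GENOME_SPEC = GenomeSpec(n_contigs=20, contig_length_mean=50_000,
                         contig_length_sd=10_000, target_gene_density=0.487,
                         exons_per_gene_mean=2.3, exon_length_mean=366,
                         intron_length_mean=168, gc_fraction=0.62, seed=SEED)


def family_specs() -> list[FamilySpec]:
    return [FamilySpec(f"fam{i:02d}", counts, ancestral_length=120,
                       within_divergence=0.1)
            for i, counts in enumerate(FAMILY_COUNTS)]


def annotation_map(ledger) -> dict[str, str]:
    """Functional labels: contracted families cycle over three categories."""
    labels: dict[str, str] = {}
    contracted = [f for f, call in sorted(ledger.expected_call.items())
                  if call == "contracted"]
    for i, fam in enumerate(contracted):
        for member in ledger.family_members[fam]:
            labels[member] = CATEGORIES[i % len(CATEGORIES)]
    for fam, call in ledger.expected_call.items():
        if call != "contracted":
            for member in ledger.family_members[fam]:
                labels[member] = "misc"
    return labels
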