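"""Assembly and gene-model compaction statistics.

Compact parasite genomes differ from their free-living relatives mostly in
intergenic spacing, intron load and gene-family size, so the basic summary
statistics — contig filtering, N50, GC, coding density (genes per kbp of
assembled sequence), exon/intron geometry and coverage-based genome-size
estimation — carry the comparison.  All coordinates are GFF3-style 1-based
closed intervals; strand never affects any statistic computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True)
class Gene:
    """A gene model: ordered, non-overlapping exon intervals on one contig."""

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based closed, sorted

    def validate(self) -> None:
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValueError(f"gene {self.id}: bad exon interval ({start},{end})")
            if start <= prev_end:
                raise ValueError(f"gene {self.id}: overlapping/unsorted exons")
            prev_end = end


@dataclass
class Contig:
    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AnnotatedGenome:
    contigs: list[Contig]
    genes: list[Gene]

    def validate(self) -> None:
        contig_ids = {c.id for c in self.contigs}
        for gene in self.genes:
            gene.validate()
            if gene.contig not in contig_ids:
                raise ValueError(f"gene {gene.id}: unknown contig {gene.contig}")


@dataclass(frozen=True)
class AssemblySummary:
    n_contigs: int
    total_bp: int
    n50_bp: int
    gc_percent: float


@dataclass(frozen=True)
class GeneStructureStats:
    mean_exons_per_gene: float
    mean_exon_bp: int
    mean_introns_per_gene: float
    mean_intron_bp: Optional[int]  # None when no gene has an intron


def filter_contigs(contigs: Sequence[Contig], min_len: int = 500) -> list[Contig]:
    """Keep contigs of at least ``min_len`` bp, preserving order."""
    return [c for c in contigs if len(c) >= min_len]


def gc_percent(sequences: Iterable[str]) -> float:
    """GC as a percentage of unambiguous (ACGT) bases."""
    gc = at = 0
    for seq in sequences:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / (gc + at)


def n50(lengths: Sequence[int]) -> int:
    """Largest L with total length of contigs >= L at least half the assembly."""
    if not lengths:
        raise ValueError("empty length set")
    total = sum(lengths)
    best = 0
    for candidate in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= candidate) >= total / 2:
            best = candidate
            break
    return best


def assembly_summary(contigs: Sequence[Contig]) -> AssemblySummary:
    if not contigs:
        raise ValueError("empty contig set")
    lengths = [len(c) for c in contigs]
    return AssemblySummary(
        n_contigs=len(contigs),
        total_bp=sum(lengths),
        n50_bp=n50(lengths),
        gc_percent=gc_percent(c.seq for c in contigs),
    )


def _round_half_away(value: float, decimals: int) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(1).scaleb(-decimals),
                                               rounding=ROUND_HALF_UP))


def coding_density(n_genes: int, assembled_size_mbp: float) -> float:
    """Genes per kbp from the assembled size in Mbp, 3-decimal rounding.

    Densities are conventionally quoted against the rounded published
    assembled size in Mbp, so that is the contract here (half away from
    zero at the third decimal).
    """
    if n_genes <= 0 or assembled_size_mbp <= 0:
        raise ValueError("gene count and assembled size must be positive")
    return _round_half_away(n_genes / (assembled_size_mbp * 1000.0), 3)


def introns_of(gene: Gene) -> list[int]:
    """Intron lengths implied by the gaps between consecutive exons."""
    return [nxt[0] - prev[1] - 1
            for prev, nxt in zip(gene.exons, gene.exons[1:])]


def gene_structure_stats(genome: AnnotatedGenome) -> GeneStructureStats:
    """Per-gene exon/intron means over all gene models.

    Mean counts are reported to 1 decimal, mean sizes as integer bp; the
    intron size mean is undefined (None) for intronless annotation sets.
    """
    genome.validate()
    if not genome.genes:
        raise ValueError("no gene models")
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    n_exons = n_introns = 0
    for gene in genome.genes:
        exon_lengths.extend(end - start + 1 for start, end in gene.exons)
        intron_lengths.extend(introns_of(gene))
        n_exons += len(gene.exons)
        n_introns += len(gene.exons) - 1
    n_genes = len(genome.genes)
    return GeneStructureStats(
        mean_exons_per_gene=round(n_exons / n_genes, 1),
        mean_exon_bp=round(sum(exon_lengths) / len(exon_lengths)),
        mean_introns_per_gene=round(n_introns / n_genes, 1),
        mean_intron_bp=(round(sum(intron_lengths) / len(intron_lengths))
                        if intron_lengths else None),
    )


def estimate_genome_size(total_mapped_bases: float, mean_coverage: float) -> float:
    """Genome size in bp as mapped bases divided by mean fold-coverage."""
    if total_mapped_bases <= 0 or mean_coverage <= 0:
        raise ValueError("mapped bases and coverage must be positive")
    return total_mapped_bases / mean_coverage
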