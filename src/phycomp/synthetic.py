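"""Three-taxon synthetic datasets with known ground truth.

The generator emulates the comparison of a parasitic alga against two
free-living relatives: three proteomes share gene families (each family
derived from one random ancestral sequence by i.i.d. substitutions), a focal
taxon carries planted family contractions/expansions, selected proteins carry
planted chitinase-like motifs, and toy annotated genomes realise a requested
gene density, exon/intron geometry and GC content.  Every dataset is emitted
together with a TruthLedger so downstream calls (family contraction,
retention, motif presence, compaction statistics) can be scored against the
planted truth.

Randomness: one master seed; each family and each genome contig draws from
its own child stream spawned from the master seed, so outputs are
byte-identical across runs for a given seed and spec list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_stats import AnnotatedGenome, Contig, Gene
from .motifs import ALL_PATTERNS, CANONICAL_AA, MotifPattern
from .records import ProteinRecord

DEFAULT_TAXA = ("focal", "relative1", "relative2")

_AA = np.frombuffer(CANONICAL_AA.encode(), dtype="S1")


@dataclass(frozen=True)
class FamilySpec:
    """Ground-truth description of one planted gene family."""

    family_id: str
    counts_per_taxon: tuple[int, int, int]  # (focal, comparator1, comparator2)
    ancestral_length: int = 150
    within_divergence: float = 0.05
    motif_plan: tuple[tuple[str, Optional[str], int], ...] = ()
    # motif_plan entries: (motif_name, variant or None, 1-based position),
    # applied to every member after divergence.

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts_per_taxon):
            raise ValueError(f"{self.family_id}: negative member count")
        if not (0 <= self.within_divergence < 0.5):
            raise ValueError(f"{self.family_id}: within_divergence must be in [0, 0.5)")
        if self.ancestral_length < 50:
            raise ValueError(f"{self.family_id}: ancestral_length must be >= 50")
        for name, _variant, pos in self.motif_plan:
            width = max(len(p) for p in ALL_PATTERNS[name].patterns)
            if pos < 1 or pos + width - 1 > self.ancestral_length:
                raise ValueError(
                    f"{self.family_id}: motif {name} at {pos} does not fit in "
                    f"{self.ancestral_length} residues")


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of a toy annotated genome."""

    n_contigs: int = 20
    contig_length_mean: float = 60_000.0
    contig_length_sd: float = 15_000.0
    contig_length_min: int = 500
    target_gene_density: float = 0.487   # genes per kbp of assembled sequence
    exons_per_gene_mean: float = 2.3
    exon_length_mean: float = 366.0
    intron_length_mean: float = 168.0
    gc_fraction: float = 0.62
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_gene_density <= 0:
            raise ValueError("target_gene_density must be positive")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.n_contigs < 1 or self.contig_length_min < 1:
            raise ValueError("need at least one contig of positive length")
        span = (self.exons_per_gene_mean * self.exon_length_mean
                + max(self.exons_per_gene_mean - 1, 0) * self.intron_length_mean)
        if span > self.contig_length_mean:
            raise ValueError("mean gene span exceeds mean contig length")
        if span > 1000.0 / self.target_gene_density:
            raise ValueError("gene density infeasible: genes cannot fit")


@dataclass
class TruthLedger:
    """Everything the generator knows that downstream stages must recover."""

    family_members: dict[str, list[str]] = field(default_factory=dict)
    member_family: dict[str, str] = field(default_factory=dict)
    member_taxon: dict[str, str] = field(default_factory=dict)
    counts_per_taxon: dict[str, tuple[int, ...]] = field(default_factory=dict)
    expected_call: dict[str, str] = field(default_factory=dict)
    motif_positions: dict[str, list[tuple[str, Optional[str], int]]] = field(default_factory=dict)
    genome_spec: Optional[dict] = None
    genome_size_bp: Optional[int] = None
    mean_coverage: Optional[float] = None

    def within_family_pairs(self) -> set[frozenset[str]]:
        pairs: set[frozenset[str]] = set()
        for members in self.family_members.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add(frozenset((a, b)))
        return pairs

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True, default=list)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``divergence``.

    Replacements are uniform over the 19 alternative residues.
    """
    if divergence == 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < divergence)
    for i in hits:
        alternatives = CANONICAL_AA.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def expected_representation_call(counts: Sequence[int]) -> str:
    """Ground-truth family call from planted per-taxon counts (focal first)."""
    focal, *comps = counts
    if focal == 0 and all(c >= 1 for c in comps):
        return "absent-in-focal"
    if 1 <= focal < min(comps, default=0):
        return "contracted"
    if comps and focal > max(comps) and all(c >= 1 for c in comps):
        return "expanded"
    return "balanced"


def plant_motifs(protein: ProteinRecord,
                 plan: Sequence[tuple[str, Optional[str], int]]) -> ProteinRecord:
    """Overwrite fixed motif positions at the planned 1-based positions.

    ``variant`` is None (canonical) or a conserved-position label with the
    replacement residue, e.g. "E>P" or "D1>T"; wildcard positions keep the
    original residues.  Plans with overlapping or out-of-range windows are
    rejected.
    """
    chars = list(protein.seq)
    claimed: set[int] = set()
    for name, variant, pos in plan:
        pattern: MotifPattern = ALL_PATTERNS[name]
        pat = pattern.patterns[0]  # canonical arity
        start = pos - 1
        if start < 0 or start + len(pat) > len(chars):
            raise ValueError(f"motif {name} at {pos} outside sequence")
        window = set(range(start, start + len(pat)))
        if window & claimed:
            raise ValueError(f"motif {name} at {pos} overlaps another planned motif")
        claimed |= window
        substitution: Optional[tuple[int, str]] = None
        if variant is not None:
            label, _, replacement = variant.partition(">")
            offsets = {lab: off for off, lab in pattern.conserved.items()}
            if label not in offsets:
                raise ValueError(f"motif {name} has no conserved position {label!r}")
            substitution = (offsets[label], replacement)
        for offset, p in enumerate(pat):
            if p != ".":
                chars[start + offset] = p
        if substitution is not None:
            offset, replacement = substitution
            chars[start + offset] = replacement
    return ProteinRecord(protein.id, protein.taxon, "".join(chars))


def generate_proteomes(
    specs: Sequence[FamilySpec],
    seed: int,
    taxa: tuple[str, str, str] = DEFAULT_TAXA,
) -> tuple[dict[str, list[ProteinRecord]], TruthLedger]:
    """Generate three proteomes from family specs; returns proteomes + ledger.

    Each family descends from one random ancestral sequence; members of
    different families share no ancestor, so between-family similarity is
    random-background only.
    """
    ids_seen: set[str] = set()
    for spec in specs:
        if spec.family_id in ids_seen:
            raise ValueError(f"duplicate family_id {spec.family_id}")
        ids_seen.add(spec.family_id)

    proteomes: dict[str, list[ProteinRecord]] = {t: [] for t in taxa}
    ledger = TruthLedger()
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    for spec, stream in zip(specs, streams):
        rng = np.random.default_rng(stream)
        ancestor = _random_protein(rng, spec.ancestral_length)
        members: list[str] = []
        for taxon, count in zip(taxa, spec.counts_per_taxon):
            for k in range(count):
                pid = f"{taxon}|{spec.family_id}.{k}"
                seq = _mutate(ancestor, spec.within_divergence, rng)
                record = ProteinRecord(pid, taxon, seq)
                if spec.motif_plan:
                    record = plant_motifs(record, spec.motif_plan)
                    ledger.motif_positions[pid] = list(spec.motif_plan)
                proteomes[taxon].append(record)
                members.append(pid)
                ledger.member_family[pid] = spec.family_id
                ledger.member_taxon[pid] = taxon
        ledger.family_members[spec.family_id] = members
        ledger.counts_per_taxon[spec.family_id] = spec.counts_per_taxon
        ledger.expected_call[spec.family_id] = expected_representation_call(
            spec.counts_per_taxon)
    return proteomes, ledger


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def generate_genome(spec: GenomeSpec) -> tuple[AnnotatedGenome, TruthLedger]:
    """Toy annotated genome realising the requested geometry.

    Per contig, the number of genes is the rounded density target for the
    contig's length; exon counts are 1 + Poisson, exon/intron lengths gamma
    with shape 4 around their means, and the leftover length is spread over
    the intergenic gaps.
    """
    contigs: list[Contig] = []
    genes: list[Gene] = []
    for ci in range(spec.n_contigs):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(ci + 1)[-1])
        length = int(max(spec.contig_length_min,
                         round(rng.normal(spec.contig_length_mean,
                                          spec.contig_length_sd))))
        contig_id = f"ctg{ci + 1:04d}"
        seq = _random_dna(rng, length, spec.gc_fraction)
        contigs.append(Contig(contig_id, seq.tobytes().decode()))

        n_genes = int(round(length * spec.target_gene_density / 1000.0))
        models: list[list[tuple[int, int]]] = []
        spans: list[int] = []
        for _ in range(n_genes):
            n_exons = 1 + rng.poisson(max(spec.exons_per_gene_mean - 1.0, 0.0))
            exon_lens = np.maximum(
                10, np.round(rng.gamma(4.0, spec.exon_length_mean / 4.0,
                                       size=n_exons))).astype(int)
            intron_lens = np.maximum(
                20, np.round(rng.gamma(4.0, spec.intron_length_mean / 4.0,
                                       size=max(n_exons - 1, 0)))).astype(int)
            models.append([(int(e), int(i)) for e, i in
                           zip(exon_lens, np.append(intron_lens, 0))])
            spans.append(int(exon_lens.sum() + intron_lens.sum()))
        total_span = sum(spans)
        free = length - total_span
        if n_genes and free < n_genes + 1:
            raise ValueError(
                f"contig {contig_id}: {n_genes} genes of total span "
                f"{total_span} bp cannot fit in {length} bp")
        if n_genes:
            gaps = rng.multinomial(free - (n_genes + 1), [1.0 / (n_genes + 1)] * (n_genes + 1))
            gaps = gaps + 1  # every gap at least 1 bp
            pos = 0
            for gi, model in enumerate(models):
                pos += int(gaps[gi])
                start = pos + 1  # 1-based
                exons: list[tuple[int, int]] = []
                cursor = start
                for e_len, i_len in model:
                    exons.append((cursor, cursor + e_len - 1))
                    cursor += e_len + i_len
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(Gene(f"{contig_id}.g{gi + 1}", contig_id, strand,
                                  tuple(exons)))
                pos += spans[gi]
    genome = AnnotatedGenome(contigs, genes)
    genome.validate()
    ledger = TruthLedger(genome_spec=asdict(spec))
    return genome, ledger


@dataclass(frozen=True)
class CoverageSummary:
    """Mapped-read summary used for coverage-based genome sizing."""

    n_reads: int
    read_length: int
    total_mapped_bases: int
    mean_coverage: float


def simulate_coverage(genome_size: int, coverage: float, read_length: int,
                      seed: int = 0) -> CoverageSummary:
    """Reads needed to cover ``genome_size`` at ``coverage`` fold."""
    if genome_size <= 0 or coverage <= 0 or read_length <= 0:
        raise ValueError("genome size, coverage and read length must be positive")
    n_reads = int(round(genome_size * coverage / read_length))
    total = n_reads * read_length
    return CoverageSummary(
        n_reads=n_reads,
        read_length=read_length,
        total_mapped_bases=total,
        mean_coverage=total / genome_size,
    )


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    """Gene/exon features, 1-based closed coordinates."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in genome.genes:
            start = gene.exons[0][0]
            end = gene.exons[-1][1]
            handle.write(f"{gene.contig}\tphycomp\tgene\t{start}\t{end}\t.\t"
                         f"{gene.strand}\t.\tID={gene.id}\n")
            for n, (es, ee) in enumerate(gene.exons, start=1):
                handle.write(f"{gene.contig}\tphycomp\texon\t{es}\t{ee}\t.\t"
                             f"{gene.strand}\t.\tID={gene.id}.e{n};Parent={gene.id}\n")


def write_genome_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as handle:
        for contig in genome.contigs:
            handle.write(f">{contig.id}\n")
            for i in range(0, len(contig.seq), 70):
                handle.write(contig.seq[i:i + 70] + "\n")
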