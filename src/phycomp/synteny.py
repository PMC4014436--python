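"""Synteny-cluster detection between two annotated genomes.

Orthologs are assigned by reciprocal best hit (RBH) on bitscore; clusters are
maximal colinear chains of ortholog anchors whose consecutive members are
separated by at most ``max_gap`` intervening genes on *each* genome.  Chains
may run in the same direction on both genomes or inverted; a two-anchor
inverted chain is indistinguishable from a trivial adjacent transposition and
is therefore not reported (inverted clusters need at least three anchors).
The headline statistic is the fraction of genes on selected contigs (by
default the largest ones) that sit inside any cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .similarity import HitTable, SimilarityHit

MIN_INVERTED_ANCHORS = 3


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    bitscore: float


@dataclass(frozen=True)
class GenePosition:
    """Positional index of a gene along its contig (0-based rank)."""

    contig: str
    index: int


@dataclass
class SyntenyCluster:
    pairs: list[OrthologPair]
    contig_a: str
    contig_b: str
    orientation: str  # "forward" or "inverted"
    n_gaps_a: int
    n_gaps_b: int

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def genes_a(self) -> set[str]:
        return {p.gene_a for p in self.pairs}


def _best_per_query(hits: HitTable) -> dict[str, SimilarityHit]:
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        rank = (-hit.bitscore, hit.evalue, hit.subject_id)
        if cur is None or rank < (-cur.bitscore, cur.evalue, cur.subject_id):
            best[hit.query_id] = hit
    return best


def rbh_orthologs(hits_ab: HitTable, hits_ba: HitTable) -> list[OrthologPair]:
    """Reciprocal best hits: highest bitscore, ties by lower E then subject id."""
    best_ab = _best_per_query(hits_ab)
    best_ba = _best_per_query(hits_ba)
    pairs = []
    for gene_a, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == gene_a:
            pairs.append(OrthologPair(gene_a, hit.subject_id, hit.bitscore))
    return pairs


def gene_order_from_genome(genome) -> dict[str, GenePosition]:
    """Positional ranks from an AnnotatedGenome, per contig, by exon start."""
    order: dict[str, GenePosition] = {}
    by_contig: dict[str, list] = {}
    for gene in genome.genes:
        by_contig.setdefault(gene.contig, []).append(gene)
    for contig, genes in by_contig.items():
        for idx, gene in enumerate(sorted(genes, key=lambda g: g.exons[0][0])):
            order[gene.id] = GenePosition(contig, idx)
    return order


def _chain(anchors: list[tuple[int, int, OrthologPair]], direction: int,
           max_gap: int) -> list[list[int]]:
    """Longest-chain DP over anchors sorted by genome-A index.

    ``direction`` is +1 for co-oriented chains, -1 for inverted; returns all
    chains obtainable as best chains ending at each anchor (as index lists).
    """
    n = len(anchors)
    best_len = [1] * n
    prev: list[Optional[int]] = [None] * n
    for j in range(n):
        for i in range(j):
            ia, ib, _ = anchors[i]
            ja, jb, _ = anchors[j]
            gap_a = ja - ia - 1
            gap_b = direction * (jb - ib) - 1
            if gap_a < 0 or gap_a > max_gap or gap_b < 0 or gap_b > max_gap:
                continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    chains = []
    for j in range(n):
        chain = [j]
        while prev[chain[-1]] is not None:
            chain.append(prev[chain[-1]])
        chains.append(chain[::-1])
    return chains


def find_clusters(orthologs: Sequence[OrthologPair],
                  order_a: Mapping[str, GenePosition],
                  order_b: Mapping[str, GenePosition],
                  max_gap: int = 2,
                  min_cluster_size: int = 2) -> list[SyntenyCluster]:
    """Maximal colinear anchor chains, each ortholog pair used at most once.

    Longest chains are reported first (ties resolved to the leftmost start on
    genome A); anchors already claimed by a longer chain are skipped when
    shorter candidates are considered.
    """
    for pair in orthologs:
        if pair.gene_a not in order_a:
            raise ValueError(f"gene {pair.gene_a!r} missing from genome A order")
        if pair.gene_b not in order_b:
            raise ValueError(f"gene {pair.gene_b!r} missing from genome B order")

    unused: dict[tuple[str, str], list[tuple[int, int, OrthologPair]]] = {}
    for pair in orthologs:
        pa, pb = order_a[pair.gene_a], order_b[pair.gene_b]
        unused.setdefault((pa.contig, pb.contig), []).append(
            (pa.index, pb.index, pair))

    clusters: list[SyntenyCluster] = []
    while True:
        # best chain over anchors not yet claimed by a reported cluster
        best: Optional[tuple[int, int, tuple, str,
                             list[tuple[int, int, OrthologPair]]]] = None
        for contigs in sorted(unused):
            anchors = sorted(unused[contigs], key=lambda a: (a[0], a[1]))
            for direction, name in ((1, "forward"), (-1, "inverted")):
                min_size = (max(min_cluster_size, MIN_INVERTED_ANCHORS)
                            if direction == -1 else min_cluster_size)
                for chain in _chain(anchors, direction, max_gap):
                    if len(chain) < min_size:
                        continue
                    members = [anchors[i] for i in chain]
                    key = (-len(chain), members[0][0], contigs, name)
                    if best is None or key < (-len(best[4]), best[1],
                                              best[2], best[3]):
                        best = (len(chain), members[0][0], contigs, name, members)
        if best is None:
            break
        _, _, (ca, cb), orientation, members = best
        gaps_a = sum(b[0] - a[0] - 1 for a, b in zip(members, members[1:]))
        gaps_b = sum(abs(b[1] - a[1]) - 1 for a, b in zip(members, members[1:]))
        clusters.append(SyntenyCluster(
            pairs=[m[2] for m in members], contig_a=ca, contig_b=cb,
            orientation=orientation, n_gaps_a=gaps_a, n_gaps_b=gaps_b))
        claimed = {id(m[2]) for m in members}
        unused[(ca, cb)] = [a for a in unused[(ca, cb)]
                            if id(a[2]) not in claimed]
        if not unused[(ca, cb)]:
            del unused[(ca, cb)]
    return clusters


def synteny_fraction(clusters: Sequence[SyntenyCluster],
                     genes_on_selected_contigs: Iterable[str]) -> float:
    """Fraction of the selected genome-A genes lying in any cluster."""
    selected = set(genes_on_selected_contigs)
    if not selected:
        raise ValueError("empty contig selection")
    clustered = set().union(*(c.genes_a for c in clusters)) if clusters else set()
    return len(selected & clustered) / len(selected)


def largest_contig_genes(genome, n_contigs: int = 10) -> set[str]:
    """Gene ids on the ``n_contigs`` largest contigs of a genome."""
    largest = {c.id for c in sorted(genome.contigs, key=len, reverse=True)[:n_contigs]}
    return {g.id for g in genome.genes if g.contig in largest}
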