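"""Pairwise protein similarity: internal local alignment or BLAST tabular input.

The gene-network analysis downstream needs, for every ordered pair of
proteins, the best local-alignment hit with its E-value, percent identity,
identical-residue count and alignment length.  At desk scale these are
computed internally with Smith–Waterman (BLOSUM62, gap open 11 / extend 1,
the classic BLASTP defaults) and Karlin–Altschul E-values
E = K·m·n·exp(−λS) with m the query length and n the total residue count of
the subject database.  Real BLASTP ``-outfmt 6`` files can be ingested
instead; either route fills the same HitTable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import ProteinRecord

# gapped BLOSUM62 Karlin–Altschul constants
LAMBDA = 0.267
K = 0.041

#: E-value above which internally computed hits are not retained,
#: mirroring the default BLAST reporting threshold.
REPORT_EVALUE = 10.0


@dataclass(frozen=True)
class SimilarityHit:
    """One directed local-alignment result (best HSP for the ordered pair)."""

    query_id: str
    subject_id: str
    evalue: float
    percent_identity: float
    n_identical: int
    alignment_length: int
    bitscore: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")
        if self.n_identical > self.alignment_length or self.alignment_length < 1:
            raise ValueError("inconsistent identity/alignment length")
        if self.evalue < 0:
            raise ValueError("negative E-value")


class HitTable:
    """Best hit per ordered (query, subject) pair; self-pairs are dropped."""

    def __init__(self, provenance: str = "internal") -> None:
        self.provenance = provenance
        self._hits: dict[tuple[str, str], SimilarityHit] = {}

    def add(self, hit: SimilarityHit) -> None:
        """Insert, keeping the better HSP on collision.

        Better = lower E-value, ties broken by higher identical-residue
        count, then lexicographically smaller subject id.
        """
        if hit.query_id == hit.subject_id:
            return
        key = (hit.query_id, hit.subject_id)
        old = self._hits.get(key)
        if old is None or _hsp_rank(hit) < _hsp_rank(old):
            self._hits[key] = hit

    def get(self, query_id: str, subject_id: str) -> Optional[SimilarityHit]:
        return self._hits.get((query_id, subject_id))

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self):
        return iter(self._hits.values())

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._hits)


def _hsp_rank(hit: SimilarityHit) -> tuple:
    return (hit.evalue, -hit.n_identical, hit.subject_id)


def make_aligner(gap_open: int = 11, gap_extend: int = 1,
                 matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    """Local aligner with BLAST-style affine gap cost open + k·extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # biopython charges open_gap_score for the first gap position, so a gap of
    # length k costs open + k·extend only with open_gap_score = -(open+extend)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def evalue(score: float, query_length: int, db_residues: int,
           lam: float = LAMBDA, kappa: float = K) -> float:
    return kappa * query_length * db_residues * math.exp(-lam * score)


def bitscore(score: float, lam: float = LAMBDA, kappa: float = K) -> float:
    return (lam * score - math.log(kappa)) / math.log(2.0)


def align_pair(a: ProteinRecord, b: ProteinRecord,
               aligner: Optional[Align.PairwiseAligner] = None,
               db_residues: Optional[int] = None) -> SimilarityHit:
    """Best Smith–Waterman hit of query ``a`` against subject ``b``.

    Gap columns count toward the alignment length but not identity.  The
    E-value treats ``b`` alone as the database unless ``db_residues`` gives
    the total subject-database size.
    """
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(a.seq, b.seq)
    if len(alignments) == 0 or alignments.score <= 0:
        raise ValueError(f"no local alignment between {a.id} and {b.id}")
    aln = alignments[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.internal_gaps
    n = db_residues if db_residues is not None else len(b.seq)
    return SimilarityHit(
        query_id=a.id,
        subject_id=b.id,
        evalue=evalue(aln.score, len(a.seq), n),
        percent_identity=100.0 * counts.identities / aln_len,
        n_identical=counts.identities,
        alignment_length=aln_len,
        bitscore=bitscore(aln.score),
        query_length=len(a.seq),
        subject_length=len(b.seq),
    )


def all_vs_all(proteomes: Mapping[str, Sequence[ProteinRecord]],
               aligner: Optional[Align.PairwiseAligner] = None,
               report_evalue: float = REPORT_EVALUE) -> HitTable:
    """Both directions of every unordered pair, within and across taxa.

    Scoring is symmetric, so each unordered pair is aligned once and both
    directed hits are derived from it; only hits with E-value below the
    reporting threshold are retained (hopeless pairs are score-screened
    without traceback).
    """
    records: list[ProteinRecord] = [r for recs in proteomes.values() for r in recs]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein identifiers across proteomes")
    if aligner is None:
        aligner = make_aligner()
    db_residues = sum(len(r.seq) for r in records)
    table = HitTable(provenance="internal")
    min_len = min((len(r.seq) for r in records), default=0)
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            score = aligner.score(a.seq, b.seq)
            if score <= 0:
                continue
            # smallest possible E for this pair; skip traceback if hopeless
            if evalue(score, min(len(a.seq), len(b.seq)), db_residues) >= report_evalue:
                continue
            hit_ab = align_pair(a, b, aligner=aligner, db_residues=db_residues)
            hit_ba = SimilarityHit(
                query_id=b.id, subject_id=a.id,
                evalue=evalue(_score_from_bits(hit_ab.bitscore), len(b.seq), db_residues),
                percent_identity=hit_ab.percent_identity,
                n_identical=hit_ab.n_identical,
                alignment_length=hit_ab.alignment_length,
                bitscore=hit_ab.bitscore,
                query_length=len(b.seq), subject_length=len(a.seq),
            )
            if hit_ab.evalue < report_evalue:
                table.add(hit_ab)
            if hit_ba.evalue < report_evalue:
                table.add(hit_ba)
    return table


def _score_from_bits(bits: float, lam: float = LAMBDA, kappa: float = K) -> float:
    return (bits * math.log(2.0) + math.log(kappa)) / lam


BLAST_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore")


def read_hit_table(path: str | Path, lengths: Mapping[str, int]) -> HitTable:
    """Ingest a 12-column BLAST ``-outfmt 6`` file.

    ``lengths`` supplies query/subject sequence lengths (from a sidecar table
    or the FASTA the search used).  The identical-residue count is
    reconstructed as round(pident × length / 100); the best-HSP rule
    deduplicates repeated pairs and self-pairs are dropped.
    """
    table = HitTable(provenance=f"file:{path}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, "
                                 f"got {len(fields)}")
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                ev = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            for seq_id in (qseqid, sseqid):
                if seq_id not in lengths:
                    raise ValueError(f"{path}:{lineno}: no sequence length "
                                     f"for {seq_id!r}")
            table.add(SimilarityHit(
                query_id=qseqid, subject_id=sseqid, evalue=ev,
                percent_identity=pident,
                n_identical=round(pident * length / 100.0),
                alignment_length=length, bitscore=bits,
                query_length=lengths[qseqid], subject_length=lengths[sseqid],
            ))
    return table


def write_hit_table(table: HitTable, path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (coordinates as 0)."""
    with open(path, "w") as handle:
        for hit in sorted(table, key=lambda h: (h.query_id, h.subject_id)):
            handle.write("\t".join(map(str, (
                hit.query_id, hit.subject_id,
                f"{hit.percent_identity:.2f}", hit.alignment_length,
                hit.alignment_length - hit.n_identical, 0, 0, 0, 0, 0,
                f"{hit.evalue:.3g}", f"{hit.bitscore:.1f}")))
                         + "\n")
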