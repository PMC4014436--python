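"""Generator ground truth: determinism, divergence control, geometry recovery."""

from __future__ import annotations

import numpy as np
import pytest

from phycomp.genome_stats import assembly_summary, gene_structure_stats
from phycomp.records import ProteinRecord
from phycomp.synthetic import (CoverageSummary, FamilySpec, GenomeSpec,
                               generate_genome, generate_proteomes,
                               plant_motifs, simulate_coverage)


class TestFamilySpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"counts_per_taxon": (-1, 1, 1)},
        {"within_divergence": 0.5},
        {"within_divergence": -0.1},
        {"ancestral_length": 49},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(family_id="f", counts_per_taxon=(1, 1, 1))
        base.update(kwargs)
        with pytest.raises(ValueError):
            FamilySpec(**base)

    def test_motif_must_fit_in_ancestor(self):
        with pytest.raises(ValueError):
            FamilySpec("f", (1, 1, 1), ancestral_length=50,
                       motif_plan=(("catalytic", None, 48),))


class TestGenerateProteomes:
    def test_empty_specs_give_empty_collections(self):
        proteomes, ledger = generate_proteomes([], seed=0)
        assert all(not recs for recs in proteomes.values())
        assert not ledger.member_family

    def test_zero_divergence_yields_identical_members(self):
        spec = FamilySpec("f", (1, 1, 1), ancestral_length=100,
                          within_divergence=0.0)
        proteomes, _ = generate_proteomes([spec], seed=3)
        seqs = {r.seq for recs in proteomes.values() for r in recs}
        assert len(seqs) == 1
        assert len(next(iter(seqs))) == 100

    def test_counts_match_spec_and_partition(self, planted):
        proteomes, ledger = planted
        for fam, counts in ledger.counts_per_taxon.items():
            members = ledger.family_members[fam]
            assert len(members) == sum(counts)
        # every protein in exactly one family
        all_ids = [r.id for recs in proteomes.values() for r in recs]
        assert sorted(all_ids) == sorted(ledger.member_family)

    def test_deterministic_given_seed(self):
        specs = [FamilySpec("f", (2, 1, 1), within_divergence=0.1)]
        p1, _ = generate_proteomes(specs, seed=11)
        p2, _ = generate_proteomes(specs, seed=11)
        p3, _ = generate_proteomes(specs, seed=12)
        assert p1 == p2
        assert p1 != p3

    def test_within_family_similar_between_family_dissimilar(self):
        """Within-family identity tracks (1-d)^2; between stays at background."""
        specs = [FamilySpec(f"f{i}", (1, 1, 1), ancestral_length=150,
                            within_divergence=0.1) for i in range(4)]
        proteomes, ledger = generate_proteomes(specs, seed=5)
        records = {r.id: r for recs in proteomes.values() for r in recs}
        ids = sorted(records)
        expected = (1 - 0.1) ** 2
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ra, rb = records[a], records[b]
                hamming_id = np.mean([x == y for x, y in zip(ra.seq, rb.seq)])
                if ledger.member_family[a] == ledger.member_family[b]:
                    assert abs(hamming_id - expected) < 0.12
                else:
                    assert hamming_id < 0.15


class TestPlantMotifs:
    def test_canonical_catalytic_pattern_forced(self):
        protein = ProteinRecord("p", "t", "A" * 20)
        planted = plant_motifs(protein, [("catalytic", None, 1)])
        assert planted.seq[:8] == "DAADADAE"
        assert planted.seq[8:] == "A" * 12

    def test_variant_substitutes_single_conserved_position(self):
        protein = ProteinRecord("p", "t", "A" * 20)
        planted = plant_motifs(protein, [("catalytic", "E>P", 1)])
        assert planted.seq[:8] == "DAADADAP"

    def test_overlapping_plan_rejected(self):
        protein = ProteinRecord("p", "t", "A" * 30)
        with pytest.raises(ValueError, match="overlap"):
            plant_motifs(protein, [("catalytic", None, 1),
                                   ("Kx6GG", None, 5)])

    def test_out_of_range_rejected(self):
        protein = ProteinRecord("p", "t", "A" * 10)
        with pytest.raises(ValueError):
            plant_motifs(protein, [("catalytic", None, 5)])


class TestGenerateGenome:
    def test_zero_genes_single_contig(self):
        spec = GenomeSpec(n_contigs=1, contig_length_mean=2000,
                          contig_length_sd=0, target_gene_density=1e-9,
                          exons_per_gene_mean=1, exon_length_mean=300,
                          intron_length_mean=100, seed=0)
        genome, _ = generate_genome(spec)
        assert len(genome.contigs) == 1
        assert genome.genes == []

    def test_pure_gc_boundary(self):
        spec = GenomeSpec(n_contigs=1, contig_length_mean=1000,
                          contig_length_sd=0, target_gene_density=1e-9,
                          exons_per_gene_mean=1, exon_length_mean=300,
                          intron_length_mean=100, gc_fraction=1.0, seed=0)
        genome, _ = generate_genome(spec)
        assert set(genome.contigs[0].seq) <= {"G", "C"}

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            GenomeSpec(target_gene_density=2.0, exons_per_gene_mean=2.3,
                       exon_length_mean=366, intron_length_mean=168)

    def test_parameter_recovery_at_scale(self):
        """Realized GC/density/geometry must track the spec within tolerance."""
        spec = GenomeSpec(n_contigs=20, contig_length_mean=50_000,
                          contig_length_sd=10_000, target_gene_density=0.487,
                          exons_per_gene_mean=2.3, exon_length_mean=366,
                          intron_length_mean=168, gc_fraction=0.62, seed=42)
        genome, _ = generate_genome(spec)
        summary = assembly_summary(genome.contigs)
        assert summary.total_bp >= 100_000
        assert len(genome.genes) >= 200
        assert abs(summary.gc_percent / 100 - spec.gc_fraction) < 0.02
        density = len(genome.genes) / (summary.total_bp / 1000)
        assert abs(density - spec.target_gene_density) < 0.1 * spec.target_gene_density
        stats = gene_structure_stats(genome)
        assert abs(stats.mean_exons_per_gene - 2.3) <= 0.05 * 2.3
        assert abs(stats.mean_exon_bp - 366) <= 0.05 * 366
        assert abs(stats.mean_intron_bp - 168) <= 0.05 * 168

    def test_deterministic_given_seed(self):
        spec = GenomeSpec(n_contigs=3, contig_length_mean=10_000,
                          contig_length_sd=1000, seed=9)
        g1, _ = generate_genome(spec)
        g2, _ = generate_genome(spec)
        assert [c.seq for c in g1.contigs] == [c.seq for c in g2.contigs]
        assert g1.genes == g2.genes


def test_fasta_gff_output_byte_identical_across_runs(tmp_path):
    from phycomp.records import write_fasta
    from phycomp.synthetic import write_genome_fasta, write_gff3

    specs = [FamilySpec("f", (1, 1, 1), within_divergence=0.05)]
    gspec = GenomeSpec(n_contigs=2, contig_length_mean=8000,
                       contig_length_sd=500, seed=3)
    outputs = []
    for run in ("a", "b"):
        proteomes, _ = generate_proteomes(specs, seed=2)
        genome, _ = generate_genome(gspec)
        faa = tmp_path / f"{run}.faa"
        fna = tmp_path / f"{run}.fna"
        gff = tmp_path / f"{run}.gff3"
        write_fasta([r for recs in proteomes.values() for r in recs], faa)
        write_genome_fasta(genome, fna)
        write_gff3(genome, gff)
        outputs.append((faa.read_bytes(), fna.read_bytes(), gff.read_bytes()))
    assert outputs[0] == outputs[1]


class TestSimulateCoverage:
    def test_exact_arithmetic(self):
        summary = simulate_coverage(10_000, 10, 100)
        assert summary == CoverageSummary(1000, 100, 100_000, 10.0)

    def test_total_bases_consistent_with_coverage(self):
        summary = simulate_coverage(17_000_000, 62, 101, seed=4)
        assert summary.total_mapped_bases == summary.n_reads * summary.read_length
        assert abs(summary.mean_coverage * 17_000_000
                   - summary.total_mapped_bases) / summary.total_mapped_bases < 0.01

    @pytest.mark.parametrize("size,cov,read", [(0, 10, 100), (100, 0, 100),
                                               (100, 10, 0)])
    def test_nonpositive_inputs_rejected(self, size, cov, read):
        with pytest.raises(ValueError):
            simulate_coverage(size, cov, read)
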