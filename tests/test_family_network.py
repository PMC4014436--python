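"""Edge criteria, components vs a reachability oracle, and planted-truth recovery."""

from __future__ import annotations

import random

import networkx as nx
import numpy as np
import pytest

from phycomp.family_network import (EdgeCriteria, FamilyComponent,
                                    assign_category, build_network,
                                    classify_components, connected_components,
                                    edge_test, summarize_categories)
from phycomp.similarity import HitTable, SimilarityHit
from phycomp.synthetic import DEFAULT_TAXA


def _hit(q="a", s="b", evalue=1e-12, pident=25.0, n_id=30, length=50,
         qlen=100, slen=100):
    return SimilarityHit(q, s, evalue, pident, n_id, length, 50.0, qlen, slen)


def _pair(**kwargs):
    fwd = _hit("a", "b", **kwargs)
    rev = _hit("b", "a", **kwargs)
    return fwd, rev


class TestEdgeTest:
    def test_all_four_conditions_met(self):
        fwd, rev = _pair(evalue=1e-12, pident=25.0, n_id=30, length=50)
        assert edge_test(fwd, rev) is True

    def test_one_direction_failing_evalue_blocks_edge(self):
        fwd = _hit("a", "b", evalue=1e-9)
        rev = _hit("b", "a", evalue=1e-12)
        assert edge_test(fwd, rev) is False

    def test_boundary_identity_exactly_20_fails(self):
        fwd, rev = _pair(pident=20.0, n_id=30, length=150)
        assert edge_test(fwd, rev) is False

    def test_boundary_length_exactly_20_fails(self):
        fwd, rev = _pair(pident=50.0, n_id=20, length=20)
        assert edge_test(fwd, rev) is False

    def test_boundary_identical_fraction_exactly_020_passes(self):
        fwd, rev = _pair(pident=50.0, n_id=20, length=40, qlen=100, slen=120)
        assert edge_test(fwd, rev) is True

    def test_boundary_grid_matches_strict_inclusive_reading(self):
        """Sweep each criterion around its threshold; only the identical-residue
        fraction is inclusive."""
        criteria = EdgeCriteria()
        for evalue in (1e-11, 1e-10, 1e-9):
            for pident in (19.0, 20.0, 21.0):
                for length in (19, 20, 21):
                    for n_id in (19, 20, 21):
                        n_id_eff = min(n_id, length)
                        fwd, rev = _pair(evalue=evalue, pident=pident,
                                         n_id=n_id_eff, length=length)
                        expected = (evalue < 1e-10 and pident > 20.0
                                    and n_id_eff >= 0.20 * 100 and length > 20)
                        assert edge_test(fwd, rev, criteria) is expected

    def test_mismatched_pair_rejected(self):
        with pytest.raises(ValueError):
            edge_test(_hit("a", "b"), _hit("c", "a"))

    def test_relaxing_any_threshold_never_removes_edges(self, planted_hits,
                                                        planted):
        proteomes, _ = planted
        ids = [r.id for recs in proteomes.values() for r in recs]
        strict = EdgeCriteria()
        base_edges = set(build_network(planted_hits, ids, strict).edges())
        relaxed_variants = [
            EdgeCriteria(max_evalue=1e-5),
            EdgeCriteria(min_percent_identity=10.0),
            EdgeCriteria(min_identical_fraction_of_shorter=0.10),
            EdgeCriteria(min_alignment_length=10),
        ]
        for criteria in relaxed_variants:
            relaxed_edges = set(build_network(planted_hits, ids, criteria).edges())
            assert base_edges <= relaxed_edges


class TestBuildNetwork:
    def test_empty_hits_leave_isolated_vertices(self):
        graph = build_network(HitTable(), ["p1", "p2", "p3", "p4", "p5"])
        assert graph.number_of_nodes() == 5
        assert graph.number_of_edges() == 0

    def test_reciprocity_required(self):
        table = HitTable()
        table.add(_hit("a", "b"))
        graph = build_network(table, ["a", "b"])
        assert graph.number_of_edges() == 0

    def test_planted_families_recovered_exactly(self, planted, planted_hits):
        """Edges must equal the within-family pair set from the ledger."""
        proteomes, ledger = planted
        ids = [r.id for recs in proteomes.values() for r in recs]
        graph = build_network(planted_hits, ids)
        edges = {frozenset(e) for e in graph.edges()}
        assert edges == ledger.within_family_pairs()


def oracle_components(graph: nx.Graph) -> set[frozenset]:
    """Partition by brute-force transitive closure over the adjacency matrix."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    reach = np.eye(n, dtype=bool)
    for u, v in graph.edges():
        reach[index[u], index[v]] = reach[index[v], index[u]] = True
    for _ in range(n):
        new = reach | ((reach.astype(int) @ reach.astype(int)) > 0)
        if (new == reach).all():
            break
        reach = new
    return {frozenset(nodes[j] for j in np.flatnonzero(row)) for row in reach}


class TestConnectedComponents:
    TAXA = {"a": "t1", "b": "t1", "c": "t2", "d": "t2", "e": "t3"}

    def test_clique_plus_isolate(self):
        graph = nx.complete_graph(["a", "b", "c", "d"])
        graph.add_node("e")
        comps = connected_components(graph, self.TAXA)
        assert [c.size for c in comps] == [4, 1]
        assert comps[0].counts == {"t1": 2, "t2": 2}

    def test_path_and_disjoint_edge(self):
        graph = nx.Graph([("a", "b"), ("b", "c"), ("d", "e")])
        comps = connected_components(graph, self.TAXA)
        assert {frozenset(c.members) for c in comps} == {
            frozenset("abc"), frozenset("de")}

    def test_ordering_by_size_then_smallest_member(self):
        graph = nx.Graph([("d", "e"), ("a", "b")])
        graph.add_node("c")
        comps = connected_components(graph, self.TAXA)
        assert [c.members for c in comps] == [("a", "b"), ("d", "e"), ("c",)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reachability_oracle_on_random_graphs(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 50)
        graph = nx.gnp_random_graph(n, rng.uniform(0.02, 0.2), seed=seed)
        graph = nx.relabel_nodes(graph, {i: f"v{i:02d}" for i in graph.nodes()})
        taxa = {v: "t1" for v in graph.nodes()}
        ours = {frozenset(c.members)
                for c in connected_components(graph, taxa)}
        assert ours == oracle_components(graph)
        sizes = [c.size for c in connected_components(graph, taxa)]
        assert sum(sizes) == graph.number_of_nodes()


class TestClassifyComponents:
    def _component(self, focal, c1, c2):
        members = tuple(f"m{i}" for i in range(focal + c1 + c2))
        counts = {t: c for t, c in zip(DEFAULT_TAXA, (focal, c1, c2)) if c}
        return FamilyComponent("fam1", members, counts)

    @pytest.mark.parametrize("counts,expected", [
        ((1, 3, 2), "contracted"),
        ((14, 2, 1), "expanded"),
        ((2, 2, 2), "balanced"),
        ((0, 3, 1), "absent-in-focal"),
        ((1, 1, 2), "balanced"),   # focal equals one comparator: not contracted
        ((3, 0, 1), "balanced"),   # missing comparator blocks expansion call
        ((0, 0, 2), "balanced"),   # missing comparator blocks absence call
    ])
    def test_representation_calls(self, counts, expected):
        comp = self._component(*counts)
        out = classify_components([comp], DEFAULT_TAXA[0], list(DEFAULT_TAXA[1:]))
        assert out[0].representation_call == expected

    def test_unknown_taxon_rejected(self):
        comp = FamilyComponent("fam1", ("x",), {"mystery": 1})
        with pytest.raises(ValueError, match="mystery"):
            classify_components([comp], "focal", ["relative1"])

    def test_planted_contractions_recovered_perfectly(self, planted,
                                                      planted_components):
        """Precision and recall of every representation call equal 1.0."""
        _, ledger = planted
        member_to_family = ledger.member_family
        for comp in planted_components:
            families = {member_to_family[m] for m in comp.members}
            assert len(families) == 1  # components == planted families
            expected = ledger.expected_call[families.pop()]
            assert comp.representation_call == expected


class TestSummarizeCategories:
    def test_majority_and_tie_rules(self):
        comp = FamilyComponent("f", ("a", "b", "c"), {"t": 3})
        assert assign_category(comp, {"a": "A", "b": "A", "c": "B"}) == "A"
        assert assign_category(comp, {"a": "A", "b": "B"}) == "ambiguous"
        assert assign_category(comp, {}) == "unknown"

    def test_category_table_matches_ledger(self, planted, planted_components,
                                           annotation_map):
        _, ledger = planted
        table = summarize_categories(planted_components, annotation_map,
                                     DEFAULT_TAXA[0])
        contracted = table[table["call"] == "contracted"]
        # 10 planted contractions cycle over 3 categories: 4 + 3 + 3
        assert int(contracted["n_components"].sum()) == 10
        per_category = dict(zip(contracted["category"],
                                contracted["n_components"]))
        assert sorted(per_category.values(), reverse=True) == [4, 3, 3]

    def test_blacklist_excludes_category(self, planted_components,
                                         annotation_map):
        table = summarize_categories(planted_components, annotation_map,
                                     DEFAULT_TAXA[0],
                                     category_blacklist=("transcription",))
        assert "transcription" not in set(table["category"])
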