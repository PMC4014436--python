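"""Evolutionary gene network: families as connected components.

Vertices are proteins from all compared proteomes; an undirected edge joins
two proteins when their *reciprocal* best hits both satisfy four criteria
(E-value < 1e-10, percent identity > 20, identical residues covering at least
20% of the shorter sequence, alignment longer than 20 aa).  Connected
components of this graph approximate gene families; comparing per-taxon
member counts against a focal taxon yields contraction/expansion calls, the
signature of genome streamlining (or its absence) in a parasite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .similarity import HitTable, SimilarityHit


@dataclass(frozen=True)
class EdgeCriteria:
    """The four reciprocal-hit conditions; strictness as documented per field."""

    max_evalue: float = 1e-10                      # exclusive: E < max_evalue
    min_percent_identity: float = 20.0             # exclusive: pident > value
    min_identical_fraction_of_shorter: float = 0.20  # inclusive: n_id >= frac*shorter
    min_alignment_length: int = 20                 # exclusive: length > value

    def __post_init__(self) -> None:
        if min(self.max_evalue, self.min_percent_identity,
               self.min_identical_fraction_of_shorter,
               self.min_alignment_length) <= 0:
            raise ValueError("all thresholds must be positive")

    def passes(self, hit: SimilarityHit) -> bool:
        shorter = min(hit.query_length, hit.subject_length)
        return (hit.evalue < self.max_evalue
                and hit.percent_identity > self.min_percent_identity
                and hit.n_identical >= self.min_identical_fraction_of_shorter * shorter
                and hit.alignment_length > self.min_alignment_length)


@dataclass
class FamilyComponent:
    """One connected component with per-taxon counts and a representation call."""

    component_id: str
    members: tuple[str, ...]
    counts: dict[str, int]
    representation_call: Optional[str] = None
    category_label: Optional[str] = None

    @property
    def size(self) -> int:
        return len(self.members)


def edge_test(fwd: SimilarityHit, rev: SimilarityHit,
              criteria: EdgeCriteria = EdgeCriteria()) -> bool:
    """True iff both directions of one unordered pair pass all four criteria."""
    if (fwd.query_id, fwd.subject_id) != (rev.subject_id, rev.query_id):
        raise ValueError("hits are not the two directions of one pair")
    return criteria.passes(fwd) and criteria.passes(rev)


def build_network(hits: HitTable, node_ids: Iterable[str],
                  criteria: EdgeCriteria = EdgeCriteria()) -> nx.Graph:
    """Undirected graph over all proteins; isolated vertices are kept."""
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    for hit in hits:
        rev = hits.get(hit.subject_id, hit.query_id)
        if rev is None or hit.query_id > hit.subject_id:
            continue  # need reciprocity; visit each unordered pair once
        if edge_test(hit, rev, criteria):
            graph.add_edge(hit.query_id, hit.subject_id)
    return graph


def connected_components(graph: nx.Graph,
                         taxon_of: Mapping[str, str]) -> list[FamilyComponent]:
    """Components (singletons included) with per-taxon member counts.

    Ordered by decreasing size, then by lexicographically smallest member.
    """
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda members: (-len(members), members[0]))
    out = []
    for i, members in enumerate(comps, start=1):
        counts = Counter(taxon_of[m] for m in members)
        out.append(FamilyComponent(
            component_id=f"fam{i:05d}",
            members=tuple(members),
            counts=dict(counts),
        ))
    return out


def classify_components(components: Sequence[FamilyComponent],
                        focal_taxon: str,
                        comparator_taxa: Sequence[str]) -> list[FamilyComponent]:
    """Contracted / expanded / balanced / absent-in-focal calls.

    Contracted: 1 <= focal < every comparator count.  Expanded: focal >
    every comparator count with all comparators represented.  Absent: focal
    missing while every comparator is represented.  Everything else is
    balanced.  Requires all taxa in every component to be known labels.
    """
    if not comparator_taxa:
        raise ValueError("need at least one comparator taxon")
    known = {focal_taxon, *comparator_taxa}
    out = []
    for comp in components:
        unknown = set(comp.counts) - known
        if unknown:
            raise ValueError(f"{comp.component_id}: unknown taxa {sorted(unknown)}")
        focal = comp.counts.get(focal_taxon, 0)
        comps = [comp.counts.get(t, 0) for t in comparator_taxa]
        if focal == 0 and all(c >= 1 for c in comps):
            call = "absent-in-focal"
        elif 1 <= focal < min(comps):
            call = "contracted"
        elif focal > max(comps) and all(c >= 1 for c in comps):
            call = "expanded"
        else:
            call = "balanced"
        out.append(replace(comp, representation_call=call))
    return out


def assign_category(component: FamilyComponent,
                    annotation_map: Mapping[str, str]) -> str:
    """Majority functional label among annotated members.

    Ties give "ambiguous"; components with no annotated member "unknown".
    """
    labels = [annotation_map[m] for m in component.members if m in annotation_map]
    if not labels:
        return "unknown"
    counts = Counter(labels).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return "ambiguous"
    return counts[0][0]


def summarize_categories(components: Sequence[FamilyComponent],
                         annotation_map: Mapping[str, str],
                         focal_taxon: str,
                         category_blacklist: Sequence[str] = ()) -> pd.DataFrame:
    """Per-category counts of components and genes by representation call.

    ``category_blacklist`` optionally drops categories (e.g. photosynthesis-
    related families excluded from a contraction census).
    """
    rows = []
    for comp in components:
        category = assign_category(comp, annotation_map)
        if category in category_blacklist:
            continue
        focal_genes = comp.counts.get(focal_taxon, 0)
        rows.append({
            "category": category,
            "call": comp.representation_call,
            "component_id": comp.component_id,
            "focal_genes": focal_genes,
            "comparator_genes": comp.size - focal_genes,
        })
    if not rows:
        return pd.DataFrame(columns=["category", "call", "n_components",
                                     "focal_genes", "comparator_genes"])
    frame = pd.DataFrame(rows)
    return (frame.groupby(["category", "call"], as_index=False)
            .agg(n_components=("component_id", "count"),
                 focal_genes=("focal_genes", "sum"),
                 comparator_genes=("comparator_genes", "sum")))
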