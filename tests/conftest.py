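"""Shared fixtures: a planted three-taxon dataset built once per session."""

from __future__ import annotations

import pytest

from phycomp.family_network import (EdgeCriteria, build_network,
                                    classify_components, connected_components)
from phycomp.similarity import all_vs_all
from phycomp.synthetic import DEFAULT_TAXA, FamilySpec, generate_proteomes

SEED = 1

# 30 planted families: 10 contracted in the focal taxon, 3 expanded,
# 2 absent-in-focal, 15 balanced (including the focal==min boundary case).
CONTRACTED_COUNTS = [(1, 2, 2), (1, 3, 2), (2, 3, 4), (1, 2, 3), (2, 4, 3),
                     (1, 2, 2), (3, 4, 5), (1, 4, 4), (2, 3, 3), (1, 3, 3)]
EXPANDED_COUNTS = [(4, 1, 1), (3, 2, 1), (5, 2, 2)]
ABSENT_COUNTS = [(0, 2, 1), (0, 1, 1)]
BALANCED_COUNTS = [(2, 2, 2), (1, 1, 1), (1, 1, 2), (2, 1, 3), (3, 3, 3)] * 3

CATEGORIES = ("transcription", "transport", "metabolism")


def family_specs() -> list[FamilySpec]:
    specs = []
    counts = (CONTRACTED_COUNTS + EXPANDED_COUNTS + ABSENT_COUNTS
              + BALANCED_COUNTS)
    for i, c in enumerate(counts):
        specs.append(FamilySpec(f"fam{i:02d}", c, ancestral_length=120,
                                within_divergence=0.1))
    return specs


@pytest.fixture(scope="session")
def planted():
    """Proteomes + ledger for the 30-family planted dataset (seed fixed)."""
    proteomes, ledger = generate_proteomes(family_specs(), seed=SEED)
    return proteomes, ledger


@pytest.fixture(scope="session")
def planted_hits(planted):
    proteomes, _ = planted
    return all_vs_all(proteomes)


@pytest.fixture(scope="session")
def planted_components(planted, planted_hits):
    proteomes, ledger = planted
    ids = [r.id for recs in proteomes.values() for r in recs]
    graph = build_network(planted_hits, ids, EdgeCriteria())
    comps = connected_components(graph, ledger.member_taxon)
    return classify_components(comps, DEFAULT_TAXA[0], list(DEFAULT_TAXA[1:]))


@pytest.fixture(scope="session")
def annotation_map(planted):
    """Functional labels: contracted families cycle over three categories."""
    _, ledger = planted
    labels = {}
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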