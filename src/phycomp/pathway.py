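"""Pathway presence/absence profiling and retention statistics.

Reference gene sets (KEGG pathway maps from related green algae, or the
GreenCut2 inventory of plastid-targeted proteins) are searched against a
proteome, a genome and a transcriptome; a reference gene is present in a
dataset when its best hit beats that dataset's E-value threshold (1e-10 for
protein-vs-protein, 1e-5 for translated searches against nucleotide data),
and absent from the organism only when absent from all three.  Retention
fractions per pathway, cross-dataset congruence, and a Fisher exact test for
whether losses concentrate in a focus set of pathways (e.g. photosynthesis)
summarise the profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PROTEOME_THRESHOLD = 1e-10
NUCLEOTIDE_THRESHOLD = 1e-5

_DATASETS = ("proteome", "genome", "transcriptome")


@dataclass(frozen=True)
class ReferenceGene:
    gene_id: str
    pathway_label: str
    seq: str = ""


@dataclass(frozen=True)
class ReferenceSet:
    """A labelled reference gene set (a KEGG ko map, GreenCut2, ...)."""

    set_id: str
    entries: tuple[ReferenceGene, ...]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [e.gene_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.set_id}: duplicate gene ids")


def map_presence(refset: ReferenceSet,
                 proteome_hits: Mapping[str, float],
                 genome_hits: Mapping[str, float],
                 transcriptome_hits: Mapping[str, float],
                 proteome_threshold: float = PROTEOME_THRESHOLD,
                 nucleotide_threshold: float = NUCLEOTIDE_THRESHOLD) -> pd.DataFrame:
    """Per-reference-gene presence calls across the three datasets.

    Hit maps give the best E-value per reference gene id; a missing entry
    means no hit.  Presence requires the best E-value to be strictly below
    the dataset's threshold; ``overall_present`` is the OR across datasets.
    """
    thresholds = {"proteome": proteome_threshold,
                  "genome": nucleotide_threshold,
                  "transcriptome": nucleotide_threshold}
    hit_maps = {"proteome": proteome_hits, "genome": genome_hits,
                "transcriptome": transcriptome_hits}
    rows = []
    for entry in refset.entries:
        row: dict = {"gene_id": entry.gene_id,
                     "pathway_label": entry.pathway_label}
        for ds in _DATASETS:
            best = hit_maps[ds].get(entry.gene_id)
            row[f"best_evalue_{ds}"] = np.nan if best is None else best
            row[f"present_in_{ds}"] = best is not None and best < thresholds[ds]
        row["overall_present"] = any(row[f"present_in_{ds}"] for ds in _DATASETS)
        rows.append(row)
    return pd.DataFrame(rows)


def retention_fraction(profiles: pd.DataFrame,
                       group_by: str = "pathway_label") -> pd.DataFrame:
    """Retained fraction per pathway plus an "overall" row.

    Empty groups cannot arise from a populated profile table; zero-row
    inputs yield an empty result with a warning.
    """
    if profiles.empty:
        warnings.warn("empty profile table; nothing to summarize")
        return pd.DataFrame(columns=[group_by, "n_present", "n_total", "fraction"])
    grouped = (profiles.groupby(group_by)["overall_present"]
               .agg(n_present="sum", n_total="count").reset_index())
    grouped["n_present"] = grouped["n_present"].astype(int)
    grouped["fraction"] = grouped["n_present"] / grouped["n_total"]
    overall = pd.DataFrame([{
        group_by: "overall",
        "n_present": int(profiles["overall_present"].sum()),
        "n_total": len(profiles),
        "fraction": profiles["overall_present"].mean(),
    }])
    return pd.concat([grouped, overall], ignore_index=True)


def cross_dataset_congruence(profiles: pd.DataFrame) -> dict[str, float]:
    """Fractions found in both genome and transcriptome, or exclusively in one.

    Reported over two denominators: genes called present overall (primary)
    and all reference genes (suffix ``_of_all``); the primary three sum to
    at most 1, the remainder being proteome-only calls.
    """
    g = profiles["present_in_genome"]
    t = profiles["present_in_transcriptome"]
    present = profiles["overall_present"]
    counts = {
        "both": int((g & t).sum()),
        "genome_only": int((g & ~t).sum()),
        "transcriptome_only": int((~g & t).sum()),
    }
    n_present = int(present.sum())
    n_all = len(profiles)
    out: dict[str, float] = {}
    for key, c in counts.items():
        out[key] = c / n_present if n_present else 0.0
        out[f"{key}_of_all"] = c / n_all if n_all else 0.0
    out["n_present"] = n_present
    out["n_total"] = n_all
    return out


def loss_concentration_test(profiles: pd.DataFrame,
                            focus_labels: Sequence[str]) -> tuple[np.ndarray, float]:
    """Are gene losses concentrated in the focus pathways?

    Builds the 2×2 table (lost vs retained × focus vs other) and returns it
    with a two-sided Fisher exact p-value.  A degenerate table (an all-zero
    margin) is reported as p = 1 with a warning.
    """
    if not len(focus_labels):
        raise ValueError("focus label set is empty")
    if profiles["pathway_label"].isna().any():
        raise ValueError("every reference gene needs a pathway label")
    in_focus = profiles["pathway_label"].isin(set(focus_labels))
    lost = ~profiles["overall_present"]
    table = np.array([
        [int((lost & in_focus).sum()), int((lost & ~in_focus).sum())],
        [int((~lost & in_focus).sum()), int((~lost & ~in_focus).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        return table, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)
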