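"""GH18 chitinase motif scanning and peptide statistics.

Family-18 glycoside hydrolases carry a catalytic DxxDxDxE motif whose terminal
glutamate is the proton donor of the hydrolysis reaction; chitinases with
experimentally confirmed activity additionally carry up to three accessory
motifs (Kx6GG, MxYDx(x)G, Gx3Wx2DxD).  This module detects those motifs,
tolerating single substitutions at the conserved positions of the catalytic
motif (substituted copies are reported as putatively inactive variants), and
produces a per-protein report with motif order, start methionine, length and
average-isotopic peptide mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

# average isotopic residue masses (Da), i.e. amino acid minus water
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.0153


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-residue/wildcard pattern; '.' positions are free.

    ``conserved`` maps 0-based offsets within the pattern to a position label
    (e.g. the three aspartates D1/D2/D3 and the catalytic E).  Only conserved
    positions may be substituted in a "variant" match.
    """

    name: str
    patterns: tuple[str, ...]  # alternative arities, any may match
    conserved: dict[int, str] = field(default_factory=dict)


CATALYTIC = MotifPattern("catalytic", ("D..D.D.E",),
                         conserved={0: "D1", 3: "D2", 5: "D3", 7: "E"})
KX6GG = MotifPattern("Kx6GG", ("K......GG",))
MXYDXG = MotifPattern("MxYDx(x)G", ("M.YD.G", "M.YD..G"))
GX3WX2DXD = MotifPattern("Gx3Wx2DxD", ("G...W..D.D",))

ACCESSORY = (KX6GG, MXYDXG, GX3WX2DXD)
ALL_PATTERNS = {p.name: p for p in (CATALYTIC,) + ACCESSORY}


@dataclass(frozen=True)
class CatalyticStatus:
    """Outcome of the catalytic-motif scan.

    status is "canonical", "variant" or "absent".  For variants,
    ``substitution`` holds (position label, expected residue, observed
    residue), e.g. ("E", "E", "P") for the E-to-P exchange.
    """

    status: str
    position: Optional[int] = None  # 1-based start of the matched window
    substitution: Optional[tuple[str, str, str]] = None

    def __str__(self) -> str:
        if self.status == "canonical":
            return "+"
        if self.status == "variant":
            label, exp, obs = self.substitution
            return f"+ {label} to {obs}" if label.startswith("D") else f"+ {exp} to {obs}"
        return "-"


def _window_matches(window: str, pattern: str) -> bool:
    return all(p == "." or p == w for p, w in zip(pattern, window))


def _variant_mismatches(window: str, pattern: MotifPattern,
                        pat: str) -> Optional[tuple[str, str, str]]:
    """Return the single conserved-position substitution, if exactly one."""
    subs = []
    for i, (p, w) in enumerate(zip(pat, window)):
        if p == "." or p == w:
            continue
        if i not in pattern.conserved:
            return None
        subs.append((pattern.conserved[i], p, w))
    return subs[0] if len(subs) == 1 else None


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    for i, aa in enumerate(seq):
        if aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {aa!r} at position {i + 1}")


def scan_catalytic(seq: str) -> CatalyticStatus:
    """Scan for the DxxDxDxE catalytic motif.

    Leftmost canonical window wins; if none matches exactly, the leftmost
    window differing at exactly one conserved position (the three D's or the
    terminal E) is reported as a variant; otherwise absent.
    """
    _check_sequence(seq)
    pat = CATALYTIC.patterns[0]
    w = len(pat)
    best_variant: Optional[CatalyticStatus] = None
    for start in range(len(seq) - w + 1):
        window = seq[start:start + w]
        if _window_matches(window, pat):
            return CatalyticStatus("canonical", start + 1)
        if best_variant is None:
            sub = _variant_mismatches(window, CATALYTIC, pat)
            if sub is not None:
                best_variant = CatalyticStatus("variant", start + 1, sub)
    return best_variant if best_variant is not None else CatalyticStatus("absent")


def scan_accessory(seq: str) -> dict[str, list[int]]:
    """Exact-match positions (1-based) of the three accessory motifs.

    MxYDx(x)G matches in either arity; overlapping matches are all reported.
    """
    _check_sequence(seq)
    found: dict[str, list[int]] = {}
    for motif in ACCESSORY:
        positions = []
        for pat in motif.patterns:
            w = len(pat)
            for start in range(len(seq) - w + 1):
                if _window_matches(seq[start:start + w], pat):
                    positions.append(start + 1)
        found[motif.name] = sorted(set(positions))
    return found


def peptide_mass(seq: str) -> float:
    """Average-isotopic peptide mass in kDa, rounded to 2 decimals.

    Sum of residue masses plus one water (18.0153 Da) for the termini.
    """
    _check_sequence(seq)
    da = sum(_RESIDUE_MASS[aa] for aa in seq) + _WATER
    return round(da / 1000.0, 2)


@dataclass
class MotifReportRow:
    protein_id: str
    catalytic: CatalyticStatus
    accessory: dict[str, list[int]]
    motif_order: str
    start_methionine: bool
    length: int
    mass_kda: float


def _motif_order(catalytic: CatalyticStatus,
                 accessory: dict[str, list[int]]) -> str:
    entries = []
    if catalytic.status in ("canonical", "variant"):
        entries.append((catalytic.position, "catalytic"))
    for name, positions in accessory.items():
        for pos in positions:
            entries.append((pos, name))
    entries.sort()
    return ",".join(name for _, name in entries)


def build_report(proteins: Iterable) -> tuple[pd.DataFrame, dict[str, int]]:
    """Motif report over protein records (objects with .id and .seq).

    Returns the per-protein table plus summary counts: proteins carrying the
    catalytic motif (canonical or variant) and proteins with at least one
    accessory motif.
    """
    rows = []
    for prot in proteins:
        cat = scan_catalytic(prot.seq)
        acc = scan_accessory(prot.seq)
        rows.append(MotifReportRow(
            protein_id=prot.id,
            catalytic=cat,
            accessory=acc,
            motif_order=_motif_order(cat, acc),
            start_methionine=prot.seq.startswith("M"),
            length=len(prot.seq),
            mass_kda=peptide_mass(prot.seq),
        ))
    table = pd.DataFrame({
        "protein_id": [r.protein_id for r in rows],
        "catalytic": [str(r.catalytic) for r in rows],
        "catalytic_position": [r.catalytic.position for r in rows],
        "Kx6GG": ["+" if r.accessory["Kx6GG"] else "-" for r in rows],
        "MxYDx(x)G": ["+" if r.accessory["MxYDx(x)G"] else "-" for r in rows],
        "Gx3Wx2DxD": ["+" if r.accessory["Gx3Wx2DxD"] else "-" for r in rows],
        "motif_order": [r.motif_order for r in rows],
        "Met": ["+" if r.start_methionine else "-" for r in rows],
        "length": [r.length for r in rows],
        "kDa": [r.mass_kda for r in rows],
        # external-predictor columns we do not recompute
        "Gly18": "NA", "ChtBD": "NA", "PEST": "NA", "SP": "NA",
    })
    summary = {
        "n_catalytic": sum(r.catalytic.status in ("canonical", "variant")
                           for r in rows),
        "n_with_accessory": sum(any(r.accessory.values()) for r in rows),
    }
    return table, summary
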