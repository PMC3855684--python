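"""Annotation of helical ice-binding features shared by type I AFPs.

Type I antifreeze proteins are single Ala-rich α-helices.  The recurring
sequence features are: Ala content above 50 mol%; an 11-residue repeat with
Thr at position *i* and Ala at *i*+4 and *i*+8 forming the ice-binding face;
helix-stabilizing salt bridges between acidic and basic residues spaced
*i*, *i*+4; an N-terminal cap (an acidic residue right after Met plus a
nearby Pro/Gly); and an absence of helix-breaking Pro/Gly away from the
termini (the snailfish isoforms being the notable exception).

Positions are 0-based throughout the machine-facing API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .seqio import ProteinRecord

__all__ = [
    "ThrPeriod",
    "NCap",
    "SaltBridge",
    "HelixFeatureReport",
    "ala_mol_percent",
    "thr_periodicity",
    "ice_binding_triplets",
    "salt_bridges",
    "n_cap",
    "internal_breakers",
    "build_report",
]

ACIDIC = frozenset("DE")
BASIC = frozenset("KR")
BREAKERS = frozenset("PG")
#: residues accepted at the i+4 / i+8 slots of an ice-binding triplet
FACE_RESIDUES = frozenset("AT")
#: residues that may substitute for Thr at repeat slots (seen in sculpin SS-8)
DEFAULT_THR_SUBSTITUTES = frozenset("IL")


class ThrPeriod(NamedTuple):
    best_phase: int
    n_hits: int  # Thr at slots of the best phase
    n_substitute_hits: int  # Ile/Leu (or configured) at those slots
    n_slots: int
    score: float  # n_hits / n_slots


class NCap(NamedTuple):
    acidic_pos: int | None
    pg_pos: int | None


class SaltBridge(NamedTuple):
    pos1: int
    pos2: int  # always pos1 + 4
    orientation: str  # "acid-first" | "base-first"


def ala_mol_percent(p: ProteinRecord) -> float:
    """Mole percent of Ala over the full sequence, Met1 included."""
    return 100.0 * p.seq.count("A") / len(p.seq)


def thr_periodicity(
    p: ProteinRecord,
    period: int = 11,
    allowed_substitutes: frozenset[str] = DEFAULT_THR_SUBSTITUTES,
) -> ThrPeriod:
    """Best phase of a fixed-period Thr repeat.

    For each phase φ the slots are positions ≡ φ (mod period); hits are
    slots holding Thr, with Ile/Leu counted separately as substitute hits.
    The best phase maximizes hits + substitute hits (ties to the smallest
    phase); the score counts true Thr hits only.
    """
    if len(p.seq) < period:
        raise ValueError(f"sequence shorter than period {period}")
    best: ThrPeriod | None = None
    for phase in range(period):
        slots = range(phase, len(p.seq), period)
        n_slots = len(slots)
        hits = sum(1 for s in slots if p.seq[s] == "T")
        subs = sum(1 for s in slots if p.seq[s] in allowed_substitutes)
        cand = ThrPeriod(phase, hits, subs, n_slots, hits / n_slots)
        if best is None or (cand.n_hits + cand.n_substitute_hits) > (
            best.n_hits + best.n_substitute_hits
        ):
            best = cand
    assert best is not None
    return best


def ice_binding_triplets(p: ProteinRecord, period: int = 11) -> list[tuple[int, int, int]]:
    """All (i, i+4, i+8) triplets anchored on a Thr with Ala/Thr at both
    downstream slots — the putative ice-binding face of the 11-aa repeat."""
    triplets = []
    for i, aa in enumerate(p.seq):
        if aa == "T" and i + 8 < len(p.seq):
            if p.seq[i + 4] in FACE_RESIDUES and p.seq[i + 8] in FACE_RESIDUES:
                triplets.append((i, i + 4, i + 8))
    return triplets


def salt_bridges(p: ProteinRecord) -> list[SaltBridge]:
    """All acid/base pairs at the helix-favourable i, i+4 spacing."""
    bridges = []
    for i in range(len(p.seq) - 4):
        x, y = p.seq[i], p.seq[i + 4]
        if x in ACIDIC and y in BASIC:
            bridges.append(SaltBridge(i, i + 4, "acid-first"))
        elif x in BASIC and y in ACIDIC:
            bridges.append(SaltBridge(i, i + 4, "base-first"))
    return bridges


def n_cap(p: ProteinRecord, acid_window: int = 3, pg_window: int = 8) -> NCap:
    """N-terminal capping residues: the first Asp/Glu within ``acid_window``
    residues after an initiator Met (or from residue 0 if the chain starts
    without Met), and the first Pro/Gly within ``pg_window``."""
    offset = 1 if p.seq.startswith("M") else 0
    acidic_pos = next(
        (i for i in range(offset, min(offset + acid_window, len(p.seq))) if p.seq[i] in ACIDIC),
        None,
    )
    pg_pos = next(
        (i for i in range(offset, min(offset + pg_window, len(p.seq))) if p.seq[i] in BREAKERS),
        None,
    )
    return NCap(acidic_pos, pg_pos)


def internal_breakers(p: ProteinRecord, margin: int = 5) -> list[int]:
    """Positions of helix-breaking Pro/Gly away from both termini (at least
    ``margin`` residues in).  Canonical flounder/sculpin isoforms have none;
    snailfish isoforms do."""
    if len(p.seq) <= 2 * margin:
        raise ValueError(f"sequence of length {len(p.seq)} too short for margin {margin}")
    return [i for i in range(margin, len(p.seq) - margin) if p.seq[i] in BREAKERS]


@dataclass
class HelixFeatureReport:
    id: str
    length: int
    ala_mol_percent: float
    thr_period: ThrPeriod
    motif_triplets: list[tuple[int, int, int]]
    salt_bridges: list[SaltBridge]
    n_cap: NCap
    internal_breakers: list[int]
    n_thr_substitutions: int


def build_report(
    p: ProteinRecord,
    period: int = 11,
    acid_window: int = 3,
    pg_window: int = 8,
    margin: int = 5,
) -> HelixFeatureReport:
    """Full feature annotation of one peptide."""
    tp = thr_periodicity(p, period=period)
    return HelixFeatureReport(
        id=p.id,
        length=len(p.seq),
        ala_mol_percent=ala_mol_percent(p),
        thr_period=tp,
        motif_triplets=ice_binding_triplets(p, period=period),
        salt_bridges=salt_bridges(p),
        n_cap=n_cap(p, acid_window=acid_window, pg_window=pg_window),
        internal_breakers=(
            internal_breakers(p, margin=margin) if len(p.seq) > 2 * margin else []
        ),
        n_thr_substitutions=tp.n_substitute_hits,
    )
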