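"""Codon-usage statistics and background-dataset curation.

The central statistic of the whole analysis is the 4-vector of Ala codon
fractions (GCT, GCC, GCA, GCG) within a gene or a pooled gene set.  Type I
antifreeze-protein genes from different fish lineages peak on different Ala
codons (cunner GCT, flounder/snailfish GCC, sculpin GCG) even though the
non-AFP genes of all four groups share a mild GCC preference — one line of
evidence that the AFP genes do not descend from one progenitor.

Background (non-AFP) datasets are curated before profiling: within one
species, among mutually similar coding sequences (>65% global-alignment
identity by default) only the longest is kept, and sequences shorter than
50 codons are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .seqio import AnnotatedSequence, FrameError, coding_sequence

__all__ = [
    "ALA_CODONS",
    "CodonUsageTable",
    "AlaCodonProfile",
    "count_codons",
    "ala_profile",
    "gc_content",
    "profile_distance",
    "pairwise_identity",
    "curate_background",
]

ALA_CODONS = ("GCT", "GCC", "GCA", "GCG")

_BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass
class CodonUsageTable:
    """Per-codon counts over in-frame codons; N-containing codons excluded."""

    counts: dict[str, int] = field(default_factory=dict)
    n_codons: int = 0
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_codons != sum(self.counts.values()):
            raise ValueError("n_codons must equal the sum of counts")


@dataclass(frozen=True)
class AlaCodonProfile:
    """Fractions of the four Ala codons in fixed order (GCT, GCC, GCA, GCG)."""

    fractions: tuple[float, float, float, float]
    n_ala: int

    def __post_init__(self) -> None:
        if self.n_ala > 0:
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1 when n_ala > 0")
        elif any(self.fractions):
            raise ValueError("fractions must be all zero when n_ala == 0")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ALA_CODONS, self.fractions))


def trim_partial_codons(cds: str) -> str:
    """Drop trailing bases so the length is a multiple of 3."""
    return cds[: len(cds) - len(cds) % 3]


def count_codons(cds: str, source_id: str = "") -> CodonUsageTable:
    """Tally in-frame codons of a CDS; codons containing N are skipped
    (they count neither in ``counts`` nor in ``n_codons``)."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not divisible by 3 (trim first)")
    counts: dict[str, int] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(
        counts=counts,
        n_codons=sum(counts.values()),
        source_ids=[source_id] if source_id else [],
    )


def ala_profile(tables: CodonUsageTable | Iterable[CodonUsageTable]) -> AlaCodonProfile:
    """Pool one or more codon tables and return the Ala codon fractions."""
    if isinstance(tables, CodonUsageTable):
        tables = [tables]
    pooled = {c: 0 for c in ALA_CODONS}
    for t in tables:
        for c in ALA_CODONS:
            pooled[c] += t.counts.get(c, 0)
    n_ala = sum(pooled.values())
    if n_ala == 0:
        return AlaCodonProfile(fractions=(0.0, 0.0, 0.0, 0.0), n_ala=0)
    return AlaCodonProfile(
        fractions=tuple(pooled[c] / n_ala for c in ALA_CODONS), n_ala=n_ala
    )


def gc_content(nt: str) -> float:
    """GC content in percent, ignoring N."""
    nt = nt.upper().replace("U", "T")
    counted = [b for b in nt if b in "ACGT"]
    if not counted:
        raise ValueError("GC content undefined: no unambiguous bases")
    gc = sum(1 for b in counted if b in "GC")
    return 100.0 * gc / len(counted)


def profile_distance(p: AlaCodonProfile, q: AlaCodonProfile) -> float:
    """Total variation distance between two Ala codon profiles, in [0, 1]."""
    if p.n_ala == 0 or q.n_ala == 0:
        raise ValueError("profile_distance undefined for empty profiles")
    return 0.5 * sum(abs(a - b) for a, b in zip(p.fractions, q.fractions))


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )


def pairwise_identity(
    a: str, b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> float:
    """Percent identity from a global (Needleman-Wunsch) alignment.

    Identity is matched columns over all alignment columns, gap columns
    included, so indels dilute identity rather than being ignored.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    aln = _aligner(match, mismatch, gap).align(a.upper(), b.upper())[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    return 100.0 * c.identities / columns


def _curation_cds(rec: AnnotatedSequence) -> str:
    try:
        cds = coding_sequence(rec)
    except Exception:
        cds = rec.seq  # bare-CDS records without annotations
    return trim_partial_codons(cds)


def curate_background(
    seqs: Sequence[AnnotatedSequence],
    identity_threshold: float = 65.0,
    min_codons: int = 50,
) -> list[AnnotatedSequence]:
    """Redundancy- and length-filter a background CDS set, per species.

    Greedy by descending CDS length (ties broken by id): a sequence is kept
    only if it shares at most ``identity_threshold`` percent global-alignment
    identity with every longer sequence already kept from the same species.
    Sequences with fewer than ``min_codons`` complete codons are dropped.
    Idempotent; input order is restored on output.
    """
    order = {rec.id: i for i, rec in enumerate(seqs)}
    long_enough = [rec for rec in seqs if len(_curation_cds(rec)) // 3 >= min_codons]
    kept: list[AnnotatedSequence] = []
    kept_cds_by_species: dict[str, list[str]] = {}
    for rec in sorted(long_enough, key=lambda r: (-len(_curation_cds(r)), r.id)):
        cds = _curation_cds(rec)
        rivals = kept_cds_by_species.setdefault(rec.species, [])
        if all(pairwise_identity(cds, other) <= identity_threshold for other in rivals):
            kept.append(rec)
            rivals.append(cds)
    return sorted(kept, key=lambda r: order[r.id])


def usage_table_rows(
    records: Sequence[AnnotatedSequence],
    mature_only: bool = False,
) -> list[dict]:
    """Long-form codon usage rows for TSV output: one row per codon with its
    amino acid, count and within-synonymous-family fraction."""
    from .seqio import _FORWARD, STOP_CODONS  # codon -> amino acid map

    tables = []
    for rec in records:
        cds = trim_partial_codons(coding_sequence(rec, mature_only=mature_only))
        tables.append(count_codons(cds, source_id=rec.id))
    pooled: dict[str, int] = {c: 0 for c in ALL_CODONS}
    for t in tables:
        for c, n in t.counts.items():
            pooled[c] += n
    aa_of = {c: ("*" if c in STOP_CODONS else _FORWARD[c]) for c in ALL_CODONS}
    family_total: dict[str, int] = {}
    for c in ALL_CODONS:
        family_total[aa_of[c]] = family_total.get(aa_of[c], 0) + pooled[c]
    rows = []
    for c in ALL_CODONS:
        tot = family_total[aa_of[c]]
        rows.append(
            {
                "codon": c,
                "amino_acid": aa_of[c],
                "count": pooled[c],
                "fraction_within_family": (pooled[c] / tot) if tot else 0.0,
            }
        )
    return rows


def record_ala_profile(rec: AnnotatedSequence, mature_only: bool = False) -> AlaCodonProfile:
    """Ala codon profile of one annotated record's coding sequence."""
    cds = trim_partial_codons(coding_sequence(rec, mature_only=mature_only))
    return ala_profile(count_codons(cds, source_id=rec.id))


def utr_gc_content(rec: AnnotatedSequence) -> float:
    """GC percent of the concatenated untranslated flanks of a record."""
    from .seqio import UTR_KINDS

    parts = [rec.seq[r.start : r.end] for r in rec.regions if r.kind in UTR_KINDS]
    if not parts:
        raise ValueError(f"{rec.id}: no UTR regions annotated")
    return gc_content("".join(parts))
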