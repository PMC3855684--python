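"""Sequence and region-annotation I/O with one coordinate convention.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Stored nucleotide sequences are always the sense strand; the antisense
strand is computed on the fly where needed and never stored.  ``N`` is the
only ambiguity code accepted: it never matches in dot plots, codons
containing it are excluded from codon counts, and it translates to ``X``.

Region annotations travel in a BED-like 4-column TSV
(``seq_id<TAB>start<TAB>end<TAB>kind``) rather than GenBank flat files, so
the whole pipeline runs offline on FASTA + TSV pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO as _BioSeqIO
from Bio.Data import CodonTable

__all__ = [
    "RegionKind",
    "Region",
    "AnnotatedSequence",
    "ProteinRecord",
    "SeqIOError",
    "DuplicateIdError",
    "RegionError",
    "RegionAbsentError",
    "FrameError",
    "PrematureStopError",
    "read_fasta",
    "write_fasta",
    "read_protein_fasta",
    "read_regions",
    "write_regions",
    "extract_region",
    "coding_sequence",
    "translate",
    "reverse_complement",
]

NUCLEOTIDES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# translation table 1 (standard genetic code)
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class SeqIOError(ValueError):
    """Base error for sequence/region I/O problems."""


class DuplicateIdError(SeqIOError):
    pass


class RegionError(SeqIOError):
    pass


class RegionAbsentError(RegionError):
    """A requested region kind does not exist on the record (distinct from
    an annotated-but-empty region, which cannot occur: start < end)."""


class FrameError(SeqIOError):
    pass


class PrematureStopError(FrameError):
    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon at codon {codon_index}")


class RegionKind(str, enum.Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    SIGNAL_PEPTIDE = "signal_peptide"
    PROPEPTIDE = "propeptide"
    MATURE_CDS = "mature_cds"
    INTRON = "intron"
    THREE_PRIME_UTR = "three_prime_utr"

    def __str__(self) -> str:  # TSV round-trip friendliness
        return self.value


#: region kinds that contribute to the translated product, in reading order
CODING_KINDS = (RegionKind.SIGNAL_PEPTIDE, RegionKind.PROPEPTIDE, RegionKind.MATURE_CDS)

#: untranslated flanks
UTR_KINDS = (RegionKind.FIVE_PRIME_UTR, RegionKind.THREE_PRIME_UTR)


@dataclass(frozen=True, order=True)
class Region:
    """A typed, 0-based half-open interval on one sequence."""

    start: int
    end: int
    kind: RegionKind
    note: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionError(
                f"invalid region range [{self.start}, {self.end}) for kind {self.kind}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def _validate_regions(regions: Iterable[Region], seq_len: int, seq_id: str = "?") -> list[Region]:
    regs = sorted(regions, key=lambda r: (r.start, r.end))
    for r in regs:
        if r.end > seq_len:
            raise RegionError(
                f"{seq_id}: region {r.kind}[{r.start},{r.end}) exceeds sequence length {seq_len}"
            )
    for prev, nxt in zip(regs, regs[1:]):
        if nxt.start < prev.end:
            raise RegionError(
                f"{seq_id}: overlapping regions {prev.kind}[{prev.start},{prev.end}) "
                f"and {nxt.kind}[{nxt.start},{nxt.end})"
            )
    return regs


@dataclass
class AnnotatedSequence:
    """A sense-strand nucleotide record plus its typed regions."""

    id: str
    seq: str
    species: str = ""
    group: str = "other"
    regions: list[Region] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise SeqIOError(f"{self.id}: empty sequence")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise SeqIOError(f"{self.id}: non-nucleotide characters {sorted(bad)}")
        self.regions = _validate_regions(self.regions, len(self.seq), self.id)

    def with_regions(self, regions: Iterable[Region]) -> "AnnotatedSequence":
        return replace(self, regions=list(regions))

    def region_kinds(self) -> set[RegionKind]:
        return {r.kind for r in self.regions}


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence (20 letters + X), no internal stop."""

    id: str
    seq: str
    provenance: str = "direct"  # "translated" | "direct"

    def __post_init__(self) -> None:
        if not self.seq:
            raise SeqIOError(f"{self.id}: empty protein sequence")
        bad = set(self.seq) - AMINO_ACIDS - {"X"}
        if bad:
            raise SeqIOError(f"{self.id}: invalid amino-acid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


def _normalize_nt(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise SeqIOError(f"{rec_id}: non-nucleotide characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[AnnotatedSequence]:
    """Read nucleotide FASTA into annotation-free records.

    Ids are the header token up to the first whitespace; input order is
    preserved.  RNA (``U``) and lowercase are normalized to uppercase DNA.
    """
    records: list[AnnotatedSequence] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            AnnotatedSequence(id=rec.id, seq=_normalize_nt(str(rec.seq), rec.id), source=str(path))
        )
    if not records:
        raise SeqIOError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[AnnotatedSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_protein_fasta(path: str | Path, provenance: str = "direct") -> list[ProteinRecord]:
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, seq=str(rec.seq).upper(), provenance=provenance))
    if not records:
        raise SeqIOError(f"no records in {path}")
    return records


def read_regions(path: str | Path) -> dict[str, list[Region]]:
    """Read a BED-like 4-column TSV of regions, validated per sequence id.

    Columns: seq_id, start (0-based), end (exclusive), kind.  Lines starting
    with ``#`` and blank lines are ignored.  Overlaps within one id and
    unknown kinds are errors.
    """
    by_id: dict[str, list[Region]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise RegionError(f"{path}:{lineno}: expected 4 tab-separated columns")
            seq_id, start_s, end_s, kind_s = fields[:4]
            note = fields[4] if len(fields) > 4 else ""
            try:
                kind = RegionKind(kind_s)
            except ValueError:
                raise RegionError(f"{path}:{lineno}: unknown region kind {kind_s!r}") from None
            by_id.setdefault(seq_id, []).append(
                Region(start=int(start_s), end=int(end_s), kind=kind, note=note)
            )
    # overlap validation (sequence length unknown here; checked on attach)
    for seq_id, regs in by_id.items():
        regs.sort(key=lambda r: (r.start, r.end))
        for prev, nxt in zip(regs, regs[1:]):
            if nxt.start < prev.end:
                raise RegionError(
                    f"{seq_id}: overlapping regions {prev.kind}[{prev.start},{prev.end}) "
                    f"and {nxt.kind}[{nxt.start},{nxt.end})"
                )
    return by_id


def write_regions(by_id: dict[str, list[Region]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id in by_id:
            for r in sorted(by_id[seq_id], key=lambda r: (r.start, r.end)):
                fh.write(f"{seq_id}\t{r.start}\t{r.end}\t{r.kind.value}")
                fh.write(f"\t{r.note}\n" if r.note else "\n")


def attach_regions(
    records: Iterable[AnnotatedSequence], by_id: dict[str, list[Region]]
) -> list[AnnotatedSequence]:
    """Return records with regions from ``by_id`` attached and validated."""
    return [rec.with_regions(by_id.get(rec.id, [])) for rec in records]


def extract_region(rec: AnnotatedSequence, kind: RegionKind | str) -> str:
    """Concatenate all regions of ``kind`` in coordinate order.

    Raises :class:`RegionAbsentError` if the record has no region of that
    kind — deliberately distinct from returning an empty string.
    """
    kind = RegionKind(kind)
    parts = [rec.seq[r.start : r.end] for r in rec.regions if r.kind == kind]
    if not parts:
        raise RegionAbsentError(f"{rec.id}: no region of kind {kind.value}")
    return "".join(parts)


def coding_sequence(rec: AnnotatedSequence, mature_only: bool = False) -> str:
    """The translatable sequence: signal peptide + propeptide + mature CDS,
    concatenated in coordinate order (introns are excluded by construction
    since they are separate regions)."""
    kinds = (RegionKind.MATURE_CDS,) if mature_only else CODING_KINDS
    parts = [rec.seq[r.start : r.end] for r in sorted(rec.regions) if r.kind in kinds]
    if not parts:
        raise RegionAbsentError(f"{rec.id}: no coding regions")
    return "".join(parts)


def translate(cds: str, rec_id: str = "cds") -> ProteinRecord:
    """Translate an in-frame CDS under the standard genetic code.

    Codons containing ``N`` become ``X``; a trailing stop codon is stripped;
    an internal stop raises :class:`PrematureStopError` with its 0-based
    codon index.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise FrameError(f"{rec_id}: CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    aas: list[str] = []
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in STOP_CODONS:
            if ci == n_codons - 1:
                break  # trailing stop stripped
            raise PrematureStopError(ci)
        else:
            aas.append(_FORWARD[codon])
    if not aas:
        raise FrameError(f"{rec_id}: CDS is a bare stop codon")
    return ProteinRecord(id=rec_id, seq="".join(aas), provenance="translated")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]
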