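"""Alternative-reading-frame products of codon runs and poly-Ala potential.

A tandem run of one codon encodes a homopolymer, but the same DNA read in
the two shifted sense frames, or in any of the three antisense frames,
encodes five other homopolymers.  A GCT run (poly-Ala) read shifted gives
poly-Leu or poly-Cys, and its antisense gives poly-Ser/Ala/Gln — so an
Ala-rich coding sequence can arise from a frameshift or strand switch on a
run of some other codon.  These utilities enumerate those products and scan
sequences for trinucleotide microsatellites and for any segment that could
encode a run of Ala in one of the six frames.

Frame convention: sense frame +1 discards the first base of the repeat,
+2 discards two; antisense frame 0 is the reverse complement read from its
own 5' end, with +1/+2 discarding bases from there.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import reverse_complement

__all__ = [
    "FrameProducts",
    "CodonRun",
    "PolyAlaSegment",
    "alt_frame_products",
    "find_codon_runs",
    "poly_ala_potential",
    "ala_frames_of_codon",
]

_SENSE_FRAMES = ("sense+0", "sense+1", "sense+2")
_ANTI_FRAMES = ("antisense+0", "antisense+1", "antisense+2")


def _translate_codon(codon: str) -> str:
    from .seqio import STOP_CODONS, _FORWARD

    return "*" if codon in STOP_CODONS else _FORWARD[codon]


@dataclass(frozen=True)
class FrameProducts:
    """The five alternative homopolymer products of a tandem codon run."""

    codon: str
    sense_alt: tuple[str, str]  # frames +1, +2
    antisense: tuple[str, str, str]  # antisense frames 0, +1, +2

    def row(self) -> str:
        """Tabular rendering: codon, Xaa/Xaa, Xaa/Xaa/Xaa."""
        return "{}\t{}\t{}".format(
            self.codon, "/".join(self.sense_alt), "/".join(self.antisense)
        )


@dataclass(frozen=True)
class CodonRun:
    """A maximal tandem repeat of one codon within a sequence."""

    codon: str
    start: int
    n_repeats: int
    frame_of_ala: str | None  # which of the 6 frames reads the run as poly-Ala

    @property
    def end(self) -> int:
        return self.start + 3 * self.n_repeats


@dataclass(frozen=True)
class PolyAlaSegment:
    """A segment encoding >= min_ala consecutive Ala in one reading frame.

    Coordinates are on the input (sense) strand, 0-based half-open; for
    antisense frames they delimit the same physical bases.
    """

    start: int
    end: int
    frame: str
    n_ala: int


def _check_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"need an unambiguous trinucleotide, got {codon!r}")
    return codon


def alt_frame_products(codon: str) -> FrameProducts:
    """Amino acids encoded by an infinite tandem repeat of ``codon`` in the
    two shifted sense frames and the three antisense frames.

    Two concatenated copies of the codon suffice: every shifted codon of the
    infinite repeat appears within them.
    """
    codon = _check_codon(codon)
    double = codon + codon
    sense_alt = (_translate_codon(double[1:4]), _translate_codon(double[2:5]))
    rc = reverse_complement(double)
    antisense = tuple(_translate_codon(rc[f : f + 3]) for f in range(3))
    return FrameProducts(codon=codon, sense_alt=sense_alt, antisense=antisense)


def ala_frames_of_codon(codon: str) -> list[str]:
    """The reading frames (of the six) in which a tandem run of ``codon``
    encodes poly-Ala; empty if none."""
    codon = _check_codon(codon)
    fp = alt_frame_products(codon)
    frames = []
    if _translate_codon(codon) == "A":
        frames.append("sense+0")
    for label, aa in zip(_SENSE_FRAMES[1:], fp.sense_alt):
        if aa == "A":
            frames.append(label)
    for label, aa in zip(_ANTI_FRAMES, fp.antisense):
        if aa == "A":
            frames.append(label)
    return frames


def find_codon_runs(nt: str, codon: str, min_run: int = 4) -> list[CodonRun]:
    """Maximal tandem repeats of ``codon`` anywhere in ``nt``.

    Runs at different offsets are reported separately; a run is maximal when
    it cannot be extended by a whole copy of the codon on either side.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    codon = _check_codon(codon)
    nt = nt.upper().replace("U", "T")
    ala_frames = ala_frames_of_codon(codon)
    frame_of_ala = ala_frames[0] if ala_frames else None
    runs: list[CodonRun] = []
    for start in range(len(nt) - 3 * min_run + 1):
        if nt[start : start + 3] != codon:
            continue
        if start >= 3 and nt[start - 3 : start] == codon:
            continue  # not left-maximal
        n = 1
        while nt[start + 3 * n : start + 3 * n + 3] == codon:
            n += 1
        if n >= min_run:
            runs.append(CodonRun(codon=codon, start=start, n_repeats=n, frame_of_ala=frame_of_ala))
    return runs


def _ala_runs_one_frame(nt: str, frame: int, min_ala: int) -> list[tuple[int, int, int]]:
    """(start, end, n_ala) of Ala runs in one sense frame of ``nt``."""
    out = []
    usable = nt[frame:]
    usable = usable[: len(usable) - len(usable) % 3]
    run_start = None
    n_codons = len(usable) // 3
    for ci in range(n_codons + 1):
        codon = usable[3 * ci : 3 * ci + 3] if ci < n_codons else ""
        is_ala = len(codon) == 3 and codon[:2] == "GC" and "N" not in codon
        if is_ala and run_start is None:
            run_start = ci
        elif not is_ala and run_start is not None:
            n = ci - run_start
            if n >= min_ala:
                out.append((frame + 3 * run_start, frame + 3 * ci, n))
            run_start = None
    return out


def poly_ala_potential(nt: str, min_ala: int = 6) -> list[PolyAlaSegment]:
    """All maximal segments encoding >= ``min_ala`` consecutive Ala in any of
    the six reading frames, with the frame that yields the run.

    A Gly-rich GGC run is flagged through its antisense (GCC) frame; a GCG
    run is flagged in sense frame 0; an AT-rich tract is never flagged.
    """
    nt = nt.upper().replace("U", "T")
    segments: list[PolyAlaSegment] = []
    for frame in range(3):
        for start, end, n in _ala_runs_one_frame(nt, frame, min_ala):
            segments.append(PolyAlaSegment(start, end, f"sense+{frame}", n))
    rc = reverse_complement(nt)
    for frame in range(3):
        for start, end, n in _ala_runs_one_frame(rc, frame, min_ala):
            # map back to sense-strand coordinates
            segments.append(
                PolyAlaSegment(len(nt) - end, len(nt) - start, f"antisense+{frame}", n)
            )
    segments.sort(key=lambda s: (s.start, s.end, s.frame))
    return segments
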