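"""Synthetic AFP-like gene families with known ground truth.

The generator emulates the statistical structure the comparative analysis
relies on, so every pipeline stage is testable offline:

* mature peptides built from an ``MDAPA``-style capped start plus 11-aa
  ice-binding repeats (Thr at the repeat start, Ala on the i+4/i+8 face,
  one engineered i,i+4 salt bridge off the ice face), always >50 mol% Ala;
* coding sequences back-translated with a configurable Ala codon bias — the
  lineage fingerprint the codon-usage module is meant to recover;
* paralog families descending from one ancestor: point substitutions, UTR
  indels, whole-repeat (33-nt) copy-number changes in the Ala-coding block,
  and a length-variable GT microsatellite in the 3' UTR; UTR divergence is
  kept low (>90% pairwise identity at defaults) as in a real gene family;
* independent "convergent" groups sharing only the peptide design
  constraints, with unrelated UTRs and distinct codon biases;
* background (non-AFP) gene sets with a common, mildly GCC-leaning Ala
  codon usage.

Flanking non-coding GC content is drawn uniformly from 37-44%, the range
observed for the real cDNAs.  Every stochastic choice flows from one
``numpy`` generator seeded by the config, so identical configs produce
byte-identical datasets, and each paralog's event log can be replayed
exactly on the ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .seqio import (
    AnnotatedSequence,
    ProteinRecord,
    Region,
    RegionKind,
    _FORWARD,
)

__all__ = [
    "SyntheticConfig",
    "FamilyTruth",
    "make_mature_peptide",
    "back_translate",
    "make_ancestor",
    "make_family",
    "make_convergent_groups",
    "make_background_genes",
    "apply_events",
]

ALA_CODONS = ("GCT", "GCC", "GCA", "GCG")

# synonymous codon lists per amino acid, in fixed (sorted) order
_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_FORWARD.items()):
    _SYNONYMS.setdefault(_aa, ())
    _SYNONYMS[_aa] = _SYNONYMS[_aa] + (_codon,)

#: length of the capped peptide start (Met, Asp cap, Pro cap: "MDAPA")
_CAP = "MDAPA"
_REPEAT_LEN = 11


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults define the reference study conditions."""

    seed: int = 0
    n_repeats: int = 3
    #: Ala codon bias of the AFP family over (GCT, GCC, GCA, GCG);
    #: default is a sculpin-like GCG-dominant profile
    ala_bias: tuple[float, float, float, float] = (0.06, 0.14, 0.26, 0.54)
    #: Ala bias of background genes: mild GCC preference shared by all groups
    background_bias: tuple[float, float, float, float] = (0.30, 0.40, 0.20, 0.10)
    utr5_len: int = 150
    utr3_len: int = 300
    point_mut_rate: float = 0.01
    indel_rate: float = 0.5  # expected indel events per UTR per paralog
    indel_len_range: tuple[int, int] = (1, 6)
    repeat_cnv_prob: float = 0.2
    #: probability that a Thr repeat slot carries an Ile/Leu substitute
    thr_substitution_rate: float = 0.0
    #: introns inserted within the 5' UTR (gene-structure variation between
    #: lineages; the coding sequence itself stays contiguous)
    n_introns: int = 0
    intron_len: int = 90
    n_paralogs: int = 6
    scenario: str = "homologous"  # "homologous" | "convergent"

    def __post_init__(self) -> None:
        for bias in (self.ala_bias, self.background_bias):
            if abs(sum(bias) - 1.0) > 1e-9 or any(b < 0 for b in bias):
                raise ValueError("codon biases must be non-negative and sum to 1")
        for p in (self.point_mut_rate, self.repeat_cnv_prob, self.thr_substitution_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.scenario not in ("homologous", "convergent"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


#: event tuples: ("sub", pos, base) | ("ins"/"cnv_ins", pos, seq) |
#: ("del"/"cnv_del", pos, length); positions refer to the sequence state
#: at the moment the event is applied.
Event = tuple


@dataclass
class FamilyTruth:
    """Ground truth of one simulated family: replaying each paralog's event
    log on the ancestor reproduces the paralog byte-exactly."""

    ancestor_seq: str
    ancestor_regions: list[Region]
    events: dict[str, list[Event]]
    true_phase: int
    true_ala_bias: tuple[float, float, float, float]


def make_mature_peptide(cfg: SyntheticConfig, rng: np.random.Generator) -> ProteinRecord:
    """Design one capped, repeat-structured, Ala-dominated peptide.

    Layout: ``MDAPA`` then ``n_repeats`` × (Thr + 10 Ala), with Lys/Asp at
    off-face slots 2 and 6 of the first repeat forming an i,i+4 salt bridge.
    Thr slots may carry Ile/Leu substitutes at ``thr_substitution_rate``.
    The first Thr sits at position 5, so the true repeat phase is
    ``5 mod 11``.
    """
    residues = list(_CAP)
    for r in range(cfg.n_repeats):
        block = ["A"] * _REPEAT_LEN
        if rng.random() < cfg.thr_substitution_rate:
            block[0] = "I" if rng.random() < 0.5 else "L"
        else:
            block[0] = "T"
        if r == 0:
            block[2], block[6] = "K", "D"
        residues.extend(block)
    return ProteinRecord(id="peptide", seq="".join(residues), provenance="direct")


TRUE_PHASE = len(_CAP) % _REPEAT_LEN  # repeat phase of generated peptides


def back_translate(
    p: ProteinRecord,
    ala_bias: Sequence[float],
    rng: np.random.Generator,
) -> str:
    """Back-translate a peptide: Ala codons drawn from ``ala_bias`` (over
    GCT, GCC, GCA, GCG), all other residues uniform over their synonymous
    codons.  No stop codon is appended, so translating the result restores
    ``p`` exactly."""
    bias = np.asarray(ala_bias, dtype=float)
    if bias.shape != (4,) or abs(bias.sum() - 1.0) > 1e-9:
        raise ValueError("ala_bias must be a 4-vector summing to 1")
    codons: list[str] = []
    for aa in p.seq:
        if aa == "A":
            codons.append(ALA_CODONS[rng.choice(4, p=bias)])
        else:
            syn = _SYNONYMS[aa]
            codons.append(syn[rng.integers(len(syn))])
    return "".join(codons)


def _random_utr(length: int, rng: np.random.Generator) -> str:
    """Random non-coding tract at a GC content drawn uniformly in 37-44%."""
    gc = rng.uniform(0.37, 0.44)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_ancestor(
    cfg: SyntheticConfig, rng: np.random.Generator, seq_id: str = "ancestor"
) -> AnnotatedSequence:
    """One ancestral gene: 5' UTR (with an in-frame stop 15 nt upstream of
    the start codon), CDS ending in a stop codon, and a 3' UTR carrying a
    GT microsatellite."""
    utr5 = list(_random_utr(cfg.utr5_len, rng))
    if cfg.utr5_len >= 15:
        utr5[-15:-12] = "TAA"  # upstream in-frame stop: no signal peptide here
    utr5 = "".join(utr5)
    # introns split the 5' UTR at evenly spaced offsets
    upstream_regions: list[Region] = []
    if cfg.n_introns > 0:
        step = cfg.utr5_len // (cfg.n_introns + 1)
        pieces: list[str] = []
        prev = 0
        pos = 0
        for k in range(1, cfg.n_introns + 1):
            cut = step * k
            pieces.append(utr5[prev:cut])
            upstream_regions.append(
                Region(pos, pos + (cut - prev), RegionKind.FIVE_PRIME_UTR)
            )
            pos += cut - prev
            intron = _random_utr(cfg.intron_len, rng)
            pieces.append(intron)
            upstream_regions.append(Region(pos, pos + len(intron), RegionKind.INTRON))
            pos += len(intron)
            prev = cut
        pieces.append(utr5[prev:])
        upstream_regions.append(
            Region(pos, pos + (cfg.utr5_len - prev), RegionKind.FIVE_PRIME_UTR)
        )
        utr5 = "".join(pieces)
    else:
        upstream_regions.append(Region(0, cfg.utr5_len, RegionKind.FIVE_PRIME_UTR))
    peptide = make_mature_peptide(cfg, rng)
    cds = back_translate(peptide, cfg.ala_bias, rng) + "TAA"
    gt_units = int(rng.integers(5, 10))
    tract = "GT" * gt_units
    flank = max(cfg.utr3_len - len(tract), 2)
    cut = flank // 2
    raw3 = _random_utr(flank, rng)
    utr3 = raw3[:cut] + tract + raw3[cut:]
    seq = utr5 + cds + utr3
    u5, c = len(utr5), len(cds)
    regions = upstream_regions + [
        Region(u5, u5 + c, RegionKind.MATURE_CDS),
        Region(u5 + c, len(seq), RegionKind.THREE_PRIME_UTR),
    ]
    return AnnotatedSequence(
        id=seq_id, seq=seq, species="synthetic", group="synthetic", regions=regions,
        source="synthetic",
    )


def apply_events(
    seq: str, regions: Sequence[Region], events: Sequence[Event]
) -> tuple[str, list[Region]]:
    """Apply an event log to a sequence, keeping region annotations in
    register.  Insertions are generated strictly inside a region and extend
    it; deletions fall wholly inside one region."""
    regs = list(regions)
    for ev in events:
        kind = ev[0]
        if kind == "sub":
            _, pos, base = ev
            seq = seq[:pos] + base + seq[pos + 1 :]
        elif kind in ("ins", "cnv_ins"):
            _, pos, ins = ev
            seq = seq[:pos] + ins + seq[pos:]
            delta = len(ins)
            regs = [
                replace(
                    r,
                    start=r.start + delta if pos <= r.start else r.start,
                    end=r.end + delta if pos < r.end or pos <= r.start else r.end,
                )
                for r in regs
            ]
        elif kind in ("del", "cnv_del"):
            _, pos, length = ev
            seq = seq[:pos] + seq[pos + length :]
            regs = [
                replace(
                    r,
                    start=r.start - length if pos < r.start else r.start,
                    end=r.end - length if pos + length <= r.end else r.end,
                )
                for r in regs
            ]
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    return seq, regs


def _sample_events(
    cfg: SyntheticConfig,
    ancestor: AnnotatedSequence,
    rng: np.random.Generator,
) -> list[Event]:
    """Sample one paralog's mutation history on the ancestor.

    Order: repeat copy-number change first (on pristine coordinates), then
    point substitutions, then UTR indels.  Substitutions inside the coding
    region that would create a premature stop codon are discarded, so every
    paralog stays translatable."""
    events: list[Event] = []
    seq, regs = ancestor.seq, list(ancestor.regions)

    cds_region = next(r for r in regs if r.kind == RegionKind.MATURE_CDS)
    block_start = cds_region.start + 3 * len(_CAP)
    if rng.random() < cfg.repeat_cnv_prob and cfg.n_repeats >= 1:
        unit = 3 * _REPEAT_LEN
        r_idx = int(rng.integers(cfg.n_repeats))
        pos = block_start + unit * r_idx
        if cfg.n_repeats >= 2 and rng.random() < 0.5:
            events.append(("cnv_del", pos, unit))
        else:
            events.append(("cnv_ins", pos, seq[pos : pos + unit]))
        seq, regs = apply_events(seq, regs, events[-1:])

    cds_region = next(r for r in regs if r.kind == RegionKind.MATURE_CDS)
    n_sites = len(seq)
    hit = np.nonzero(rng.random(n_sites) < cfg.point_mut_rate)[0]
    bases = "ACGT"
    subs: list[Event] = []
    for pos in hit:
        pos = int(pos)
        old = seq[pos]
        alternatives = [b for b in bases if b != old]
        new = alternatives[rng.integers(3)]
        if cds_region.contains(pos):
            ci = (pos - cds_region.start) // 3
            c0 = cds_region.start + 3 * ci
            codon = seq[c0 : c0 + 3]
            mutated = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
            is_last_codon = c0 + 3 >= cds_region.end
            if mutated in ("TAA", "TAG", "TGA") and not is_last_codon:
                continue  # keep paralogs translatable
        subs.append(("sub", pos, new))
    seq, regs = apply_events(seq, regs, subs)
    events.extend(subs)

    for kind in (RegionKind.FIVE_PRIME_UTR, RegionKind.THREE_PRIME_UTR):
        n_indels = int(rng.poisson(cfg.indel_rate))
        for _ in range(n_indels):
            # choose among the (possibly intron-split) parts, weighted by length
            parts = [r for r in regs if r.kind == kind]
            weights = np.array([len(r) for r in parts], dtype=float)
            region = parts[rng.choice(len(parts), p=weights / weights.sum())]
            lo, hi = cfg.indel_len_range
            length = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5 and len(region) > length + 2:
                pos = int(rng.integers(region.start + 1, region.end - length))
                ev: Event = ("del", pos, length)
            else:
                pos = int(rng.integers(region.start + 1, region.end))
                ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
                ev = ("ins", pos, ins)
            seq, regs = apply_events(seq, regs, [ev])
            events.append(ev)
    return events


def make_family(
    cfg: SyntheticConfig, label: str = "fam"
) -> tuple[list[AnnotatedSequence], FamilyTruth]:
    """One homologous paralog family descending from a single ancestor."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = make_ancestor(cfg, rng, seq_id=f"{label}_anc")
    records: list[AnnotatedSequence] = []
    events: dict[str, list[Event]] = {}
    for k in range(cfg.n_paralogs):
        pid = f"{label}_p{k + 1}"
        evs = _sample_events(cfg, ancestor, rng)
        seq, regs = apply_events(ancestor.seq, ancestor.regions, evs)
        records.append(
            AnnotatedSequence(
                id=pid, seq=seq, species="synthetic", group=label, regions=regs,
                source="synthetic",
            )
        )
        events[pid] = evs
    truth = FamilyTruth(
        ancestor_seq=ancestor.seq,
        ancestor_regions=list(ancestor.regions),
        events=events,
        true_phase=TRUE_PHASE,
        true_ala_bias=cfg.ala_bias,
    )
    return records, truth


def make_convergent_groups(
    cfgs: Sequence[SyntheticConfig], labels: Sequence[str] | None = None
) -> dict[str, tuple[list[AnnotatedSequence], FamilyTruth]]:
    """Independent families sharing only the peptide design constraints:
    separate ancestors, unrelated UTRs, and (by precondition) distinct Ala
    codon biases — the convergent-evolution scenario."""
    if len(cfgs) < 2:
        raise ValueError("need at least 2 groups for a convergent scenario")
    for cfg in cfgs:
        if cfg.scenario != "convergent":
            raise ValueError("all configs must have scenario='convergent'")
    if len({cfg.ala_bias for cfg in cfgs}) != len(cfgs):
        raise ValueError("convergent groups must have distinct ala_bias")
    if labels is None:
        labels = [f"group{chr(ord('A') + i)}" for i in range(len(cfgs))]
    return {
        label: make_family(cfg, label=label) for label, cfg in zip(labels, cfgs)
    }


def make_background_genes(
    cfg: SyntheticConfig,
    n_genes: int,
    rng: np.random.Generator,
    codon_len_range: tuple[int, int] = (50, 500),
) -> list[AnnotatedSequence]:
    """Random non-AFP coding sequences: uniform amino acids, Ala codons
    drawn from the shared GCC-leaning background bias, lengths 50-500
    codons.  Long and mutually dissimilar, so they survive the curation
    filters by construction."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    aa_alphabet = sorted(set(_FORWARD.values()))
    out: list[AnnotatedSequence] = []
    for g in range(n_genes):
        n_codons = int(rng.integers(codon_len_range[0], codon_len_range[1] + 1))
        aas = "M" + "".join(
            aa_alphabet[i] for i in rng.integers(len(aa_alphabet), size=n_codons - 1)
        )
        p = ProteinRecord(id=f"bg{g + 1}", seq=aas, provenance="direct")
        cds = back_translate(p, cfg.background_bias, rng) + "TAA"
        out.append(
            AnnotatedSequence(
                id=f"bg{g + 1}",
                seq=cds,
                species="synthetic",
                group="background",
                regions=[Region(0, len(cds), RegionKind.MATURE_CDS)],
                source="synthetic",
            )
        )
    return out
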