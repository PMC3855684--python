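"""Convergence-diagnostic report over groups of annotated AFP genes.

The verdict logic makes the comparative argument explicit: genes that
descend from one progenitor should share recognizable UTRs, a common Ala
codon bias, and a common gene structure (intron count/placement).  For each
pair of lineage groups the report computes a UTR similarity score from the
dot matrix, the total-variation distance between pooled Ala codon profiles,
and an intron-structure agreement bit, then sets three heuristic flags
(``utr_dissimilar``, ``codon_bias_discordant``, ``gene_structure_discordant``)
at configurable thresholds.  The flags are deliberately labelled heuristics:
they formalize a qualitative argument, not a statistical test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import codon_usage as cu
from . import dotplot as dp
from . import helix_features as hf
from .seqio import (
    AnnotatedSequence,
    RegionKind,
    coding_sequence,
    translate,
)

__all__ = ["ReportParams", "GroupSummary", "PairComparison", "ConvergenceReport",
           "run_report", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReportParams:
    window: int = 12
    min_matches: int = 9
    min_run: int = 3
    utr_dissimilar_below: float = 0.1
    codon_discordant_above: float = 0.3


@dataclass
class GroupSummary:
    group: str
    n_records: int
    afp_profile: cu.AlaCodonProfile
    background_profile: cu.AlaCodonProfile | None
    intron_counts: set[int]
    signal_peptide_present: bool
    mean_ala_mol_percent: float
    mean_period_score: float


@dataclass
class PairComparison:
    group_a: str
    group_b: str
    utr_similarity: float | None  # None when a UTR annotation is missing
    cds_match_density: float
    profile_distance: float
    intron_structure_agrees: bool
    utr_dissimilar: bool | None
    codon_bias_discordant: bool
    gene_structure_discordant: bool


@dataclass
class ConvergenceReport:
    params: ReportParams
    per_group: dict[str, GroupSummary]
    pairwise: dict[tuple[str, str], PairComparison]
    dotplots: dict[tuple[str, str], dp.DotplotResult] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)


def _group_records(records: Sequence[AnnotatedSequence]) -> dict[str, list[AnnotatedSequence]]:
    by_group: dict[str, list[AnnotatedSequence]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)
    return by_group


def _group_profile(records: Sequence[AnnotatedSequence]) -> cu.AlaCodonProfile:
    tables = []
    for rec in records:
        cds = cu.trim_partial_codons(coding_sequence(rec))
        tables.append(cu.count_codons(cds, source_id=rec.id))
    return cu.ala_profile(tables)


def _summarize_group(
    group: str,
    records: Sequence[AnnotatedSequence],
    background: Sequence[AnnotatedSequence] | None,
) -> GroupSummary:
    reports = []
    for rec in records:
        protein = translate(coding_sequence(rec), rec_id=rec.id)
        reports.append(hf.build_report(protein))
    return GroupSummary(
        group=group,
        n_records=len(records),
        afp_profile=_group_profile(records),
        background_profile=_group_profile(background) if background else None,
        intron_counts={
            sum(1 for r in rec.regions if r.kind == RegionKind.INTRON) for rec in records
        },
        signal_peptide_present=any(
            RegionKind.SIGNAL_PEPTIDE in rec.region_kinds() for rec in records
        ),
        mean_ala_mol_percent=sum(r.ala_mol_percent for r in reports) / len(reports),
        mean_period_score=sum(r.thr_period.score for r in reports) / len(reports),
    )


def _has_utr(rec: AnnotatedSequence) -> bool:
    kinds = rec.region_kinds()
    return RegionKind.FIVE_PRIME_UTR in kinds or RegionKind.THREE_PRIME_UTR in kinds


def _cds_density(res: dp.DotplotResult, rec_a, rec_b) -> float:
    coding = {k.value for k in (RegionKind.SIGNAL_PEPTIDE, RegionKind.PROPEPTIDE,
                                RegionKind.MATURE_CDS)}
    tally = dp.region_overlap(res, rec_a.regions, rec_b.regions)
    n_cds = sum(v for (ka, kb), v in tally.items() if ka in coding and kb in coding)
    len_a = sum(len(r) for r in rec_a.regions if r.kind.value in coding)
    len_b = sum(len(r) for r in rec_b.regions if r.kind.value in coding)
    if not len_a or not len_b:
        return 0.0
    return n_cds / (len_a * len_b)


def run_report(
    records: Sequence[AnnotatedSequence],
    background: Sequence[AnnotatedSequence] | None = None,
    params: ReportParams = ReportParams(),
) -> ConvergenceReport:
    """Full pairwise comparison of lineage groups.

    ``records`` carry their group in ``AnnotatedSequence.group``; an
    optional ``background`` set is matched to groups the same way.  Each
    pair of groups is compared through the dot matrix of its longest
    (representative) records, pooled Ala codon profiles, and intron
    structure.  Missing UTR annotations degrade gracefully: the UTR metric
    and its flag become ``None`` and a warning is logged.
    """
    by_group = _group_records(records)
    if len(by_group) < 2:
        raise ValueError("run_report needs records from at least 2 groups")
    bg_by_group = _group_records(background) if background else {}
    logger.info(
        "report over %d groups (%d records), window=%d k=%d",
        len(by_group), len(records), params.window, params.min_matches,
    )

    per_group = {
        g: _summarize_group(g, recs, bg_by_group.get(g))
        for g, recs in sorted(by_group.items())
    }
    representatives = {
        g: max(recs, key=lambda r: (len(r.seq), r.id)).id for g, recs in by_group.items()
    }
    rec_of = {rec.id: rec for rec in records}

    dparams = dp.DotplotParams(window=params.window, min_matches=params.min_matches)
    pairwise: dict[tuple[str, str], PairComparison] = {}
    dotplots: dict[tuple[str, str], dp.DotplotResult] = {}
    groups = sorted(by_group)
    for idx, ga in enumerate(groups):
        for gb in groups[idx + 1 :]:
            ra, rb = rec_of[representatives[ga]], rec_of[representatives[gb]]
            res = dp.compute_dotplot(ra.seq, rb.seq, dparams, a_id=ra.id, b_id=rb.id)
            dotplots[(ga, gb)] = res
            if _has_utr(ra) and _has_utr(rb):
                utr_sim = dp.utr_similarity_score(
                    res, ra.regions, rb.regions, min_run=params.min_run
                )
                utr_flag = utr_sim < params.utr_dissimilar_below
            else:
                logger.warning("pair (%s, %s): UTR annotations missing; "
                               "UTR similarity unavailable", ga, gb)
                utr_sim, utr_flag = None, None
            dist = cu.profile_distance(per_group[ga].afp_profile, per_group[gb].afp_profile)
            introns_agree = per_group[ga].intron_counts == per_group[gb].intron_counts
            pairwise[(ga, gb)] = PairComparison(
                group_a=ga,
                group_b=gb,
                utr_similarity=utr_sim,
                cds_match_density=_cds_density(res, ra, rb),
                profile_distance=dist,
                intron_structure_agrees=introns_agree,
                utr_dissimilar=utr_flag,
                codon_bias_discordant=dist > params.codon_discordant_above,
                gene_structure_discordant=not introns_agree,
            )
    return ConvergenceReport(
        params=params,
        per_group=per_group,
        pairwise=pairwise,
        dotplots=dotplots,
        representatives=dict(sorted(representatives.items())),
    )


def _fmt(x: float | None, nd: int = 4) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def write_report(report: ConvergenceReport, out_dir: str | Path) -> list[Path]:
    """Write profiles/pairwise/summary TSVs and ASCII dot plots; output is a
    pure function of the report, so re-runs are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out / "group_profiles.tsv"
    with open(p, "w") as fh:
        fh.write("group\tset\tn_ala\tGCT\tGCC\tGCA\tGCG\n")
        for g, s in report.per_group.items():
            for label, prof in (("afp", s.afp_profile), ("background", s.background_profile)):
                if prof is None:
                    continue
                fh.write(
                    f"{g}\t{label}\t{prof.n_ala}\t"
                    + "\t".join(f"{f:.4f}" for f in prof.fractions)
                    + "\n"
                )
    written.append(p)

    p = out / "pairwise_metrics.tsv"
    with open(p, "w") as fh:
        fh.write(
            "group_a\tgroup_b\tutr_similarity\tcds_match_density\tprofile_distance\t"
            "intron_structure_agrees\tutr_dissimilar\tcodon_bias_discordant\t"
            "gene_structure_discordant\n"
        )
        for (ga, gb), pc in sorted(report.pairwise.items()):
            fh.write(
                f"{ga}\t{gb}\t{_fmt(pc.utr_similarity)}\t{pc.cds_match_density:.3e}\t"
                f"{pc.profile_distance:.4f}\t{pc.intron_structure_agrees}\t"
                f"{'NA' if pc.utr_dissimilar is None else pc.utr_dissimilar}\t"
                f"{pc.codon_bias_discordant}\t{pc.gene_structure_discordant}\n"
            )
    written.append(p)

    p = out / "group_features.tsv"
    with open(p, "w") as fh:
        fh.write(
            "group\tn_records\tmean_ala_mol_percent\tmean_period_score\t"
            "intron_counts\tsignal_peptide_present\n"
        )
        for g, s in report.per_group.items():
            counts = ",".join(str(c) for c in sorted(s.intron_counts))
            fh.write(
                f"{g}\t{s.n_records}\t{s.mean_ala_mol_percent:.1f}\t"
                f"{s.mean_period_score:.3f}\t{counts}\t{s.signal_peptide_present}\n"
            )
    written.append(p)

    for (ga, gb), res in sorted(report.dotplots.items()):
        p = out / f"dotplot_{ga}_vs_{gb}.txt"
        bin_size = max(1, max(res.a_len, res.b_len) // 100)
        p.write_text(
            f"# {res.a_id} (rows) vs {res.b_id} (cols), window={res.params.window}, "
            f"k={res.params.min_matches}, bin={bin_size}\n" + dp.render_text(res, bin_size) + "\n"
        )
        written.append(p)

    p = out / "summary.txt"
    with open(p, "w") as fh:
        fh.write("Convergence-diagnostic summary (heuristic flags, not tests)\n")
        fh.write(f"thresholds: utr_dissimilar < {report.params.utr_dissimilar_below}, "
                 f"codon_bias_discordant > {report.params.codon_discordant_above}\n\n")
        for (ga, gb), pc in sorted(report.pairwise.items()):
            reasons = []
            if pc.utr_dissimilar:
                reasons.append(f"UTRs dissimilar (score {_fmt(pc.utr_similarity, 3)})")
            if pc.codon_bias_discordant:
                reasons.append(f"Ala codon bias discordant (TV {pc.profile_distance:.3f})")
            if pc.gene_structure_discordant:
                reasons.append("intron structure differs")
            verdict = "consistent with independent origin" if reasons else \
                "no discordance detected"
            fh.write(f"{ga} vs {gb}: {verdict}" +
                     (f" — {'; '.join(reasons)}" if reasons else "") + "\n")
    written.append(p)
    return written
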