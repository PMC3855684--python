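# Methods

## The question and the approach

Type I AFPs from four fish lineages (flounders, sculpins, snailfishes,
cunner) are short Ala-rich α-helices with strikingly similar protein
features. Shared ancestry would predict that the *genes* also agree:
untranslated regions recognizably similar, synonymous-codon usage drawn
from a common ancestral gene, and a common exon/intron architecture.
Convergence predicts the opposite — similar proteins riding on unrelated
nucleotide scaffolds. The package operationalizes that contrast as three
computable diagnostics per pair of lineage groups (UTR similarity from a
dot matrix, total-variation distance between Ala codon profiles,
intron-structure agreement), plus supporting analyses: helical feature
annotation of the peptides and alternative-reading-frame analysis of the
codon runs from which Ala-rich coding sequence can arise.

## Dot-matrix comparison

A sense match is plotted at (i, j) when the n-base windows at `a[i]` and
`b[j]` agree at ≥ k positions; antisense matches compare against the
reverse complement of `b` and are reported in B's sense coordinates
(j = |b| − n − j′) so one matrix carries both orientations. `N` matches
nothing. Defaults: (n, k) = (10, 9) within a gene family, (12, 9) across
lineages — the relaxed cross-lineage threshold tolerates one extra
mismatch per window so that even diverged homology would register.
The matrix is computed by n vectorized diagonal shifts (O(n·|a|·|b|) word
operations); tests verify exact agreement with a brute-force
window-by-window oracle. Runs of consecutive same-diagonal points are
collapsed to segments (antisense runs step i+1, j−1, so their invariant is
i + j).

**UTR similarity score.** The fraction of A's UTR positions covered by
qualifying sense diagonal runs whose window midpoints lie in a UTR of both
sequences. A run qualifies when its diagonal extent spans at least
`min_run` (default 3) *window-lengths*. This unit matters: adjacent
windows overlap in n−1 bases, so window hits are strongly autocorrelated
and a single lucky stretch of ~12 bases already produces several
consecutive window hits; requiring min_run windows-worth of contiguous
diagonal suppresses that background (measured: unrelated 200-nt UTRs score
0.00 at (12, 9); independently simulated lineages ≤ 0.004) while
homologous paralog UTRs, whose diagonals run for tens of windows, score
0.80–0.98. Coverage counts window start positions, so identical UTRs score
1 up to window-edge loss (≈ (L−n)/L).

**Region tallies.** Each match point is assigned to the region pair
containing its window midpoints (i + ⌊n/2⌋); points outside annotations
are tallied as `unannotated`. Midpoint assignment minimizes boundary
misassignment relative to anchoring at the window start.

## Codon usage

Codon counts run over in-frame codons with N-containing codons excluded
from both the counts and the total. The Ala profile is the 4-vector of
fractions over (GCT, GCC, GCA, GCG); profiles pool by summing counts, so
pooling is order-invariant and short sequences do not get equal weight
with long ones. Profile distance is total variation, ½·Σ|pᵢ − qᵢ| ∈ [0, 1]
— 0.3 is the default discordance threshold, roughly "a third of Ala codons
would have to switch family to reconcile the two profiles".

Background sets are curated before profiling: per species, greedily by
descending CDS length (ties by id), a sequence is kept only if it shares
≤ 65% global-alignment identity with every longer kept sequence; CDSs
under 50 codons are dropped; partial codons are trimmed first. The greedy
scheme implements "keep the longest of each similarity cluster" and is
idempotent. Identity, both here and for UTR comparisons, is
Needleman–Wunsch global alignment (match +1, mismatch −1, gap −2, via
Biopython's PairwiseAligner) scored as matched columns over all alignment
columns — indel columns count, so the statistic penalizes length
differences rather than ignoring them.

## Helical features

All positions 0-based. Ala mol% counts the full chain including Met1.
Thr periodicity scans all 11 phases, counting Thr at the phase's slots as
hits and Ile/Leu as substitute hits (seen in sculpin isoform SS-8); the
best phase maximizes hits + substitutes with ties to the smallest phase,
while the score (hits/slots) counts true Thr only. Ice-binding triplets
are (i, i+4, i+8) anchored on Thr with Ala or Thr at both downstream
slots; substitute-carrying slots count for periodicity but do not anchor
triplets, since only Thr/Ala faces are credited with ice binding. Salt
bridges are all acid/base pairs at spacing exactly 4. The N-cap looks for
the first Asp/Glu within 3 residues after Met1 (from residue 0 if the
chain starts without Met) and the first Pro/Gly within 8; internal
breakers are Pro/Gly at least 5 residues from both termini. The windows
(3, 8, 5) quantify "near the terminus"; they classify the canonical short
flounder/sculpin isoforms as breaker-free and snailfish-like sequences as
breaker-containing, and are all configurable.

## Alternative reading frames

A tandem run of codon c encodes five other homopolymers: the +1/+2 shifted
sense frames and the three antisense frames. Products are computed on
c + c (6 nt), which contains every shifted codon of the infinite repeat.
Frame labels: sense +1 discards the first base; antisense frame 0 is the
reverse complement read from its own 5′ end. Under this convention the
GCT row reads Leu/Cys (sense) and Ser/Ala/Gln (antisense), GCC reads
Pro/Arg and Gly/Ala/Arg, GCG reads Arg/Gly and Arg/Ala/Pro. Microsatellite
detection reports maximal tandem repeats per phase; the six-frame poly-Ala
scan returns every maximal segment encoding ≥ 6 consecutive Ala in some
frame (a Gly-rich GGC run flags through its antisense GCC frame). Only
perfect tandem repeats are scanned; interrupted repeats would need an
alignment-based model and `min_run` is exposed instead.

## The simulator and what it does (not) show

`SyntheticConfig` defaults define the reference conditions:

| parameter | default | meaning |
|---|---|---|
| `n_repeats` | 3 | 11-aa repeats per mature peptide (37–40 aa total, as in short isoforms) |
| `ala_bias` | (0.06, 0.14, 0.26, 0.54) | AFP Ala codon bias (GCG-dominant, sculpin-like) |
| `background_bias` | (0.30, 0.40, 0.20, 0.10) | shared mild GCC preference of non-AFP genes |
| `utr5_len`, `utr3_len` | 150, 300 nt | flank lengths, GC drawn uniformly in 37–44% |
| `point_mut_rate` | 0.01 /site | per-paralog substitutions |
| `indel_rate`, `indel_len_range` | 0.5 /UTR, 1–6 nt | UTR indel events per paralog |
| `repeat_cnv_prob` | 0.2 | whole-repeat (33 nt) gain/loss in the Ala block |
| `thr_substitution_rate` | 0.0 | Ile/Leu at Thr repeat slots (SS-8-style) |
| `n_introns`, `intron_len` | 0, 90 nt | introns placed within the 5′ UTR |
| `n_paralogs` | 6 | descendants per family |

Peptides are `MDAPA` + n × (Thr + 10 Ala) with Lys/Asp at off-face slots
2/6 of the first repeat, guaranteeing the N-cap, one salt bridge, and
>50 mol% Ala by construction. Back-translation draws Ala codons from
`ala_bias` and every other residue uniformly from its synonymous codons,
so the Ala profile is the only deliberate codon signal. Families descend
from one ancestor via an explicit event log (repeat CNV, then
substitutions, then UTR indels, each positioned in the current coordinate
frame); replaying the log reproduces every paralog byte-exactly, which is
the ground truth the recovery tests use. Substitutions that would create a
premature stop are discarded so paralogs stay translatable. The 3′ UTR
carries a length-variable GT microsatellite and the 5′ UTR an in-frame
stop 15 nt upstream of ATG, mirroring the secreted-peptide-free
architecture of sculpin transcripts. Mutation-rate defaults were set so
that paralog 5′ UTRs stay >90% identical (measured ≈ 96% mean), the
regime the analysis is meant to operate in.

The simulator deliberately omits: organism-specific codon usage outside
Ala, selection/dN–dS structure, recombination mechanics (repeat CNV is a
whole-unit jump process), signal-peptide evolution, and phylogenetic tree
shape. Passing tests therefore show that the pipeline recovers planted
signals of exactly these kinds — not that real fish data contain no
confounders (e.g. genuinely diverged homologous UTRs beyond recognition,
which the analysis cannot distinguish from independence; the real-data
argument needs the non-AFP homolog comparisons as a positive control).

## Report and verdict flags

Groups are compared through their longest (representative) records for the
dot matrix, and through pooled profiles for codon usage. Flags:
`utr_dissimilar` (UTR similarity < 0.1), `codon_bias_discordant` (TV
distance > 0.3), `gene_structure_discordant` (intron-count sets differ).
The thresholds are configurable heuristics that make a qualitative
argument explicit; the report labels them as such and performs no
hypothesis test. Missing UTR annotations degrade gracefully (metric and
flag become NA). Output is a pure function of input: re-runs are
byte-identical.

## Numerical and degenerate-input choices

- One coordinate convention everywhere: 0-based half-open; machine output
  0-based, human-readable report text 1-based.
- `N`: never matches in dot plots, excluded from codon counts, translates
  to X; all-N input to GC content is an error, not 0.
- Requesting an absent region kind is an error, distinct from an annotated
  empty region (which cannot exist: start < end is enforced).
- Alignment ties: Biopython's first-reported optimal alignment is used;
  identity can vary by a few percent among co-optimal alignments of
  unrelated sequences, which is far from both decision thresholds.
- Periodicity ties break to the smallest phase; an all-Ala sequence
  reports phase 0 with score 0.
- Profile distance on an empty (n_ala = 0) profile is an error rather
  than 0, so missing data cannot masquerade as agreement.
- Acceptance-script problem sizes (3 families × 6 paralogs, 50 dot-matrix
  oracle pairs ≤ 200 nt, 100 back-translated CDSs, 200 peptide draws,
  20 background genes of 100–300 codons) were chosen as the smallest sets
  at which the stochastic quantities are stable to well within their
  decision margins across seeds.
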