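# Methods

## The assay this package models

Anchored one-sided (uni-directional) targeted sequencing quantifies the
repair outcomes of programmable nuclease cuts in a single library: a
transposase (Tn5) simultaneously fragments genomic DNA and attaches an
adapter carrying a 10-nt unique molecular identifier (UMI) and a sample
barcode; a locus-specific *anchor primer* then fixes one side of every
amplified fragment. One end of each molecule is therefore known (the
primer), the other is a random tagmentation breakpoint, and every original
molecule is countable exactly once through its UMI. Because amplification is
anchored on one side only, junctions that PCR across two fixed primers would
miss — large deletions, inversions, translocations to anywhere — are
captured as long as they retain the primer's flank.

The package implements the complete analysis for that design — reference
(junction amplicon) construction, demultiplexing, UMI extraction, adapter
trimming, alignment, junction-window classification, UMI-based counting —
plus a ground-truth simulator and the binomial/regression statistics used to
validate such an assay.

## Coordinates and junction classes

All coordinates are 0-based, half-open; a cut at position `p` falls between
bases `p-1` and `p`.

A cut creates two free ends: LEFT (the upstream fragment, free at its right
terminus) and RIGHT (the downstream fragment). Any two free ends can ligate,
and once the free termini are fixed there is exactly one way to join them:
LEFT+RIGHT is a direct, collinear junction; LEFT+LEFT and RIGHT+RIGHT force
one fragment to flip, giving head-to-head junctions. Enumerating unordered
end pairs (with replacement, because like ends of two homologous copies can
fuse) gives 3 outcome classes for one cut and 10 for two cuts — for two cuts
on one molecule these include the excision deletion, the two inversion
junctions and a duplication-type junction; across two loci they include the
two balanced (reciprocal) translocations and the two head-to-head fusions.
A junction read from the other strand is the same molecule, so
reverse-complement-equivalent joins are stored once, canonically (a LEFT end
first where possible; ties by locus name, then position). Centromere-
relative names (balanced / dicentric / acentric) are annotations derived
from an optional per-locus centromere side, not separate sequence classes.

Re-ligated homolog joins of complementary ends (one allele's LEFT to
another's RIGHT) restore the reference sequence and are therefore
sequence-indistinguishable from simple NHEJ at that cut; they are subsumed
by the NHEJ/wild-type path rather than modeled as separate classes. For the
same reason the alignment reference set folds NHEJ amplicons into the
wild-type amplicon of their cut.

## Reference amplicons

For every junction class an amplicon is built as `flank` bases of the first
end (5'→3' into the junction) followed by `flank` bases of the second end
(reverse-complemented when its orientation demands), junction at offset
`flank`; wild-type amplicons span each cut ± `flank`. The default
`flank = 350` bp comfortably exceeds read length (150 nt) plus the junction
window, so any read that could support a junction fits on its amplicon.

## Alignment

Reads are aligned with an affine-gap semi-global ("glocal") dynamic program
written for this package: the read is consumed end-to-end (terminal read
overhangs are penalized insertions) while the reference contributes free end
gaps. Defaults: match +2, mismatch −4, gap open −6, gap extend −1. The
traceback is deterministic — op priority MATCH/SUB > DEL > INS, ties between
gap-open and gap-extend resolved toward closing the gap, and the leftmost
optimal end column. The suite checks the DP against an exhaustive
path-enumeration oracle on short sequences.

A read pair is assigned to the amplicon with the highest summed mate score
among amplicons where every mate passes `min_identity = 0.8` (match columns
over aligned columns) and `min_aligned_fraction = 0.8` (reference-overlapping
read span over read length). Score ties prefer wild-type amplicons — the
conservative error direction for an assay quantifying edits — then the
lexicographically first id. Pairs whose Tn5-side mate falls beyond the
amplicon (long fragments) are assigned on the passing primer-side mate alone
and flagged `single_mate`; pairs passing nowhere land in the unassigned
bucket (the analysis does not map residual reads to a whole genome; that
step is outside this package's scope and served by the unassigned counts).

The pipeline's batch path prescreens candidates with an exact edit-distance
scan (edlib, infix mode; two-stage distance cap 6 then ≥40, candidates
within 8 of the best) and runs the affine DP on a window padded 24 bp around
the reported location. With reads a few edits from their amplicon this is
equivalent to the exhaustive scan (the suite asserts agreement) at a small
fraction of the cost; `assign_amplicon` itself always scans exhaustively.

## Classification and counting

A read supports a junction only if one mate covers the whole window
`junction ± 15 bp` with match/substitution columns — a deletion overlapping
the window, or an insertion strictly inside it, opens a hole across the
junction and disqualifies the read (strict rule, configurable via
`require_contiguous`). The 15 bp window is symmetric and configurable; the
strict reading is the most stringent plausible one.

On the wild-type amplicon the same window is inspected for small indels.
There the window must only be *spanned* by the alignment, because the indel
being called is itself a gap inside the window — a gap-free requirement
would define the indel category out of existence. Insertions and deletions
whose reference interval intersects `cut ± 15 bp` are merged into one
descriptor; a pure match/substitution window is wild type.

Molecules are UMI groups: reads are grouped by (sample, UMI), the molecule's
category is the majority read call (exact ties → AMBIGUOUS, excluded from
frequencies, reported in QC). Optional directional Hamming-1 collapse merges
a UMI into a neighbor with at least `2c − 1` reads. Frequencies are always
UMI-based — read counts are QC only — so PCR depth cancels exactly (the
suite asserts duplication invariance). The denominator is every molecule in
a detectable category including wild type; inversion junction subclasses
aggregate to one INVERSION category (a molecule supporting either junction
counts once), homolog fusions to HOMOLOG_FUSION, and cross-locus fusions are
reported per subtype (`FUSION_LR`, …) and summed for translocation totals.

## The simulator

The simulator is the package's ground-truth instrument. Per molecule it
draws an outcome class from the configured proportions, realizes the edited
molecule (wild type; one small indel touching the cut — insertion/deletion
50/50, geometric sizes p = 0.3 capped at 30 bp; full deletion/inversion
molecules; or any enumerated junction class), places the fragment from the
primer's 3' terminus to a tagmentation breakpoint with length ~
Uniform(150, 600) bp, and emits R1 from the primer side and R2 back from the
breakpoint. Duplicates (geometric, mean 5) share UMI and fragment ends and
re-draw substitution errors (default 0.001/base) independently; errors also
hit UMIs and barcodes, exercising the 1-mismatch demultiplexer. UMIs are
uniform 10-mers, so collisions occur at the birthday rate for 4^10 labels
and are recorded in the truth table. Everything is reproducible from one
seed; a per-molecule dropout probability is the only stand-in for library
process yield.

Deliberately not modeled: Tn5 insertion-site sequence bias, polymerase
(jackpot) errors, chimeric PCR artifacts, quality-score realism beyond a
constant Q, and microhomology or templated insertions at junctions. Passing
recovery tests therefore demonstrates that the analysis is correct and
unbiased under idealized molecule sampling — not that it is robust to every
artifact of real libraries.

## Validation statistics

* **Input accounting.** Haplome equivalents = mass · 1000 / 3.5 pg; 3.5
  pg/haplome is back-derived so 50 ng ≈ 14,300 haplomes (3.2–3.4 Gb genome
  assumptions give 14,200–14,700; the value is a parameter). Expected
  observations = haplomes × process yield × frequency; at 14,300 × 20% ×
  0.1% this is 2.86 molecules. The expectation and the confidence statement
  are exposed separately (`expected_observations` vs `min_trials`) rather
  than conflated.
* **Detection power.** `min_trials(k, p, confidence)` is the minimal n with
  P(X ≥ k) ≥ confidence under Binomial(n, p), computed from exact tails
  (scipy) with a bracketing + bisection search; no normal approximation.
* **Linearity.** OLS of log10(measured) on log10(expected); the slope β is
  the linearity parameter (1 = proportional response) with a t-based 95% CI.
  Slope differences between two assays are tested by the F-test on the
  group × log-input interaction in the pooled model. Zero measurements are
  routed to detection analysis, never log-regressed.
* **LLoD.** The detection-limit rule is this package's formalization (the
  quantity is usually reported as "~x%" without a rule): the lowest
  titration level at which ≥ 90% of replicates detect ≥ 1 molecule and the
  median measured frequency is within 2-fold of truth.
* **Reproducibility.** Squared Pearson correlation of log measurements
  between replicate titrations, excluding pairs with a zero. Note the
  counting-noise ceiling: at 2,860 molecules per library a 0.1% event is ~3
  expected molecules, which alone bounds the attainable replicate R² near
  0.98 — reaching 0.99 requires more input molecules at the lowest levels,
  exactly as the power calculation predicts.

## Problem sizes used by the test suite and acceptance script

Simulated validation runs use 30,000 molecules for the dual-guide outcome
mix, 20,000 per primer for the two-locus translocation design, 2,860 per
titration library (the molecule count implied by 50 ng at 20% yield),
and 10,000 for the assignment-accuracy measurement — the study-scale
conditions. Tolerances on recovered frequencies are 3 binomial standard
errors at the configured truth.

## Known limitations

* Outcome enumeration is specified for at most two simultaneous cuts;
  the data model does not preclude more, but no multiplex enumeration is
  offered.
* The aligner does not soft-clip; long Tn5-side overhangs rely on the
  single-mate path rather than clipped alignment.
* Frequencies condition on capture by the configured primer; molecules
  lacking the primer's flank are invisible, as in the assay itself.
* The batch aligner's prescreen is exact-distance-based; adversarial
  references more than 8 edits closer in unit cost than in affine score
  could in principle evade the shortlist (never observed in tests, and the
  exhaustive path is available).
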