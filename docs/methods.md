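# Methods

This note documents the models, conventions and parameter choices behind
`phagechar`, what the synthetic-data generator does and does not emulate,
and the numerical details a user would need to reproduce or modify the
pipeline.

## Coordinate and sequence conventions

All coordinates are 0-based half-open on the top strand internally; emitted
feature tables are 1-based inclusive (GenBank convention), and the
conversion is bijective.  Sequences are strict ACGT: ambiguity codes are
rejected on input rather than masked, because every downstream detector is
an exact-word or Hamming scanner and a silently masked base would corrupt
coordinates.  For `linear_cos` genomes, position 0 is by convention the
first base 3′ of the cos cut on the top strand; scanners that must see
elements spanning the chromosome ends (cos search, PCR) use a circular view
of the sequence.

## ORF calling and region partition

The gene caller is a six-frame scanner: within each stop-bounded frame
segment the ORF is anchored at the most upstream in-segment start codon
(ATG/GTG/TTG) and reported when it reaches `min_orf_len` (default 90 nt —
small enough to admit the four short middle-region genes, large enough to
suppress most noise).  Coordinates include the stop codon.  There is no
ribosome-binding-site or coding-potential model, so the caller also reports
overlapping ORFs in alternative frames; planted-truth comparisons are
therefore subset checks ("every planted ORF recovered exactly") rather than
equality checks.

936-type genomes carry three same-strand transcription regions — late,
early, middle in genome order from the cos cut (cos lies between the middle
and late regions on the circular map).  Homology is out of scope, so the
partition uses the only sequence-intrinsic surrogate: the coding-strand ORF
chain (the strand with the larger summed ORF length) is split at its two
largest intergenic gaps.  Gaps are measured against the running coverage
end of the chain, not the previous ORF's end; otherwise ORFs nested in
other reading frames would fabricate gaps.  Ties break toward the earliest
gap.  The generator plants 400/350-bp boundary gaps against ≤ 80-bp
intra-region gaps, so the split is unambiguous on synthetic data.

Transmembrane domains are counted with the standard Kyte–Doolittle
sliding-window heuristic (window 19 residues, mean hydropathy threshold
1.6); maximal runs of qualifying windows count once.  Three TMDs map to a
class I holin, two to class II, one to class III.

## cos region mapping

The cos site is searched as an exact 11-mer by default (the motif is
conserved and identical across 936-type phages); a Hamming tolerance is
available.  Inverted repeats are enumerated as all left/right arm pairs
within a 200-bp window on each side of cos whose right arm matches the
reverse complement of the left arm with ≤ 1 mismatch; overlapping redundant
pairs are pruned best-first (fewest mismatches, then smallest span, then
leftmost), which keeps exactly the planted pair ahead of its frame-shifted
ghosts.  Direct repeats are exact AATCT hits in the window, labelled
D1..Dn.  Terminase-site motifs R1–R3 are configuration inputs, not
constants of the method: the repository's defaults are the synthetic
generator's own planted motifs, and real sequences must be supplied by the
user.  Each motif is mapped to its best (lowest-Hamming, earliest) window
position; a site is complete when its matched fraction reaches the
threshold (default 1.0), and any direct repeat lying inside a partial match
is annotated as a truncation of that site — the relationship in which the
last direct repeat is a truncated R2.

## Restriction digestion and RFLP grouping

Cut positions are site start + cut offset on the top strand; for the type
II palindromic enzymes used here the two strand nicks collapse to one
double-strand cut.  Dissociated mode digests the linear molecule; cohesive
mode digests the circularized molecule, which joins the two terminal
fragments — exactly the band difference formamide treatment removes.
Fragment sizes always sum to genome length in both modes.

Gel awareness: fragments below `min_size` (default 200 bp, a proxy for
what a 0.7% agarose gel resolves; exposed as a flag) are dropped, and
fragments within a ratio tolerance (default 5%, test |ln(s1/s2)| ≤
ln(1.05)) merge into one band at their mean.  Band patterns are compared by
greedy largest-first matching under the same ratio test; the distance is
1 − 2m/(|b1|+|b2|).  This is a semimetric (symmetric, zero on identity);
the triangle inequality is not claimed, because the matching is greedy.
Grouping is single linkage at threshold 0.1: identical-archetype digests
(distance 0 under footprint-masked SNVs) merge, distinct archetypes (whose
pairwise distances the generator verifies exceed the threshold) do not.

## In-silico PCR

A primer binds where its 3′-terminal clamp (5 bases) matches exactly and
the remainder carries at most 2 mismatches — polymerase extension requires
a matched 3′ end; the clamp length and mismatch budget are configurable
because the underlying assay defines no mismatch model.  Product length is
the standard amplicon size (both primer footprints included), which is what
makes the 936 pair's product exactly 179 bp.  Scanning covers both
orientations (either primer may bind the top strand), so results are
invariant to reverse-complementing the template, and circular templates are
scanned across the join with products capped at template length.
Multiplexing is simulated as independent single-pair reactions.  The type
call is the expected type of the single amplifying pair, "mixed" when
several pairs amplify, "untyped" when none does.

## Shifty-stop frameshift

A candidate is a coding-strand ORF whose last sense codon is CCC and whose
terminator is TAG, with a +1-frame stop available within 3 kb.  Shift
mechanics: after incorporating Pro at the CCC, the ribosome resumes one
nucleotide past the CCC/TAG junction, i.e. the first post-shift codon
starts at the A of the TAG.  The published notation for this signal does
not fix the register, so the choice is isolated in one function
(`_post_shift_start`) and the alternative (+1 from the T) is a one-line
change; the adopted register is the one the generator's 520-residue planted
fusion is built against, and it is the natural reading of a +1 slip after
P-site re-pairing.  Only TAG terminators qualify by default.

## One-step growth estimation

Titers span orders of magnitude, so the three-phase model (flat /
log-linear rise / flat) is fitted in log10 space; a linear-space fit would
be dominated by the plateau.  Breakpoints are restricted to observed time
points (the assay samples every 3 min), making the fit an exhaustive,
deterministic grid search over breakpoint pairs with ≥ 2 samples per
phase; ties break toward the earliest pair.  The latent period is the first
breakpoint and the burst time the second.  Burst size deliberately follows
the assay's own ratio definition — mean plateau titer divided by mean
pre-rise titer (pre-rise excludes the breakpoint sample; plateau includes
everything from the second breakpoint on) — rather than a fitted
amplitude.  The estimator is invariant to scaling all titers.  "Burst
period" and "burst time" are treated as the same quantity (time of plateau
onset).

## Comparative genomics

Distances use canonical k-mers (lexicographic minimum of each k-mer and its
reverse complement; k = 15) so they are strand-neutral, with the Mash
formulation d = −ln(2J/(1+J))/k on the Jaccard index, 0 for equal sets and
capped at 1.0 (the sentinel for disjoint sets).  Trees are classic
neighbour joining with deterministic lowest-index tie-breaking; negative
branch lengths are clamped to zero with a warning.  NJ on alignment-free
distances stands in for alignment-based maximum-likelihood phylogeny, which
requires external engines; correspondingly, the package's phylogenetic
claims are limited to exact inversion of additive matrices and clade
recovery on synthetic truth, not to branch supports.  Dot plots report
maximal exact-match segments (word size 20, both orientations) by merging
consecutive shared-word anchors along diagonals, which reconstructs maximal
matches exactly.

## The synthetic-data generator

The generator emulates the genome architecture the pipeline is built for:
length uniform in 29,300–30,200 bp; GC 34.7%; one cos 11-mer near position
0 flanked by a 10-bp inverted-repeat pair; five AATCT direct repeats plus a
sixth that is the 10-nt prefix of the planted R2 motif (with two fixed
mismatching bases after it, so the site is unambiguously truncated); R1 and
R3 planted intact; three same-strand gene regions (22 late, 28 early, 4
middle ORFs by default, totalling 54, within the observed 53–57 range) with
the conserved 483-nt middle ORF; an mtp of 543 nt ending CCC.TAG followed
by a +1-frame tpeX region sized to give a 520-aa fusion; a planted 936
primer-site construct with a 179-bp product; and 6–12 planted sites per
default enzyme.  Variable ORF lengths are drawn from 150–840 nt and
rescaled to the genome-length budget (a 54-gene complement cannot
accommodate longer draws in a 30-kb genome).

Background sequence is i.i.d. with base probabilities tuned to the target
GC, then *scrubbed* so the planted truth is exact: duplicate cos motifs,
unplanned restriction sites, stray AATCT words near cos, coding-strand ORFs
outside planted footprints (stop codons are stuffed into their free
background and protected), and accidental CCC.TAG shifty stops are mutated
away; mutations inside planted ORFs are only accepted when every governing
reading frame stays sense, and ORF start/stop codons, guards and planted
elements are immutable.  GC is then re-balanced on free background.  A
final verification pass re-detects every planted element with the analysis
modules themselves and regenerates from a fresh derived seed on any
failure, so generation is a deterministic function of the spec seed.
Cohorts draw archetypes independently, verify that archetype EcoRV band
patterns are pairwise more distant than the grouping threshold
(regenerating up to 100 attempts), assign each cohort genome an archetype
(every archetype non-empty, remainder uniform — per-group isolate counts
are not prescribed by the assay, so uniform is the neutral choice), and
apply SNVs that by default avoid feature footprints and are rejected if
they would create a new enzyme site or cos motif.  Growth curves follow the
three-phase model with pointwise multiplicative lognormal noise
(natural-log sd 0.05 by default) sampled every 3 min.

What the generator does **not** emulate: realistic codon usage, promoter
and terminator signals, mobile elements, sequence evolution along a
phylogeny, or partial digestion and gel artefacts.  Passing tests on
synthetic data therefore demonstrate the correctness of the computational
procedures under the stated genome architecture, not the biological
fidelity of any particular detector threshold on wild isolates.

## Problem sizes in tests

The default test run keeps every scenario at desk scale on one CPU: the
RFLP acceptance cohort is the full 90 genomes × 8 archetypes; cos-element
recovery uses 50 full-size genomes; growth recovery uses 100 noisy
replicates per parameter row of interest; digestion oracle equivalence uses
200 random 2–9-kb genomes; NJ clade recovery uses 100 cohorts of nine
12-kb genomes (8 same-archetype descendants at SNV rate 10⁻³ plus one
independent outgroup) — a size at which k-mer distances are already fully
informative.  Checks that require deposited GenBank records (reference
genome statistics, typing of sk1/c2) are covered by synthetic equivalents
generated at the same scale, and a thin `fetch_genbank_fasta` helper exists
for users who want to run the pipeline on the deposited sequences
themselves.

## Known limitations

Greedy band matching can under-count matches in pathological band lists;
an exact bipartite matcher was deliberately not built.  The ORF caller's
"most upstream start" rule differs from annotation engines that model
ribosome-binding sites, so gene counts are caller-dependent.  The
frameshift register, terminase motifs and gel-visibility threshold are
explicit configuration points rather than fixed truths.  Pattern-distance
grouping has one declared free parameter (threshold 0.1): the underlying
assay groups gels by eye and states no tolerance.
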