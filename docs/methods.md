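# Methods

This note documents the models, estimators and design choices behind
`microevo`, and what the synthetic experiments do and do not demonstrate.

## Coordinates and data model

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted only at the I/O boundary. Genomes are linear. A
CDS with phase p has its 5' end advanced by p bases; if the trimmed length
is still not a multiple of 3 the feature is kept but flagged
pseudogenized and excluded from translation-dependent analyses. The
"non-coding moiety" of a genome is the strand-agnostic complement of the
CDS union; UTR and ncRNA features refine hit classification but do not
shrink it.

The bundled phylogeny has 10 strains in two clades with internal nodes
labeled 1–9 by depth (root = 1, clade-A root = 2, celtis/quercus MRCA =
9). Published sources give the topology and labels but not branch
lengths; the fixture's lengths are plausible values chosen once — a deep
inter-clade split (~0.7 substitutions/site path length) and a very recent
focal-pair split (~0.023) consistent with ~96% ortholog identity — and are
not fitted to anything.

## Translated non-coding search and dating

The search is a deliberately minimal tblastn analogue: exact 4-mer
peptide seeds between the query and each of the six frame translations,
ungapped X-drop extension (X = 20) under BLOSUM62, one best hit per
(frame, diagonal), and ungapped Karlin–Altschul statistics
E = K·m·n·exp(−λS) with the standard ungapped BLOSUM62 parameters
λ = 0.318, K = 0.13. Ungapped extension keeps the E-value analytic; the
screening threshold E ≤ 10⁻³ does not require gapped sensitivity, and the
false-positive rate on shuffled subjects is verified to track K·m·n·e^(−λS)
within small factors. Hits are discarded when more than half of the hit
lies on a same-strand, same-frame annotated CDS (those merely rediscover
coding homologs); antisense, alternative-frame, UTR and ncRNA overlaps are
kept and classified with that priority order, each category requiring
majority coverage of the hit.

The creation node of a unique gene is the MRCA of the focal leaf and all
strains with evidence (non-coding trace hits plus annotated cluster
homologs). Evidence can only move the assignment rootward. A stricter
variant requiring evidence in every other descendant of the assigned node
is available (`require_full_clade=True`); the default is the MRCA rule.

## Clustering and accumulation curves

Proteins are clustered by single-linkage over edges where global
(Needleman–Wunsch, BLOSUM62, gap 11/1) identity ≥ min_identity and
aligned-column coverage ≥ min_coverage of the shorter protein. The
operation defaults are 0.30/0.50. One empirical caveat discovered during
development: at ~64% G+C the encoded proteomes concentrate amino-acid
usage (Ala/Gly/Pro/Arg-heavy) enough that *unrelated* proteins average
~27% global identity, so a 30% cutoff chains unrelated families. The
synthetic protocol therefore clusters at 0.50, which cleanly separates
orthologs (> 80% identity at the simulated divergences) from that
compositional baseline; both thresholds are plain config values. Deeply
diverged ortholog families (inter-clade identity below the cutoff) split
into clade-level clusters, which mirrors the well-known sensitivity of
core-genome estimates to clustering protocol.

Accumulation curves enumerate pan (union) and core (intersection) cluster
counts over every genome combination, exhaustively up to 12 genomes and by
seeded sampling beyond. The pan increment is mean pan(G) − mean pan(G−1).

## Selection estimation

dN/dS uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions with stop-producing changes excluded from each position's
denominator (S + N = 3 exactly); difference counts averaged over all
shortest stop-free mutational pathways with equal weights (if every
pathway crosses a stop — a rare corner — all pathways are used and
stop-crossing steps count as nonsynonymous); Jukes–Cantor correction
d = −(3/4)ln(1 − 4p/3), undefined at p ≥ 3/4. Codon alignments come from
global protein alignment back-mapped to codons with gapped columns
removed. Pairs must pass dN > 0, dS > 0, dS ≤ 2 and dN/dS ≤ 10 before
node-level aggregation; shared genes are dated by the MRCA of the strains
carrying the cluster, independent of trace-based dating.

NG86 ignores transition/transversion bias, so the estimator-recovery
experiments run the simulator at κ = 1, where NG86 with JC is calibrated:
simulated ω ∈ {0.2, 0.5, 1.0} is recovered within ±0.1 at 3000 codons
(20 replicates). A κ-weighted site-counting variant (YN00-flavoured) is
provided for κ ≠ 1 data; it shares the pathway-based difference counts.

## Compositional signatures

The CAI reference set is configurable; the pipeline uses the focal
strain's non-novel genes (callers may pass core-cluster genes instead).
Relative adaptiveness is per-synonymous-family count ratios with a 0.01
floor for unobserved codons; CAI is the geometric mean over codons
(terminal stop dropped, internal stop is an error, ambiguous codons
skipped). The amino-acid χ² pools residue counts (20 categories, df = 19)
with expected counts from the background's frequencies scaled to the
novel total and a 0.5 pseudocount for residues absent from the
background. This treats the background frequencies as known; the test's
type-I error is within [0.03, 0.07] when the background exceeds the novel
set by an order of magnitude (the tabulated regime: ~3.8k vs ~450k
residues). Wilcoxon rank-sum contrasts use the normal approximation with
tie correction, appropriate at the 30-vs-1000 scale.

## ncRNA calling

A single expression floor — median per-base coverage strictly greater
than 5 — validates both coding and non-coding transcripts. ncRNA
candidates are maximal above-threshold runs per strand that do not
overlap a same-strand CDS and are at least min_len (default 200 nt) long.
Antisense classification requires opposite-strand CDS overlap strictly
greater than half the call's length. Cross-strain matching is
reciprocal-best by nucleotide local alignment at 80% identity / 50%
coverage by default (these thresholds are assumptions, stated in config);
a position-based mode (reciprocal ≥ 50% coordinate overlap) suits
collinear genome pairs.

## Structural features

The dotplot is exact shared words (default 15-mers) in both orientations
merged into maximal collinear segments per (anti)diagonal. Terminal
palindrome detection computes, via FFT correlation of per-base indicator
channels, the number of complementary pairs for every candidate prefix
length at once, and returns the longest even prefix within the mismatch
budget (default 5%). TIR-flanked transposon candidates are seeded by
exact 8-mer inverted matches at a separation within the configured
segment bounds, grown inward under the mismatch budget, and resolved by
longest TIR then leftmost position. With the permissive defaults
(TIR ≥ 15 bp, ≤ 2 mismatches) random megabase-scale DNA contains many
qualifying short inverted repeats — that is a property of the statistics,
not a bug — so scans aimed at confident elements should use stricter
settings (e.g. TIR ≥ 20, 0 mismatches), as the synthetic experiments do.

## The simulator

The generator emulates the study conditions rather than any particular
dataset: coding G+C 64.4% versus intergenic 57.5% (stop-codon rejection
enriches naive iid-codon G+C by about one point, so the base composition
is solved numerically to hit the target); genes evolving under a
Goldman–Yang-style codon process with F1x4 target frequencies (making the
coding composition stationary along deep branches), branch lengths in
expected substitutions per nucleotide site; intergenic DNA under an
HKY-like process with geometric indels (p = 0.5, max 10 nt); gene birth
inserting protogene-derived ORFs (intergenic composition, ATG…stop,
stop-free body) on the drawn branch; death converting a gene to drifting
non-coding sequence so traces stay discoverable; and ncRNA loci toggling
on/off along branches. Scripted births place a protogene at a chosen
internal node and activate it only in chosen leaves — the exact scenario
the trace-dating experiment tests. Per-branch random substreams are
derived from the global seed with a stable hash, so adding a leaf does
not perturb other branches.

Defaults are illustrative where no empirical values exist: births ~1 and
deaths ~0.05 per branch (chosen so the surviving ancestral fraction lands
below one half, like the observed core/genome ratio), ancestral gene
lengths lognormal with median ~245 aa, newborn genes ~120 aa. Expression
simulation draws "on" features from a clamped lognormal (median ~300) and
"off" features uniformly below the threshold.

What the simulator does **not** model: read-level sequencing noise,
recombination, transposition dynamics (TIR elements are planted, not
evolved), poly(A) selection bias, UTR annotation, codon-usage selection.
Passing synthetic tests therefore demonstrates the estimators' internal
correctness and calibration under the stated generative model, not
robustness to real-data artifacts such as assembly errors or annotation
asymmetries.

## Problem sizes

The bundled experiments are desk-scale by design: simulated genomes of
15–40 kb with 8–40 genes per strain, 3000-codon alignments for estimator
recovery, 20 replicates per stochastic check, 100 random trees for the
MRCA oracle, and 500 replicates for χ² calibration. All estimators are
linear or near-linear in sequence length and run unchanged on
megabase-scale inputs.
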