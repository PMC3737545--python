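# Methods

## The PQS grammar and its disambiguation semantics

A putative G-quadruplex sequence (PQS) is defined by the grammar
G≥3(N1–7G≥3)≥3: at least four tracts of three or more consecutive
guanines, separated by loops of one to seven nucleotides of *any* base,
including G. Because loops may contain G, a given G-rich region can be
decomposed in many ways, and the reported match depends entirely on the
disambiguation policy. `g4scan` fixes that policy to be the one a
backtracking regular-expression engine applies to the pattern
`G{3,}(.{1,7}?G{3,}){3,}` under repeated global matching:

* decisions are resolved in chronological order (earlier decisions
  dominate later ones);
* each G-tract quantifier is greedy: it takes the longest available run
  of Gs, giving back bases only when the remainder of the match would
  otherwise fail;
* each loop quantifier is lazy: it prefers the shortest spacer;
* the tract+loop repeat is greedy: after completing a unit the engine
  prefers adding another unit over accepting;
* matching is leftmost-first; after a match is accepted, scanning
  resumes at its end offset, so matches never overlap and a G-rich
  region yields one maximal leftmost match.

Two worked consequences. In `GGGGAGGGAGGGAGGGAGGG` the greedy repeat
absorbs all five tracts into a single 5-tract match. In
`GGGGGGGAGGGAGGGAGGG` the first tract greedily takes the whole 7-G run
and the engine settles for a 4-unit parse — it does *not* re-split the
run to manufacture a fifth unit, because the tract-length decision
precedes the unit-count decision. Both behaviours are cross-checked
against Python's `re` engine (same backtracking family as the Perl
original of the pattern) in the test suite.

The production scanner (`pattern.scan_forward`) implements this as a
recursive backtracking matcher that is only attempted at the start of
each maximal G-run (a match cannot begin elsewhere, and if an attempt at
a run start fails, attempts deeper inside the run must fail too). The
oracle (`oracle.oracle_scan`) shares no parsing code: it enumerates
*every* legal decomposition at each candidate offset (with a
dynamic-programming feasibility table used purely to prune dead
branches, which cannot change the enumerated set) and selects the winner
by an explicit lexicographic key over the decision sequence. Scanner
and oracle are required to agree exactly — coordinates, strands, tract
counts — on thousands of random G-enriched sequences.

Input handling: sequences are uppercased before scanning, so
soft-masked (lowercase) genome sequence is scanned like any other — no
repeat masking is applied. IUPAC ambiguity codes (N, R, Y, …) are legal
loop characters but never count toward a tract; any character outside
the IUPAC nucleotide alphabet raises an error naming its position.
Coordinates are 0-based half-open internally; BED output keeps that
convention, anchor-relative coordinates (below) use the field's ±1
convention.

### Exact-length subclass

The subclass filter ("G3 tracts with 1-nt loops") re-parses each
matched motif with `exact_tract_len=3, exact_loop_len=1` and counts it
only when the *whole* motif parses under those constraints, where a
tract must additionally be a maximal G-run (a 4-G tract disqualifies,
as does any loop ≠ 1 nt). "At least four tracts" is retained. Whether
a stricter or looser reading was intended by the verbal phrase is
ambiguous; this strict reading is a documented package decision.

## Flanks and anchor coordinates

A gene is the annotated transcribed region (gene-level, one TSS/TES per
gene id — no transcript isoforms). For a + strand gene [g0, g1) the
TSS-upstream flank is genome[g0−L, g0) and the TES-downstream flank is
genome[g1, g1+L); for a − strand gene the mirror-image slices are
reverse complemented, so flanks always read 5′→3′ on the sense
(non-template) strand and the two gene orientations are
indistinguishable downstream. Flanks truncated at a chromosome edge are
kept, flagged, with the anchor-adjacent end intact. Overlapping genes
are processed independently.

Upstream flank offset i maps to anchor coordinate i − L (last base =
−1); downstream offset i maps to i + 1. A multi-base motif is
represented by the coordinate of its match *start* offset — for
upstream flanks its most anchor-distal (most negative) base — and a
motif counts as lying "within d bp of the TSS" only when wholly
contained in [−d, −1]. This makes cumulative curves stable under flank
truncation. Plus-strand matches on the sense-oriented flank are
classed non-template; minus-strand matches are template.

## Profile and cumulative statistics

Frequency profiles count each motif once, in the window containing its
representative coordinate, and normalize to occurrences per 100
sequences (window 100 nt by default; 20 nt for the TES-downstream
strand-split profiles over +1…+1000). Main profiles count both strand
classes; only the TES insert profiles split strands. Window counts are
conserved (Σ counts = number of matches in scope) and scopes are
additive (both = non-template + template) — both asserted as tests.

The cumulative distribution traverses distances d = 1…L, counting
motifs with |coord| ≤ d and, via first-insertion into a hash set over
the motif list sorted by descending coordinate, the percentage of genes
with at least one such motif. `percent_positive` is defined as the
endpoint of that curve and the identity is asserted. Genes whose
flanks are truncated stay in the denominator.

## The decay model

%qDNA — quadruplex-bearing DNA as a percentage of total DNA, computed
from band intensities as 100·g4/total — decays with the
promoter-to-motif separation X (bp) as Y = max·exp(−k·X) + plateau.
Parameters: max (%, inducible amplitude), k (1/bp), plateau (%,
distance-independent residual). The half-decay distance D½ = ln 2/k is
additionally verified against its verbal definition (the X at which Y
falls to the midpoint between maximum and minimum) by bisection on
[0, 50/k]; the two agree to < 1e−9 relative on randomized parameters.

Fitting is unweighted nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region reflective) with constraints max ≥ 0, k ≥ 0, plateau
free; initialization plateau₀ = min y, max₀ = max y − min y,
k₀ = ln 2/(x-range/2); tolerances 1e−12, at most 10 000 function
evaluations. Constant y raises an unidentifiability error; a fit
driven to the k = 0 boundary is flagged non-decaying with D½ undefined
(NaN). Standard errors come from the curve_fit covariance. Whether
weighting or constraints beyond these are appropriate for real
densitometry data is left to the user; the defaults are the package's
own choice.

Because no raw distance/%qDNA table is published for the regime this
models, the printed fit (max = 59%, plateau = 40%, D½ = 489 bp) is used
as a *generator* for recovery tests — noiseless recovery to 1e−6
relative, and median recovered D½ within ±15% over 100 replicates with
3-percentage-point Gaussian noise at 11 default distances spanning
0–2500 bp — never as a reproduction claim from experimental data.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical regime the genomic analysis
assumes: 5-kb flanks per gene; a per-position planting rate of 1e−4
motifs/nt with a five-fold step enrichment within 1000 bp upstream of
the TSS (matching a promoter-proximal peak about five times background)
and a flat rate downstream of the TES; plants assigned to the template
strand with probability 0.5 (reverse complemented before embedding).
These defaults give ≈0.9 expected upstream plants per gene, i.e. ≈60%
PQS-positive genes — the warm-blooded-vertebrate regime.

Ground truth is exact by construction, not by estimation:

* the background (A/C/G/T = .30/.20/.20/.30) is repaired until it
  contains no run of ≥3 G or ≥3 C, so the background alone can never
  match on either strand;
* plants on one flank keep ≥8 nt clearance, so two motifs can never
  bridge into one match through a ≤7 nt loop;
* each plant is embedded with a 2-nt 'A' buffer so background G/C
  adjacent to a motif edge cannot extend a terminal tract and shift the
  match;
* sampled motif loops are drawn from {A, C, T} with 'CCC' triples
  rejected, so a plant's reverse complement cannot itself contain a
  G-tract.

Under these conditions, scanning + anchoring recovers 100% of plants at
their exact coordinates and strand classes with zero false positives —
through the direct flank route and through a synthetic genome +
annotation with genes on both strands (`generate_genome_set`), which
exercises all four gene-strand × flank-side combinations.

What the generator deliberately does *not* emulate: real genomic base
composition and autocorrelation, repeats, CpG islands, overlapping
PQS, imperfect motifs, or true inter-species differences. Passing the
exactness tests therefore demonstrates correctness of the machinery,
not performance on real genomes, where overlapping and G-run-adjacent
motifs make "the" match coordinate a convention rather than a truth.

All randomness flows from a single root seed through numpy Generators;
identical configurations produce byte-identical FASTA and truth tables.

## Problem sizes used in validation

The standing validation suite uses 5000 random sequences (≤300 nt) for
scanner-oracle agreement, 1000 genes × two 5-kb flanks for planted
recovery through the genome route, 300 genes for the statistic
identities, 20 000 genes (upstream only) for enrichment-fold recovery
— the estimator compares mean window frequency over −1000…−101 against
−5000…−1001, excluding the TSS-adjacent window where whole-motif
containment structurally thins eligible start positions — and 26-point
noiseless plus 100×11-point noisy datasets for the decay model. These
sizes give sub-percent Monte-Carlo error on the fold estimate while
keeping the whole suite inside a coffee break on one core.

## Known limitations

* The scanner's worst case is super-linear on adversarial inputs
  (kilobase homopolymeric G runs); genomic and synthetic inputs are
  nowhere near this regime.
* The oracle enumerates all parses and is intended for test-scale
  sequences (≤ a few hundred nt), as stated on the tin.
* Exact-length subclass patterns have no plain-regex equivalent (run
  maximality is context-dependent), so the `re` cross-check covers only
  the default grammar.
* `percent_qdna` takes band intensities as numbers; densitometry and
  gel-image processing are out of scope.
* No thermodynamic or structural scoring of motifs — presence/absence
  under the grammar only.
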