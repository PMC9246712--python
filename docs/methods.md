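# Methods

This note documents the models, algorithms, parameter choices and
limitations of `crisprlink`, in the order the pipeline runs them.

## Problem setting

Metagenome-assembled genomes (MAGs) are usually fragmented, and the short
contigs surrounding a draft chromosome are a mixture of assembly debris and
genuine extrachromosomal elements — plasmids and viruses.  Three lines of
in-silico evidence can separate and link them without any reference
database:

1. **CRISPR spacers** on the host chromosome are sequence records of past
   encounters with mobile elements; a spacer matching a short contig at
   full query coverage ties that contig to the host.
2. **Terminal repeats** reveal element topology: an assembler represents a
   circular molecule as a linear string whose first bases are duplicated at
   the end (terminal direct repeat), while linear dsDNA virus genomes with
   protein-primed replication carry terminal *inverted* repeats (TIRs).
3. **Read depth** well above the chromosome's suggests an element
   replicating independently of it.

Additionally, when an assembler breaks a chromosome *inside* a CRISPR
array, the two fragments end in partial arrays that can share a run of
consecutive spacers — evidence for a specific join, and for circularity of
the reassembled chromosome.  `crisprlink` implements all four analyses plus
cumulative-skew replication-origin selection, and ships a synthetic-genome
generator so that every stage is testable against planted truth with no
downloads.

## Coordinates and alphabet

All internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive (converted only at serialization).  Sequences are upper-cased on
read and restricted to `{A,C,G,T,N}`.  `N` is treated conservatively
throughout: it is excluded from every skew denominator and it *mismatches
everything* in spacer comparison, including another `N`.

## CRISPR array detection (`arrays`)

A minimal seed–cluster–extend detector, deliberately simpler than full
CRISPR annotation tools: downstream stages only need array coordinates and
ordered spacer sequences, not scores, leaders or orientation calls.

1. **Seed**: exact k-mers (default `k = 13`) occurring at least
   `min_repeats` (default 3) times on the contig.
2. **Cluster**: occurrence positions whose successive gaps lie in
   `[repeat_min + spacer_min, repeat_max + spacer_max]` (defaults: repeats
   23–50 nt, spacers 20–50 nt, so gaps 43–100 nt) and are near-constant
   (gap spread ≤ 12 nt).
3. **Extend**: each clustered seed grows left/right to the maximal repeat
   consensus by column-majority vote over occurrences, stopping when column
   agreement drops below 0.8.  Two refinements make the boundary robust:
   occurrences truncated by a contig edge count as *disagreeing* votes for
   columns they cannot see, and after extension the outer columns are
   trimmed while their agreement sits more than 0.1 below the median
   interior column agreement.  Without the second step, a random flanking
   column passes the 0.8 vote by chance at a rate of roughly 5×10⁻⁴ per
   array side when only ~10 occurrences vote, which would shift every
   spacer boundary by one base.
4. **Emit** an array when ≥ `min_repeats` repeats survive; spacers are the
   inter-repeat gaps.  Boundary repeats truncated by the contig edge count
   toward the repeat total when at least half the consensus length —
   contig-edge arrays are exactly the ones the join stage needs.
5. **Merge** overlapping candidates, keeping the one with more repeats.

Orientation is reported as `unknown`: leader-sequence inference is out of
scope, and nothing downstream needs it.

## Spacer–protospacer matching (`matching`)

Matching is **ungapped Hamming search at full query coverage**: a spacer of
length L hits every target window of length L (both strands) whose
mismatch count is within the budget (default 1).  This operationalizes
short-query BLAST searches read at 100% identity/coverage with at most one
mismatch; indel-containing alignments are deliberately out of contract,
which makes the semantics exact and testable against a naive sliding scan.
The implementation vectorizes the scan per query column (NumPy), with
encodings chosen so `N` never equals anything; the test suite requires
set-identity with an independent character-by-character oracle.

Self-hits are suppressed by default: any hit overlapping a detected CRISPR
array on the target, padded by one repeat length, is removed (a spacer
trivially matches its own array).  The synthetic generator has an
adversarial mode that plants a spacer copy inside the *other* array so this
filter is exercised in isolation.

The linkage summary counts, per target, distinct spacers with at least one
exact hit, additional distinct spacers whose best hit has exactly one
mismatch, and total hit positions.  A spacer hitting two contigs counts
toward both rows; deduplicated totals should be computed from the union,
which the summary also exposes.

## Element classification (`classify`)

Terminal **direct** repeats are found by scanning for the longest prefix
equal (within `max_mismatch`, default 0) to an equal-length suffix, down
from half the contig length; at least `min_overlap` (20 nt) is required —
a ≥20 nt chance overlap on a random contig is negligible.

Terminal **inverted** repeats are found by ungapped extension from the
contig ends: position *i* from the left is compared with the complement of
position *n−1−i*, and the arm grows under a scored extension (match +1,
mismatch −5, stop when the score falls 15 below its running maximum, ties
resolved to the shortest arm, result trimmed to end on a match).  A pure
"maximal arm with identity ≥ 0.85" rule would routinely overshoot an exact
arm, because random flanking bases match at ~25% and keep the identity
above threshold for another ~20 nt; the scored rule recovers an exact arm
at exactly its length.  Arms shorter than `min_len` (20 nt) or below
`min_identity` (0.85) are discarded.  The 80 nt default planted in the
generator reflects the length scale reported for linear archaeal virus
genomes; detection itself has no upper bound.

The coverage ratio is contig depth over chromosome depth, from the depth
table (mean per-contig depth by default; a thin optional adapter can
compute mean or median depth from a coordinate-sorted alignment, but the
pipeline never requires alignments).

Labels are assigned by a fixed cascade, first match wins:

1. designated (or longest) contig → `chromosome`;
2. ≥ 50% of length covered by arrays → `crispr_fragment`;
3. terminal direct repeat → `circular_mobile`;
4. TIR → `linear_tir_mobile`;
5. any spacer hit as target, coverage ratio ≥ 2.0, or a user-supplied
   mobile-gene annotation → `mobile_other`;
6. otherwise `unclassified`.

Every non-`unclassified` label carries its triggering evidence.  Mobile-
gene and rRNA-contaminant evidence enter only through an optional
annotation TSV — no gene calling or homology search happens here.

## Skew and origin (`skew`)

Per window (default 1000 nt, step = window; a trailing partial window is
kept when ≥ half a window):

- GC skew = (G−C)/(G+C), AT skew = (A−T)/(A+T),
- R−Y = ((A+G)−(C+T))/N, M−K = ((A+C)−(G+T))/N,

with zero denominators giving skew 0 and N excluded from all counts.
Cumulative tracks are prefix sums of the per-window values.  Sign
convention: skew positive when G (resp. A, R, M) is in excess, and the
**origin is the boundary after the window where the cumulative GC skew
attains its global minimum** (leftmost on ties) — so the leading strand is
G-rich downstream of the origin, which makes the convention and the
criterion mutually consistent.  The published procedure picks a *local*
minimum by inspection; the global minimum removes the human step, and
`origin_candidates` lists the deepest local minima for manual review when
the global one is not the biologically sensible choice.  Flags record
whether the cumulative AT, R−Y and M−K tracks sit below their medians at
the chosen window; they are advisory and never veto the GC-based choice.
`rotate_to_origin` permutes a circular contig so the chosen base becomes
nucleotide +1 and refuses to rotate linear contigs.

## Contig joining (`joins`)

For every pair of boundary arrays (arrays reaching within 500 nt of a
contig end), in both orientations of the second contig and including the
two ends of a single contig (a self-join is circularization evidence), the
stage computes the longest run of consecutive spacers matching end-to-end
between the suffix of one boundary array and the prefix of the other.
Spacer identity is exact string equality with one concession to reality:
two independent detections of the same array can place a repeat boundary a
base or two apart, so a spacer equal to another after trimming at most
2 nt from its ends also matches (for distinct random 35–42-mers such a
containment cannot occur by chance, so this cannot create false runs).
A run of `min_k` (default 4 — the evidence level that historically
justified hypothesizing a join, configurable) yields a proposal.

Merging concatenates the two contigs in the proposed orientation and
collapses the duplicated block once.  The exact block length is fixed by
the sequences themselves: the merge scans ±8 nt around the length implied
by the detected spacer spans for the longest suffix/prefix agreement
within `tolerance` mismatches (default 0) and rejects the proposal when
none qualifies — a corrupted overlap cannot slip through, because no
length in the scan range aligns the two copies while the block itself
disagrees.  Merged contigs are explicitly provisional: the output records
evidence level `in_silico`, never closure; confirming a join requires
independent wet-lab evidence such as long-range PCR across the gap.

## Synthetic assemblies (`synthetic`)

The generator emulates, at desk scale, a hot-spring archaeal host–virus
system; its defaults are the package's study conditions and are not tuned
per test:

- **Chromosome**, 60 kb (configurable ≥ 20 kb; thresholds are
  length-independent, and 60 kb keeps the suite in seconds).  Composition
  is strand-biased around a planted origin at 0.7 of the length: on the
  leading strand G−C = +0.04 and A−T = +0.06 per base, mirrored on the
  lagging strand, GC content 0.41 (a plausible neutral choice, no claim of
  realism).  Because the R−Y numerator is (A−T)+(G−C) and the M−K
  numerator is (A−T)−(G−C), choosing the A excess *larger* than the G
  excess makes all four cumulative tracks dip at the origin, so the
  corroboration flags are exercised.
- **Two CRISPR arrays** (30 nt repeat, 20 and 10 spacers, spacer lengths
  uniform on 35–42 nt, globally distinct) flanking a 1.5 kb marker locus
  at ~0.4 of the chromosome, inside the lagging-strand segment and away
  from both origin and terminus.
- **Circular virus**: 8 kb, represented with its first 30 nt duplicated at
  the end, as assemblers emit circular contigs.
- **Linear TIR virus**: 12.7 kb with exact (or 1-mismatch) 80 nt TIRs; the
  first core base is adjusted so the planted arm is *maximal* — otherwise
  the true TIR would be 81 nt and exact-length recovery meaningless.
- **Two plain mobile contigs** of 6 kb.
- **Protospacers**: 12 planted spacer copies — 9 distinct spacers with
  exact protospacers spread over all 4 mobile contigs, the TIR virus
  carrying 3 exact plus 3 single-substitution targets — on either strand,
  never inside an array, with recorded positions/strands/mismatch counts
  that the test suite recounts directly from the emitted sequences.
- **Depth table**: chromosome 20×, viruses 3.5× that, plain mobiles 1×.
- **Fragmentation mode** breaks the chromosome inside the first array so
  the fragments end in partial arrays sharing exactly *k* consecutive
  spacers (default 4), recording the correct join; concatenating the
  fragments minus the duplicated block reconstructs the chromosome
  byte-for-byte.
- **Adversarial mode** (`plant_in_array_decoy`) reuses one array-1 spacer
  as an array-2 spacer, giving the self-hit filter a decoy that must be
  suppressed only by the filter.

Everything is a pure function of (parameters, seed).  What the generator
does *not* emulate: read-level noise (depth is emitted directly, so planted
coverage ratios are recovered exactly), degenerate repeats, array erosion,
insertion sequences, or compositional heterogeneity beyond the single
origin-centred bias.  Passing tests therefore demonstrate correctness of
the algorithms under clean planted signals, not detection power on noisy
real assemblies.

## Problem sizes used by tests and the acceptance script

Sweeps use 20 seeds (detection/classification/joins), 50 seeds (origin
recovery), 10 seeds (matcher-oracle identity, each assembly ≤ 100 kb
total), and 10 shuffled-control replicates; these sizes give stable
percentages while keeping a full run in a couple of minutes on one CPU.

## Known limitations

- The matcher is ungapped by design; a protospacer containing an indel
  relative to its spacer is invisible at any mismatch budget.
- Array orientation and leader inference are not attempted, so spacer
  acquisition order is not interpretable from the output.
- The global-minimum origin rule can pick a different replichore boundary
  than a human would on genomes with multiple comparable minima; use the
  candidate list there.
- Coverage ratios use whatever single depth statistic the table provides;
  no within-contig depth variance is modelled or checked.
- Classification labels are assembly-level heuristics, not taxonomy; the
  per-element minimal-information blocks emit `not_computed` for fields
  (taxonomy, host-prediction method) that would require out-of-scope
  tools.
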