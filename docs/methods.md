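# Methods

## The merging model

For one reference contig and one SV class, every caller `c` defines a
binary occupancy signal `s_c(x)` over bases `x`: 1 where any of its
calls of that class covers `x`, 0 elsewhere. Overlapping calls from
the same caller count once — per-caller occupancy is binary by
construction, so duplicated records cannot inflate support (identical
records are additionally deduplicated at ingest). The consensus
signal is the weighted sum `S(x) = Σ_c w_c·s_c(x)` with integer
weights `w_c ≥ 1`.

Merging then proceeds in four steps:

1. **Threshold.** Maximal runs with `S(x) ≥ minCallers` are kept.
   The threshold is class-specific: one value for the CNV group
   (deletions and duplications share it), one for inversions, one for
   insertions, reflecting that fewer callers can call the latter two.
2. **Gap fusion.** Consecutive kept runs separated by ≤ `maxGap` bp
   are fused, transitively, into one event. We interpret `maxGap` as
   the gap between supra-threshold segments of the summed signal; on
   the signal this is equivalent to bounding the disagreement between
   the callers' start/stop coordinates, and it stays well defined when
   more than two callers disagree.
3. **maxSup.** Within each event the maximum of `S` is the event's
   support; the narrowest coordinates reported (`maxsup_start/end`)
   are the longest maximal run attaining that maximum, leftmost on
   ties. The tie-break is a package convention — any rule consistent
   with "narrowest coordinates of maximal support" would do, and ties
   are rare on real signals.
4. **Backtrack.** Each event is re-associated with the original
   caller records overlapping its span: per-caller sub-event counts
   and the fraction of the span covered by the union of that caller's
   overlapping calls (clipped to the span). A long event reported by
   one caller as several shards therefore shows, e.g., `subevents 3,
   coverage 0.9`.

`support` is the peak weighted sum, which with unit weights equals the
number of distinct callers stacked at the best-supported bases; the
distinct-caller count over the whole event is reported separately as
`n_callers`, so consumers can filter on either.

Insertions have no reference footprint; they are modelled as width-1
intervals at the breakpoint (the inserted length travels in `SVLEN`).
Two insertion breakpoints within `maxGap` of each other therefore fuse
into one event, consistently with the interval classes. The
insertion-specialist weighting (`w = 2` on INS for a caller such as
INSurVeyor, with `minCallers(INS) = 2`) makes that caller's solo calls
pass the vote while still requiring two independent split-read callers
to agree otherwise; this guarantee is asserted by a dedicated test.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `min_callers_cnv` | 2 | weighted support needed for DEL and for DUP regions |
| `min_callers_inv` | 2 | same, inversions (at most 3 callers can call them) |
| `min_callers_ins` | 2 | same, insertions |
| `max_gap` | 100 bp | largest fused gap between supra-threshold regions; no canonical value exists, so it is configurable and 100 bp is a deliberate, conservative default well below typical event spacing |
| `weights` | specialist ×2 on INS | per-caller, optionally per-class integer weights |

A threshold of 2 is the sensible floor for a consensus: it removes
single-caller false positives (historically dominated by the chatty
split-read and short-CNV callers) while keeping events that any two
independent callers support. Raising the CNV threshold to 3–4 trades
recall for precision and suits long, easy events.

### Implementation and the oracle

`merge_all` materializes one dense integer array per (contig, class)
using numpy difference arrays — O(genome length) per caller, which is
cheap at bacterial scale (a 4 Mb chromosome × 4 classes is a few tens
of MB transiently). `baseline.bruteforce_signal_merge` restates the
same rules as per-base Python loops with no shortcuts and is capped at
100 kb genomes; the test suite asserts exact equality of the two on
hundreds of randomized instances (spans, support, maxSup, caller sets,
coverages). Coordinates are 0-based half-open internally; VCF's
1-based, END-inclusive convention is converted only at the I/O
boundary. Signals are linear: events are never fused across the
replication origin of a circular chromosome (a documented limitation —
origin-spanning rearrangements will appear as two events at the contig
ends).

## The interval-distance baseline

`survivor_merge` implements the merging rule popularized by the
SURVIVOR toolkit: two same-class calls belong together when both their
start and end coordinates agree within `max_distance` (1 kbp in the
canonical setting), closed under single linkage; clusters with at
least `min_callers` distinct callers are reported with outer
coordinates. Whether the distance should be tested pairwise within a
growing cluster or against a representative is not specified by the
rule as usually stated; pairwise single linkage is implemented. The
cluster representative for the `maxsup` columns is the lower-median
start and end of the members — there is no summed signal here, so
"support" is the distinct-caller count. This is an implementation of
the *rule*, not a bit-for-bit port of the external tool.

On concordant, well-separated input the two backends produce identical
events (asserted in tests). On long events fragmented by one caller
they legitimately differ: the signal backend consolidates shards into
one continuous event, while interval-distance clustering may keep or
split them depending on shard geometry; the test suite measures and
reports that divergence instead of asserting it away. Note that
single-linkage clustering can also fuse *distinct* short events whose
breakpoints all lie within the distance bound — visible in the demo as
399 clusters for 400 truth events.

## The simulator

The simulator emulates, at the call level, the artificial benchmark
design used for bacterial SV mergers: 100 truth events per class
(uniform lengths 50–10,000 bp; insertions as width-1 breakpoints with
a stored inserted length) placed without overlap on a 4 Mb synthetic
chromosome. Placement draws the residual free space by sorted uniform
offsets, guaranteeing exact class counts and a minimum spacing
(default 500 bp) in a single pass. Each synthetic caller observes the
truth through an error profile: miss probability, rounded-normal
breakpoint jitter (clipped to the contig, re-ordered if inverted, and
never thinner than 2 bp so every record round-trips through VCF),
Poisson false positives per Mb, fragmentation of long events into ≥ 2
sub-calls whose union stays inside the event span with ≤ 50 bp
internal gaps, and class confusion (a 5 % inversion→duplication rate
for callers that call both, mirroring how split-read signatures of the
two can be conflated).

The default panel mirrors the common six-caller setup: three
breakpoint callers handling all four classes, two depth-based CNV
callers (DEL/DUP only), and one insertion specialist (INS only). The
"5x"/"20x"/"100x" presets map sequencing depth to error severity
(higher miss rates and jitter at low coverage); this mapping is the
package's own illustrative choice — real caller error characteristics
vary — so quantitative results under noise characterize the merging
algorithm's behaviour, not any specific caller. What the simulator
deliberately does *not* model: read-level effects (mappability,
GC-content, repeat-induced systematic errors shared between callers),
correlated errors across callers, and genotype or quality annotations.
Passing tests therefore demonstrate correctness of the merging and
scoring machinery and realistic-shaped robustness, not field accuracy
of any particular caller combination.

## Evaluation conventions

A DEL/DUP/INV prediction is a true positive when it overlaps a
same-class truth interval by ≥ 1 bp (a stricter reciprocal-overlap
mode is available but off by default, matching the permissive
convention under which fragmented calls still count). An insertion
matches when the truth breakpoint lies within ±50 bp of the predicted
footprint (distance from the point to the interval, for merged events
wider than 1 bp). A truth event matched by several predictions counts
once as TP and the extras are not false positives (configurable).
`tp + fn = |truth|` always holds per class.

Precision, recall/sensitivity and F1 are reported as percentages to
one decimal; F1 is computed as `2·tp / (2·tp + fp + fn)` directly from
counts so that printed rounding of P and R cannot distort it. True
negatives are undefined for interval detection unless the user
supplies explicit negative regions (`match_with_negatives`), in which
case accuracy and specificity are computed event-wise over positives
plus negatives; the package takes no position on how any external
benchmark defined its negative set.

## Numerical and degenerate-input choices

* Empty call lists merge to empty outputs; empty merged lists write
  header-only TSVs; all-zero signals produce no segments.
* A merged span with no signal is a contract violation and raises.
* VCF records with unsupported types (BND/TRA/direction-less CNV),
  with neither END nor SVLEN, or with END ≤ POS are skipped with a
  per-reason tally surfaced in the run manifest; a record on a contig
  absent from the genome table is a hard error. A 1 bp symbolic
  record whose explicit END equals POS is indistinguishable after
  htslib normalization from one lacking END and is likewise skipped.
* Coverage fractions are serialized at 4 decimal places; event
  coordinates and counts are exact integers, so merged TSVs round-trip
  losslessly up to that precision.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; identical seeds give byte-identical output files
  (asserted end to end).

## Problem sizes used in the test and acceptance runs

Differential-oracle suites run on randomized genomes of 0.5–3 kb
(every 50th instance up to 20 kb) with up to six callers and twenty
calls per caller — small enough for the per-base oracle to stay fast,
large enough to exercise every rule interaction; end-to-end closure
and demo runs use the full 400-event, 4 Mb configuration. The demo
completes in seconds on one CPU.
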