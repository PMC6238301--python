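# Methods

This note documents the models and procedures implemented in
`promclust`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical conventions.

## Signal matrix

For a TSS at position *t* and an experiment's peak calls, the recorded
value is the height of the peak whose **summit** minimizes |summit − t|
among summits within ±`tss_window` (default 1000 bp, symmetric, strand
ignored); 0 when no summit qualifies. Distance ties are broken by
larger height, then smaller coordinate — the tie direction is
immaterial in practice but fixed for determinism. Summit distance is
used rather than interval distance because the summit is the single
most informative point of a peak; the choice is switchable by
preprocessing the peak table.

Per experiment, heights are normalized by holding out the top
`winsor_fraction` (default 0.0005, i.e. 0.05%) of values — exactly
k = ⌊winsor_fraction · n⌋ of them — mapping the remaining values
linearly so min → 0 and max → 1, and setting the held-out values to 1.
Flooring makes k = 0 below 2000 promoters, where a "top 0.05%" is not
meaningful. Degenerate constant vectors preserve the no-signal /
saturated distinction: all-zero → all 0, constant positive → all 1.

Coordinates are 0-based half-open throughout; "overlap" always means
at least one shared base.

## Promoter definition and activity

Two definitions are supported.

*RefSeq-style*: any TSS with another TSS within 1 kb (pairwise
distance ≤ 1000 bp, compared across strands and genes) is dropped,
along with all members of the offending group — peak-resolution data
cannot attribute signal among such TSSs. The cross-everything
comparison is the stricter reading and is switchable by pre-filtering.

*CAGE-cluster-style*: TSSs chain into clusters by single linkage at
gaps strictly below 200 bp. Clusters spanning more than 1000 bp,
containing both strands, or containing more than one annotated gene
are excluded with a recorded reason (a TSS without a gene assignment
excludes its cluster rather than raising). Activity is then called on
the cluster span extended 500 bp on each side, strand-specifically.

Activity tiers: a robust CAGE peak in the window ⇒ **active**; not
even a permissive peak ⇒ **inactive**; permissive only ⇒ **low**
(excluded from both the active and the inactive analyses). The tiers
must be nested; a robust peak without a permissive counterpart is an
input-consistency error. The RefSeq-style single-TSS call uses a
strand-agnostic window; strand specificity is applied in the
CAGE-cluster pipeline only, where the promoter has a defined cluster
strand.

Matrix reduction: inactive promoters whose matrix column is all zeros
are dropped; within a TSS cluster, columns with exactly identical
signal collapse to the first by coordinate. Inactive TSSs in
intergenic regions (no overlap with any annotated gene span) are
dropped by `drop_intergenic_inactive`.

## SSVD biclustering engine

The base engine extracts rank-1 layers ũṽᵀ with sparse supports:

1. The leading right singular vector is found by power iteration from
   a seeded random start.
2. Alternating updates z = Xv and z = Xᵀu are hard-thresholded at the
   support size minimizing a BIC-type criterion
   RSS(k)/σ̂² + k·c·log(mn), where σ̂² is the dense rank-1 residual
   variance and c (`bic_penalty`, default 2.0) sets the entrywise cut
   at σ̂·√(c·log mn) ≈ 3σ̂. Alternation stops when the supports
   stabilize (≤ 15 rounds).
3. Stability selection: the fit is repeated on `n_subsamples` (100)
   random subsamples of half the rows and half the columns
   (`subsample_fraction` 0.5). Subsamples whose leading layer matches
   the full-matrix layer (a majority of selected rows and columns fall
   in its support) vote; an element joins the layer if selected in at
   least `stability_threshold` (0.6) of the matching subsamples that
   contained it. The matching requirement is essential when several
   structures coexist: a subsample dominated by a *different* planted
   block says nothing about this layer's stability.
4. The layer is removed by subtracting the rank-1 SVD fit restricted
   to its support (background cells stay untouched) and extraction
   repeats, up to `max_layers` (10) or until no stable layer remains.
   Columns (and rows) claimed by several layers go to the layer with
   the largest mean original signal over the layer's rows (columns),
   so column sets partition a subset of the columns.

All constants are exposed on `SSVDParams`. This is a documented
variant with the published contract of randomized seedable SVD-based
biclustering — randomness enters through the power-iteration start and
the subsamples — not a re-implementation of any specific package's
internals, whose defaults are version-dependent; the consensus wrapper
is deliberately engine-agnostic and is tested with both engines and
with stub engines.

## k-means + t-test engine

Columns are partitioned by k-means (k-means++ initialization, seeded,
10 restarts). For each column cluster, each row is Welch-tested inside
vs outside; rows with p < `alpha` (default 0.001) **and** a positive
mean difference form the associated row cluster. The sign condition
restricts association to enrichment: a depleted row also achieves a
small p, but attaching it would mark a track as characteristic of a
cluster where it is conspicuously absent, and would break exact
recovery of planted blocks. Rows may join several clusters. Clusters
with fewer than two columns cannot be tested and get no rows.

`choose_k` applies a 5% SSE elbow: the smallest k in range whose
relative inertia improvement to k+1 falls below 5%; if no k qualifies
the largest k in range is returned, and an all-identical-columns
matrix returns the smallest.

## Consensus procedure

The engine runs `n_runs` times with seeds derived from one seed
(SeedSequence fan-out). The run with the most column clusters is the
*target* (ties broken by the seeded RNG). Every run's clusters are
matched one-to-one to the target clusters by maximizing total column
overlap — a linear assignment problem solved on the negated confusion
matrix (zero-padded to square; assignments on padding are dropped).
LAP ties resolve deterministically; randomness is reserved for the
target-selection tie-break.

Per column, the frequency of being mapped into each target cluster is
tallied over all `n_runs` runs (the target run counts as mapping its
own columns to themselves — the literal reading of "more than half of
the solutions"). A column is retained iff its best frequency strictly
exceeds `min_freq` (default 0.5), with its best cluster; rows are
retained by the same rule applied to the row sides of the matched
biclusters, reusing `min_freq` so the column and row rules stay
symmetric (at the default they coincide with the more-than-half rule).
A column mapped to different target clusters across runs contributes
to each cluster's frequency; only its best frequency is thresholded.
Frequencies per column therefore sum to at most 1, and raising
`min_freq` can only shrink the retained sets.

For every retained row and every retained column cluster, a two-sided
Welch t-test compares the row's values inside the cluster's columns
against all other columns of the matrix; the bar height reported is
−log₁₀ p. Welch (unequal variance) is the safe default for the very
unequal group sizes involved; degenerate rows follow a fixed
convention — equal constants give p = 1 (bar 0), different constants
give p = 10⁻³⁰⁰ (finite bar) — so bars are always plottable.

`order_heatmap` lays out columns grouped by cluster (clusters by
retained size descending), within-cluster by column mean descending,
rows analogously, unassigned last, and reports group boundaries.

## Regression feature selection

Expression is regressed by OLS (with intercept) on all matrix rows;
the benchmark is the Pearson correlation r_full between fitted and
observed values. CAGE tag counts are log(x+1)-transformed by default
(`log_transform`), matching how tag counts are displayed and
stabilizing their dynamic range; the transform is switchable, and the
synthetic-recovery tests disable it because generated expression
already lives on the normalized-signal scale. Every subset of 4
experiments is fitted exactly: with the Gram matrix G = AᵀA of the
full design precomputed, each subset needs one 5×5 solve and the
Pearson r follows from Gram pieces, so the full C(60, 4) = 487 635
scan takes under a second at 2000 promoters (verified identical to
per-subset `lstsq` fits at 1e-10). "Good sets" are subsets with
r strictly above `fraction` · r_full (default 0.95, strict reading of
"better than"). Each experiment v is then scored by the upper-tail
hypergeometric probability of observing its count among the good sets:
population C(n, 4) subsets, of which C(n−1, 3) contain v, drawn
|good| times. Rank-deficient designs fall back to the minimum-norm
solution with a warning. r is computed in-sample.

## Motif maps

Motif scanning is upstream; the module consumes a TSV hit table
(promoter, motif, strand, TSS-relative strand-oriented position,
score, p). Per promoter and motif the smallest-p hit is kept, ties
broken by distance to the TSS then leftmost. Score matrices are laid
out in heatmap column order with 0 for missing hits; raw scores are
reported without renormalization. Positions are reported for best hits
with p < 0.001 within ±200 bp by default.

## Loop / enhancer overlap

Loops whose anchor overlaps the promoter region (≥ 1 bp) are
collected; the other anchor is the remote region (when both anchors
overlap, the larger overlap is the promoter side). Among several loops
the one with the highest H3K27ac over its remote anchor wins; the
summary is the **mean** coverage (switchable to max — the summary
statistic is not standardized in the field), ties to the leftmost
remote start. The remote region padded ±500 bp is classified by
enhancer-segment overlap with strong > weak > none precedence, so the
class is total and can only escalate as the pad grows. For coverage
profiles the remote region is re-centered on its maximum-CTCF position
(ties leftmost) and extended ±1000 bp; zero coverage falls back to the
geometric midpoint with a flag.

## Synthetic generators

`make_planted_matrix` plants disjoint blocks on contiguous disjoint
row/column ranges: block cells are mean_signal + N(0, noise_sd)
clipped to [0, 1] (the matrix is defined on the normalized scale);
background cells are exactly 0 except with probability
`background_rate` a small positive spurious height (U(0.01, 0.2)) —
peak-call matrices are mostly exact zeros, so background is sparse
rather than dense Gaussian. Defaults (300 promoters × 30 experiments;
blocks 8×120, 7×90, 6×60 at signal 1.0; noise 0.2; background 2%) are
the reference simulation conditions used by the test suite; the block
shapes are deliberately unequal, as real promoter clusters are, which
also gives the layers distinct singular values. One seed fans out into
per-generator substreams, so adding a generator never perturbs
existing output; fixed seed ⇒ bit-identical output.

`make_toy_genome` cycles eight scenario types (active / low / inactive
single TSSs, an isolation-violating pair, a chainable CAGE cluster,
mixed-strand and multi-gene pairs, and a > 1 kb chain) so every
promoter rule fires at least once for n_genes ≥ 8, and records the
expected label of every TSS and cluster. `make_expression` produces
Σ wᵢ·X[i,·] + N(0, σ²) with the driving rows recorded. `make_loops`
anchors loops on given promoters, assigns remote-anchor enhancer
classes with default mix (65.04% strong, 26.07% weak, 8.89% none —
the proportions reported for active CTCF-cluster promoters), gives
each promoter's loops distinct H3K27ac levels so the selected loop is
unambiguous, and places a single CTCF coverage apex per remote anchor.

What the generators do **not** emulate: read-level noise, replicate
structure, correlated occupancy between tracks, mappability artifacts,
distance-dependent loop frequencies, and genome-scale coordinate
ranges. Passing tests therefore demonstrate correctness of the
procedures and recoverability under idealized block structure, not
performance on real ENCODE-scale data.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: consensus
recovery on five 30×300 matrices with 20 runs each, the full
C(60, 4) regression scan at 2000 promoters, feature recovery over 20
seeds at 1000 promoters, and loop fixtures with 60 promoters and 180
loops — sizes chosen so the whole suite completes in a few minutes
while every code path runs at full fidelity. All randomness flows from
explicit seeds (NumPy `SeedSequence` fan-out; derived seeds kept below
2³¹); repeated runs with the same seed are bit-identical, including
tie-breaks.

## Interfaces

The package is a library: the importable API plus the narrative
scripts under `examples/` are the interface, and file exchange uses
plain-text formats (BED6, 5-column peak tables, BEDPE, TSV matrices
and tables, JSON solutions) via the readers/writers in `signal`,
`synthetic`, `motifs` and `loops`. No shell entry points are
installed; every operation is a composable function.

## Known limitations

- The SSVD engine targets non-negative block structure on [0, 1]
  matrices; anticorrelated (sign-split) biclusters are found but the
  overlap-resolution step assumes enrichment.
- Exact numerical equivalence with any particular published
  biclustering package is not claimed and not attainable from
  contract-level descriptions; the consensus layer is the tested,
  engine-agnostic contribution.
- `enhancer_class` precedence collapses mixed overlaps to the
  stronger state; partial-overlap fractions are not reported.
- The regression scan is exhaustive only for the subset size
  requested (default 4); larger subset sizes grow combinatorially.
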