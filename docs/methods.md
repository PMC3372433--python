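# Methods

This note documents the models, rules and numerical choices behind the
package, the conditions the synthetic-data generator emulates, and the
limits of what the tests demonstrate.

## Ortholog assignment

Marker sequences queried against a reference genome produce BLAST tabular
hits.  Because one gene typically yields several HSPs, hits of a query on
the same subject sequence are first merged: HSP midpoints within the
`hsp_merge_window` (default 50 kb, single linkage along the subject) form
one *locus*, placed at the midpoint of the merged span and carrying the
best member E-value.  The window size is an operational choice — the
single-position notion in marker-based mapping is not defined at the HSP
level — and is exposed as configuration.

The cascade thresholds are `e_strict = 1e-10` (stringent screen, kept for
bookkeeping), `e_primary = 1e-6` (the working orthology cutoff) and the
relaxed fallback series `1e-30, 1e-20, 1e-5` used against EST/CDS sets for
queries that the primary search misses.  Assignment per query:

- exactly one merged locus among hits with E ≤ `e_primary` →
  `single_locus`, with the locus position as the target coordinate
  (subjects named in the unplaced-contig or position-unknown lists are
  booked as `unplaced_contig` / `chrom_unknown_position` instead and are
  excluded from chaining);
- two or more loci → `multi_locus`, excluded from synteny — this includes
  equal-E-value ties on different chromosomes (conservative exclusion of
  possible family expansions);
- no primary hit but some hit at or below the loosest fallback cutoff →
  `absent_primary_conserved_fallback` (bookkeeping only, never mapped);
- otherwise `absent`.

The statuses partition the queries.  The count of queries with at least
one primary locus is monotone in `e_primary`; the `single_locus` count
alone is not, because relaxing the cutoff can surface a second locus and
flip a marker from single- to multi-locus.

## Conserved syntenic segments

A segment (CSS) needs at least `min_markers = 3` single-locus markers on
one (linkage group, chromosome) pair, with consecutive markers — in map
order — within `max_gap_query` cM on the map and `max_gap_target` bp on
the genome.  Defaults: 3.2 Mb for the physical gap (a 200-gene window:
`gene_window × genome_size / n_genes` = 200 × 475 Mb / 30,434 ≈ 3.12 Mb,
rounded up to the working 3.2 Mb) and 12 cM for the genetic gap (about 1%
of a ~1350 cM map; for other maps `map_fraction × map_length` with an
explicit floor-to-integer policy, e.g. 14.63 → 14 cM for a 1463 cM map).
The 12 cM value is stored as an explicit override rather than derived,
since 1% of 1349 cM is 13.49.

Chaining is greedy in query-cM order (co-segregating markers ordered by
id, their mutual gap zero): a gap violating either threshold closes the
chain.  Because the validity of a chain depends only on consecutive pairs,
the greedy partition coincides with the enumeration of maximal valid
chains; a brute-force O(n³) enumeration guards this equivalence in the
tests for instances up to 15 markers.  Target gaps are unsigned, so
inversions inside a segment do not break it.  Map markers lying inside a
block's query span that are not members are counted per block as
interspersed when their own assignment is single-locus elsewhere or
absent; multi-locus and unanchored markers are not counted, since they
carry no usable position.  Interspersed runs never break chains by
default; the optional `max_interspersed` limit closes a chain that would
skip a longer foreign run.

Genetic-versus-genetic comparisons reuse the same chaining with a cM gap
threshold on each axis (each map contributes its own 1%-derived limit).

`summarize` reports block counts, spans on both axes, markers per block
and adjacent-marker distances; distances are pooled over all consecutive
member pairs across blocks (the per-block-mean alternative is available
as `adjacent="per_block"`).  `project_multiway` overlays two pairwise
block sets on their shared reference: every block pair gets its target
overlap in bp (zero across chromosomes) and Jaccard index, and each
reference chromosome its covered fraction under the union of block spans.

No significance testing is applied to blocks; the method is a
deterministic rule, and the package does not attempt ancestral-karyotype
reconstruction or per-lineage breakpoint attribution beyond reporting
overlaps.

## Microsynteny

Segments are ordered, oriented gene lists with family labels supplied as
input (an attribute in the GFF3, default key `family`); genes without a
label are lineage-specific by definition.  The collinear backbone is a
longest common subsequence of family labels; when several backbones of
equal length exist the leftmost one in the lexicographically first
segment is chosen, and the comparison is computed in that canonical
segment order and mirrored, which makes `align(A, B)` and `align(B, A)`
mirror images by construction.  The consensus relative orientation is the
majority over matched pairs (ties read as same-strand); a matched pair
agreeing with the consensus is `same_order_and_orientation`, otherwise
`inverted`.  Unmatched genes whose family is in the backbone are tandem
`duplicated` copies; the remainder are `a_specific`/`b_specific`.  With
`allow_reverse_reading` the second segment is also tried reversed with
strands flipped and the reading with the larger backbone wins (forward on
ties).  A gene family present in both segments but transposed out of any
optimal backbone is classified lineage-specific on both sides — order
breaks are deliberately not matched.

The single-linkage family helper (connected components over a similarity
threshold) exists to build fixtures; family inference from sequence is
out of scope.  The shipped ovate-style segments are synthetic fixtures:
their gene content encodes the qualitative structure of a three-species
fruit-shape-locus comparison (a grape-like segment conserving 13 of 16
coffee-like families, 12 in identical order and orientation and one
inverted; a tomato-like segment conserving 10, two inverted, with two
families absent from the coffee-like segment), and the tests assert those
fixture-defined counts plus the directional contrast, not any published
values.

## The generator

`simulate_ancestor` lays out `n_chromosomes × markers_per_chromosome`
point markers with i.i.d. Gamma(shape 4) inter-marker gaps of mean
`mean_gap_bp` (default 1.1 Mb; 11 × 40 markers then span ~480 Mb, the
scale of a few-hundred-marker panel on a mid-size plant genome).  Gaps
are capped at `max_gap_bp` (default 2.8 Mb): curated marker panels are
chosen for roughly even coverage, and the cap guarantees that an
unrearranged genome can never present a spacing wider than the default
chaining threshold — the zero-event identity invariant (one detected
block per chromosome, for every seed) is structural, not statistical.

`evolve` applies `n_events_per_lineage` random events per lineage with
kind weights {inversion .4, reciprocal translocation .4, fusion .1,
fission .1}; fusions and fissions change the chromosome number, emulating
different basic numbers in the descendants.  Breakpoints fall only
between markers (markers are points; sub-marker breakage is unobservable
at map resolution).  Marker loss removes each marker independently with
`marker_loss_rate`, its gap absorbed by the neighbour so physical spans
are preserved; paralog insertion adds uniquely named copies at random
positions.  Explicit event lists can replace the random draw to construct
known scenarios.

**Truth blocks.**  Shared markers are grouped by their (chromosome in A,
chromosome in B) pair; within a group a true segment is a maximal run, in
A order, whose members occupy consecutive ranks among the group's markers
in B (a common interval of the group-restricted orders).  Markers of
other groups interleaved on either chromosome are exactly the
interspersed foreign markers that distance-based chaining does not break
on, so they do not split truth segments either; inversions and
within-segment transpositions are invisible to the definition, as they
are to the detector.  The blocks partition the shared markers, and an
independent set-based recount backs the construction in the tests.

**Observation.**  `project_genetic` multiplies each physical gap by its
own recombination rate from a clipped normal (mean 2.8 cM/Mb, sd 0.4,
clipped to [0.5, 4.0] cM/Mb) — rank-preserving jitter around linearity;
the defaults give a ~1350 cM total map over 11 linkage groups.  The clip
also bounds a single capped gap at 11.2 cM, below the 12 cM chaining
limit, for the same structural reason as the gap cap.  Map noise that
reorders markers is deliberately absent: it would make truth blocks
ill-defined.  `emit_hits` gives every true ortholog one strong hit
(E-value log-uniform in [1e-180, 1e-30]); designated markers additionally
get a second strong hit elsewhere (multi-locus plant), a weak-only hit in
(1e-6, 1e-5] (fallback-only plant), or a true hit split into two nearby
HSPs (merge exercise).

**What the simulation does not model:** sequence evolution, whole-genome
duplication (the study system is explicitly unduplicated), E-value
dependence on divergence time, assembly errors, or map-order errors.
Passing recovery tests therefore show that the chaining rule inverts the
rearrangement process under clean anchoring — not that it is robust to
mis-assembled references or mis-ordered maps.

## Study scales and reported quantities

The recovery study uses an 11 × 40 ancestor, 8 events per lineage, 10%
marker loss and rank-preserving map noise; at these conditions detected
segments cover ≥ 90% of true-segment adjacencies (pairs of markers
adjacent within a true segment landing in one detected block) with zero
blocks spanning a true breakpoint.  Coverage losses come from segments
smaller than `min_markers` and from loss-widened gaps that exceed a
threshold; both are properties of the rule, not bugs.  The acceptance
script runs this study at full scale (seconds of runtime), checks
chaining against exhaustive enumeration on 300 random small instances,
derives the thresholds from the genome constants, triangulates a third
lineage and reports the bundled-fixture microsynteny counts; every number
in its JSON is computed at run time from the seed given.

## Numerical and degenerate-input choices

- Physical coordinates are 1-based closed internally (GFF3 convention);
  BED converts on read/write.  Genetic positions stay as printed, in cM.
- Marker and feature ids are case-sensitive opaque strings.
- Float serialization uses `repr` round-tripping, so read → write → read
  is the identity and equal inputs give byte-identical reports.
- Empty block lists summarize to zeros; empty hit tables assign
  everything in `query_ids` as absent; an empty genetic map is an error
  (`no markers`).
- Ties everywhere break deterministically (marker id, subject name,
  leftmost backbone), so no output depends on iteration order.
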