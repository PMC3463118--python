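# Methods

`splitmap` is a seed-and-extend DNA aligner built for split-read
structural-variant (SV) breakpoint detection from long queries (reads of
100 bp – 30 kb, or assembled contigs).  The distinguishing stage is the
selection of an *Optimal Coverage Set* of alignments along each query by a
max-path search over a directed acyclic graph, with a biologically motivated
penalty per split, followed by a similarity filter that reports repetitive
secondary alignments for the selected segments.  This note records the model,
the parameters that matter, the numerical choices, and what the simulation
suite does and does not demonstrate.

## Pipeline

### 1. Hash index

The reference is concatenated into one offset space (per-sequence boundaries
recorded; no seed spans a boundary) and 2-bit encoded (A=0, C=1, G=2, T=3,
first base most significant, so key order matches lexicographic sequence
order).  For every seed start position on the `skip` grid whose k-mer is free
of ambiguous bases, the offset is recorded under the k-mer's integer key.
Hits per key are stored ascending in one Reference Offset Array (ROA).  The
key table is stored *compressed* — only keys present in the reference, looked
up by binary search — because a dense 4^k table at the default k=15 costs
gigabytes without changing any observable behaviour at the scales this
package targets.  Only the forward strand is indexed; reverse-strand hits
come from aligning the reverse-complemented query, which halves index size.

k-mers with more than `max_hits` occurrences are excluded, or — with
`sampling` on — down-sampled uniformly without replacement to exactly
`max_hits` (re-sorted ascending, reproducible from `rng_seed`).  Defaults
k=15, skip=1, max_hits=650: with these, essentially all k-mers of a random
megabase-scale genome are retained, while pathologically repetitive keys are
cheap to bound.

The index persists as a single self-describing little-endian binary
(magic `SSIX`, format version, all build parameters), so an index can never
be silently used with mismatched parameters.  Ambiguous reference positions
are carried in a sparse side list next to the 2-bit payload.  Two builds from
identical inputs produce byte-identical files.

### 2. Seeding

Each query position contributes one k-mer whose presorted hit list comes
straight from the ROA.  A QL-way merge with a binary heap (at most one live
entry per query position, shrinking as lists exhaust) emits all seed matches
sorted by (diagonal, query offset) without materialising and sorting the full
N-element seed array.  Same-diagonal seeds whose query spans overlap or abut
(`next.qo <= prev.qo + k`) coalesce into *fragments*.  Because the merge
condition forces contiguous k-mer coverage of the merged span, every fragment
is an exact match run by construction, for any skip value.

### 3. Chaining

Fragments of one strand are grouped into reference regions (a new region
when the reference gap exceeds 10x the query length, capped at 50 kb, or at a
sequence boundary).  Within a region the best chain is found over fragments
presorted by query start, relaxing each ordered pair once — O(n²) time,
O(n) space, no edge materialisation.  Node reward: `match * length`.  Edge
cost for fragment f2 following f1:

* diagonal difference d: one indel, `gap_open + gap_extend * d` (0 if d = 0);
* bases of f2 overlapping f1 on query or reference are trimmed from f2's
  reward (each matching base counts once);
* the unmatched middle, `min(qGap, rGap)`, is charged as a substitution run
  at `mismatch` per base.

The third term is this package's own extension of the classic
matches-plus-single-indel estimate.  Without it, two fragments on the *same*
diagonal but thousands of bases apart chain at zero estimated cost; the DP
fill then discovers the estimate was wildly optimistic and the alignment is
discarded whole.  On shattered (chromothripsis-style) contigs this failure
mode halved junction recovery.  The substitution-run charge is exactly zero
in the abutting and pure-indel configurations the estimate was designed for,
and is a worst-case (hence admissible-in-spirit) bound on what the fill can
lose crossing the middle.

Chaining repeats on remaining fragments that do not overlap on the query with
any chain already produced in the region, so query-disjoint repeats of a
region each yield a potential alignment.  Potential alignments whose seeds
cover fewer than `min_match` non-overlapping query bases are discarded.
`min_match` is counted in bases, not seed hits: 15 equals a single seed hit
at k=15; defaults here are 20 for ~100 bp reads and 25 for 500 bp reads and
contigs.

### 4. DP completion

Scoring is affine-gap throughout: `match=+1, mismatch=-3, gap_open=-5,
gap_extend=-2`; a gap of length L costs `gap_open + gap_extend*L`.  The same
convention is used by the chain estimator, the fills, the extensions, and the
SAM `AS` tag, so scores are comparable across stages.

* **Inter-fragment fills** are *global* (endpoints pinned by exact-match
  fragments), banded: cells with diagonal j−i in
  `[min(0, m−n) − bw, max(0, m−n) + bw]`.  This band always contains both
  corners, so a complete path exists for any bw ≥ 1 and the fill cannot
  fail; with bw ≥ max(m, n) it is exactly unbanded global DP.  bw defaults
  to 15 (widened to the length difference when an indel larger than the band
  is being bridged).
* **End extensions** are *local* (free to stop), run at twice the band
  width, and use an X-dropoff: a row of the banded matrix whose best cell
  falls more than X (default 25) below the best score seen terminates the
  extension; the reported extension is the best-scoring cell.  Pruning is
  per query row; with the band centred on the anchor diagonal a row is
  within ±band of an antidiagonal, and the huge-X behaviour (equal to
  unrestricted extension) is verified against an independent full-DP oracle.
* The row recurrences are vectorised with numpy; the horizontal gap state is
  computed with a running-maximum prefix scan, valid because re-opening a
  gap out of a gap never beats the single direct gap when `gap_open <= 0`.
* Traceback ties prefer match over deletion over insertion — CIGARs are
  deterministic.
* Chained fragments may overlap; the overlap is physically trimmed from the
  later fragment (both coordinates move together on a diagonal) before
  filling.

Completed alignments carry CIGAR (M/I/D core; soft clips added on output),
exact integer score, strand, and both aligned-orientation and forward-query
coordinates.  Rescoring the CIGAR against the sequences reproduces the score
exactly; this is asserted throughout the suite.

`full_sw_oracle` — exact, unbanded, local affine-gap DP with no heuristics —
lives alongside the production kernels and serves as the accuracy benchmark,
the same role a full Smith–Waterman tool plays when benchmarking heuristic
aligners.

### 5. Optimal Query Coverage (OQC)

All completed alignments of a query (both strands, all reference sequences —
an inversion or translocation junction *requires* joining such pairs) are
presorted by forward-query start and the same edge-free DAG relaxation
selects the subset maximising

    score(a1) + sum_i [ gain(a_{i-1}, a_i)  -  BP * GDP(a_{i-1}, a_i) ]

* `gain` is the appended alignment's score minus credit for any query
  overlap, prorated at the per-base rate of the weaker alignment — an
  approximation of re-scoring the overlap that costs O(1); containment is
  disallowed.
* `GDP = min(max_gdp, log10(max(1, refGap)))` with refGap the distance
  between nearest reference endpoints (0 when touching/overlapping);
  different reference sequences always incur `max_gdp`.  Defaults BP=5,
  max_gdp=5.

High `max_gdp` favours collections of alignments near each other on one
chromosome (deletions, tandem duplications, inversions); high BP favours
fewer, larger alignments.  The winners are the primary alignments.  OQC can
be bypassed (`report-all`), in which case every completed alignment is
emitted and only the single best-scoring one is flagged primary.

### 6. Filter By Similarity (FBS)

Non-primary alignments with reciprocal query-interval overlap ≥ 0.9 with a
primary and score ≥ 0.9 of that primary's are reported as secondary
alignments (tagged to their best-matching primary); the rest are discarded.
The thresholds are exposed on the CLI; the defaults are this package's
choice.  Secondaries are what make repeat-element insertions recoverable:
when several near-identical donor loci tie, the primary may sit on the wrong
copy while a secondary covers the true donor.

### SAM output

Plain-text SAM: `@HD`/`@SQ`/`@PG` header from the index; FLAG 16 for minus
strand (SEQ reverse-complemented), 256 for every non-primary record, 4 for
unmapped queries; POS 1-based; soft clips cover unaligned query ends;
`AS:i` carries the exact score.  MAPQ is 255 (unavailable) deliberately: no
mapping-quality model is defined, and score-based benchmarking is used
instead.  Secondary records carry full SEQ so downstream clustering tools
can consume them.

## Simulation components

* **Reference**: i.i.d. uniform (optionally GC-biased) sequences from a
  seed.  Optionally a family of highly similar ~300 bp elements (an Alu-like
  short interspersed repeat) is planted: one random consensus, each copy
  independently diverged at a configurable substitution rate (default 0.5–1%,
  matching near-active-element divergence), at non-overlapping loci.
* **Simple SVs**: equal numbers of deletions, tandem duplications,
  inversions, and insertions from a distant locus (≥100 kb away or another
  sequence; for repeat insertions the donor is a planted family locus).
  Event lengths are log-uniform on [100, 10 000] — the range is prescribed,
  the law is this package's choice to cover both scales evenly.  Each event
  yields one contig with 500 bp flanks spanning the event if it fits within
  the flank, else a left-breakpoint-only contig; every novel junction is
  recorded with both reference sides (name, boundary position, strand).
* **Chromothripsis contigs**: a ~30 kb region (or two regions) is cut into
  fragments with exponential lengths (mean 300, floor 50 — the stated mean
  and minimum, with the law being our choice), 30% deleted, 10% duplicated,
  50% inverted, shuffled, and ligated; junctions between
  non-reference-adjacent neighbours are truth.
* **Reads**: uniform over both strands to a target coverage (5x, 500-mers by
  default), each base errored independently (default 2%); an error is a 1 bp
  indel with probability `indel_frac` (default 0.1, the assembled-contig
  convention) else a random substitution.  No quality-dependent or
  homopolymer structure is modelled.
* **Verification**: a query verifies a junction when two of its reported
  alignments are adjacent on the query (within 20 bp of abutting) and their
  facing reference boundaries match the junction's two sides within 5 bases
  (inclusive), strands matching, in either read orientation.  Both
  per-query and per-junction rates are reported.

## What the tests show — and what they do not

The oracle checks (heap merge vs concatenate-and-sort; chain DP vs
exhaustive enumeration; banded DP vs unbanded DP; OQC vs ordered-subset
brute force; CIGAR-vs-score identity) are exact and demonstrate algorithmic
correctness of each stage in isolation.

The simulation analogs run the whole tool at desk scale: a 1 Mb i.i.d.
genome has essentially no repeat structure beyond what is planted, so
breakpoint-verification rates here are *upper bounds* on what the same
settings achieve on a mammalian genome, and the accuracy analog measures
heuristic loss (banding, X-dropoff, maxHits) rather than mapping ambiguity.
Problem sizes (1000 accuracy reads, 100 SV events, 20 repeat insertions, 4
shattered contigs) were chosen as the package's own desk-scale defaults;
they complete in about a minute on one CPU.

## Known limitations

* No mapping quality; no paired-end fields; SAM only (no BAM/CRAM).
* O(n²) chaining and OQC are intentional (matching the edge-free DAG
  design); queries with tens of thousands of fragments in one region will
  be slow.
* The overlap credit in OQC prorates rather than re-scores the overlap
  region; with strongly non-uniform per-base score distributions the
  selected set can differ from the re-scoring ideal.
* Genomes beyond ~tens of Mb are untested territory for the pure-Python
  index (memory ~9 bytes/base plus ROA).
* The simulators draw i.i.d. backgrounds; microhomology at junctions,
  realistic repeat landscapes, and platform error structure are out of
  scope.
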