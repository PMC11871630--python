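# Methods

## Model

panmem answers k-mer membership and conservation queries over a
pangenome G = [G₁, …, G_t] by indexing match lengths between a pivot
genome (G₁) and each of the others, rather than k-mers themselves.

**Matching statistics.** For pivot contig P[1..m] and target text T,
MS[j] is the length of the longest suffix of P[1..j] occurring in T.
The target text is the concatenation of every target contig *and its
reverse complement*, each followed by a unique sentinel drawn from the
Unicode private-use area, so a match can never span a contig or strand
boundary. MS is computed exactly by building a suffix automaton over
the target text and streaming the pivot through it with per-character
extension — linear in pivot plus target length — and is validated in
the test suite against the naive O(m²·n) definition. MS vectors are
1-based internally; the fixed conversion rule (peak at 1-based j with
length ℓ ⇒ 0-based half-open [j−ℓ, j)) is applied everywhere.

**MEMs and overlaps.** MS values obey the sawtooth property
(MS[j] − MS[j−1] ≤ 1); MEMs map one-to-one to sawtooth peaks
(MS[j] ≥ MS[j+1], or j = m). A k-mer is present in a target iff it is
contained in a MEM, so only MEM geometry — independent of k — needs to
be stored. The index keeps just the overlaps of consecutive MEMs:
[a,b), [c,d) yield [c,b) when c < b, and the point [c,c) when the MEMs
adjoin (c = b). A k-mer [x, x+k) is absent iff it spans an overlap with
overhang on both sides (x < start and x+k > end).

**Gap records.** Pivot positions with MS = 0 are covered by no MEM;
the spanning test alone cannot express them (nothing to span). Each
maximal zero run is stored as an explicit gap interval, and any k-mer
*intersecting* a gap is absent. Real genomes over {A,C,G,T} rarely
produce zero columns (a single shared base gives MS ≥ 1), but pivots
containing N runs or novel characters do, and the gap convention keeps
query answers exactly equal to the brute-force oracle in those cases
too. Consecutive MEMs separated by a zero run (next start > previous
end) contribute no pair record; the zero-run gap covers that span.

**Order transform.** Stacking the per-genome MS vectors and sorting
each column in descending order gives the order matrix O[1..t−1][1..m];
row i is the i-th largest match length per position and is again a
sawtooth, so the same MEM/overlap extraction applies row-wise. A k-mer
contained in an order-i MEM (equivalently O[i][x+k] ≥ k) occurs in ≥ i
non-pivot genomes, and containment at order i+1 implies containment at
order i. Genome identity is discarded by the sort; the original
per-genome landscape is not reconstructible from the order rows, but is
superfluous for counting. Ties within a column need no tie-breaking:
only the multiset of values matters.

## Queries

Records intersecting the query region are fetched once (predicate:
start < region.end and end > region.start, which also selects exactly
the point records strictly inside the region — the only points any
k-mer of the region can span). Each genome or order is then evaluated
with a difference-array sweep: a non-gap record [s,e) marks k-mer
starts [e−k+1, s−1] absent, a gap record marks [s−k+1, e−1] absent.
Total work is O(t · region length), independent of k; k-mers are
enumerated at starts x ∈ [region.start, region.end − k], i.e. only
k-mers fully inside the region.

Conservation = 1 (the pivot always contains its own k-mers) + the
deepest order certifying containment. Orders are scanned deepest-first;
positions certified at a deep order are skipped at shallower ones, and
the scan stops once every position is resolved (early stopping, sound
by the nesting property). Users comparing against k-mer counters that
exclude the reference should subtract 1.

## Lossy and lossless reductions

**Quantile sampling.** Thresholds are conservation counts *including
the pivot*: ⌊q·t⌋ for each quantile q (deciles by default),
deduplicated, ascending; threshold c maps to order row c−1, and
threshold 1 — the pivot itself — needs no stored row. This bookkeeping
reproduces the decile sequence 8, 17, 26, …, 89 for t = 89 while
keeping the (t−1)-row matrix well-defined. Retained records are
relabeled with the minimum count they certify (the threshold itself),
and a quantile query reports the largest certified threshold, or 1 if
none — exactly the exact count floored onto the retained set. An
alternative labeling that annotates a retained row with the *previous*
threshold boundary was considered and rejected: labeling by the
certified minimum makes the query's floor semantics self-evident and
testable against the exact query.

**Length filtering.** A k-mer can only span-with-overhang an overlap of
length ≤ k−2, so dropping non-gap records longer than l preserves every
answer for k ≤ l+2 (l = 29 ⇒ k ≤ 31). Gap records are always retained
(the intersection test has no such bound). A filtered index stores l in
its metadata and refuses larger k with an error naming the bound.

## Storage

Records sorted by (contig, start, end, label) are written to a Parquet
file with ZSTD-compressed columns: contig (dictionary), start/end
(int64), label (int32), is_gap (bool); sortedness makes the start/end
columns non-decreasing within blocks, which is what columnar
compression exploits. All labels are interleaved in one file. Rows are
chunked into row groups of ≈ chunk_bytes (default 0.5 GB; tests use
kilobytes so multiple row groups are exercised). Index metadata —
pivot, genome names, t, mode, filter l, thresholds, format version —
lives in the Parquet footer under `panmem.*` keys, so an index file is
self-describing. Writes go to a temporary path renamed into place on
success. Rebuilds from identical inputs are byte-identical; permuting
the non-pivot input order changes only genome-id labels in membership
mode and nothing in conservation or quantile mode (the column sort
erases input order).

## Synthetic pangenomes and oracles

The generator produces a uniform-random pivot (1–3 contigs) and t−1
independent mutated copies: per-base substitutions to a uniformly
chosen different base, geometric(0.5)-length indels capped at 50 bp,
and optional non-overlapping 100–1000 bp segments replaced by their
reverse complement. One integer seed drives a single `numpy` Generator;
identical configs give byte-identical FASTA output. Defaults (t = 5,
10 kb pivot, 1% substitutions, 0.1% indel rates, one inversion) give
divergence in the range typical of intraspecies pangenomes while
creating MEM breakpoints, strand effects and occasional MS-zero runs.

What the generator does *not* emulate: recombination, coalescent
structure, large duplications, repeat families, or realistic chromosome
counts. Passing tests therefore demonstrate the exactness of the
index/query machinery on sequences with point and structural
divergence on either strand — not performance or biology at
chromosome scale.

Ground truth never comes from the generator's bookkeeping: the oracles
re-derive presence by exhaustive substring search of each k-mer against
every target contig and its reverse complement, and conservation as
1 + the sum of per-genome presence. All query tests compare against
these oracles position-by-position for k ∈ {4, 11, 21, 31, 64, 101}.

## Numerical and design choices

* Coordinates are 0-based half-open throughout (BED convention).
* N is a literal character: it matches only N on the same strand
  orientation (N complements to N), never acting as a wildcard; the
  oracles use the same rule, so equivalence is well-defined. Input
  characters outside {A,C,G,T,N} are an error by default, with an
  opt-in coercion to N.
* MS is presented left-to-right (longest suffix of each prefix); tools
  that compute MS right-to-left produce a mirrored but equivalent
  landscape.
* Plateaus in MS (equal neighbors) are peaks wherever MS[j] ≥ MS[j+1];
  no extra tie-breaking exists or is needed.
* Degenerate inputs: empty pivot/target contigs are rejected; a region
  shorter than k is an error; a single MEM with no zero columns yields
  an empty record list (every k-mer present).
* Histogram binning maps a count c to proportion c/t and assigns bin
  ⌈c/t · bins⌉ − 1 of `bins` equal-width bins over (0,1], aggregated in
  fixed-size windows whose proportions each sum to 1.

## Problem sizes

The bundled test panel uses twenty pangenomes with t ∈ {2, 3, 5, 10},
5–8 kb pivots over 1–3 contigs, substitution rates 0.5–5%, indels on
and 1–2 inversions; the acceptance script uses an eight-pangenome panel
of the same conditions. These sizes exercise every code path (multiple
row groups, multi-contig pivots, deep order matrices) while keeping
the exhaustive brute-force oracles — the expensive part — tractable.

## Limitations

* Queries are limited to k-mers occurring in the pivot; k-mers private
  to other genomes are invisible. One pivot per index.
* Conservation counts genome presence/absence, not copy number.
* The suffix automaton is held in memory per pairwise comparison; the
  implementation targets method-development and moderate genome sizes,
  not terabase pangenomes.
* Pairwise MS computations are independent and may be parallelized by
  the caller; the final canonical sort makes output schedule-independent.
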