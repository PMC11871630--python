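# panmem

A maximal-exact-match (MEM) based pangenome index for **arbitrary-length
k-mer membership and conservation queries** over the coordinates of a
designated "pivot" genome.

## The problem

Given a pangenome of *t* genomes, two questions come up constantly in
comparative genomics: *which* genomes contain the k-mer starting at each
position of a region of interest (membership), and *how many* genomes
contain it (conservation). k-mer tables and de Bruijn graph indexes
answer these only for the single k chosen at indexing time, and they
grow with the k-mer universe. panmem instead indexes *match lengths*:
one compact index answers the same questions for **every k at once**,
for any k-mer drawn from the pivot.

## The method

For pivot contig P[1..m] and target genome T (both strands,
separator-delimited), the matching-statistics vector is

    MS[j] = length of the longest suffix of P[1..j] occurring in T

Consecutive values rise by at most 1 (the *sawtooth* property), and MEMs
correspond one-to-one to sawtooth peaks (positions j with
MS[j] ≥ MS[j+1], or j = m): each peak of length ℓ is the MEM interval
[j−ℓ, j). A k-mer [x, x+k) is present in T **iff it is contained in a
MEM**, equivalently iff MS[x+k] ≥ k — true for every k simultaneously.

panmem stores only the *overlaps* of consecutive MEMs (from MEMs
[i, i+ℓ), [j, j+ℓ′) the overlap [j, i+ℓ); adjoining MEMs become a point
with start = end). A k-mer is absent exactly when it strictly spans an
overlap with one base of overhang on each side. Pivot positions covered
by no MEM at all (MS = 0) are kept as explicit *gap* intervals; any
k-mer touching a gap is absent.

For conservation, the per-genome MS matrix is sorted column-wise in
descending order into the **order-MS matrix** O: row i gives the i-th
largest match length at each pivot position, still a sawtooth. A k-mer
contained in an order-i MEM occurs in ≥ i non-pivot genomes, and orders
nest, so the conservation count is 1 (the pivot) + the deepest certified
order — found by scanning orders deepest-first with early stopping.

Two lossy/lossless reductions:

* **Quantile sampling** keeps only order rows at conservation-count
  thresholds ⌊q·t⌋ (deciles by default); queries then floor the exact
  count onto the retained thresholds. For t = 89 the decile thresholds
  are 8, 17, 26, …, 89.
* **Interval-length filtering** at l drops overlaps longer than l; a
  k-mer can only span an overlap of length ≤ k−2, so every query with
  k ≤ l+2 is answered identically (l = 29 supports k ≤ 31).

Records (contig, start, end, label, is_gap) are sorted and written as a
ZSTD-compressed Parquet file; region queries use predicate pushdown and
run in O(t · region length) independent of k.

## Worked example

```sh
# a 5-genome synthetic pangenome: 3 kb pivot, 2% substitutions, indels,
# one reverse-complemented segment per copy
panmem simulate --seed 7 --t 5 --pivot-length 3000 --sub-rate 0.02 --out data/

# conservation index anchored to the pivot
panmem build --pivot data/pivot.fa \
    --genomes data/sample2.fa data/sample3.fa data/sample4.fa data/sample5.fa \
    --mode conservation --out cons.parquet

# 31-mer conservation across positions 0-2000 of chr1
panmem query-conservation --index cons.parquet --region chr1:0-2000 --k 31 \
    | head -4
```

prints (stderr log lines omitted):

```
position	conservation
0	2
1	2
2	2
```

i.e. the 31-mer starting at pivot position 0 occurs in 2 of the 5
genomes (the pivot plus one mutated copy). At a 2% per-base
substitution rate most 31-mers are disrupted in at least one copy:
over this region the counts break down as 101 positions at 1 (pivot
only), 548 at 2, 767 at 3, 476 at 4 and 78 at 5 (conserved in all
genomes). The same index answers `--k 11` or `--k 101` without
rebuilding. `query-membership` (on a `--mode membership` index) prints
one 0/1 presence column per genome, `export-bed` dumps the interval
table as BED text, and `plot` draws a stacked conservation-proportion
histogram over the region.

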