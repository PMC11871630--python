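"""Membership, conservation and quantile queries over an index file.

All queries share one access pattern: fetch the records intersecting
the query region once (Parquet predicate pushdown), then sweep them
per genome or per order with a difference-array accumulation, giving
O(t * region length) work regardless of k.  A k-mer starting at pivot
position x is *absent* from a genome/order exactly when it strictly
spans a non-gap overlap record [s, e) with overhang on both sides
(x < s and x + k > e), or intersects a gap record at all.

Conservation exploits order nesting: containment in an order-(i+1) MEM
implies containment in an order-i MEM, so orders are evaluated from the
deepest retained row downward and each position stops at the first
order that certifies containment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from panmem.interval_store import read_metadata, read_region
from panmem.matching_statistics import MemInterval, OverlapRecord
from panmem.pangenome_io import QueryRegion


class QueryError(ValueError):
    """Invalid query parameters for the given index."""


@dataclass(frozen=True)
class MembershipResult:
    """Per-genome k-mer presence vectors over a pivot region.

    ``vectors[genome_id]`` is a boolean array indexed by k-mer start
    offset relative to ``region.start``; the pivot row (id 1) is
    identically true.
    """

    region: QueryRegion
    k: int
    vectors: Dict[int, np.ndarray]

    @property
    def n_kmers(self) -> int:
        return len(self.region) - self.k + 1


def _n_kmers(region: QueryRegion, k: int) -> int:
    n = len(region) - k + 1
    if k < 1:
        raise QueryError("k must be >= 1")
    if n < 1:
        raise QueryError(
            f"region length {len(region)} is shorter than k={k}"
        )
    return n


def _check_k_bound(meta, k: int) -> None:
    if meta.max_k is not None and k > meta.max_k:
        raise QueryError(
            f"index was length-filtered at l={meta.filter_l}; the maximum "
            f"supported k is {meta.max_k} (got k={k})"
        )


def absent_mask(
    records: Sequence[OverlapRecord], region: QueryRegion, k: int
) -> np.ndarray:
    """Absence mask over k-mer starts for one genome/order's records.

    Non-gap [s, e): absent for starts x with e - k + 1 <= x <= s - 1.
    Gap [s, e): absent for starts x with s - k + 1 <= x <= e - 1.
    """
    n = _n_kmers(region, k)
    diff = np.zeros(n + 1, dtype=np.int32)
    x_min, x_max = region.start, region.end - k
    for r in records:
        if r.is_gap:
            lo, hi = r.start - k + 1, r.end - 1
        else:
            lo, hi = r.end - k + 1, r.start - 1
        lo = max(lo, x_min)
        hi = min(hi, x_max)
        if lo <= hi:
            diff[lo - x_min] += 1
            diff[hi - x_min + 1] -= 1
    return np.cumsum(diff[:-1]) > 0


def _records_by_label(records: Sequence[OverlapRecord]) -> Dict[int, List[OverlapRecord]]:
    grouped: Dict[int, List[OverlapRecord]] = {}
    for r in records:
        grouped.setdefault(r.label, []).append(r)
    return grouped


def membership_query(index_path, region: QueryRegion, k: int) -> MembershipResult:
    """Per-genome presence/absence of every k-mer of a pivot region."""
    meta = read_metadata(index_path)
    if meta.mode != "membership":
        raise QueryError(f"membership query requires a membership index, got {meta.mode!r}")
    _check_k_bound(meta, k)
    n = _n_kmers(region, k)
    grouped = _records_by_label(read_region(index_path, region))
    vectors: Dict[int, np.ndarray] = {1: np.ones(n, dtype=bool)}
    for genome_id in range(2, meta.t + 1):
        vectors[genome_id] = ~absent_mask(grouped.get(genome_id, []), region, k)
    return MembershipResult(region, k, vectors)


def conservation_query(
    index_path, region: QueryRegion, k: int, early_stop: bool = True
) -> np.ndarray:
    """Count, per k-mer start, the genomes (pivot included) containing it.

    Evaluates orders from the deepest downward; with ``early_stop`` the
    sweep skips positions already certified at a deeper order, which by
    order nesting cannot change the answer.
    """
    meta = read_metadata(index_path)
    if meta.mode != "conservation":
        raise QueryError(
            f"conservation query requires a conservation index, got {meta.mode!r}"
        )
    _check_k_bound(meta, k)
    orders = list(range(meta.t - 1, 0, -1))
    values = _layered_query(index_path, region, k, orders, early_stop)
    # conservation = 1 (pivot) + deepest certified order
    return values + 1


def quantile_conservation_query(
    index_path, region: QueryRegion, k: int, early_stop: bool = True
) -> np.ndarray:
    """Conservation floored to the retained quantile thresholds.

    Each position reports the largest threshold whose order row
    certifies containment; positions certified by no retained row
    report 1 (the pivot itself).
    """
    meta = read_metadata(index_path)
    if meta.mode != "quantile":
        raise QueryError(f"quantile query requires a quantile index, got {meta.mode!r}")
    _check_k_bound(meta, k)
    thresholds = sorted(t for t in meta.thresholds if t >= 2)
    values = _layered_query(index_path, region, k, thresholds[::-1], early_stop)
    values[values == 0] = 1
    return values


def _layered_query(
    index_path, region: QueryRegion, k: int, labels_desc: Sequence[int],
    early_stop: bool,
) -> np.ndarray:
    """Shared sweep: for each position, the largest label (scanned in
    descending order) whose records certify k-mer containment; 0 if none."""
    n = _n_kmers(region, k)
    grouped = _records_by_label(read_region(index_path, region))
    values = np.zeros(n, dtype=np.int64)
    unresolved = np.ones(n, dtype=bool)
    for label in labels_desc:
        if early_stop and not unresolved.any():
            break
        present = ~absent_mask(grouped.get(label, []), region, k)
        newly = unresolved & present
        values[newly] = label
        unresolved &= ~present
    return values


def presence_from_mem_containment(
    mems: Sequence[MemInterval], region: QueryRegion, k: int
) -> np.ndarray:
    """Reference path: a k-mer is present iff contained in some MEM.

    Used in tests to cross-check the production overlap-spanning path;
    the two are equivalent because a k-mer not contained in any MEM must
    strictly span the overlap of two consecutive MEMs or touch a
    position covered by no MEM.
    """
    n = _n_kmers(region, k)
    x_min, x_max = region.start, region.end - k
    present = np.zeros(n, dtype=bool)
    for mm in mems:
        if mm.contig != region.contig:
            continue
        lo = max(mm.start, x_min)
        hi = min(mm.end - k, x_max)
        if lo <= hi:
            present[lo - x_min : hi - x_min + 1] = True
    return present


def bin_conservation(
    cons: np.ndarray, t: int, bin_count: int, window: Optional[int] = None
) -> np.ndarray:
    """Histogram of conservation proportions per window.

    Each conservation count c is mapped to the proportion c/t and
    assigned to one of ``bin_count`` equal-width bins over (0, 1]; the
    result has one row per window (``window`` positions each, last
    window possibly shorter; one window covering everything when None)
    and rows sum to 1.
    """
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    cons = np.asarray(cons)
    if cons.size == 0:
        raise ValueError("empty conservation vector")
    if window is None:
        window = cons.size
    if window < 1:
        raise ValueError("window must be >= 1")
    # bin index for proportion p in (0,1]: ceil(p * bin_count) - 1
    bins = np.ceil(cons / t * bin_count).astype(np.int64) - 1
    bins = np.clip(bins, 0, bin_count - 1)
    n_windows = -(-cons.size // window)
    out = np.zeros((n_windows, bin_count), dtype=np.float64)
    for w in range(n_windows):
        chunk = bins[w * window : (w + 1) * window]
        counts = np.bincount(chunk, minlength=bin_count)
        out[w] = counts / chunk.size
    return out


def result_to_tsv(result: MembershipResult) -> str:
    """Membership result as TSV: position then one 0/1 column per genome."""
    genome_ids = sorted(result.vectors)
    lines = ["position\t" + "\t".join(f"G{g}" for g in genome_ids)]
    starts = np.arange(result.region.start, result.region.end - result.k + 1)
    for i, x in enumerate(starts):
        flags = "\t".join(str(int(result.vectors[g][i])) for g in genome_ids)
        lines.append(f"{x}\t{flags}")
    return "\n".join(lines) + "\n"


def conservation_to_tsv(region: QueryRegion, k: int, cons: np.ndarray) -> str:
    """Conservation vector as TSV (position, count)."""
    starts = np.arange(region.start, region.end - k + 1)
    lines = ["position\tconservation"]
    lines.extend(f"{x}\t{c}" for x, c in zip(starts, cons))
    return "\n".join(lines) + "\n"


def conservation_to_bedgraph(region: QueryRegion, k: int, cons: np.ndarray) -> str:
    """Position-wise conservation as BedGraph, merging equal runs."""
    starts = np.arange(region.start, region.end - k + 1)
    lines = []
    run_start = 0
    for i in range(1, len(cons) + 1):
        if i == len(cons) or cons[i] != cons[run_start]:
            lines.append(
                f"{region.contig}\t{starts[run_start]}\t{starts[i - 1] + 1}\t{cons[run_start]}"
            )
            run_start = i
    return "\n".join(lines) + "\n"
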