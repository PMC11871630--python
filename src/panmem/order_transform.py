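"""Order-MS matrix, order-MEM overlaps, quantile sampling, length filter.

Sorting the per-genome MS matrix column-wise in descending order turns
rows from "MS against genome i" into "i-th largest match length at each
pivot position".  Each sorted row still obeys the sawtooth property, so
MEM extraction applies row-wise; a k-mer contained in an order-i MEM is
present in at least i non-pivot genomes.  Orders nest: containment at
order i+1 implies containment at order i, which is what allows early
stopping during conservation queries and lossy row subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor
from typing import List, Sequence

import numpy as np

from panmem.matching_statistics import (
    MatchingStatisticsVector,
    OverlapRecord,
    mems_to_overlaps,
    ms_to_mems,
)

DECILES = tuple(q / 10 for q in range(1, 11))


@dataclass(frozen=True)
class OrderMatrix:
    """Column-wise descending-sorted MS matrix O[1..t-1][1..m].

    Row i (1-based) is the i-th largest MS value per pivot column; the
    originating genome of each value is discarded.
    """

    pivot_contig: str
    rows: np.ndarray  # shape (t-1, m)

    def __post_init__(self) -> None:
        arr = np.asarray(self.rows, dtype=np.int64)
        object.__setattr__(self, "rows", arr)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("order matrix must be a non-empty 2-d array")

    @property
    def n_orders(self) -> int:
        return int(self.rows.shape[0])

    def row(self, order: int) -> MatchingStatisticsVector:
        """Order row as an MS vector (order is 1-based)."""
        return MatchingStatisticsVector(self.pivot_contig, self.rows[order - 1])

    def columns_descending(self) -> bool:
        return bool((np.diff(self.rows, axis=0) <= 0).all())


@dataclass(frozen=True)
class QuantileScheme:
    """Lossy row-subsampling scheme over conservation counts.

    Thresholds are conservation counts *including the pivot* (range
    1..t), computed as floor(q * t); threshold c maps to order row
    c - 1 (threshold 1 is the pivot itself and needs no stored row).
    """

    t: int
    quantiles: tuple = DECILES

    def __post_init__(self) -> None:
        object.__setattr__(self, "quantiles", tuple(sorted(self.quantiles)))
        if self.t < 2:
            raise ValueError("quantile scheme requires t >= 2")
        if any(not (0 < q <= 1) for q in self.quantiles):
            raise ValueError("quantiles must lie in (0, 1]")

    @property
    def thresholds(self) -> List[int]:
        return quantile_thresholds(self.t, self.quantiles)

    @property
    def retained_orders(self) -> List[int]:
        """Order rows kept in the index (threshold - 1, dropping 0)."""
        return [c - 1 for c in self.thresholds if c >= 2]


@dataclass(frozen=True)
class FilterConfig:
    """Interval-length filter: keep overlaps of length <= l.

    A k-mer can mark itself absent only by spanning an overlap with one
    base of overhang on each side, i.e. an overlap of length <= k - 2;
    dropping overlaps longer than l therefore losslessly supports all
    queries with k <= l + 2.
    """

    l: int

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("filter length must be >= 0")

    @property
    def max_k(self) -> int:
        return self.l + 2


def build_order_matrix(ms_rows: Sequence[MatchingStatisticsVector]) -> OrderMatrix:
    """Sort the MS matrix column-wise in descending order."""
    if not ms_rows:
        raise ValueError("need at least one MS row")
    contig = ms_rows[0].pivot_contig
    m = len(ms_rows[0])
    for row in ms_rows:
        if row.pivot_contig != contig or len(row) != m:
            raise ValueError("ragged or mismatched MS rows")
    stacked = np.vstack([row.lengths for row in ms_rows])
    ordered = -np.sort(-stacked, axis=0)
    return OrderMatrix(contig, ordered)


def extract_order_overlaps(om: OrderMatrix) -> List[OverlapRecord]:
    """Overlap and gap records of every order row, labeled by order."""
    if not om.columns_descending():
        raise ValueError("order matrix columns must be sorted descending")
    records: List[OverlapRecord] = []
    for order in range(1, om.n_orders + 1):
        row = om.row(order)
        mems = ms_to_mems(row, label=order)
        records.extend(mems_to_overlaps(mems, row, label=order))
    records.sort(key=lambda r: r.sort_key)
    return records


def quantile_thresholds(t: int, quantiles: Sequence[float] = DECILES) -> List[int]:
    """Conservation-count thresholds floor(q*t), deduplicated, ascending.

    A threshold of 0 after flooring is dropped with a warning.
    """
    if t < 2:
        raise ValueError("t must be >= 2")
    out = sorted({floor(q * t) for q in quantiles})
    if out and out[0] == 0:
        warnings.warn("quantile threshold floored to 0; dropped", stacklevel=2)
        out = out[1:]
    if not out:
        raise ValueError("all quantile thresholds floored to 0")
    return out


def apply_quantile_sampling(
    records: Sequence[OverlapRecord], scheme: QuantileScheme
) -> List[OverlapRecord]:
    """Keep only records of retained order rows; relabel by the
    conservation-count threshold each retained row certifies."""
    order_to_threshold = {c - 1: c for c in scheme.thresholds if c >= 2}
    out = [
        OverlapRecord(r.contig, r.start, r.end, order_to_threshold[r.label], r.is_gap)
        for r in records
        if r.label in order_to_threshold
    ]
    out.sort(key=lambda r: r.sort_key)
    return out


def apply_length_filter(
    records: Sequence[OverlapRecord], cfg: FilterConfig
) -> List[OverlapRecord]:
    """Drop non-gap overlap records longer than l; gaps are always kept."""
    return [r for r in records if r.is_gap or r.end - r.start <= cfg.l]
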