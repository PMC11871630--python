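"""Exact matching statistics, MEM extraction and overlap records.

The matching-statistics vector of a pivot contig P[1..m] against a
target text T is MS[1..m] with MS[j] = length of the longest suffix of
P[1..j] occurring anywhere in T.  The target text used here is the
concatenation of every target contig and its reverse complement, each
terminated by a unique sentinel so that matches can never cross a
contig or strand boundary.

Successive MS values obey the sawtooth property MS[j] - MS[j-1] <= 1.
MEMs correspond one-to-one to sawtooth peaks: position j is a peak when
j = m or MS[j] >= MS[j+1]; the peak of length l yields the 0-based
half-open pivot interval [j - l, j).

From consecutive MEMs we keep only their *overlaps*.  A k-mer interval
that strictly spans an overlap with overhang on both sides cannot be
contained in either flanking MEM, hence is absent from the target; a
k-mer contained in some MEM is present.  Positions with MS = 0 are
covered by no MEM at all and are kept as explicit *gap* records: any
k-mer intersecting a gap is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np

from panmem.pangenome_io import Contig, Genome, reverse_complement

# Unicode private-use area supplies an unbounded pool of sentinels that
# cannot collide with the DNA alphabet.
_SENTINEL_BASE = 0xE000


@dataclass(frozen=True)
class MatchingStatisticsVector:
    """MS lengths of one pivot contig against one target (or order row).

    ``lengths[i]`` holds MS[i+1] of the 1-based vector MS[1..m].
    """

    pivot_contig: str
    lengths: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=np.int64)
        object.__setattr__(self, "lengths", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("MS vector must be a non-empty 1-d array")
        if (arr < 0).any():
            raise ValueError("MS lengths must be non-negative")

    def __len__(self) -> int:
        return int(self.lengths.size)

    def is_sawtooth(self) -> bool:
        """Check MS[j] - MS[j-1] <= 1 and MS[j] <= j."""
        arr = self.lengths
        if (np.diff(arr) > 1).any():
            return False
        return bool((arr <= np.arange(1, arr.size + 1)).all())


@dataclass(frozen=True)
class MemInterval:
    """A maximal exact match on pivot coordinates, 0-based half-open."""

    contig: str
    start: int
    end: int
    label: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid MEM interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class OverlapRecord:
    """Overlap between consecutive MEMs, or a gap uncovered by any MEM.

    Non-gap records may have ``start == end``: adjoining MEMs, where one
    MEM ends exactly where the next begins, are stored as a point.
    """

    contig: str
    start: int
    end: int
    label: int
    is_gap: bool = False

    def __post_init__(self) -> None:
        if self.is_gap:
            if not (0 <= self.start < self.end):
                raise ValueError("gap records require start < end")
        else:
            if not (0 <= self.start <= self.end):
                raise ValueError("overlap records require start <= end")

    @property
    def sort_key(self):
        return (self.contig, self.start, self.end, self.label, self.is_gap)


class _SuffixAutomaton:
    """Suffix automaton over an arbitrary text; built in O(n log sigma).

    Recognizes exactly the substrings of the text, enabling streaming
    computation of matching statistics by per-character extension.
    """

    __slots__ = ("link", "length", "next")

    def __init__(self, text: str):
        self.link = [-1]
        self.length = [0]
        self.next = [{}]
        last = 0
        for ch in text:
            last = self._extend(last, ch)

    def _extend(self, last: int, ch: str) -> int:
        link, length, nxt = self.link, self.length, self.next
        cur = len(length)
        length.append(length[last] + 1)
        link.append(-1)
        nxt.append({})
        p = last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(length)
                length.append(length[p] + 1)
                link.append(link[q])
                nxt.append(dict(nxt[q]))
                while p != -1 and nxt[p].get(ch) == q:
                    nxt[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        return cur

    def matching_statistics(self, pattern: str) -> np.ndarray:
        """MS[j] = longest suffix of pattern[:j] that is a substring."""
        link, length, nxt = self.link, self.length, self.next
        ms = np.zeros(len(pattern), dtype=np.int64)
        state, cur_len = 0, 0
        for j, ch in enumerate(pattern):
            while state != 0 and ch not in nxt[state]:
                state = link[state]
                cur_len = length[state]
            if ch in nxt[state]:
                state = nxt[state][ch]
                cur_len += 1
            else:
                state, cur_len = 0, 0
            ms[j] = cur_len
        return ms


def target_text(target: Genome) -> str:
    """Concatenate every contig and its reverse complement with unique
    sentinels, so matches never span contigs or strands."""
    pieces = []
    counter = 0
    for contig in target.contigs:
        pieces.append(contig.sequence)
        pieces.append(chr(_SENTINEL_BASE + counter))
        counter += 1
        pieces.append(reverse_complement(contig.sequence))
        pieces.append(chr(_SENTINEL_BASE + counter))
        counter += 1
    return "".join(pieces)


def compute_matching_statistics(
    pivot_contig: Contig, target: Genome
) -> MatchingStatisticsVector:
    """Exact MS of a pivot contig against a whole target genome.

    Builds a suffix automaton over the separator-delimited target text
    (both strands) and streams the pivot through it; exact, with no
    heuristics, in time linear in pivot plus target length.
    """
    if len(pivot_contig.sequence) == 0:
        raise ValueError("empty pivot contig")
    if not target.contigs:
        raise ValueError("empty target genome")
    automaton = _SuffixAutomaton(target_text(target))
    ms = automaton.matching_statistics(pivot_contig.sequence)
    return MatchingStatisticsVector(pivot_contig.name, ms)


def brute_force_matching_statistics(pattern: str, text: str) -> np.ndarray:
    """Naive O(m^2 * n) reference: for each j scan suffix lengths downward.

    Independent of the suffix-automaton path; used as the test oracle.
    """
    m = len(pattern)
    ms = np.zeros(m, dtype=np.int64)
    for j in range(1, m + 1):
        for ell in range(j, 0, -1):
            if pattern[j - ell : j] in text:
                ms[j - 1] = ell
                break
    return ms


def ms_to_mems(ms: MatchingStatisticsVector, label: int = 0) -> List[MemInterval]:
    """Extract MEMs as sawtooth peaks of the MS vector.

    Position j (1-based) is a peak when j = m or MS[j] >= MS[j+1]; each
    peak of positive length l yields [j - l, j).  Zero-length peaks are
    excluded; the positions they cover become gap records instead.
    """
    arr = ms.lengths
    if not ms.is_sawtooth():
        raise ValueError("MS vector violates the sawtooth property")
    m = arr.size
    # peak mask: MS[j] >= MS[j+1] for j < m, always at j = m
    peak = np.empty(m, dtype=bool)
    peak[:-1] = arr[:-1] >= arr[1:]
    peak[-1] = True
    peak &= arr >= 1
    out = []
    for j0 in np.flatnonzero(peak):
        j = int(j0) + 1  # 1-based peak position
        ell = int(arr[j0])
        out.append(MemInterval(ms.pivot_contig, j - ell, j, label))
    return out


def _zero_runs(arr: np.ndarray) -> List[tuple]:
    """Maximal runs of zeros as 0-based half-open intervals."""
    zero = arr == 0
    if not zero.any():
        return []
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def mems_to_overlaps(
    mems: Sequence[MemInterval], ms: MatchingStatisticsVector, label: int = 0
) -> List[OverlapRecord]:
    """Derive overlap and gap records from a sorted MEM list.

    Consecutive MEMs [a,b), [c,d) yield the overlap [c,b) when c < b and
    the point record [c,c) when c == b.  Maximal runs of MS-zero columns
    yield gap records (these also account for consecutive MEMs separated
    by a zero run, where c > b).
    """
    starts = [mm.start for mm in mems]
    if starts != sorted(starts):
        raise ValueError("MEMs must be sorted by start")
    contig = ms.pivot_contig
    out: List[OverlapRecord] = []
    for prev, nxt in zip(mems, mems[1:]):
        if nxt.start < prev.end:
            out.append(OverlapRecord(contig, nxt.start, prev.end, label))
        elif nxt.start == prev.end:
            out.append(OverlapRecord(contig, nxt.start, nxt.start, label))
        # nxt.start > prev.end happens only across an MS-zero run,
        # already covered by the gap records below
    for s, e in _zero_runs(ms.lengths):
        out.append(OverlapRecord(contig, s, e, label, is_gap=True))
    out.sort(key=lambda r: r.sort_key)
    return out


def reconstruct_ms(
    mems: Sequence[MemInterval], length: int, contig: str
) -> MatchingStatisticsVector:
    """Rebuild MS from MEM intervals: MS[j] = max over MEMs [s,e) with
    s < j <= e of (j - s), else 0.  Inverse of ``ms_to_mems`` by the
    one-to-one peak mapping."""
    arr = np.zeros(length, dtype=np.int64)
    for mm in mems:
        j = np.arange(mm.start + 1, mm.end + 1)  # 1-based positions covered
        np.maximum.at(arr, j - 1, j - mm.start)
    return MatchingStatisticsVector(contig, arr)
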