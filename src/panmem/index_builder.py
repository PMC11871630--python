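"""End-to-end index construction: FASTA inputs -> written index file.

Building factors into (t-1) independent pivot-vs-genome matching
statistics computations, one per non-pivot genome, each against the
whole target genome text (both strands).  Record emission is
canonicalized by a final sort, so the output is identical regardless of
the order the pairwise comparisons complete in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

from panmem.interval_store import (
    DEFAULT_CHUNK_BYTES,
    IndexMetadata,
    write_index,
)
from panmem.matching_statistics import (
    MatchingStatisticsVector,
    OverlapRecord,
    compute_matching_statistics,
    mems_to_overlaps,
    ms_to_mems,
)
from panmem.order_transform import (
    DECILES,
    FilterConfig,
    QuantileScheme,
    apply_length_filter,
    apply_quantile_sampling,
    build_order_matrix,
    extract_order_overlaps,
)
from panmem.pangenome_io import Genome, read_fasta


@dataclass(frozen=True)
class BuildConfig:
    """Configuration for one index build.

    ``mode`` selects the annotation: per-genome ids for membership,
    order rows for conservation, retained thresholds for quantile.
    """

    pivot_path: str
    genome_paths: tuple
    out_path: str
    mode: str = "membership"
    quantiles: tuple = DECILES
    filter_l: Optional[int] = None
    chunk_bytes: int = DEFAULT_CHUNK_BYTES
    ambiguous: str = "error"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genome_paths", tuple(self.genome_paths))
        object.__setattr__(self, "quantiles", tuple(self.quantiles))
        if not self.genome_paths:
            raise ValueError("need at least one non-pivot genome")
        if self.mode not in ("membership", "conservation", "quantile"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _load_genomes(cfg: BuildConfig) -> List[Genome]:
    pivot = read_fasta(cfg.pivot_path, genome_id=1, ambiguous=cfg.ambiguous)
    genomes = [pivot]
    for i, path in enumerate(cfg.genome_paths, start=2):
        genomes.append(read_fasta(path, genome_id=i, ambiguous=cfg.ambiguous))
    names = [g.name for g in genomes]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate genome names: {names}")
    return genomes


def membership_records(pivot: Genome, others: Sequence[Genome]) -> List[OverlapRecord]:
    """Overlap/gap records for every (pivot contig, non-pivot genome) pair,
    labeled by genome id."""
    records: List[OverlapRecord] = []
    for contig in pivot.contigs:
        for target in others:
            ms = compute_matching_statistics(contig, target)
            mems = ms_to_mems(ms, label=target.genome_id)
            records.extend(mems_to_overlaps(mems, ms, label=target.genome_id))
    records.sort(key=lambda r: r.sort_key)
    return records


def conservation_records(pivot: Genome, others: Sequence[Genome]) -> List[OverlapRecord]:
    """Order-overlap records per pivot contig, labeled by order."""
    records: List[OverlapRecord] = []
    for contig in pivot.contigs:
        rows = [compute_matching_statistics(contig, target) for target in others]
        om = build_order_matrix(rows)
        records.extend(extract_order_overlaps(om))
    records.sort(key=lambda r: r.sort_key)
    return records


def build_records(
    genomes: Sequence[Genome],
    mode: str,
    quantiles: Sequence[float] = DECILES,
    filter_l: Optional[int] = None,
):
    """In-memory build from already-loaded genomes.

    Returns (records, metadata); ``build_index`` wraps this with FASTA
    loading and the file write.
    """
    pivot, others = genomes[0], list(genomes[1:])
    if not others:
        raise ValueError("need at least one non-pivot genome")
    t = len(genomes)
    thresholds = None
    if mode == "membership":
        records = membership_records(pivot, others)
    else:
        records = conservation_records(pivot, others)
        if mode == "quantile":
            scheme = QuantileScheme(t, tuple(quantiles))
            thresholds = tuple(scheme.thresholds)
            records = apply_quantile_sampling(records, scheme)
    if filter_l is not None:
        records = apply_length_filter(records, FilterConfig(filter_l))
    meta = IndexMetadata(
        pivot=pivot.name,
        genomes=tuple(g.name for g in genomes),
        t=t,
        mode=mode,
        filter_l=filter_l,
        thresholds=thresholds,
    )
    return records, meta


def build_index(cfg: BuildConfig) -> IndexMetadata:
    """Build and write an index per the config; returns its metadata."""
    genomes = _load_genomes(cfg)
    records, meta = build_records(
        genomes, cfg.mode, cfg.quantiles, cfg.filter_l
    )
    write_index(records, meta, cfg.out_path, chunk_bytes=cfg.chunk_bytes)
    return meta
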