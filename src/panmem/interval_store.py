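"""Columnar-compressed persistence of overlap records (the index file).

Records are stored in a Parquet file, one row per overlap/gap record,
with ZSTD-compressed columns.  Consecutive rows of a sorted record set
share contig names and have non-decreasing start coordinates, which is
exactly the redundancy a column-major layout compresses well.  All
genomes (or orders) are interleaved into a single file, which
compresses better than one file per label.  Index-level metadata lives
in the Parquet footer as key-value pairs, so the file is self-describing
and readable by standard columnar tooling.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pyarrow as pa
import pyarrow.parquet as pq

from panmem.matching_statistics import OverlapRecord
from panmem.pangenome_io import QueryRegion

FORMAT_VERSION = "1"
DEFAULT_CHUNK_BYTES = 512 * 1024 * 1024
# rough uncompressed in-memory footprint of one record row, used to turn
# a chunk-byte budget into a Parquet row-group size
_BYTES_PER_ROW = 24

_META_PREFIX = "panmem."

MODES = ("membership", "conservation", "quantile")

_SCHEMA = pa.schema(
    [
        pa.field("contig", pa.dictionary(pa.int32(), pa.string())),
        pa.field("start", pa.int64()),
        pa.field("end", pa.int64()),
        pa.field("label", pa.int32()),
        pa.field("is_gap", pa.bool_()),
    ]
)


@dataclass(frozen=True)
class IndexMetadata:
    """Self-description of an index file."""

    pivot: str
    genomes: tuple  # names, pivot first
    t: int
    mode: str
    filter_l: Optional[int] = None
    thresholds: Optional[tuple] = None
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.t < 2:
            raise ValueError("t must be >= 2")
        if self.mode == "quantile" and not self.thresholds:
            raise ValueError("quantile mode requires thresholds")
        object.__setattr__(self, "genomes", tuple(self.genomes))
        if self.thresholds is not None:
            object.__setattr__(self, "thresholds", tuple(self.thresholds))

    @property
    def max_k(self) -> Optional[int]:
        return None if self.filter_l is None else self.filter_l + 2

    def to_kv(self) -> dict:
        kv = {
            _META_PREFIX + "version": self.version,
            _META_PREFIX + "mode": self.mode,
            _META_PREFIX + "pivot": self.pivot,
            _META_PREFIX + "genomes": json.dumps(list(self.genomes)),
            _META_PREFIX + "t": str(self.t),
            _META_PREFIX + "filter_l": json.dumps(self.filter_l),
            _META_PREFIX + "thresholds": json.dumps(
                list(self.thresholds) if self.thresholds is not None else None
            ),
        }
        return {k.encode(): v.encode() for k, v in kv.items()}

    @classmethod
    def from_kv(cls, kv: dict) -> "IndexMetadata":
        def get(key: str) -> str:
            raw = kv.get((_META_PREFIX + key).encode())
            if raw is None:
                raise ValueError(f"index file missing metadata key {key!r}")
            return raw.decode()

        thresholds = json.loads(get("thresholds"))
        return cls(
            pivot=get("pivot"),
            genomes=tuple(json.loads(get("genomes"))),
            t=int(get("t")),
            mode=get("mode"),
            filter_l=json.loads(get("filter_l")),
            thresholds=tuple(thresholds) if thresholds is not None else None,
            version=get("version"),
        )


def _records_to_table(records: Sequence[OverlapRecord], meta: IndexMetadata) -> pa.Table:
    table = pa.table(
        {
            "contig": pa.array([r.contig for r in records]).dictionary_encode(),
            "start": pa.array([r.start for r in records], pa.int64()),
            "end": pa.array([r.end for r in records], pa.int64()),
            "label": pa.array([r.label for r in records], pa.int32()),
            "is_gap": pa.array([r.is_gap for r in records], pa.bool_()),
        }
    )
    return table.replace_schema_metadata(meta.to_kv())


def _check_sorted(records: Sequence[OverlapRecord]) -> None:
    keys = [r.sort_key for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (contig, start, end, label)")


def write_index(
    records: Sequence[OverlapRecord],
    meta: IndexMetadata,
    path,
    chunk_bytes: int = DEFAULT_CHUNK_BYTES,
) -> None:
    """Write sorted records to a ZSTD-compressed Parquet index file.

    Rows are chunked into row groups of approximately ``chunk_bytes``
    each.  The write is atomic: a temporary file is renamed into place
    on success.
    """
    _check_sorted(records)
    table = _records_to_table(records, meta)
    row_group_size = max(1, chunk_bytes // _BYTES_PER_ROW)
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    try:
        pq.write_table(
            table,
            tmp,
            compression="zstd",
            row_group_size=row_group_size,
            write_statistics=True,
        )
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def read_metadata(path) -> IndexMetadata:
    meta = pq.read_schema(Path(path)).metadata or {}
    return IndexMetadata.from_kv(meta)


def _table_to_records(table: pa.Table) -> List[OverlapRecord]:
    cols = {name: table.column(name).to_pylist() for name in
            ("contig", "start", "end", "label", "is_gap")}
    return [
        OverlapRecord(c, s, e, l, g)
        for c, s, e, l, g in zip(
            cols["contig"], cols["start"], cols["end"], cols["label"], cols["is_gap"]
        )
    ]


def read_index(path):
    """Read the whole index; returns (records, metadata)."""
    path = Path(path)
    table = pq.read_table(path)
    meta = IndexMetadata.from_kv(table.schema.metadata or {})
    return _table_to_records(table), meta


def read_region(path, region: QueryRegion) -> List[OverlapRecord]:
    """Records intersecting a pivot region, via Parquet predicate pushdown.

    The intersection predicate is ``r.contig == region.contig and
    r.start < region.end and r.end > region.start``; for point records
    (start == end) it keeps exactly those strictly inside the region,
    the only ones any k-mer of the region can span.  Row groups whose
    column statistics exclude the predicate are never decoded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pq.read_table(
        path,
        filters=[
            [
                ("contig", "=", region.contig),
                ("start", "<", region.end),
                ("end", ">", region.start),
            ]
        ],
    )
    return _table_to_records(table)


def intersect_full_scan(
    records: Sequence[OverlapRecord], region: QueryRegion
) -> List[OverlapRecord]:
    """Naive reference filter with the same intersection predicate."""
    return [
        r
        for r in records
        if r.contig == region.contig and r.start < region.end and r.end > region.start
    ]


def export_bed(path_index, path_bed) -> None:
    """Export the index as tab-delimited BED: contig, start, end, label,
    with a 5th column marking gap records."""
    records, _ = read_index(path_index)
    with open(path_bed, "wt") as fh:
        for r in records:
            row = f"{r.contig}\t{r.start}\t{r.end}\t{r.label}"
            if r.is_gap:
                row += "\tgap"
            fh.write(row + "\n")


def import_bed(path_bed) -> List[OverlapRecord]:
    """Inverse of ``export_bed`` (records only; no metadata in BED)."""
    out = []
    with open(path_bed, "rt") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"malformed BED line: {line!r}")
            out.append(
                OverlapRecord(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    int(fields[3]),
                    len(fields) >= 5 and fields[4] == "gap",
                )
            )
    return out
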