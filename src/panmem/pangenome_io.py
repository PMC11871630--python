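"""FASTA input/output, sequence normalization and pivot coordinates.

Conventions fixed here and used everywhere else in the package:

* All genomic intervals and query regions are **0-based, half-open**
  (the BED convention).
* Matching-statistics vectors are 1-based internally (``MS[1..m]``); a
  peak at 1-based position ``j`` of length ``l`` maps to the 0-based
  interval ``[j - l, j)``.
* Sequences are uppercased on input.  Characters outside ``{A,C,G,T,N}``
  are an error by default; ``ambiguous="coerce"`` maps them to ``N``.
* ``N`` is an ordinary literal character: it matches only itself, never
  acting as a wildcard.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

from Bio import SeqIO

VALID_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_REGION_RE = re.compile(r"^(?P<contig>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence over the alphabet {A,C,G,T,N}, uppercase."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.name!r}: empty sequence")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise ValueError(
                f"contig {self.name!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """An ordered collection of contigs with a small-integer id (1 = pivot)."""

    genome_id: int
    name: str
    contigs: tuple

    def __post_init__(self) -> None:
        if self.genome_id < 1:
            raise ValueError("genome_id must be >= 1")
        names = [c.name for c in self.contigs]
        if len(names) != len(set(names)):
            raise ValueError(f"genome {self.name!r}: duplicate contig names")
        object.__setattr__(self, "contigs", tuple(self.contigs))

    def contig(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(f"no contig {name!r} in genome {self.name!r}")

    @property
    def contig_names(self) -> List[str]:
        return [c.name for c in self.contigs]


@dataclass(frozen=True)
class QueryRegion:
    """A 0-based half-open interval on a pivot contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def normalize_sequence(seq: str, ambiguous: str = "error") -> str:
    """Uppercase ``seq``; handle non-ACGTN characters per ``ambiguous``.

    ``ambiguous="error"`` rejects them, ``ambiguous="coerce"`` maps them
    to ``N``.
    """
    seq = seq.upper()
    bad = set(seq) - VALID_CHARS
    if not bad:
        return seq
    if ambiguous == "coerce":
        return "".join(c if c in VALID_CHARS else "N" for c in seq)
    raise FastaError(f"invalid sequence characters {sorted(bad)!r}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - VALID_CHARS
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, genome_id: int = 1, name: str | None = None,
               ambiguous: str = "error") -> Genome:
    """Read a (possibly gzip-compressed) FASTA file into a Genome.

    One Contig per record, record order preserved, sequences uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs = []
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            seq = str(record.seq)
            if not seq:
                raise FastaError(f"{path}: record {record.id!r} has empty sequence")
            try:
                seq = normalize_sequence(seq, ambiguous=ambiguous)
            except FastaError as exc:
                raise FastaError(f"{path}: record {record.id!r}: {exc}") from exc
            contigs.append(Contig(record.id, seq))
    if not contigs:
        raise FastaError(f"{path}: no FASTA records found")
    return Genome(genome_id=genome_id, name=name or path.stem, contigs=tuple(contigs))


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    """Write a Genome as FASTA (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for contig in genome.contigs:
            fh.write(f">{contig.name}\n")
            for i in range(0, len(contig.sequence), width):
                fh.write(contig.sequence[i : i + width] + "\n")


def parse_region(text: str, pivot: Genome | None = None) -> QueryRegion:
    """Parse ``contig:start-end`` (0-based half-open) into a QueryRegion.

    If ``pivot`` is given, the contig must exist and the region must lie
    within it.
    """
    m = _REGION_RE.match(text)
    if not m:
        raise ValueError(
            f"cannot parse region {text!r}: expected contig:start-end"
        )
    region = QueryRegion(m["contig"], int(m["start"]), int(m["end"]))
    if pivot is not None:
        validate_region(region, pivot)
    return region


def validate_region(region: QueryRegion, pivot: Genome) -> None:
    try:
        contig = pivot.contig(region.contig)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    if region.end > len(contig):
        raise ValueError(
            f"region {region.contig}:{region.start}-{region.end} exceeds "
            f"contig length {len(contig)}"
        )
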