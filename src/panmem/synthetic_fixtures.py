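"""Synthetic pangenomes and brute-force oracles.

The generator produces a uniform-random pivot genome plus independently
mutated copies (substitutions, geometric-length indels, optional
reverse-complemented segments).  It emulates the features of real
pangenomes the index cares about — shared sequence broken by point and
structural differences on either strand — not population-genetic
realism; the brute-force oracles below, not the mutation model, define
ground truth for every test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import List, Sequence

import numpy as np

from panmem.pangenome_io import (
    Contig,
    Genome,
    QueryRegion,
    reverse_complement,
    write_fasta,
)

BASES = np.array(list("ACGT"))

_INDEL_CAP = 50
_INVERSION_MIN, _INVERSION_MAX = 100, 1000


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    t: int = 5
    pivot_length: int = 10_000
    contig_count: int = 1
    substitution_rate: float = 0.01
    insertion_rate: float = 0.001
    deletion_rate: float = 0.001
    inversion_count: int = 1

    def __post_init__(self) -> None:
        if self.t < 2:
            raise ValueError("t must be >= 2")
        if self.pivot_length < 100:
            raise ValueError("pivot_length must be >= 100")
        if self.contig_count < 1:
            raise ValueError("contig_count must be >= 1")
        for rate in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not (0 <= rate < 1):
                raise ValueError("rates must lie in [0, 1)")
        if self.inversion_count < 0:
            raise ValueError("inversion_count must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, cfg: SimulationConfig) -> str:
    """Apply per-base substitutions and geometric-length indels."""
    out: List[str] = []
    i = 0
    n = len(seq)
    while i < n:
        r = rng.random()
        if r < cfg.deletion_rate:
            length = min(int(rng.geometric(0.5)), _INDEL_CAP)
            i += length
            continue
        if r < cfg.deletion_rate + cfg.insertion_rate:
            length = min(int(rng.geometric(0.5)), _INDEL_CAP)
            out.append(_random_sequence(rng, length))
        base = seq[i]
        if rng.random() < cfg.substitution_rate:
            alternatives = [b for b in "ACGT" if b != base]
            out.append(alternatives[rng.integers(0, 3)])
        else:
            out.append(base)
        i += 1
    return "".join(out)


def _invert_segments(rng: np.random.Generator, seq: str, count: int) -> str:
    """Replace up to ``count`` non-overlapping random segments by their
    reverse complement."""
    n = len(seq)
    chosen: List[tuple] = []
    for _ in range(count):
        length = int(rng.integers(_INVERSION_MIN, _INVERSION_MAX + 1))
        if length >= n:
            continue
        for _attempt in range(20):
            start = int(rng.integers(0, n - length))
            if all(start + length <= s or start >= e for s, e in chosen):
                chosen.append((start, start + length))
                break
    for start, end in sorted(chosen, reverse=True):
        seq = seq[:start] + reverse_complement(seq[start:end]) + seq[end:]
    return seq


def simulate_pangenome(cfg: SimulationConfig) -> List[Genome]:
    """Pivot plus t-1 independently mutated copies; deterministic by seed."""
    rng = np.random.default_rng(cfg.seed)
    per_contig = cfg.pivot_length // cfg.contig_count
    pivot_contigs = [
        Contig(f"chr{i + 1}", _random_sequence(rng, per_contig))
        for i in range(cfg.contig_count)
    ]
    genomes = [Genome(1, "pivot", tuple(pivot_contigs))]
    for gid in range(2, cfg.t + 1):
        contigs = []
        for contig in pivot_contigs:
            seq = _mutate(rng, contig.sequence, cfg)
            if cfg.inversion_count:
                seq = _invert_segments(rng, seq, cfg.inversion_count)
            if not seq:
                seq = _random_sequence(rng, 10)
            contigs.append(Contig(contig.name, seq))
        genomes.append(Genome(gid, f"sample{gid}", tuple(contigs)))
    return genomes


def write_pangenome(genomes: Sequence[Genome], out_dir, cfg: SimulationConfig | None = None) -> List[Path]:
    """Write one FASTA per genome plus a JSON manifest; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome in genomes:
        path = out_dir / f"{genome.name}.fa"
        write_fasta(genome, path)
        paths.append(path)
    manifest = {
        "genomes": [g.name for g in genomes],
        "files": [p.name for p in paths],
        "config": asdict(cfg) if cfg is not None else None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def _target_texts(target: Genome) -> List[str]:
    return [c.sequence for c in target.contigs] + [
        reverse_complement(c.sequence) for c in target.contigs
    ]


def oracle_kmer_presence(
    pivot: Genome, target: Genome, region: QueryRegion, k: int
) -> np.ndarray:
    """Naive truth: pivot k-mer at each region offset occurs as an exact
    substring of some target contig or its reverse complement (matches
    never span contigs)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(region) < k:
        raise ValueError(f"region shorter than k={k}")
    seq = pivot.contig(region.contig).sequence
    texts = _target_texts(target)
    n = len(region) - k + 1
    out = np.zeros(n, dtype=bool)
    for x in range(n):
        kmer = seq[region.start + x : region.start + x + k]
        out[x] = any(kmer in text for text in texts)
    return out


def oracle_conservation(
    pivot: Genome, genomes: Sequence[Genome], region: QueryRegion, k: int
) -> np.ndarray:
    """1 (pivot) + number of non-pivot genomes containing each k-mer."""
    others = [g for g in genomes if g.genome_id != pivot.genome_id]
    n = len(region) - k + 1
    counts = np.ones(n, dtype=np.int64)
    for target in others:
        counts += oracle_kmer_presence(pivot, target, region, k)
    return counts
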