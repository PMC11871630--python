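"""Shared fixtures: small synthetic pangenomes and pre-built indexes."""

from types import SimpleNamespace

import pytest

from panmem.index_builder import build_records
from panmem.interval_store import write_index
from panmem.synthetic_fixtures import SimulationConfig, simulate_pangenome

# Study-condition fixture panel: 20 seeded pangenomes spanning t in
# {2,3,5,10}, 1-3 contigs, substitution rates 0.5-5%, indels on, and at
# least one reverse-complemented segment each.
SUITE_SPECS = [
    SimulationConfig(
        seed=100 + i,
        t=[2, 3, 5, 10][i % 4],
        pivot_length=[5000, 6000, 7000, 8000, 5500][i % 5],
        contig_count=[1, 2, 3][i % 3],
        substitution_rate=[0.005, 0.01, 0.02, 0.035, 0.05][i % 5],
        insertion_rate=[0.001, 0.003][i % 2],
        deletion_rate=[0.002, 0.001][i % 2],
        inversion_count=1 + i % 2,
    )
    for i in range(20)
]

QUERY_KS = (4, 11, 21, 31, 64, 101)


def build_fixture(cfg: SimulationConfig, directory) -> SimpleNamespace:
    """Simulate a pangenome and build its membership + conservation
    indexes under ``directory``."""
    directory.mkdir(parents=True, exist_ok=True)
    genomes = simulate_pangenome(cfg)
    mrecords, mmeta = build_records(genomes, "membership")
    crecords, cmeta = build_records(genomes, "conservation")
    mpath = directory / "membership.parquet"
    cpath = directory / "conservation.parquet"
    write_index(mrecords, mmeta, mpath, chunk_bytes=1 << 16)
    write_index(crecords, cmeta, cpath, chunk_bytes=1 << 16)
    return SimpleNamespace(
        cfg=cfg,
        genomes=genomes,
        pivot=genomes[0],
        dir=directory,
        membership_path=mpath,
        conservation_path=cpath,
        membership_records=mrecords,
        conservation_records=crecords,
        membership_meta=mmeta,
        conservation_meta=cmeta,
    )


@pytest.fixture(scope="session")
def suite(tmp_path_factory):
    """The full 20-pangenome panel with pre-built indexes."""
    root = tmp_path_factory.mktemp("suite")
    return [
        build_fixture(cfg, root / f"fixture_{i:02d}")
        for i, cfg in enumerate(SUITE_SPECS)
    ]


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """One modest pangenome for unit tests that just need a real index."""
    cfg = SimulationConfig(
        seed=42, t=4, pivot_length=2500, contig_count=2,
        substitution_rate=0.02, insertion_rate=0.002, deletion_rate=0.002,
        inversion_count=1,
    )
    return build_fixture(cfg, tmp_path_factory.mktemp("small"))
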