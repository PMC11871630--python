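"""Membership, conservation and quantile queries against oracles."""

import numpy as np
import pytest

from panmem.index_builder import build_records
from panmem.interval_store import IndexMetadata, write_index
from panmem.matching_statistics import (
    OverlapRecord,
    compute_matching_statistics,
    ms_to_mems,
)
from panmem.order_transform import QuantileScheme, apply_quantile_sampling
from panmem.pangenome_io import QueryRegion
from panmem.query_engine import (
    QueryError,
    bin_conservation,
    conservation_query,
    membership_query,
    presence_from_mem_containment,
    quantile_conservation_query,
)
from panmem.synthetic_fixtures import (
    SimulationConfig,
    oracle_conservation,
    oracle_kmer_presence,
    simulate_pangenome,
)


def _identical_pangenome(t=4, length=400):
    return simulate_pangenome(
        SimulationConfig(seed=1, t=t, pivot_length=length, substitution_rate=0.0,
                         insertion_rate=0.0, deletion_rate=0.0, inversion_count=0)
    )


def _write(tmp_path, records, meta, name="idx.parquet"):
    path = tmp_path / name
    write_index(records, meta, path, chunk_bytes=1 << 12)
    return path


def test_identical_genomes_all_present_any_k(tmp_path):
    genomes = _identical_pangenome()
    records, meta = build_records(genomes, "membership")
    path = _write(tmp_path, records, meta)
    region = QueryRegion("chr1", 0, 400)
    for k in (1, 13, 399):
        result = membership_query(path, region, k)
        for vec in result.vectors.values():
            assert vec.all()


def test_point_overlap_blocks_exactly_spanning_kmers(tmp_path):
    """With a single point record [c,c), absent k-mers are exactly those
    with x < c and x + k > c."""
    c, k, length = 50, 7, 100
    meta = IndexMetadata(pivot="p", genomes=("p", "s2"), t=2, mode="membership")
    path = _write(tmp_path, [OverlapRecord("chr1", c, c, 2, False)], meta)
    region = QueryRegion("chr1", 0, length)
    result = membership_query(path, region, k)
    expected = np.array([not (x < c < x + k) for x in range(length - k + 1)])
    assert np.array_equal(result.vectors[2], expected)


def test_membership_matches_oracle(small_fixture):
    pivot = small_fixture.pivot
    for contig in pivot.contigs:
        region = QueryRegion(contig.name, 0, len(contig))
        for k in (4, 11, 31):
            result = membership_query(small_fixture.membership_path, region, k)
            assert result.vectors[1].all()  # pivot row identically true
            for target in small_fixture.genomes[1:]:
                oracle = oracle_kmer_presence(pivot, target, region, k)
                assert np.array_equal(result.vectors[target.genome_id], oracle)


def test_conservation_matches_oracle(small_fixture):
    pivot = small_fixture.pivot
    for contig in pivot.contigs:
        region = QueryRegion(contig.name, 0, len(contig))
        for k in (4, 21):
            cons = conservation_query(small_fixture.conservation_path, region, k)
            oracle = oracle_conservation(pivot, small_fixture.genomes, region, k)
            assert np.array_equal(cons, oracle)


def test_t2_conservation_is_one_plus_membership(tmp_path):
    genomes = simulate_pangenome(
        SimulationConfig(seed=8, t=2, pivot_length=800, substitution_rate=0.02)
    )
    mrec, mmeta = build_records(genomes, "membership")
    crec, cmeta = build_records(genomes, "conservation")
    mpath = _write(tmp_path, mrec, mmeta, "m.parquet")
    cpath = _write(tmp_path, crec, cmeta, "c.parquet")
    region = QueryRegion("chr1", 100, 700)
    k = 9
    membership = membership_query(mpath, region, k).vectors[2]
    cons = conservation_query(cpath, region, k)
    assert np.array_equal(cons, 1 + membership.astype(int))


def test_mem_containment_reference_path_agrees(small_fixture):
    """Spanning an overlap with overhang == not contained in any MEM."""
    pivot = small_fixture.pivot
    for contig in pivot.contigs:
        region = QueryRegion(contig.name, 0, len(contig))
        for target in small_fixture.genomes[1:]:
            ms = compute_matching_statistics(contig, target)
            mems = ms_to_mems(ms, label=target.genome_id)
            for k in (4, 11, 31):
                reference = presence_from_mem_containment(mems, region, k)
                production = membership_query(
                    small_fixture.membership_path, region, k
                ).vectors[target.genome_id]
                assert np.array_equal(reference, production)


def test_early_stopping_matches_exhaustive(small_fixture):
    region = QueryRegion(small_fixture.pivot.contigs[0].name, 0,
                         len(small_fixture.pivot.contigs[0]))
    for k in (5, 17):
        fast = conservation_query(small_fixture.conservation_path, region, k,
                                  early_stop=True)
        slow = conservation_query(small_fixture.conservation_path, region, k,
                                  early_stop=False)
        assert np.array_equal(fast, slow)


def test_conservation_monotone_in_k(small_fixture):
    contig = small_fixture.pivot.contigs[0]
    region = QueryRegion(contig.name, 0, len(contig))
    k = 12
    cons_k = conservation_query(small_fixture.conservation_path, region, k)
    cons_k1 = conservation_query(small_fixture.conservation_path, region, k + 1)
    assert (cons_k1 <= cons_k[: cons_k1.size]).all()


def test_quantile_query_floors_to_retained_threshold(small_fixture, tmp_path):
    t = small_fixture.cfg.t
    scheme = QuantileScheme(t, (0.5, 1.0))
    sampled = apply_quantile_sampling(small_fixture.conservation_records, scheme)
    meta = small_fixture.conservation_meta
    qmeta = IndexMetadata(pivot=meta.pivot, genomes=meta.genomes, t=t,
                          mode="quantile", thresholds=tuple(scheme.thresholds))
    qpath = _write(tmp_path, sampled, qmeta, "q.parquet")
    contig = small_fixture.pivot.contigs[0]
    region = QueryRegion(contig.name, 0, len(contig))
    thresholds = np.array(scheme.thresholds)
    for k in (7, 21):
        exact = conservation_query(small_fixture.conservation_path, region, k)
        approx = quantile_conservation_query(qpath, region, k)
        floored = np.array(
            [max([1] + [c for c in thresholds if c <= e]) for e in exact]
        )
        assert np.array_equal(approx, floored)


def test_quantile_scheme_retaining_all_rows_equals_exact(small_fixture, tmp_path):
    t = small_fixture.cfg.t
    scheme = QuantileScheme(t, tuple((i + 1) / t for i in range(t)))
    assert scheme.thresholds == list(range(1, t + 1))
    sampled = apply_quantile_sampling(small_fixture.conservation_records, scheme)
    meta = small_fixture.conservation_meta
    qmeta = IndexMetadata(pivot=meta.pivot, genomes=meta.genomes, t=t,
                          mode="quantile", thresholds=tuple(scheme.thresholds))
    qpath = _write(tmp_path, sampled, qmeta, "qfull.parquet")
    contig = small_fixture.pivot.contigs[0]
    region = QueryRegion(contig.name, 0, len(contig))
    k = 11
    assert np.array_equal(
        quantile_conservation_query(qpath, region, k),
        conservation_query(small_fixture.conservation_path, region, k),
    )


def test_query_mode_and_k_validation(small_fixture, tmp_path):
    region = QueryRegion(small_fixture.pivot.contigs[0].name, 0, 100)
    with pytest.raises(QueryError):
        membership_query(small_fixture.conservation_path, region, 5)
    with pytest.raises(QueryError):
        conservation_query(small_fixture.membership_path, region, 5)
    with pytest.raises(QueryError):
        conservation_query(small_fixture.conservation_path, region, 101)
    # filtered index rejects k beyond l + 2, naming the bound
    from panmem.order_transform import FilterConfig, apply_length_filter

    meta = small_fixture.conservation_meta
    fmeta = IndexMetadata(pivot=meta.pivot, genomes=meta.genomes, t=meta.t,
                          mode="conservation", filter_l=29)
    filtered = apply_length_filter(
        small_fixture.conservation_records, FilterConfig(29)
    )
    fpath = _write(tmp_path, filtered, fmeta, "f.parquet")
    with pytest.raises(QueryError, match="31"):
        conservation_query(fpath, region, 40)


def test_bin_conservation_top_bin_and_normalization():
    cons = np.full(100, 5)
    props = bin_conservation(cons, t=5, bin_count=10)
    assert props.shape == (1, 10)
    assert props[0, -1] == 1.0 and props[0, :-1].sum() == 0.0


def test_bin_conservation_matches_naive_recount():
    rng = np.random.default_rng(3)
    t, bins = 7, 10
    cons = rng.integers(1, t + 1, size=500)
    props = bin_conservation(cons, t=t, bin_count=bins)
    naive = np.zeros(bins)
    for c in cons:
        b = min(bins - 1, int(np.ceil(c / t * bins)) - 1)
        naive[b] += 1
    assert np.allclose(props[0], naive / cons.size)


def test_bin_conservation_windows_sum_to_one():
    rng = np.random.default_rng(4)
    cons = rng.integers(1, 6, size=137)
    props = bin_conservation(cons, t=5, bin_count=8, window=25)
    assert props.shape == (6, 8)
    assert np.allclose(props.sum(axis=1), 1.0)


def test_bin_conservation_validation():
    with pytest.raises(ValueError):
        bin_conservation(np.array([1]), t=2, bin_count=0)
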