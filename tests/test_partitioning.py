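import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockpart.codon_sim import NucleotideAlignment
from clockpart.ml import SubstModelConfig
from clockpart.partitioning import (
    DataBlock,
    PartitionScheme,
    bic_greedy_merge,
    fixed_scheme,
    gap_statistic_cluster,
    k_medoids,
    make_blocks,
    read_scheme_json,
    sbsd_distance_matrix,
    sbsd_min_distance,
    write_scheme_json,
)
from helpers import clock_like_block_vectors, planted_block_vectors, simulate_hky


def test_fixed_schemes():
    n_genes = 5
    c = fixed_scheme("C", n_genes)
    cp = fixed_scheme("CP", n_genes)
    g = fixed_scheme("G", n_genes)
    gcp = fixed_scheme("GCP", n_genes)
    assert c.n_partitions == 1
    assert cp.n_partitions == 2
    assert g.n_partitions == 5
    assert gcp.n_partitions == 10
    # CP pools the pos12 blocks (even indices) and the pos3 blocks
    assert cp.assignment == [1, 2] * 5
    # G pools the two blocks of each gene
    assert g.assignment == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
    with pytest.raises(ValueError):
        fixed_scheme("XYZ", 5)


def test_scheme_validation_and_columns(small_replicate):
    aln, _ = small_replicate
    with pytest.raises(ValueError):
        PartitionScheme(label="bad", assignment=[1, 3])  # non-contiguous
    blocks = make_blocks(aln)
    assert len(blocks) == 16
    assert blocks[0].gene == 0 and blocks[0].pos_class == "12"
    assert blocks[1].gene == 0 and blocks[1].pos_class == "3"
    # pos12 blocks hold twice as many columns as pos3 blocks
    assert blocks[0].columns.size == 2 * blocks[1].columns.size
    scheme = fixed_scheme("G", 8)
    parts = scheme.partition_columns(blocks)
    assert len(parts) == 8
    got = np.sort(np.concatenate(parts))
    np.testing.assert_array_equal(got, np.arange(aln.n_cols))


def test_sbsd_distance_basics():
    a = np.array([1.0, 2.0, 3.0])
    assert sbsd_min_distance(a, a) == 0.0
    assert sbsd_min_distance(a, 7.3 * a) == pytest.approx(0.0, abs=1e-12)  # scale-invariant
    b = np.array([3.0, 2.0, 1.0])
    d = sbsd_min_distance(a, b)
    assert d > 0
    assert np.isclose(d, sbsd_min_distance(b, a))
    with pytest.raises(ValueError):
        sbsd_min_distance(a, np.ones(4))


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
def test_sbsd_distance_properties(seed, scale):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.01, 1.0, size=8)
    b = rng.uniform(0.01, 1.0, size=8)
    d = sbsd_min_distance(a, b)
    assert 0 <= d
    assert np.isclose(d, sbsd_min_distance(b, a))
    assert np.isclose(d, sbsd_min_distance(scale * a, b), atol=1e-9)
    assert np.isclose(d, sbsd_min_distance(a, scale * b), atol=1e-9)


def _euclidean(points):
    return np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)


def test_k_medoids_is_swap_optimal():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(9, 2))
    d = _euclidean(pts)
    for k in (1, 2, 3):
        medoids, assign = k_medoids(d, k)
        cost = d[:, medoids].min(axis=1).sum()
        # assignment is nearest-medoid
        np.testing.assert_array_equal(assign, np.argmin(d[:, medoids], axis=1))
        # no single medoid swap improves the cost
        for mi, h in itertools.product(range(k), range(9)):
            if h in medoids:
                continue
            trial = list(medoids)
            trial[mi] = h
            assert d[:, trial].min(axis=1).sum() >= cost - 1e-12
    # k=1 medoid is the brute-force 1-median
    medoids, _ = k_medoids(d, 1)
    assert medoids[0] == int(np.argmin(d.sum(axis=1)))


def test_k_medoids_recovers_planted_clusters():
    rng = np.random.default_rng(8)
    pts = np.concatenate(
        [rng.normal(0.0, 0.05, size=(6, 2)), rng.normal(3.0, 0.05, size=(5, 2))]
    )
    _, assign = k_medoids(_euclidean(pts), 2)
    assert len(set(assign[:6])) == 1
    assert len(set(assign[6:])) == 1
    assert assign[0] != assign[6]


def test_gap_statistic_recovers_planted_groups():
    rng = np.random.default_rng(17)
    bl = planted_block_vectors(rng)
    d = sbsd_distance_matrix(bl)
    scheme = gap_statistic_cluster(d, max_k=6, n_boot=120, rng=rng)
    assert scheme.n_partitions == 2
    assert len(set(scheme.assignment[:8])) == 1
    assert len(set(scheme.assignment[8:])) == 1
    assert scheme.assignment[0] != scheme.assignment[8]


def test_gap_statistic_clock_like_gives_one_cluster():
    rng = np.random.default_rng(23)
    bl = clock_like_block_vectors(rng)
    scheme = gap_statistic_cluster(sbsd_distance_matrix(bl), max_k=6, n_boot=120, rng=rng)
    assert scheme.n_partitions == 1


def test_gap_statistic_degenerate_zero_distances():
    scheme = gap_statistic_cluster(np.zeros((6, 6)))
    assert scheme.n_partitions == 1
    assert scheme.assignment == [1] * 6


def test_bic_greedy_merge_pools_iid_blocks(tree):
    """Blocks simulated from the same process should be merged, while the
    two planted overall-rate classes should stay apart.  The merge model
    gives every partition a free rate multiplier, so a merged slow+fast
    partition cannot fit both halves at once."""
    rng = np.random.default_rng(31)
    cfg = SubstModelConfig(kappa=2.0, alpha=1.0)
    durations = tree.branch_durations()
    pattern_a = 0.15 * durations
    pattern_b = 0.9 * durations  # same shape, six-fold faster
    alns = [
        simulate_hky(tree, pattern_a, cfg, 240, rng, col_gene=0),
        simulate_hky(tree, pattern_a, cfg, 240, rng, col_gene=1),
        simulate_hky(tree, pattern_b, cfg, 240, rng, col_gene=2),
        simulate_hky(tree, pattern_b, cfg, 240, rng, col_gene=3),
    ]
    aln = NucleotideAlignment(
        taxa=list(tree.tip_names),
        matrix=np.concatenate([a.matrix for a in alns], axis=1),
        col_gene=np.concatenate([a.col_gene for a in alns]),
        col_pos=np.concatenate([a.col_pos for a in alns]),
    )
    blocks = [
        DataBlock(gene=g, pos_class="12", columns=np.flatnonzero(aln.col_gene == g))
        for g in range(4)
    ]
    scheme = bic_greedy_merge(blocks, aln, tree, config=cfg)
    a0, a1, b0, b1 = scheme.assignment
    assert a0 == a1
    assert b0 == b1
    assert a0 != b0


def test_scheme_json_round_trip(tmp_path, small_replicate):
    aln, _ = small_replicate
    blocks = make_blocks(aln)
    scheme = fixed_scheme("CP", 8)
    path = tmp_path / "scheme.json"
    write_scheme_json(path, scheme, blocks)
    back = read_scheme_json(path)
    assert back.label == "CP"
    assert back.assignment == scheme.assignment
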