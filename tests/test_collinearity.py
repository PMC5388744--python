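import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_longest_chain
from synfrac.collinearity import (BlockSet, CollinearBlock, census,
                                  chain_blocks, detect_all_blocks,
                                  read_blocks, write_blocks)
from synfrac.homology import naive_all_vs_all


def test_diagonal_points_form_one_parallel_block():
    pts = [(i, i) for i in range(10)]
    out = chain_blocks(pts, max_gap=50, min_len=5)
    assert len(out) == 1
    orientation, chain = out[0]
    assert orientation == "parallel" and len(chain) == 10


def test_reversed_diagonal_is_antiparallel():
    pts = [(i, 9 - i) for i in range(10)]
    out = chain_blocks(pts, max_gap=50, min_len=5)
    assert len(out) == 1
    orientation, chain = out[0]
    assert orientation == "antiparallel" and len(chain) == 10
    assert [rb for _, rb in chain] == sorted((rb for _, rb in chain),
                                             reverse=True)


def test_gap_constraint_splits_chains():
    """A jump larger than max_gap on one axis breaks the chain."""
    pts = [(i, i) for i in range(5)] + [(i + 20, i + 200) for i in range(5)]
    out = chain_blocks(pts, max_gap=10, min_len=5)
    assert len(out) == 2
    assert all(len(chain) == 5 for _, chain in out)


def test_first_chain_matches_bruteforce_on_seeded_grids():
    """DP optimum equals exhaustive enumeration over monotone subsets."""
    rng = random.Random(7)
    for trial in range(60):
        n = rng.randint(1, 12)
        pts = set()
        while len(pts) < n:
            pts.add((rng.randrange(20), rng.randrange(20)))
        pts = sorted(pts)
        max_gap = rng.choice([1, 2, 5, 50])
        expected = brute_force_longest_chain(pts, max_gap)
        got = chain_blocks(pts, max_gap=max_gap, min_len=2)
        got_len = len(got[0][1]) if got else 1
        if expected < 2:
            assert not got
        else:
            assert got_len == expected, (pts, max_gap)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.sets(st.tuples(st.integers(0, 15), st.integers(0, 15)),
               min_size=2, max_size=10),
       st.sampled_from([1, 3, 50]))
def test_chain_optimality_property(points, max_gap):
    expected = brute_force_longest_chain(sorted(points), max_gap)
    got = chain_blocks(sorted(points), max_gap=max_gap, min_len=2)
    if expected < 2:
        assert not got
    else:
        assert got and len(got[0][1]) == expected


def test_orientation_flips_when_one_axis_reverses():
    rng = random.Random(3)
    pts = sorted({(i, i + rng.randint(0, 2)) for i in range(0, 30, 2)})
    hi = max(rb for _, rb in pts)
    flipped = [(ra, hi - rb) for ra, rb in pts]
    fwd = chain_blocks(pts, 50, 5)
    rev = chain_blocks(flipped, 50, 5)
    assert [o for o, _ in fwd] == ["parallel"] * len(fwd)
    assert [o for o, _ in rev] == ["antiparallel"] * len(rev)
    assert [len(c) for _, c in fwd] == [len(c) for _, c in rev]


def test_empty_input_and_param_validation():
    assert chain_blocks([], 50, 5) == []
    with pytest.raises(ValueError):
        chain_blocks([(0, 0)], max_gap=0, min_len=5)
    with pytest.raises(ValueError):
        chain_blocks([(0, 0)], max_gap=5, min_len=1)


def test_duplicated_chromosome_without_loss_gives_one_spanning_block():
    """WGD copies of one chromosome align as a single intra-genome block."""
    from synfrac.simulate import SimConfig, simulate
    _, derived, truth = simulate(SimConfig(
        seed=17, n_chromosomes=1, genes_per_chromosome=30,
        wgt_loss=1.0, wgd_loss=(0.0, 0.0)))  # keep subgenome A only
    hs = naive_all_vs_all(derived, derived)
    bs = detect_all_blocks(hs, derived, derived)
    spanning = [b for b in bs.blocks
                if {b.chrom_a, b.chrom_b} == {"PO1A1", "PO1A2"}]
    assert len(spanning) == 1
    assert spanning[0].length == 30
    pairs = {tuple(sorted(p[:2])) for p in spanning[0].pairs}
    assert pairs == truth.wgd_pairs


def test_unrelated_shuffled_genomes_produce_no_blocks():
    from synfrac.simulate import SimConfig, simulate
    a, _, _ = simulate(SimConfig(seed=33, n_chromosomes=1,
                                 genes_per_chromosome=25))
    b, _, _ = simulate(SimConfig(seed=44, n_chromosomes=1,
                                 genes_per_chromosome=25,
                                 ref_name="other"))
    hs = naive_all_vs_all(a, b)
    assert len(detect_all_blocks(hs, a, b).blocks) == 0


def test_tandem_collapse_keeps_strongest_of_a_run(tiny_sim):
    """Intra-mode neighbours hitting one partner chain only once."""
    ref, _, _ = tiny_sim
    hs = naive_all_vs_all(ref, ref)
    bs = detect_all_blocks(hs, ref, ref, tandem_gap=5)
    for b in bs.blocks:
        ra = [p[2] for p in b.pairs]
        rb = [p[3] for p in b.pairs]
        assert len(set(ra)) == len(ra) and len(set(rb)) == len(rb)


def test_census_counts_and_largest_block():
    def block(length, ca="c1", cb="c2"):
        return CollinearBlock("A", "B", ca, cb, "parallel",
                              [("a", "b", i, i) for i in range(length)])

    bs = BlockSet("intra", "A", "A",
                  [block(3), block(6), block(12), block(55, "c4", "c9")])
    result = census(bs)
    assert result.per_threshold == {4: (3, 73), 10: (2, 67),
                                    20: (1, 55), 50: (1, 55)}
    assert result.largest == (55, "c4", "c9")


def test_census_of_empty_blockset():
    result = census(BlockSet("intra", "A", "A", []))
    assert result.largest is None
    assert all(v == (0, 0) for v in result.per_threshold.values())


def test_census_is_monotone_in_threshold(small_run):
    res, _ = small_run
    for bs in (res.blocks_intra_ref, res.blocks_inter):
        cen = census(bs).per_threshold
        ts = sorted(cen)
        for t1, t2 in zip(ts, ts[1:]):
            assert cen[t1][0] >= cen[t2][0]
            assert cen[t1][1] >= cen[t2][1]


def test_block_file_round_trip(tmp_path, small_run):
    res, _ = small_run
    p1, p2 = tmp_path / "b1.tsv", tmp_path / "b2.tsv"
    write_blocks(res.blocks_inter, p1)
    back = read_blocks(p1)
    write_blocks(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert len(back) == len(res.blocks_inter)
    assert [b.pairs for b in back.blocks] == \
           [b.pairs for b in res.blocks_inter.blocks]
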