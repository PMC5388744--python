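import math
import random
from dataclasses import replace

import numpy as np
import pytest

from oracles import nei_gojobori
from synfrac.collinearity import CollinearBlock
from synfrac.genome_io import GeneModel
from synfrac.ks import (KsError, SENSE_CODONS, align_codons,
                        annotate_block_ks, jukes_cantor, ng86)


def _gene(gid, cds):
    from Bio.Seq import Seq
    return GeneModel(gid, "c", 1, len(cds), "+", 0, cds,
                     str(Seq(cds).translate()).rstrip("*"))


def _random_cds(rng, n_codons):
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


def _mutate(rng, cds, n_changes):
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for _ in range(n_changes):
        i = rng.randrange(len(codons))
        codons[i] = rng.choice(SENSE_CODONS)
    return "".join(codons)


def test_identical_sequences_give_zero():
    g = _gene("a", _random_cds(random.Random(0), 40))
    res = ng86(align_codons(g, replace(g, gene_id="b")))
    assert res.Ks == 0.0 and res.Ka == 0.0 and not res.saturated


def test_single_codon_synonymous_difference_saturates():
    """TTT vs TTC: one synonymous difference on 1/3 site -> pS beyond the
    Jukes-Cantor domain, flagged saturated."""
    res = ng86(align_codons(_gene("a", "TTT"), _gene("b", "TTC")))
    assert res.saturated and math.isnan(res.Ks)
    assert res.Sd == 1.0 and res.S == pytest.approx(1 / 3)


def test_ng86_is_symmetric():
    rng = random.Random(5)
    a = _gene("a", _random_cds(rng, 30))
    b = _gene("b", _mutate(rng, a.cds, 10))
    r1 = ng86(align_codons(a, b))
    r2 = ng86(align_codons(b, a))
    assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)


def test_matches_exhaustive_pathway_oracle():
    """Native NG86 equals the independent pathway-enumeration oracle on
    seeded 30-codon pairs, to 1e-9."""
    rng = random.Random(42)
    checked = 0
    for _ in range(120):
        a = _gene("a", _random_cds(rng, 30))
        b = _gene("b", _mutate(rng, a.cds, rng.randint(1, 25)))
        res = ng86(align_codons(a, b))
        ka_o, ks_o, sat_o = nei_gojobori(a.cds, b.cds)
        assert sat_o == res.saturated
        if not sat_o:
            assert res.Ks == pytest.approx(ks_o, abs=1e-9)
        if ka_o is not None:
            assert res.Ka == pytest.approx(ka_o, abs=1e-9)
        checked += 1
    assert checked == 120


def test_site_counts_sum_to_sequence_length():
    rng = random.Random(9)
    a = _gene("a", _random_cds(rng, 50))
    b = _gene("b", _mutate(rng, a.cds, 15))
    res = ng86(align_codons(a, b))
    assert res.S + res.N == pytest.approx(3 * 50)
    assert res.Ks >= res.pS or res.saturated


def test_jukes_cantor_monotone_and_diverging():
    ps = np.linspace(0.0, 0.74, 50)
    ks = [jukes_cantor(p) for p in ps]
    assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))
    assert jukes_cantor(0.7499) > 6.0
    assert math.isnan(jukes_cantor(0.75))


def test_alignment_identical_proteins_is_gapless():
    g = _gene("a", _random_cds(random.Random(1), 25))
    al = align_codons(g, replace(g, gene_id="b"))
    assert al.n_ungapped == 25 and len(al.columns) == 25


def test_insertion_becomes_one_gap_column():
    rng = random.Random(2)
    cds = _random_cds(rng, 20)
    ins = cds[:30] + "GCT" + cds[30:]
    al = align_codons(_gene("a", cds), _gene("b", ins))
    gaps = [(ca, cb) for ca, cb in al.columns if "-" in ca or "-" in cb]
    assert gaps == [("---", "GCT")]
    assert al.n_ungapped == 20


def test_internal_stop_is_an_error():
    bad = GeneModel("a", "c", 1, 9, "+", 0, "ATGTAAGCT", "M*A")
    good = _gene("b", "ATGGCTGCT")
    with pytest.raises(KsError):
        align_codons(bad, good)


def test_synonymous_only_divergence_keeps_ka_zero():
    """Mutating only 4-fold-degenerate third positions: Ka stays 0 and Ks
    grows with the number of applied changes."""
    rng = random.Random(11)
    base = "".join(rng.choice(["GCT", "GGT", "CCT", "ACT", "GTT"])
                   for _ in range(60))
    ks_values = []
    for n_changes in (2, 8, 20):
        codons = [base[i:i + 3] for i in range(0, len(base), 3)]
        positions = rng.sample(range(60), n_changes)
        for i in positions:
            codons[i] = codons[i][:2] + rng.choice(
                [nt for nt in "ACGT" if nt != codons[i][2]])
        res = ng86(align_codons(_gene("a", base),
                                _gene("b", "".join(codons))))
        assert res.Ka == 0.0
        ks_values.append(res.Ks)
    assert ks_values == sorted(ks_values)
    assert ks_values[0] > 0


def test_block_median_rules():
    genes = {}
    rng = random.Random(3)
    base = _random_cds(rng, 40)

    def pair(i, n_changes):
        a = _gene(f"a{i}", base)
        b = _gene(f"b{i}", _mutate(rng, base, n_changes))
        genes[a.gene_id] = a
        genes[b.gene_id] = b
        return (a.gene_id, b.gene_id, i, i)

    class FakeGenome:
        def __init__(self, genes):
            self.genes = genes

    block = CollinearBlock("A", "B", "c1", "c2", "parallel",
                           [pair(0, 4), pair(1, 8), pair(2, 12)])
    g = FakeGenome(genes)
    annotated = annotate_block_ks(block, g, g)
    defined = sorted(k for k in annotated.ks_values if k is not None)
    assert annotated.median_ks == pytest.approx(
        defined[len(defined) // 2] if len(defined) % 2
        else (defined[len(defined) // 2 - 1] + defined[len(defined) // 2]) / 2)


def test_even_count_median_is_mean_of_central_two():
    genes = {}
    rng = random.Random(8)
    base = _random_cds(rng, 40)
    pairs = []
    for i, n in enumerate((3, 9)):
        a = _gene(f"a{i}", base)
        b = _gene(f"b{i}", _mutate(rng, base, n))
        genes[a.gene_id] = a
        genes[b.gene_id] = b
        pairs.append((a.gene_id, b.gene_id, i, i))

    class FakeGenome:
        def __init__(self, genes):
            self.genes = genes

    g = FakeGenome(genes)
    block = CollinearBlock("A", "B", "c1", "c2", "parallel", pairs)
    annotated = annotate_block_ks(block, g, g)
    k1, k2 = annotated.ks_values
    assert annotated.median_ks == pytest.approx((k1 + k2) / 2)


def test_all_saturated_block_has_no_median():
    genes = {"a": _gene("a", "TTT"), "b": _gene("b", "TTC")}

    class FakeGenome:
        def __init__(self, genes):
            self.genes = genes

    g = FakeGenome(genes)
    block = CollinearBlock("A", "B", "c1", "c2", "parallel",
                           [("a", "b", 0, 0)])
    annotated = annotate_block_ks(block, g, g)
    assert annotated.median_ks is None
    assert annotated.ks_values == [None]
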