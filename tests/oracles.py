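"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths: the chain oracle
enumerates every subset of points, and the Ka/Ks oracle recounts sites and
pathway-averaged differences from the genetic code by recursion.
"""

from itertools import combinations, permutations
from math import log

from Bio.Data.CodonTable import standard_dna_table

_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def brute_force_longest_chain(points, max_gap):
    """Maximum size of a monotone subset (both orientations, gap-bounded),
    by exhaustive enumeration over all subsets.  Only viable for <= ~15
    points."""
    best = 0
    pts = sorted(points)
    for size in range(len(pts), 0, -1):
        if size <= best:
            break
        for subset in combinations(pts, size):
            for sign in (1, -1):
                ok = True
                for (a1, b1), (a2, b2) in zip(subset, subset[1:]):
                    da, db = a2 - a1, sign * (b2 - b1)
                    if not (1 <= da <= max_gap and 1 <= db <= max_gap):
                        ok = False
                        break
                if ok:
                    best = size
                    break
            if best == size:
                break
    return best


def _syn_sites(codon):
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut not in _STOPS and _AA[mut] == aa:
                syn += 1
    return syn / 3.0


def _count_path(path):
    """(syn, nonsyn, crosses_stop) step counts along one codon path."""
    syn = non = 0
    crosses = False
    for src, dst in zip(path, path[1:]):
        if src in _STOPS or dst in _STOPS:
            crosses = True
            non += 1
        elif _AA[src] == _AA[dst]:
            syn += 1
        else:
            non += 1
    return syn, non, crosses


def _pair_differences(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    all_paths = []
    for order in permutations(positions):
        path = [c1]
        cur = c1
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1:]
            path.append(cur)
        all_paths.append(_count_path(path))
    clean = [(s, n) for s, n, crossed in all_paths if not crossed]
    if not clean:
        clean = [(s, n) for s, n, _ in all_paths]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


def nei_gojobori(cds1, cds2):
    """Full NG86 on two gap-free, equal-length, stop-free CDS strings.

    Returns (Ka, Ks, saturated) with Jukes-Cantor correction; Ks is None
    when saturated (and Ka None when its own correction is undefined).
    """
    assert len(cds1) == len(cds2) and len(cds1) % 3 == 0
    codons1 = [cds1[i:i + 3] for i in range(0, len(cds1), 3)]
    codons2 = [cds2[i:i + 3] for i in range(0, len(cds2), 3)]
    s1 = sum(_syn_sites(c) for c in codons1)
    s2 = sum(_syn_sites(c) for c in codons2)
    S = (s1 + s2) / 2.0
    N = len(codons1) * 3 - S
    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        d_s, d_n = _pair_differences(c1, c2)
        sd += d_s
        nd += d_n
    pS = sd / S if S else 0.0
    pN = nd / N if N else 0.0

    def jc(p):
        arg = 1 - 4.0 * p / 3.0
        return None if arg <= 0 else -0.75 * log(arg)

    ks = jc(pS)
    return jc(pN), ks, ks is None
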