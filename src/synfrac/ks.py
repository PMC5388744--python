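"""Ka/Ks estimation by the Nei–Gojobori (1986) counting method.

For each colinear gene pair the proteins are globally aligned, the
alignment is threaded back onto the CDS so every protein column becomes a
codon column, and NG86 counting is applied to the ungapped codon columns:

* synonymous sites per codon = (number of the 9 single-nucleotide changes
  that are synonymous) / 3, averaged between the two sequences;
* codon pairs differing at k positions contribute differences averaged
  over the k! minimal mutational pathways; pathways passing through a stop
  codon are excluded (with renormalisation), and if every pathway is
  blocked all are included with stop-crossing steps counted nonsynonymous;
* proportions pS = Sd/S and pN = Nd/N receive the Jukes–Cantor multiple-hit
  correction  K = -(3/4) ln(1 - (4/3) p),

which is undefined (saturated) once p >= 3/4.  Block-level dating uses the
median Ks over the block's unsaturated pairs.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, replace
from math import log, nan

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .collinearity import BlockSet, CollinearBlock
from .genome_io import GeneModel, GenomeModel, validate_gene_sequences

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "KsError",
    "align_codons",
    "ng86",
    "ng86_pair_counts",
    "annotate_block_ks",
    "annotate_blockset_ks",
    "write_ks_table",
    "jukes_cantor",
    "SENSE_CODONS",
]

_NT = "TCAG"
_CODON_AA = dict(standard_dna_table.forward_table)  # sense codons only
SENSE_CODONS = tuple(sorted(_CODON_AA))
_STOPS = set(standard_dna_table.stop_codons)


class KsError(ValueError):
    """Raised for invalid codon alignments or sequences."""


def _syn_site_fraction(codon: str) -> float:
    """Synonymous sites in one codon: synonymous single-nt changes / 3."""
    aa = _CODON_AA[codon]
    syn = 0
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in _STOPS and _CODON_AA[alt] == aa:
                syn += 1
    return syn / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over minimal mutational pathways per the NG86 convention."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
                steps.append(("stop", cur, nxt))
            else:
                steps.append((None, cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [p for p in paths if not p[0]] or paths
    sd = nd = 0.0
    for _, steps in usable:
        for flag, src, dst in steps:
            if flag == "stop" or src in _STOPS or dst in _STOPS:
                nd += 1
            elif _CODON_AA[src] == _CODON_AA[dst]:
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


# Tables over the 61 sense codons, built once at import.
_SYN_SITES = {c: _syn_site_fraction(c) for c in SENSE_CODONS}
_PAIR_COUNTS = {
    (c1, c2): _pathway_counts(c1, c2)
    for c1 in SENSE_CODONS for c2 in SENSE_CODONS
}


def ng86_pair_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) contribution of one codon column."""
    return _PAIR_COUNTS[(codon_a, codon_b)]


@dataclass(frozen=True)
class CodonAlignment:
    """Codon-resolution pairwise alignment (gap codons are '---')."""

    gene_a: str
    gene_b: str
    columns: tuple[tuple[str, str], ...]

    @property
    def n_ungapped(self) -> int:
        return sum(1 for a, b in self.columns if "-" not in a and "-" not in b)


@dataclass(frozen=True)
class KaKsResult:
    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float  # nan when saturated
    Ka: float  # nan when its own correction is undefined
    saturated: bool  # Ks undefined


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; nan outside its domain."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return nan
    return -0.75 * log(arg)


_PROTEIN_ALIGNER = None


def _protein_aligner() -> PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _PROTEIN_ALIGNER = aligner
    return _PROTEIN_ALIGNER


def align_codons(gene_a: GeneModel, gene_b: GeneModel) -> CodonAlignment:
    """Globally align two proteins and back-thread onto their CDS.

    Each protein alignment column becomes one codon column; a gap in the
    protein alignment becomes a ``---`` codon.  CDS/protein inconsistency
    raises :class:`KsError`.
    """
    for g in (gene_a, gene_b):
        try:
            validate_gene_sequences(g.gene_id, g.cds, g.protein)
        except ValueError as exc:
            raise KsError(str(exc)) from None
    alignment = _protein_aligner().align(gene_a.protein, gene_b.protein)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    cols = []
    ia = ib = 0
    for aa_a, aa_b in zip(row_a, row_b):
        if aa_a == "-":
            ca = "---"
        else:
            ca = gene_a.cds[3 * ia: 3 * ia + 3]
            ia += 1
        if aa_b == "-":
            cb = "---"
        else:
            cb = gene_b.cds[3 * ib: 3 * ib + 3]
            ib += 1
        cols.append((ca, cb))
    return CodonAlignment(gene_a.gene_id, gene_b.gene_id, tuple(cols))


def ng86(al: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks from a codon alignment (gapped columns dropped)."""
    s_a = s_b = sd = nd = 0.0
    n_cols = 0
    for ca, cb in al.columns:
        if "-" in ca or "-" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            raise KsError(f"{al.gene_a}/{al.gene_b}: stop codon in alignment")
        n_cols += 1
        s_a += _SYN_SITES[ca]
        s_b += _SYN_SITES[cb]
        d_s, d_n = _PAIR_COUNTS[(ca, cb)]
        sd += d_s
        nd += d_n
    if n_cols == 0:
        raise KsError(
            f"{al.gene_a}/{al.gene_b}: no ungapped codon columns to compare"
        )
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_cols - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    return KaKsResult(al.gene_a, al.gene_b, S, N, sd, nd, pS, pN,
                      ks, ka, saturated=ks != ks)


def annotate_block_ks(block: CollinearBlock, a: GenomeModel,
                      b: GenomeModel) -> CollinearBlock:
    """Attach per-pair Ks and the block median (saturated pairs excluded).

    The median of an even number of values is the mean of the central two;
    a block whose every pair is saturated keeps ``median_ks = None``.
    """
    ks_values: list[float | None] = []
    for ga, gb, _, _ in block.pairs:
        res = ng86(align_codons(a.genes[ga], b.genes[gb]))
        ks_values.append(None if res.saturated else res.Ks)
    defined = [k for k in ks_values if k is not None]
    median = statistics.median(defined) if defined else None
    return replace(block, ks_values=ks_values, median_ks=median)


def annotate_blockset_ks(bs: BlockSet, a: GenomeModel,
                         b: GenomeModel) -> BlockSet:
    """Ks-annotate every block of a set."""
    out = BlockSet(bs.mode, bs.genome_a, bs.genome_b, params=dict(bs.params))
    out.blocks = [annotate_block_ks(blk, a, b) for blk in bs.blocks]
    return out


def write_ks_table(bs: BlockSet, a: GenomeModel, b: GenomeModel, path) -> None:
    """Per-pair Ka/Ks TSV for every pair of every block."""
    with open(path, "w") as out:
        out.write("gene_a\tgene_b\tS\tN\tSd\tNd\tKa\tKs\tsaturated\n")
        for block in bs.blocks:
            for ga, gb, _, _ in block.pairs:
                r = ng86(align_codons(a.genes[ga], b.genes[gb]))
                ka = "" if r.Ka != r.Ka else f"{r.Ka:.6f}"
                ks = "" if r.saturated else f"{r.Ks:.6f}"
                out.write(f"{ga}\t{gb}\t{r.S:.2f}\t{r.N:.2f}\t{r.Sd:.2f}\t"
                          f"{r.Nd:.2f}\t{ka}\t{ks}\t{int(r.saturated)}\n")
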