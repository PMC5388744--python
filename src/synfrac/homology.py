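"""All-vs-all protein homology search and filtering.

Homologous gene pairs seed collinearity detection.  Two routes produce
them: :func:`parse_hits` ingests standard BLAST tabular output (outfmt 6),
and :func:`naive_all_vs_all` computes Smith–Waterman local alignments
(BLOSUM62, affine gaps 11/1) directly so the package is testable without
an external search.  Both apply the same filters: E-value < 1e-5, no self
hits, and at most the top five subjects per query per target genome.
:func:`rank_hits` then classes each query's hits as best / second / other,
the three colour classes of the dot plots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import GenomeModel

__all__ = [
    "Hit",
    "HitSet",
    "HomologyError",
    "parse_hits",
    "write_hits",
    "naive_all_vs_all",
    "rank_hits",
    "DEFAULT_EVALUE",
    "DEFAULT_TOP_N",
]

log = logging.getLogger(__name__)

DEFAULT_EVALUE = 1e-5
DEFAULT_TOP_N = 5

# Karlin–Altschul parameters for gapped BLOSUM62, gap open 11 / extend 1
# (published BLAST constants; fixed, not configurable).
_KA_LAMBDA = 0.267
_KA_K = 0.041
_LN2 = math.log(2.0)


class HomologyError(ValueError):
    """Raised for malformed hit input or empty proteomes."""


@dataclass(frozen=True)
class Hit:
    query_gene: str
    subject_gene: str
    bit_score: float
    e_value: float
    rank_class: str | None = None  # "best" | "second" | "other"


@dataclass
class HitSet:
    genome_a: str
    genome_b: str
    hits: list[Hit] = field(default_factory=list)
    mode: str = "inter"  # "intra" | "inter"
    n_dropped_unknown: int = 0

    def __post_init__(self):
        if self.mode == "intra" and self.genome_a != self.genome_b:
            raise HomologyError("intra mode requires genome_a == genome_b")

    def __len__(self) -> int:
        return len(self.hits)


def _filter_top_n(hits: list[Hit], top_n: int) -> list[Hit]:
    by_query: dict[str, list[Hit]] = {}
    for h in hits:
        by_query.setdefault(h.query_gene, []).append(h)
    kept: list[Hit] = []
    for q in sorted(by_query):
        ordered = sorted(
            by_query[q],
            key=lambda h: (-h.bit_score, h.e_value, h.subject_gene),
        )
        kept.extend(ordered[:top_n])
    return kept


def parse_hits(tabular_source, genome_a: GenomeModel, genome_b: GenomeModel,
               evalue_max: float = DEFAULT_EVALUE,
               top_n: int = DEFAULT_TOP_N) -> HitSet:
    """Read 12-column BLAST tabular rows and apply the retention filters.

    Self hits are dropped in intra mode, rows at or above the E-value
    cutoff are dropped, and only the ``top_n`` strongest subjects per query
    are kept.  Rows naming genes absent from the loaded genomes are dropped
    with a warning (counted on the returned set); malformed rows raise
    :class:`HomologyError` with the line number.
    """
    intra = genome_a.name == genome_b.name
    raw: list[Hit] = []
    dropped_unknown = 0
    if hasattr(tabular_source, "read"):
        lines = tabular_source.read().splitlines()
    else:
        with open(tabular_source) as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise HomologyError(
                f"line {lineno}: expected 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            q, s = fields[0], fields[1]
            e_value = float(fields[10])
            bit = float(fields[11])
        except ValueError as exc:
            raise HomologyError(f"line {lineno}: {exc}") from None
        forward = q in genome_a.genes and s in genome_b.genes
        reverse = q in genome_b.genes and s in genome_a.genes
        if not (forward or reverse):
            dropped_unknown += 1
            log.warning("dropping hit %s-%s: gene not in loaded genomes", q, s)
            continue
        if intra and q == s:
            continue
        if e_value >= evalue_max:
            continue
        raw.append(Hit(q, s, bit, e_value))
    hs = HitSet(genome_a.name, genome_b.name,
                _filter_top_n(raw, top_n), "intra" if intra else "inter")
    hs.n_dropped_unknown = dropped_unknown
    return hs


def write_hits(hs: HitSet, path) -> None:
    """Write hits as 12-column BLAST tabular (unused columns zeroed)."""
    with open(path, "w") as out:
        for h in hs.hits:
            out.write(
                f"{h.query_gene}\t{h.subject_gene}\t0.0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.e_value:.3e}\t{h.bit_score:.1f}\n"
            )


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _bit_and_evalue(raw_score: float, m: int, n: int) -> tuple[float, float]:
    bit = (_KA_LAMBDA * raw_score - math.log(_KA_K)) / _LN2
    e_value = m * n * 2.0 ** (-bit)
    return bit, e_value


def _candidate_pairs(seqs_a: list[tuple[str, str]],
                     seqs_b: list[tuple[str, str]], intra: bool,
                     max_norm_dist: float) -> set[tuple[str, str]]:
    """Unordered candidate pairs by banded edit distance (edlib).

    Pairs whose normalised edit distance exceeds ``max_norm_dist`` (or
    whose lengths differ more than twofold) cannot reach the E-value
    cutoff at these sequence lengths and are skipped before the costly
    Smith–Waterman scoring; unrelated proteins sit near 0.75 normalised
    distance, far above the bar.
    """
    import edlib

    cands: set[tuple[str, str]] = set()
    for i, (qid, q) in enumerate(seqs_a):
        others = seqs_a[i + 1:] if intra else seqs_b
        for sid, s in others:
            if qid == sid:
                continue
            longer = max(len(q), len(s))
            if min(len(q), len(s)) * 2 < longer:
                continue
            k = int(max_norm_dist * longer)
            if edlib.align(q, s, task="distance",
                           k=k)["editDistance"] != -1:
                cands.add((qid, sid) if qid < sid else (sid, qid))
    return cands


def naive_all_vs_all(a: GenomeModel, b: GenomeModel,
                     evalue_max: float = DEFAULT_EVALUE,
                     top_n: int = DEFAULT_TOP_N,
                     prefilter: bool = True,
                     max_norm_dist: float = 0.65) -> HitSet:
    """Built-in all-vs-all protein search (Smith–Waterman + BLOSUM62).

    E-values follow the Karlin–Altschul form from the raw score and the
    search-space size (query length x total subject residues), with the
    published gapped-BLOSUM62 constants.  A banded edit-distance prefilter
    (see :func:`_candidate_pairs`) skips pairs that cannot pass the
    E-value cutoff, keeping the quadratic scoring cost manageable; it can
    be disabled with ``prefilter=False``.  Hits are emitted for both query
    directions (queries from ``a`` against ``b`` and vice versa, as an
    all-against-all search produces); the per-query top-``top_n`` filter
    applies per direction.  Intra-genome searches never emit a self hit.
    """
    if not a.genes or not b.genes:
        raise HomologyError("empty proteome")
    intra = a.name == b.name
    seqs_a = sorted((g.gene_id, g.protein) for g in a.genes.values())
    seqs_b = sorted((g.gene_id, g.protein) for g in b.genes.values())

    if prefilter:
        cands = _candidate_pairs(seqs_a, seqs_b, intra, max_norm_dist)
    else:
        cands = {(qid, sid) if qid < sid else (sid, qid)
                 for qid, _ in seqs_a for sid, _ in seqs_b if qid != sid}
    by_gene: dict[str, list[str]] = {}
    for x, y in sorted(cands):
        by_gene.setdefault(x, []).append(y)
        by_gene.setdefault(y, []).append(x)

    aligner = _make_aligner()
    score_cache: dict[tuple[str, str], float] = {}
    raw: list[Hit] = []
    passes = [(seqs_a, seqs_b)] if intra else [(seqs_a, seqs_b),
                                               (seqs_b, seqs_a)]
    for queries, subjects in passes:
        db_len = sum(len(s) for _, s in subjects)
        prot_s = dict(subjects)
        for qid, qseq in queries:
            for sid in by_gene.get(qid, ()):
                if sid not in prot_s:
                    continue
                key = (qid, sid) if qid < sid else (sid, qid)
                score = score_cache.get(key)
                if score is None:
                    score = float(aligner.score(qseq, prot_s[sid]))
                    score_cache[key] = score
                bit, e_value = _bit_and_evalue(score, len(qseq), db_len)
                if e_value < evalue_max:
                    raw.append(Hit(qid, sid, round(bit, 2), e_value))
    return HitSet(a.name, b.name, _filter_top_n(raw, top_n),
                  "intra" if intra else "inter")


def rank_hits(hs: HitSet) -> HitSet:
    """Class each query's hits best / second / other (dot-plot colours).

    Ties are broken by lower E-value, then subject gene ID, so every query
    has at most one best and one second hit.
    """
    by_query: dict[str, list[Hit]] = {}
    for h in hs.hits:
        by_query.setdefault(h.query_gene, []).append(h)
    ranked: list[Hit] = []
    for q in sorted(by_query):
        ordered = sorted(
            by_query[q],
            key=lambda h: (-h.bit_score, h.e_value, h.subject_gene),
        )
        for i, h in enumerate(ordered):
            cls = "best" if i == 0 else "second" if i == 1 else "other"
            ranked.append(replace(h, rank_class=cls))
    out = HitSet(hs.genome_a, hs.genome_b, ranked, hs.mode)
    out.n_dropped_unknown = hs.n_dropped_unknown
    return out
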