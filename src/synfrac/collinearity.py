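"""Collinear (synteny) block detection by dynamic-programming chaining.

A collinear block is a run of homologous gene pairs whose ranks increase
strictly along one chromosome and strictly increase (parallel) or decrease
(antiparallel) along the other, with consecutive rank gaps bounded by
``max_gap`` on both axes.  Per chromosome pair the highest-scoring chain
(score = number of pairs) is extracted, its genes removed, and the search
repeated until no chain of at least ``min_len`` pairs remains.  Ties are
resolved deterministically: parallel before antiparallel, then smaller
starting rank on each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome_io import GenomeModel
from .homology import HitSet

__all__ = [
    "CollinearBlock",
    "BlockSet",
    "CensusResult",
    "chain_blocks",
    "detect_all_blocks",
    "census",
    "write_blocks",
    "read_blocks",
    "DEFAULT_MAX_GAP",
    "DEFAULT_MIN_LEN",
    "DEFAULT_TANDEM_GAP",
]

DEFAULT_MAX_GAP = 50
DEFAULT_MIN_LEN = 5
DEFAULT_TANDEM_GAP = 5


@dataclass
class CollinearBlock:
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "parallel" | "antiparallel"
    pairs: list[tuple[str, str, int, int]]  # (gene_a, gene_b, rank_a, rank_b)
    median_ks: float | None = None
    ks_values: list[float | None] | None = None  # per pair, None = saturated
    event: str | None = None

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def ref_span(self) -> tuple[int, int]:
        """(min, max) rank on the a-axis."""
        ranks = [p[2] for p in self.pairs]
        return min(ranks), max(ranks)


@dataclass
class BlockSet:
    mode: str  # "intra" | "inter"
    genome_a: str
    genome_b: str
    blocks: list[CollinearBlock] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.blocks)


def _longest_chain(points: list[tuple[int, int]], max_gap: int
                   ) -> list[tuple[int, int]]:
    """Longest strictly-increasing chain (both axes, gaps in [1, max_gap]).

    Points must be unique.  Reconstruction is deterministic: among optimal
    chains the smallest (rank_a, rank_b) start is chosen, and each step
    takes the smallest valid successor.
    """
    if not points:
        return []
    pts = sorted(points)
    n = len(pts)

    def can_follow(i: int, j: int) -> bool:
        da = pts[j][0] - pts[i][0]
        db = pts[j][1] - pts[i][1]
        return 1 <= da <= max_gap and 1 <= db <= max_gap

    # g[i] = length of longest valid chain starting at i
    g = [1] * n
    for i in range(n - 2, -1, -1):
        best = 0
        for j in range(i + 1, n):
            if pts[j][0] - pts[i][0] > max_gap:
                break
            if can_follow(i, j) and g[j] > best:
                best = g[j]
        g[i] = 1 + best
    total = max(g)
    start = min(i for i in range(n) if g[i] == total)
    chain = [pts[start]]
    cur, remaining = start, total - 1
    while remaining:
        nxt = min(j for j in range(cur + 1, n)
                  if g[j] == remaining and can_follow(cur, j))
        chain.append(pts[nxt])
        cur, remaining = nxt, remaining - 1
    return chain


def chain_blocks(points: list[tuple[int, int]],
                 max_gap: int = DEFAULT_MAX_GAP,
                 min_len: int = DEFAULT_MIN_LEN
                 ) -> list[tuple[str, list[tuple[int, int]]]]:
    """Iteratively extract collinear chains from (rank_a, rank_b) points.

    Returns ``(orientation, chain)`` tuples in extraction order; chains are
    in ascending rank_a.  After each extraction every point sharing a rank
    (a gene) with the chain on either axis is removed.
    """
    if max_gap < 1 or min_len < 2:
        raise ValueError("require max_gap >= 1 and min_len >= 2")
    remaining = sorted(set(points))
    out: list[tuple[str, list[tuple[int, int]]]] = []
    while remaining:
        par = _longest_chain(remaining, max_gap)
        mirrored = [(ra, -rb) for ra, rb in remaining]
        anti_m = _longest_chain(mirrored, max_gap)
        anti = [(ra, -rb) for ra, rb in anti_m]
        # prefer parallel, then smaller starting rank_a, then rank_b
        cand = []
        if par:
            cand.append((-len(par), 0, par[0][0], par[0][1], "parallel", par))
        if anti:
            cand.append((-len(anti), 1, anti[0][0], anti[0][1],
                         "antiparallel", anti))
        cand.sort(key=lambda c: c[:4])
        _, _, _, _, orientation, chain = cand[0]
        if len(chain) < min_len:
            break
        out.append((orientation, chain))
        used_a = {ra for ra, _ in chain}
        used_b = {rb for _, rb in chain}
        remaining = [(ra, rb) for ra, rb in remaining
                     if ra not in used_a and rb not in used_b]
    return out


def _collapse_tandem(points: dict[tuple[int, int], float],
                     tandem_gap: int) -> dict[tuple[int, int], float]:
    """Collapse tandem arrays: consecutive same-axis genes (rank distance
    <= tandem_gap) hitting the same partner keep only the strongest hit."""

    def collapse(axis: int) -> None:
        groups: dict[int, list[tuple[int, int]]] = {}
        for pt in points:
            groups.setdefault(pt[1 - axis], []).append(pt)
        for partner, pts in groups.items():
            pts.sort(key=lambda p: p[axis])
            run = [pts[0]]
            runs = []
            for pt in pts[1:]:
                if pt[axis] - run[-1][axis] <= tandem_gap:
                    run.append(pt)
                else:
                    runs.append(run)
                    run = [pt]
            runs.append(run)
            for run in runs:
                if len(run) > 1:
                    keep = max(run, key=lambda p: (points[p], -p[axis]))
                    for pt in run:
                        if pt != keep:
                            del points[pt]

    points = dict(points)
    collapse(0)
    collapse(1)
    return points


def detect_all_blocks(hs: HitSet, a: GenomeModel, b: GenomeModel,
                      max_gap: int = DEFAULT_MAX_GAP,
                      min_len: int = DEFAULT_MIN_LEN,
                      tandem_gap: int = DEFAULT_TANDEM_GAP) -> BlockSet:
    """Chain blocks for every chromosome pair with retained hits.

    Intra-genome mode drops self pairs, folds mirrored hits onto a single
    canonical orientation (chromosome pair sorted; upper triangle on a
    self-pair), and collapses tandem arrays before chaining.
    """
    if hs.genome_a != a.name or hs.genome_b != b.name:
        raise ValueError(
            f"hit set names ({hs.genome_a}, {hs.genome_b}) do not match "
            f"genomes ({a.name}, {b.name})"
        )
    intra = hs.mode == "intra"
    loc_a = {g.gene_id: (g.chromosome, g.rank) for g in a.genes.values()}
    loc_b = {g.gene_id: (g.chromosome, g.rank) for g in b.genes.values()}

    per_pair: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    gene_of: dict[tuple[str, str], dict[tuple[int, int], tuple[str, str]]] = {}
    for h in hs.hits:
        ga, gb = h.query_gene, h.subject_gene
        if not intra and ga not in loc_a:
            ga, gb = gb, ga  # hit from the reverse query direction
        ca, ra = loc_a[ga]
        cb, rb = loc_b[gb]
        if intra:
            if ga == gb:
                continue
            if (ca, ra) > (cb, rb):
                ca, ra, cb, rb, ga, gb = cb, rb, ca, ra, gb, ga
        key = (ca, cb)
        pts = per_pair.setdefault(key, {})
        if h.bit_score > pts.get((ra, rb), float("-inf")):
            pts[(ra, rb)] = h.bit_score
            gene_of.setdefault(key, {})[(ra, rb)] = (ga, gb)

    bs = BlockSet("intra" if intra else "inter", a.name, b.name,
                  params=dict(max_gap=max_gap, min_len=min_len,
                              tandem_gap=tandem_gap))
    for (ca, cb) in sorted(per_pair):
        pts = per_pair[(ca, cb)]
        if intra:
            pts = _collapse_tandem(pts, tandem_gap)
        chains = chain_blocks(list(pts), max_gap, min_len)
        names = gene_of[(ca, cb)]
        for orientation, chain in chains:
            pairs = [(*names[pt], *pt) for pt in chain]
            bs.blocks.append(CollinearBlock(
                a.name, b.name, ca, cb, orientation, pairs))
    return bs


@dataclass
class CensusResult:
    """Block counts and colinear pair totals above length thresholds."""

    per_threshold: dict[int, tuple[int, int]]  # t -> (blocks, pairs)
    largest: tuple[int, str, str] | None  # (length, chrom_a, chrom_b)


def census(bs: BlockSet, thresholds=(4, 10, 20, 50)) -> CensusResult:
    """Count blocks longer than each threshold and sum their pair counts."""
    per: dict[int, tuple[int, int]] = {}
    for t in thresholds:
        big = [b for b in bs.blocks if b.length > t]
        per[t] = (len(big), sum(b.length for b in big))
    largest = None
    if bs.blocks:
        top = max(bs.blocks, key=lambda b: (b.length, b.chrom_a, b.chrom_b))
        largest = (top.length, top.chrom_a, top.chrom_b)
    return CensusResult(per, largest)


def write_blocks(bs: BlockSet, path) -> None:
    """Tab-separated block file: a header line per block, then its pairs."""
    with open(path, "w") as out:
        out.write(f"##mode={bs.mode}\tgenome_a={bs.genome_a}\t"
                  f"genome_b={bs.genome_b}\n")
        for i, b in enumerate(bs.blocks):
            med = "" if b.median_ks is None else f"{b.median_ks:.6f}"
            out.write(f"#block\t{i}\t{b.chrom_a}\t{b.chrom_b}\t"
                      f"{b.orientation}\t{b.length}\t{med}\t{b.event or ''}\n")
            ks = b.ks_values or [None] * b.length
            for (ga, gb, ra, rb), k in zip(b.pairs, ks):
                kss = "" if k is None else f"{k:.6f}"
                out.write(f"{ga}\t{gb}\t{ra}\t{rb}\t{kss}\n")


def read_blocks(path) -> BlockSet:
    """Read a block file written by :func:`write_blocks`."""
    bs = None
    block = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                meta = dict(f.split("=", 1) for f in line[2:].split("\t"))
                bs = BlockSet(meta["mode"], meta["genome_a"], meta["genome_b"])
            elif line.startswith("#block"):
                _, _, ca, cb, orient, _, med, event = line.split("\t")
                block = CollinearBlock(
                    bs.genome_a, bs.genome_b, ca, cb, orient, [],
                    median_ks=float(med) if med else None,
                    ks_values=[], event=event or None)
                bs.blocks.append(block)
            elif line:
                ga, gb, ra, rb, ks = line.split("\t")
                block.pairs.append((ga, gb, int(ra), int(rb)))
                block.ks_values.append(float(ks) if ks else None)
    if bs is None:
        raise ValueError("empty block file")
    return bs
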