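"""The hierarchical nine-column event-related gene table.

Every reference gene anchors one row.  The layout encodes both
polyploidy layers inferred upstream::

    [refA, polA1, polA2,  refB, polB1, polB2,  refC, polC1, polC2]

column 0 is the anchor; columns 1-2 are its two derived-genome ortholog
copies (post-WGD subgenome columns); columns 3 and 6 are the anchor's two
WGT homoeologs within the reference genome; columns 4-5 and 7-8 are those
homoeologs' own derived ortholog copies.  A missing relation holds the
literal marker ``.``.  Within every non-anchor column a gene ID appears at
most once: competing claims are resolved by block strength (more pairs,
then lower median Ks, then lexicographic), the loser becoming ``.`` with a
counted conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .collinearity import BlockSet, CollinearBlock
from .genome_io import GenomeModel

__all__ = [
    "MISSING",
    "COLUMN_LAYERS",
    "AlignmentRow",
    "AlignmentTable",
    "build_table",
    "fill_rate",
    "write_table",
    "read_table",
]

log = logging.getLogger(__name__)

MISSING = "."
COLUMN_LAYERS = (
    ("ref", "anchor"),
    ("derived", "ortholog_copy1"), ("derived", "ortholog_copy2"),
    ("ref", "homoeolog_b"),
    ("derived", "homoeolog_b_copy1"), ("derived", "homoeolog_b_copy2"),
    ("ref", "homoeolog_c"),
    ("derived", "homoeolog_c_copy1"), ("derived", "homoeolog_c_copy2"),
)


@dataclass
class AlignmentRow:
    anchor: str
    chromosome: str | None
    rank: int
    cells: list[str]  # 9 entries, cells[0] == anchor


@dataclass
class AlignmentTable:
    ref_name: str
    derived_name: str
    rows: list[AlignmentRow] = field(default_factory=list)
    n_conflicts: int = 0

    def __len__(self) -> int:
        return len(self.rows)


def _strength(b: CollinearBlock):
    """Block comparison key: more pairs, then lower median Ks, then stable."""
    med = b.median_ks if b.median_ks is not None else float("inf")
    return (b.length, -med, b.chrom_b, b.ref_span)


def _resolve_column(claims: dict[str, tuple[tuple, str]]) -> tuple[dict, int]:
    """anchor -> (strength, target); enforce one target per column.

    Returns (anchor -> target map, number of displaced claims)."""
    best_for_target: dict[str, tuple[tuple, str]] = {}
    for anchor in sorted(claims):
        s, target = claims[anchor]
        cur = best_for_target.get(target)
        if cur is None or (s, _lex_inv(anchor)) > (cur[0], _lex_inv(cur[1])):
            best_for_target[target] = (s, anchor)
    resolved = {anchor: target for target, (_, anchor)
                in best_for_target.items()}
    return resolved, len(claims) - len(resolved)


class _lex_inv(str):
    """Inverted lexicographic order (so max() prefers the smaller ID)."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _ortholog_maps(inter_blocks: BlockSet) -> tuple[dict, dict, int]:
    """Per-copy resolved anchor->derived maps from ortholog blocks."""
    from .fractionation import assign_copy_columns

    copy_sets = assign_copy_columns(inter_blocks)
    conflicts = 0
    maps: list[dict[str, str]] = []
    for copy_idx in (0, 1):
        claims: dict[str, tuple[tuple, str]] = {}
        for chrom in sorted(copy_sets):
            for b in copy_sets[chrom][copy_idx]:
                s = _strength(b)
                for ga, gb, _, _ in b.pairs:
                    if ga not in claims or s > claims[ga][0]:
                        claims[ga] = (s, gb)
        resolved, n = _resolve_column(claims)
        conflicts += n
        maps.append(resolved)
    return maps[0], maps[1], conflicts


def _homoeolog_maps(intra_blocks: BlockSet) -> tuple[dict, dict, int]:
    """Resolved anchor -> (refB, refC) maps from WGT paralog blocks.

    Each anchor takes its two strongest distinct homoeolog partners; the
    assignment to the B and C columns is coordinated across the anchors of
    a triplet (trying both cell orders per anchor) so that the two columns
    stay injective — anchors a/b/c of one triplet place their partners
    cyclically rather than all claiming the same gene.  An anchor whose
    partners are exhausted in a column leaves ``.`` with a counted
    conflict.
    """
    candidates: dict[str, list[tuple[tuple, str]]] = {}
    for b in intra_blocks.blocks:
        if b.event != "WGT_paralog":
            continue
        s = _strength(b)
        for ga, gb, _, _ in b.pairs:
            candidates.setdefault(ga, []).append((s, gb))
            candidates.setdefault(gb, []).append((s, ga))
    map_b: dict[str, str] = {}
    map_c: dict[str, str] = {}
    used_b: set[str] = set()
    used_c: set[str] = set()
    conflicts = 0
    for anchor in sorted(candidates):
        cands = sorted(candidates[anchor],
                       key=lambda c: (c[0], _lex_inv(c[1])), reverse=True)
        top: list[str] = []
        for _, partner in cands:
            if partner not in top:
                top.append(partner)
            if len(top) == 2:
                break
        if len(top) == 1:
            options = [(top[0], None), (None, top[0])]
        else:
            options = [(top[0], top[1]), (top[1], top[0])]

        def filled(opt):
            b_gene, c_gene = opt
            score = 0
            if b_gene is not None and b_gene not in used_b:
                score += 1
            if c_gene is not None and c_gene not in used_c:
                score += 1
            return score

        best = max(options, key=filled)  # ties keep strength order
        b_gene, c_gene = best
        want = sum(1 for g in best if g is not None)
        got = 0
        if b_gene is not None and b_gene not in used_b:
            map_b[anchor] = b_gene
            used_b.add(b_gene)
            got += 1
        if c_gene is not None and c_gene not in used_c:
            map_c[anchor] = c_gene
            used_c.add(c_gene)
            got += 1
        conflicts += want - got
    return map_b, map_c, conflicts


def build_table(ref: GenomeModel, inter_blocks: BlockSet,
                intra_blocks: BlockSet) -> AlignmentTable:
    """Assemble the nine-column table from labeled block sets.

    ``inter_blocks`` must carry ortholog/outparalog labels (reference on
    the a-axis); ``intra_blocks`` are the reference genome's labeled
    intra-genome blocks, of which the WGT paralog blocks supply the
    homoeolog columns.
    """
    orth1, orth2, c1 = _ortholog_maps(inter_blocks)
    hom_b, hom_c, c2 = _homoeolog_maps(intra_blocks)
    conflicts = c1 + c2
    if conflicts:
        log.info("alignment table: %d displaced claims resolved by block "
                 "strength", conflicts)

    table = AlignmentTable(inter_blocks.genome_a, inter_blocks.genome_b,
                           n_conflicts=conflicts)
    for chrom in ref.chromosomes:
        for g in ref.genes_on(chrom):
            cells = [g.gene_id] + [MISSING] * 8
            cells[1] = orth1.get(g.gene_id, MISSING)
            cells[2] = orth2.get(g.gene_id, MISSING)
            for base, hmap in ((3, hom_b), (6, hom_c)):
                hom = hmap.get(g.gene_id)
                if hom is not None:
                    cells[base] = hom
                    cells[base + 1] = orth1.get(hom, MISSING)
                    cells[base + 2] = orth2.get(hom, MISSING)
            table.rows.append(AlignmentRow(g.gene_id, chrom, g.rank, cells))
    return table


def fill_rate(t: AlignmentTable) -> list[float]:
    """Per-column fraction of non-missing cells (column 0 is always 1.0)."""
    if not t.rows:
        raise ValueError("empty alignment table")
    n = len(t.rows)
    return [
        sum(1 for row in t.rows if row.cells[col] != MISSING) / n
        for col in range(9)
    ]


def write_table(t: AlignmentTable, path) -> None:
    """Nine-column TSV; chromosome breaks as comment lines."""
    with open(path, "w") as out:
        out.write(f"##ref={t.ref_name}\tderived={t.derived_name}\n")
        out.write("#" + "\t".join(f"{g}:{layer}"
                                  for g, layer in COLUMN_LAYERS) + "\n")
        current = None
        for row in t.rows:
            if row.chromosome != current:
                current = row.chromosome
                out.write(f"#chromosome\t{current}\n")
            out.write("\t".join(row.cells) + "\n")


def read_table(path) -> AlignmentTable:
    """Round-trip reader for :func:`write_table` output."""
    table = None
    chrom = None
    rank = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                meta = dict(f.split("=", 1) for f in line[2:].split("\t"))
                table = AlignmentTable(meta["ref"], meta["derived"])
            elif line.startswith("#chromosome"):
                chrom = line.split("\t")[1]
                rank = 0
            elif line.startswith("#") or not line:
                continue
            else:
                cells = line.split("\t")
                if len(cells) != 9:
                    raise ValueError(f"expected 9 columns, got {len(cells)}")
                table.rows.append(AlignmentRow(cells[0], chrom, rank, cells))
                rank += 1
    if table is None:
        raise ValueError("empty alignment table file")
    return table
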