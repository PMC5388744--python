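"""Post-polyploidy gene-loss (fractionation) statistics.

With the reference genome as anchor, each reference gene expects two
surviving ortholog copies in the derived (post-WGD) genome.  This module
partitions the ortholog blocks of each reference chromosome into the two
copy columns, computes per-chromosome deletion rates for each copy (and
for both jointly), and summarises the copy-to-copy loss-rate difference —
the statistic whose genome-wide uniformity is the signature of balanced
(auto-polyploid-like) fractionation.  An ingest mode reads externally
printed loss tables verbatim and skips set-consistency checks, since
published tables do not always follow strict set semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

from .alignment_table import MISSING, AlignmentTable
from .collinearity import BlockSet, CollinearBlock

__all__ = [
    "LossRow",
    "LossSummary",
    "assign_copy_columns",
    "per_chromosome_rates",
    "summarize_loss_table",
    "retention_categories",
    "load_loss_table",
    "load_printed_loss_table",
    "write_loss_table",
    "DEFAULT_DIFF_THRESHOLD",
]

log = logging.getLogger(__name__)

DEFAULT_DIFF_THRESHOLD = 0.05
_EPS = 1e-9


@dataclass(frozen=True)
class LossRow:
    """Per-reference-chromosome deletion rates of the two derived copies."""

    chromosome: str
    gene_count: int
    lost1: float
    lost2: float
    both_lost: float
    diff: float


@dataclass(frozen=True)
class LossSummary:
    mean_diff: float
    threshold: float
    n_diff_le_threshold: int
    max_diff: float
    max_diff_chromosome: str
    min_lost: float
    max_lost: float
    min_both_lost: float
    max_both_lost: float
    retention: dict | None = None  # {"both", "one", "none"} fractions


def _block_strength(b: CollinearBlock):
    med = b.median_ks if b.median_ks is not None else float("inf")
    return (b.length, -med, b.chrom_b, b.ref_span)


def _overlaps(s1: tuple[int, int], s2: tuple[int, int]) -> bool:
    return s1[0] <= s2[1] and s2[0] <= s1[1]


def assign_copy_columns(inter_blocks: BlockSet
                        ) -> dict[str, tuple[list, list, list]]:
    """Bipartition each reference chromosome's ortholog blocks into copies.

    Blocks are taken strongest-first; a block overlapping (on reference
    ranks) blocks already placed in one copy goes to the other; a block
    overlapping both copies is demoted to unplaced with a warning.  Copy 1
    is the side with more total colinear genes.  Returns per reference
    chromosome ``(copy1_blocks, copy2_blocks, unplaced)``.
    """
    by_chrom: dict[str, list[CollinearBlock]] = {}
    for b in inter_blocks.blocks:
        if b.event == "ortholog":
            by_chrom.setdefault(b.chrom_a, []).append(b)
    out: dict[str, tuple[list, list, list]] = {}
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=_block_strength, reverse=True)
        sets: tuple[list, list] = ([], [])
        unplaced: list[CollinearBlock] = []
        for b in ordered:
            clash = [any(_overlaps(b.ref_span, o.ref_span) for o in s)
                     for s in sets]
            if not clash[0]:
                sets[0].append(b)
            elif not clash[1]:
                sets[1].append(b)
            else:
                log.warning(
                    "chromosome %s: block %s-%s overlaps both copy sets; "
                    "demoted to unplaced", chrom, b.chrom_a, b.chrom_b)
                unplaced.append(b)
        if sum(b.length for b in sets[1]) > sum(b.length for b in sets[0]):
            sets = (sets[1], sets[0])
        out[chrom] = (sets[0], sets[1], unplaced)
    return out


def per_chromosome_rates(t: AlignmentTable) -> list[LossRow]:
    """Deletion rates from the ortholog copy columns (cells 1 and 2).

    Fractions are kept at full precision; rounding (2 decimals) happens
    only when a table is written out.
    """
    by_chrom: dict[str, list] = {}
    for row in t.rows:
        by_chrom.setdefault(row.chromosome, []).append(row)
    rows = []
    for chrom, anchors in by_chrom.items():
        n = len(anchors)
        if n == 0:
            log.warning("chromosome %s has no anchors; excluded", chrom)
            continue
        l1 = sum(1 for r in anchors if r.cells[1] == MISSING) / n
        l2 = sum(1 for r in anchors if r.cells[2] == MISSING) / n
        both = sum(1 for r in anchors
                   if r.cells[1] == MISSING and r.cells[2] == MISSING) / n
        rows.append(LossRow(chrom, n, l1, l2, both, abs(l1 - l2)))
    return rows


def summarize_loss_table(rows: list[LossRow],
                         threshold: float = DEFAULT_DIFF_THRESHOLD,
                         retention: dict | None = None) -> LossSummary:
    """Genome-wide summary of the copy-to-copy loss-rate differences."""
    if not rows:
        raise ValueError("empty loss table")
    diffs = [r.diff for r in rows]
    top = max(rows, key=lambda r: (r.diff, r.chromosome))
    lost = [r.lost1 for r in rows] + [r.lost2 for r in rows]
    both = [r.both_lost for r in rows]
    return LossSummary(
        mean_diff=sum(diffs) / len(diffs),
        threshold=threshold,
        n_diff_le_threshold=sum(1 for d in diffs if d <= threshold + _EPS),
        max_diff=top.diff,
        max_diff_chromosome=top.chromosome,
        min_lost=min(lost),
        max_lost=max(lost),
        min_both_lost=min(both),
        max_both_lost=max(both),
        retention=retention,
    )


def retention_categories(t: AlignmentTable) -> dict[str, float]:
    """Fractions of anchors with both / one / no ortholog copies present."""
    if not t.rows:
        raise ValueError("empty alignment table")
    counts = {"both": 0, "one": 0, "none": 0}
    for row in t.rows:
        present = sum(1 for c in (row.cells[1], row.cells[2]) if c != MISSING)
        counts[("none", "one", "both")[present]] += 1
    n = len(t.rows)
    return {k: v / n for k, v in counts.items()}


def write_loss_table(rows: list[LossRow], path) -> None:
    """Loss-rate TSV in the printed layout (rates rounded to 2 decimals)."""
    with open(path, "w") as out:
        out.write("chromosome\tgenes\tparalog1_lost\tparalog2_lost\t"
                  "both_lost\tdiff\n")
        for r in rows:
            out.write(f"{r.chromosome}\t{r.gene_count}\t{r.lost1:.2f}\t"
                      f"{r.lost2:.2f}\t{r.both_lost:.2f}\t{r.diff:.2f}\n")


def load_loss_table(source) -> list[LossRow]:
    """Ingest an externally supplied loss table (no set-consistency checks).

    Expects the columns written by :func:`write_loss_table`; the printed
    ``diff`` column is taken verbatim when present, else recomputed.
    """
    rows = []
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    for line in lines:
        if not line.strip() or line.lower().startswith("chromosome"):
            continue
        fields = line.split("\t")
        chrom, genes, l1, l2, both = fields[:5]
        l1, l2, both = float(l1), float(l2), float(both)
        diff = float(fields[5]) if len(fields) > 5 and fields[5] != "" \
            else abs(l1 - l2)
        rows.append(LossRow(chrom, int(genes), l1, l2, both, diff))
    if not rows:
        raise ValueError("no loss rows parsed")
    return rows


def load_printed_loss_table() -> list[LossRow]:
    """The packaged 19-chromosome grape-referenced poplar deletion table."""
    ref = resources.files("synfrac.data") / "poplar_grape_loss_table.tsv"
    with ref.open() as fh:
        return load_loss_table(fh)
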