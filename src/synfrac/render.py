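"""Dot-plot rendering as deterministic SVG.

Axes are in gene-rank space (cumulative over the selected chromosomes),
which keeps the plot free of assembly gaps.  One point element is drawn
per retained hit, coloured by match rank (best = red, second = blue,
other = gray); every Ks-dated block gets an outline rectangle and a
median-Ks annotation coloured by its position relative to the event
windows (younger side red, older side blue).  Identical inputs produce
identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .collinearity import BlockSet
from .events import EventWindows
from .genome_io import GenomeModel
from .homology import HitSet

__all__ = ["DotPlotSpec", "render_dotplot"]

_RANK_COLORS = {"best": "red", "second": "blue", "other": "gray",
                None: "gray"}
_CELL = 4  # pixels per gene rank


@dataclass
class DotPlotSpec:
    genome_x: GenomeModel
    genome_y: GenomeModel
    chroms_x: list[str] | None = None  # None = all chromosomes
    chroms_y: list[str] | None = None
    windows: EventWindows = field(default_factory=EventWindows)


def _axis_offsets(genome: GenomeModel, chroms: list[str] | None
                  ) -> tuple[dict[str, int], int]:
    chroms = list(chroms) if chroms else list(genome.chromosomes)
    for c in chroms:
        if c not in genome.chromosomes:
            raise ValueError(f"genome {genome.name!r} has no chromosome {c!r}")
    offsets = {}
    total = 0
    for c in chroms:
        offsets[c] = total
        total += len(genome.genes_on(c))
    if total == 0:
        raise ValueError("empty chromosome selection")
    return offsets, total


def render_dotplot(hs: HitSet, bs: BlockSet, spec: DotPlotSpec) -> str:
    """Render hits and Ks-dated blocks for the selected chromosomes."""
    off_x, nx = _axis_offsets(spec.genome_x, spec.chroms_x)
    off_y, ny = _axis_offsets(spec.genome_y, spec.chroms_y)
    loc_x = {g.gene_id: (g.chromosome, g.rank)
             for g in spec.genome_x.genes.values()}
    loc_y = {g.gene_id: (g.chromosome, g.rank)
             for g in spec.genome_y.genes.values()}
    w, h = nx * _CELL + 40, ny * _CELL + 40
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        f'<rect x="20" y="20" width="{nx * _CELL}" height="{ny * _CELL}" '
        'fill="white" stroke="black"/>',
    ]
    for c, o in sorted(off_x.items()):
        if o:
            parts.append(f'<line x1="{20 + o * _CELL}" y1="20" '
                         f'x2="{20 + o * _CELL}" y2="{20 + ny * _CELL}" '
                         'stroke="lightgray"/>')
    for c, o in sorted(off_y.items()):
        if o:
            parts.append(f'<line x1="20" y1="{20 + o * _CELL}" '
                         f'x2="{20 + nx * _CELL}" y2="{20 + o * _CELL}" '
                         'stroke="lightgray"/>')
    for hit in hs.hits:
        cx, rx = loc_x.get(hit.query_gene, (None, None))
        cy, ry = loc_y.get(hit.subject_gene, (None, None))
        if cx not in off_x or cy not in off_y:
            continue
        x = 20 + (off_x[cx] + rx) * _CELL + _CELL // 2
        y = 20 + (off_y[cy] + ry) * _CELL + _CELL // 2
        parts.append(f'<circle class="hit" cx="{x}" cy="{y}" r="1.5" '
                     f'fill="{_RANK_COLORS[hit.rank_class]}"/>')
    split = (spec.windows.speciation[0] + spec.windows.wgt[0]) / 2.0
    for b in bs.blocks:
        if b.median_ks is None:
            continue
        if b.chrom_a not in off_x or b.chrom_b not in off_y:
            continue
        ra = [p[2] for p in b.pairs]
        rb = [p[3] for p in b.pairs]
        x0 = 20 + (off_x[b.chrom_a] + min(ra)) * _CELL
        y0 = 20 + (off_y[b.chrom_b] + min(rb)) * _CELL
        bw = (max(ra) - min(ra) + 1) * _CELL
        bh = (max(rb) - min(rb) + 1) * _CELL
        color = "red" if b.median_ks <= split else "blue"
        parts.append(f'<rect class="block" x="{x0}" y="{y0}" width="{bw}" '
                     f'height="{bh}" fill="none" stroke="{color}"/>')
        parts.append(f'<text class="ks" x="{x0}" y="{y0 - 2}" font-size="8" '
                     f'fill="{color}">{b.median_ks:.2f}</text>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
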