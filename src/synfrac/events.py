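"""Assign collinear blocks to evolutionary events from block-median Ks.

Three dating windows (centre ± half-width, configurable) correspond to the
three divergence events visible in the Ks distribution: the lineage-specific
whole-genome duplication (WGD, 0.3 ± 0.1), the speciation split
(0.9 ± 0.15), and the eudicot-common whole-genome triplication (WGT,
1.3 ± 0.3).  Intra-genome blocks are dated as WGD or WGT paralogy;
inter-genome blocks become orthologs (speciation window) or outparalogs
(WGT window).  Where the speciation and WGT windows overlap, the nearer
centre wins.  For orthology the expected 1:2 reference-to-derived region
ratio is used as a consistency check: per reference chromosome the
candidate partner regions are ranked by colinear-gene count and a block
whose rank-based expectation disagrees with its Ks label is logged as a
conflict — Ks wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .collinearity import BlockSet

__all__ = [
    "EventWindows",
    "EVENT_LABELS",
    "ks_peaks",
    "assign_intra_events",
    "assign_orthology",
]

log = logging.getLogger(__name__)

EVENT_LABELS = ("WGD_paralog", "WGT_paralog", "ortholog", "outparalog",
                "unassigned")


@dataclass(frozen=True)
class EventWindows:
    """Ks dating windows as (centre, half-width) per event."""

    wgd: tuple[float, float] = (0.3, 0.1)
    speciation: tuple[float, float] = (0.9, 0.15)
    wgt: tuple[float, float] = (1.3, 0.3)

    def __post_init__(self):
        centers = [self.wgd[0], self.speciation[0], self.wgt[0]]
        if not all(c > 0 for c in centers):
            raise ValueError("window centres must be positive")
        if sorted(centers) != centers or len(set(centers)) != 3:
            raise ValueError("windows must be ordered wgd < speciation < wgt")

    def _nearest(self, ks: float, names: list[str]) -> str:
        centers = {"wgd": self.wgd[0], "speciation": self.speciation[0],
                   "wgt": self.wgt[0]}
        return min(names, key=lambda n: (abs(ks - centers[n]), n))

    def classify(self, ks: float | None) -> str | None:
        """Window name for a median Ks, or None when outside all windows."""
        if ks is None:
            return None
        inside = [
            name for name, (c, w) in
            (("wgd", self.wgd), ("speciation", self.speciation),
             ("wgt", self.wgt))
            if c - w <= ks <= c + w
        ]
        if not inside:
            return None
        if len(inside) == 1:
            return inside[0]
        return self._nearest(ks, inside)


def ks_peaks(medians, bin_width: float = 0.05) -> list[float]:
    """Locate peaks of the block-median Ks distribution.

    Histogram at ``bin_width``, 3-bin moving-average smoothing, then local
    maxima (strictly above the previous bin, at least the next) returned as
    ascending bin centres.
    """
    values = np.asarray([m for m in medians if m is not None], dtype=float)
    if values.size == 0:
        raise ValueError("no defined block medians to locate peaks in")
    hi = float(values.max()) + bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    peaks: list[float] = []
    n = len(smooth)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and smooth[j + 1] == smooth[i]:
            j += 1
        left = smooth[i - 1] if i > 0 else -1.0
        right = smooth[j + 1] if j + 1 < n else -1.0
        if smooth[i] > left and smooth[i] > right:
            # within a smoothed plateau, report the densest raw bin
            k = i + int(np.argmax(counts[i:j + 1]))
            peaks.append(float(edges[k] + edges[k + 1]) / 2.0)
        i = j + 1
    return peaks


def assign_intra_events(bs: BlockSet, windows: EventWindows = EventWindows()
                        ) -> BlockSet:
    """Label intra-genome blocks WGD_paralog / WGT_paralog / unassigned."""
    if bs.mode != "intra":
        raise ValueError("assign_intra_events expects an intra-genome BlockSet")
    label_of = {"wgd": "WGD_paralog", "wgt": "WGT_paralog",
                "speciation": "unassigned", None: "unassigned"}
    out = BlockSet(bs.mode, bs.genome_a, bs.genome_b, params=dict(bs.params))
    out.blocks = [
        replace(b, event=label_of[windows.classify(b.median_ks)])
        for b in bs.blocks
    ]
    return out


def assign_orthology(bs: BlockSet, windows: EventWindows = EventWindows(),
                     duplication_factor: int = 2) -> BlockSet:
    """Label inter-genome blocks ortholog / outparalog / unassigned.

    The reference genome is the a-axis.  Per reference chromosome the
    candidate partner regions (blocks) are ranked by colinear-gene count;
    the top ``duplication_factor`` are expected orthologous and the next
    ``2 * duplication_factor`` out-paralogous.  The final label comes from
    the Ks window; rank/Ks disagreements are logged and recorded in
    ``BlockSet.params['orthology_conflicts']``.
    """
    if bs.mode != "inter":
        raise ValueError("assign_orthology expects an inter-genome BlockSet")
    label_of = {"speciation": "ortholog", "wgt": "outparalog",
                "wgd": "unassigned", None: "unassigned"}
    labeled = [
        replace(b, event=label_of[windows.classify(b.median_ks)])
        for b in bs.blocks
    ]
    conflicts = []
    by_chrom: dict[str, list] = {}
    for b in labeled:
        by_chrom.setdefault(b.chrom_a, []).append(b)
    for chrom in sorted(by_chrom):
        ranked = sorted(by_chrom[chrom],
                        key=lambda b: (-b.length, b.chrom_b, b.ref_span))
        for pos, b in enumerate(ranked):
            expected = ("ortholog" if pos < duplication_factor else
                        "outparalog" if pos < 3 * duplication_factor else
                        "unassigned")
            if b.event != expected:
                conflicts.append((chrom, b.chrom_b, pos, expected, b.event))
                log.info(
                    "orthology rank/Ks conflict on %s vs %s: rank %d expects "
                    "%s, Ks says %s (Ks wins)",
                    chrom, b.chrom_b, pos, expected, b.event,
                )
    out = BlockSet(bs.mode, bs.genome_a, bs.genome_b, params=dict(bs.params))
    out.blocks = labeled
    out.params["orthology_conflicts"] = conflicts
    return out
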