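"""End-to-end orchestration of the event-related alignment analysis.

:func:`analyze` runs the in-memory chain
homology -> collinearity -> Ks dating -> event classification ->
nine-column table -> fractionation summary on two loaded genomes;
:func:`run_pipeline` wraps it with simulation/loading, artifact writing
and a content-hash manifest so that reruns on unchanged inputs are
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

from . import alignment_table as at
from . import collinearity as co
from . import events as ev
from . import fractionation as fr
from . import homology as hom
from . import ks as ksmod
from . import render
from .genome_io import GenomeModel, load_annotation, write_genome
from .simulate import SimConfig, SyntheticTruth, simulate, write_truth

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "run_pipeline",
           "load_config", "load_genome_prefix"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "synfrac_out"
    seed: int = 42
    # either simulate ...
    simulate: bool = True
    sim: SimConfig | None = None
    # ... or load from file prefixes (PREFIX.gff3/.cds.fa/.pep.fa)
    ref_prefix: str | None = None
    derived_prefix: str | None = None
    # module parameters (defaults follow the published analysis settings)
    evalue: float = hom.DEFAULT_EVALUE
    top_n: int = hom.DEFAULT_TOP_N
    max_gap: int = co.DEFAULT_MAX_GAP
    min_len: int = co.DEFAULT_MIN_LEN
    tandem_gap: int = co.DEFAULT_TANDEM_GAP
    windows: ev.EventWindows = field(default_factory=ev.EventWindows)
    diff_threshold: float = fr.DEFAULT_DIFF_THRESHOLD
    write_ks_tables: bool = True
    write_plots: bool = True


@dataclass
class PipelineResult:
    ref: GenomeModel
    derived: GenomeModel
    truth: SyntheticTruth | None
    hits_intra_ref: hom.HitSet
    hits_intra_derived: hom.HitSet
    hits_inter: hom.HitSet
    blocks_intra_ref: co.BlockSet
    blocks_intra_derived: co.BlockSet
    blocks_inter: co.BlockSet
    peaks: list[float]
    table: at.AlignmentTable
    loss_rows: list[fr.LossRow]
    retention: dict[str, float]
    summary: fr.LossSummary

    def predicted_pairs(self, label: str, where: str = "any"
                        ) -> set[tuple[str, str]]:
        """Gene pairs of blocks carrying one event label."""
        sources = {
            "intra_ref": [self.blocks_intra_ref],
            "intra_derived": [self.blocks_intra_derived],
            "inter": [self.blocks_inter],
            "any": [self.blocks_intra_ref, self.blocks_intra_derived,
                    self.blocks_inter],
        }[where]
        pairs = set()
        for bs in sources:
            for b in bs.blocks:
                if b.event == label:
                    pairs.update((ga, gb) for ga, gb, _, _ in b.pairs)
        return pairs


def analyze(ref: GenomeModel, derived: GenomeModel,
            cfg: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full in-memory analysis of a reference/derived genome pair."""
    stages = {}
    log.info("stage homology: all-vs-all searches")
    stages["hits_intra_ref"] = hom.rank_hits(
        hom.naive_all_vs_all(ref, ref, cfg.evalue, cfg.top_n))
    stages["hits_intra_derived"] = hom.rank_hits(
        hom.naive_all_vs_all(derived, derived, cfg.evalue, cfg.top_n))
    stages["hits_inter"] = hom.rank_hits(
        hom.naive_all_vs_all(ref, derived, cfg.evalue, cfg.top_n))

    log.info("stage collinearity: DP chaining")
    pairs = {
        "blocks_intra_ref": (stages["hits_intra_ref"], ref, ref),
        "blocks_intra_derived": (stages["hits_intra_derived"],
                                 derived, derived),
        "blocks_inter": (stages["hits_inter"], ref, derived),
    }
    for name, (hs, a, b) in pairs.items():
        bs = co.detect_all_blocks(hs, a, b, cfg.max_gap, cfg.min_len,
                                  cfg.tandem_gap)
        log.info("stage ks: dating %d blocks (%s)", len(bs), name)
        stages[name] = ksmod.annotate_blockset_ks(bs, a, b)

    log.info("stage classify: event windows")
    stages["blocks_intra_ref"] = ev.assign_intra_events(
        stages["blocks_intra_ref"], cfg.windows)
    stages["blocks_intra_derived"] = ev.assign_intra_events(
        stages["blocks_intra_derived"], cfg.windows)
    stages["blocks_inter"] = ev.assign_orthology(
        stages["blocks_inter"], cfg.windows)

    medians = [b.median_ks
               for name in ("blocks_intra_ref", "blocks_intra_derived",
                            "blocks_inter")
               for b in stages[name].blocks if b.median_ks is not None]
    peaks = ev.ks_peaks(medians) if medians else []

    log.info("stage table: nine-column assembly")
    table = at.build_table(ref, stages["blocks_inter"],
                           stages["blocks_intra_ref"])
    loss_rows = sorted(fr.per_chromosome_rates(table),
                       key=lambda r: r.chromosome)
    retention = fr.retention_categories(table)
    summary = fr.summarize_loss_table(loss_rows, cfg.diff_threshold,
                                      retention)
    return PipelineResult(ref, derived, None, stages["hits_intra_ref"],
                          stages["hits_intra_derived"], stages["hits_inter"],
                          stages["blocks_intra_ref"],
                          stages["blocks_intra_derived"],
                          stages["blocks_inter"], peaks, table, loss_rows,
                          retention, summary)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_genome_prefix(prefix: str, name: str | None = None) -> GenomeModel:
    """Load PREFIX.gff3 / PREFIX.cds.fa / PREFIX.pep.fa."""
    return load_annotation(prefix + ".gff3", prefix + ".cds.fa",
                           prefix + ".pep.fa",
                           name or os.path.basename(prefix))


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute the pipeline, write every artifact, return the manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    truth = None
    if cfg.simulate:
        sim_cfg = cfg.sim or SimConfig(seed=cfg.seed)
        log.info("stage simulate: seed %d", sim_cfg.seed)
        ref, derived, truth = simulate(sim_cfg)
        for g in (ref, derived):
            prefix = os.path.join(cfg.outdir, g.name)
            write_genome(g, prefix + ".gff3", prefix + ".cds.fa",
                         prefix + ".pep.fa")
        write_truth(truth, cfg.outdir)
    else:
        if not (cfg.ref_prefix and cfg.derived_prefix):
            raise ValueError(
                "stage load: need ref_prefix and derived_prefix when not "
                "simulating")
        ref = load_genome_prefix(cfg.ref_prefix)
        derived = load_genome_prefix(cfg.derived_prefix)

    res = analyze(ref, derived, cfg)
    res.truth = truth
    out = cfg.outdir

    def path(name):
        return os.path.join(out, name)

    hom.write_hits(res.hits_intra_ref, path("hits_intra_ref.tsv"))
    hom.write_hits(res.hits_intra_derived, path("hits_intra_derived.tsv"))
    hom.write_hits(res.hits_inter, path("hits_inter.tsv"))
    co.write_blocks(res.blocks_intra_ref, path("blocks_intra_ref.tsv"))
    co.write_blocks(res.blocks_intra_derived,
                    path("blocks_intra_derived.tsv"))
    co.write_blocks(res.blocks_inter, path("blocks_inter.tsv"))
    if cfg.write_ks_tables:
        ksmod.write_ks_table(res.blocks_inter, ref, derived,
                             path("ks_inter.tsv"))
    at.write_table(res.table, path("alignment_table.tsv"))
    fr.write_loss_table(res.loss_rows, path("loss_table.tsv"))
    with open(path("summary.json"), "w") as fh:
        summary = asdict(res.summary)
        summary["ks_peaks"] = res.peaks
        summary["census_inter"] = co.census(res.blocks_inter).per_threshold
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if cfg.write_plots:
        svg = render.render_dotplot(
            res.hits_inter, res.blocks_inter,
            render.DotPlotSpec(ref, derived, windows=cfg.windows))
        with open(path("dotplot_inter.svg"), "w") as fh:
            fh.write(svg)

    manifest = {
        name: _sha256(path(name))
        for name in sorted(os.listdir(out))
        if name != "manifest.json" and os.path.isfile(path(name))
    }
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_config(path: str) -> PipelineConfig:
    """Parse a flat key=value config file into a PipelineConfig."""
    cfg = PipelineConfig()
    sim_kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("sim."):
                sim_kwargs[key[4:]] = value
            elif key in ("outdir", "ref_prefix", "derived_prefix"):
                setattr(cfg, key, value)
            elif key in ("seed", "top_n", "max_gap", "min_len", "tandem_gap"):
                setattr(cfg, key, int(value))
            elif key in ("evalue", "diff_threshold"):
                setattr(cfg, key, float(value))
            elif key in ("simulate", "write_ks_tables", "write_plots"):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif key in ("wgd_window", "speciation_window", "wgt_window"):
                c, _, w = value.partition(":")
                name = key.split("_")[0]
                kw = {"wgd": cfg.windows.wgd,
                      "speciation": cfg.windows.speciation,
                      "wgt": cfg.windows.wgt}
                kw[name] = (float(c), float(w))
                cfg.windows = ev.EventWindows(**kw)
            else:
                raise ValueError(f"unknown config key {key!r}")
    if sim_kwargs:
        kw = {}
        for k, v in sim_kwargs.items():
            if k in ("seed", "n_chromosomes", "genes_per_chromosome",
                     "n_fissions", "n_fusions"):
                kw[k] = int(v)
            elif k in ("ks_wgt", "ks_speciation", "ks_wgd", "wgt_loss",
                       "ka_ks_ratio"):
                kw[k] = float(v)
            elif k == "wgd_loss":
                p1, _, p2 = v.partition(",")
                kw[k] = (float(p1), float(p2))
            elif k in ("codon_range",):
                a, _, b = v.partition(",")
                kw[k] = (int(a), int(b))
            elif k in ("ref_name", "derived_name"):
                kw[k] = v
            else:
                raise ValueError(f"unknown sim config key {k!r}")
        cfg.sim = SimConfig(**kw)
    return cfg
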