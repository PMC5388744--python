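"""Genome annotation and sequence ingest.

Reads a GFF3 gene annotation together with per-gene CDS and protein FASTA
files into a validated in-memory :class:`GenomeModel`.  One representative
mRNA is chosen per gene (longest CDS, ties broken by transcript ID), the CDS
is checked to translate exactly to the supplied protein under the standard
genetic code, and genes receive a deterministic 0-based rank along each
chromosome (ascending start, ties by gene ID).  All downstream modules work
in gene-rank space, so rank assignment here is the single source of truth
for gene order.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "GenomeModel",
    "GenomeIOError",
    "load_annotation",
    "subset_chromosome_pair",
    "write_genome",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class GenomeIOError(ValueError):
    """Raised for malformed or inconsistent annotation/sequence input."""


@dataclass(frozen=True)
class GeneModel:
    """A single protein-coding gene: coordinates plus coding sequences.

    ``start``/``end`` are 1-based inclusive (GFF3 native); ``rank`` is the
    0-based order index of the gene along its chromosome.  ``cds`` may carry
    a trailing stop codon; ``protein`` never includes the stop.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int
    cds: str
    protein: str


@dataclass
class GenomeModel:
    """A named genome: ordered chromosomes and rank-ordered genes."""

    name: str
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chromosomes: list[str] = field(default_factory=list)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        """Genes of one chromosome in rank order."""
        if chromosome not in self.chromosomes:
            raise GenomeIOError(
                f"genome {self.name!r} has no chromosome {chromosome!r}"
            )
        found = [g for g in self.genes.values() if g.chromosome == chromosome]
        return sorted(found, key=lambda g: g.rank)

    def __len__(self) -> int:
        return len(self.genes)


def _translate_cds(gene_id: str, cds: str) -> str:
    if len(cds) % 3 != 0:
        raise GenomeIOError(
            f"gene {gene_id}: CDS length {len(cds)} is not divisible by 3"
        )
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise GenomeIOError(f"gene {gene_id}: CDS contains an internal stop codon")
    return aa


def validate_gene_sequences(gene_id: str, cds: str, protein: str) -> str:
    """Check CDS/protein consistency; return the translation.

    The CDS must be a whole number of codons, free of internal stops, and
    translate (standard code, trailing stop stripped) to ``protein``.
    """
    aa = _translate_cds(gene_id, cds.upper())
    if aa != protein.upper().rstrip("*"):
        raise GenomeIOError(
            f"gene {gene_id}: CDS translation does not match supplied protein"
        )
    return aa


def _index_fasta(source) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}


def _assign_ranks(records: list[dict], name: str) -> GenomeModel:
    genome = GenomeModel(name=name)
    by_chrom: dict[str, list[dict]] = {}
    for rec in records:
        by_chrom.setdefault(rec["chromosome"], []).append(rec)
    for chrom in sorted(by_chrom):
        genome.chromosomes.append(chrom)
        ordered = sorted(by_chrom[chrom], key=lambda r: (r["start"], r["gene_id"]))
        for rank, rec in enumerate(ordered):
            gid = rec["gene_id"]
            if gid in genome.genes:
                raise GenomeIOError(f"duplicate gene ID {gid!r}")
            genome.genes[gid] = GeneModel(rank=rank, **rec)
    return genome


def load_annotation(gff_source, cds_fasta_source, protein_fasta_source,
                    name: str) -> GenomeModel:
    """Load a genome from GFF3 + CDS FASTA + protein FASTA.

    One :class:`GeneModel` is produced per ``gene`` feature, using the mRNA
    with the longest summed CDS (ties by transcript ID).  Sequences are
    looked up first under the chosen mRNA ID, then under the gene ID.

    Raises :class:`GenomeIOError` if no genes parse, a sequence is missing,
    a CDS is not a whole number of codons, or translation disagrees with the
    supplied protein.
    """
    try:
        db = gffutils.create_db(
            str(gff_source), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        raise GenomeIOError("no genes parsed from GFF3 input") from None
    cds_seqs = _index_fasta(cds_fasta_source)
    pep_seqs = _index_fasta(protein_fasta_source)

    records = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        best_id = None
        best_len = -1
        for mrna in sorted(mrnas, key=lambda m: m.id):
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS")
            )
            if cds_len > best_len:
                best_len, best_id = cds_len, mrna.id
        keys = [k for k in (best_id, gene.id) if k is not None]
        cds = next((cds_seqs[k] for k in keys if k in cds_seqs), None)
        pep = next((pep_seqs[k] for k in keys if k in pep_seqs), None)
        if cds is None or pep is None:
            raise GenomeIOError(
                f"gene {gene.id}: no CDS/protein sequence found in FASTA input"
            )
        validate_gene_sequences(gene.id, cds, pep)
        records.append(dict(
            gene_id=gene.id, chromosome=gene.seqid, start=gene.start,
            end=gene.end, strand=gene.strand if gene.strand in "+-" else "+",
            cds=cds, protein=pep.upper().rstrip("*"),
        ))
    if not records:
        raise GenomeIOError("no genes parsed from GFF3 input")
    return _assign_ranks(records, name)


def subset_chromosome_pair(a: GenomeModel, chrom_a: str,
                           b: GenomeModel, chrom_b: str
                           ) -> tuple[list[GeneModel], list[GeneModel]]:
    """Rank-ordered gene lists for one chromosome pair (self-pairs allowed)."""
    return a.genes_on(chrom_a), b.genes_on(chrom_b)


def write_genome(genome: GenomeModel, gff_path, cds_path, pep_path) -> None:
    """Write a genome back out as GFF3 plus CDS/protein FASTA.

    Round-trips with :func:`load_annotation`: one gene/mRNA/CDS feature trio
    per gene, sequences keyed by gene ID.
    """
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for chrom in genome.chromosomes:
            for g in genome.genes_on(chrom):
                attrs = f"ID={g.gene_id}"
                base = [g.chromosome, "synfrac", "{}", str(g.start), str(g.end),
                        ".", g.strand, "{}", "{}"]
                gff.write("\t".join(base).format("gene", ".", attrs) + "\n")
                mid = f"{g.gene_id}.1"
                gff.write("\t".join(base).format(
                    "mRNA", ".", f"ID={mid};Parent={g.gene_id}") + "\n")
                gff.write("\t".join(base).format(
                    "CDS", "0", f"ID={mid}.cds;Parent={mid}") + "\n")
    with open(cds_path, "w") as fa:
        for chrom in genome.chromosomes:
            for g in genome.genes_on(chrom):
                fa.write(f">{g.gene_id}\n{g.cds}\n")
    with open(pep_path, "w") as fa:
        for chrom in genome.chromosomes:
            for g in genome.genes_on(chrom):
                fa.write(f">{g.gene_id}\n{g.protein}\n")
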