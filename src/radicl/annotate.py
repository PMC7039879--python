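"""Gene models, biotype groups, feature assignment, repeats, promoters.

Tags are assigned to features by their single-nucleotide center; strand is
honoured for RNA tags and ignored for DNA tags.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

from .core import Interval

__all__ = [
    "GeneModel",
    "GeneIndex",
    "RepeatIndex",
    "biotype_group",
    "read_gtf",
    "classify_region",
    "is_self_interaction",
    "promoter_window",
]

BIOTYPE_GROUPS = ("protein_coding", "long_ncRNA", "ncRNA", "other")

# GENCODE long-noncoding annotation biotypes
_LONG_NC = {
    "lncRNA", "lincRNA", "antisense", "sense_intronic", "sense_overlapping",
    "bidirectional_promoter_lncRNA", "macro_lncRNA",
    "3prime_overlapping_ncRNA", "processed_transcript",
}
# small RNAs predicted from Rfam / miRBase models
_SMALL_NC = {
    "miRNA", "snRNA", "snoRNA", "rRNA", "misc_RNA", "scaRNA", "sRNA",
    "scRNA", "ribozyme", "vault_RNA", "Mt_tRNA", "Mt_rRNA",
}
_KNOWN_OTHER = {
    "TEC", "pseudogene", "processed_pseudogene", "unprocessed_pseudogene",
    "transcribed_processed_pseudogene", "transcribed_unprocessed_pseudogene",
    "IG_V_gene", "TR_V_gene", "polymorphic_pseudogene",
}


def biotype_group(biotype: str) -> str:
    """Collapse a biotype string into one of the four major groups."""
    if biotype == "protein_coding":
        return "protein_coding"
    if biotype in _LONG_NC:
        return "long_ncRNA"
    if biotype in _SMALL_NC:
        return "ncRNA"
    if biotype not in _KNOWN_OTHER:
        warnings.warn(f"unknown biotype {biotype!r}; grouped as 'other'")
    return "other"


@dataclass(frozen=True)
class GeneModel:
    """One gene with its exon structure and biotype."""

    gene_id: str
    name: str
    chrom: str
    start: int  # 0-based half-open span
    end: int
    strand: str
    biotype: str
    exons: tuple[tuple[int, int], ...]

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """5' end of the gene respecting strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def group(self) -> str:
        return biotype_group(self.biotype)

    def __len__(self) -> int:
        return self.end - self.start


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene/exon features from a GTF (1-based closed -> half-open)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(sorted(
            (e.start - 1, e.end) for e in db.children(g, featuretype="exon")
        ))
        genes.append(GeneModel(
            gene_id=g.attributes.get("gene_id", [g.id])[0],
            name=g.attributes.get("gene_name", [g.id])[0],
            chrom=g.seqid,
            start=g.start - 1,
            end=g.end,
            strand=g.strand,
            biotype=g.attributes.get("gene_type", ["other"])[0],
            exons=exons,
        ))
    return genes


class GeneIndex:
    """Interval index over gene spans for center-point assignment."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g
            )

    def assign_gene(
        self, chrom: str, pos: int, strand: str | None = None
    ) -> GeneModel | None:
        """Gene whose span contains ``pos``; strand-matched when ``strand``
        is given (RNA tags). Ties go to the smallest span, then the
        lexicographically smallest gene id. None means intergenic."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = [
            h.data for h in tree.at(pos)
            if strand is None or h.data.strand == strand
        ]
        if not hits:
            return None
        return min(hits, key=lambda g: (len(g), g.gene_id))


def classify_region(gene: GeneModel | None, pos: int) -> str:
    """exon / intron / intergenic for a tag center given its assigned gene."""
    if gene is None:
        return "intergenic"
    for s, e in gene.exons:
        if s <= pos < e:
            return "exon"
    return "intron"


class RepeatIndex:
    """Strand-aware center-point lookup of repeat-family annotations."""

    def __init__(self, intervals: Sequence[tuple[str, int, int, str, str]]):
        # rows of (chrom, start, end, family, strand)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, family, strand in intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(
                start, end, (family, strand)
            )

    @classmethod
    def from_bed(cls, df) -> "RepeatIndex":
        rows = list(zip(df["chrom"], df["start"], df["end"],
                        df["name"], df.get("strand", ["."] * len(df))))
        return cls(rows)

    def family_at(self, chrom: str, pos: int, strand: str) -> str:
        """Repeat family whose interval contains the tag center on the same
        strand; 'NR' (no repeat) otherwise. Ties go to the alphabetically
        first family."""
        tree = self._trees.get(chrom)
        if tree is None:
            return "NR"
        fams = sorted(
            fam for fam, st in (h.data for h in tree.at(pos))
            if st == strand or st == "."
        )
        return fams[0] if fams else "NR"


def is_self_interaction(
    rna_gene: GeneModel | None, dna_gene: GeneModel | None
) -> bool:
    """True when both tags of a pair fall in the same annotated gene."""
    return (
        rna_gene is not None
        and dna_gene is not None
        and rna_gene.gene_id == dna_gene.gene_id
    )


def annotate_pairs(
    pairs,
    gene_index: GeneIndex,
    repeat_index: "RepeatIndex | None" = None,
):
    """Add annotation columns to a pair table in place-copy style.

    Adds: gene_id (RNA tag center, strand-aware; NA if intergenic),
    region (exon/intron/intergenic), rna_class (biotype group; NA if
    intergenic), dna_gene_id (strand-blind), self_interaction, and
    repeat_family when a repeat index is given.
    """
    df = pairs.copy()
    gene_ids, regions, classes, dna_ids, selfs, fams = [], [], [], [], [], []
    for row in df.itertuples(index=False):
        g = gene_index.assign_gene(row.rna_chrom, row.rna_center,
                                   row.rna_strand)
        gene_ids.append(g.gene_id if g else None)
        regions.append(classify_region(g, row.rna_center))
        classes.append(g.group if g else None)
        dg = gene_index.assign_gene(row.dna_chrom, row.dna_center, None)
        dna_ids.append(dg.gene_id if dg else None)
        selfs.append(is_self_interaction(g, dg))
        if repeat_index is not None:
            fams.append(repeat_index.family_at(
                row.rna_chrom, row.rna_center, row.rna_strand))
    df["gene_id"] = gene_ids
    df["region"] = regions
    df["rna_class"] = classes
    df["dna_gene_id"] = dna_ids
    df["self_interaction"] = selfs
    if repeat_index is not None:
        df["repeat_family"] = fams
    return df


def promoter_window(
    gene: GeneModel, flank: int = 2000, chrom_length: int | None = None
) -> Interval:
    """+/- flank window around the TSS, clipped to the chromosome."""
    start = max(0, gene.tss - flank)
    end = gene.tss + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return Interval(gene.chrom, start, end, gene.strand)
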