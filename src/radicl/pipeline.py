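"""End-to-end glue: reads -> tag records -> mapped, annotated pairs.

Convenience layer over the module surface; each step can also be driven
individually (and is, by the CLI).
"""
from __future__ import annotations

import pandas as pd

from .anatomy import ReadAnatomy
from .annotate import GeneIndex, RepeatIndex, annotate_pairs
from .extract import KmerScreen, dedup_pairs, extract_reads, filter_rrna
from .mapping import GenomeIndex, build_pairs, map_records
from .simulate import Fixture

__all__ = ["process_reads"]


def process_reads(
    reads: list[tuple[str, str]],
    fixture: Fixture,
    anatomy: ReadAnatomy | None = None,
    mapq_min: int = 37,
    screen_rrna: bool = True,
    deduplicate: bool = True,
    annotate: bool = True,
    genome_index: GenomeIndex | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run extraction, rRNA screening, dedup, exact mapping, pairing and
    annotation against a fixture. Returns (pairs, stats)."""
    anatomy = anatomy or ReadAnatomy(
        barcodes=fixture.config.barcodes,
        tag_len_range=fixture.config.tag_len_range,
    )
    records, stats = extract_reads(reads, anatomy)
    accepted = records[records["rejection_reason"] == ""]

    if screen_rrna:
        screen = KmerScreen(fixture.rrna, k=21)
        is_contaminant = accepted["rna_seq"].map(
            lambda t: filter_rrna(t, screen))
        stats["rrna_removed"] = int(is_contaminant.sum())
        accepted = accepted[~is_contaminant]

    if deduplicate:
        before = len(accepted)
        accepted = dedup_pairs(accepted)
        stats["duplicates_removed"] = before - len(accepted)

    index = genome_index or GenomeIndex(fixture.genome)
    raw = map_records(accepted, index)
    pairs, map_stats = build_pairs(raw, fixture.bins, mapq_min=mapq_min)
    stats.update({f"mapping_{k}": v for k, v in map_stats.items()})

    if annotate:
        gene_index = GeneIndex(fixture.genes)
        repeat_index = RepeatIndex.from_bed(fixture.repeats)
        pairs = annotate_pairs(pairs, gene_index, repeat_index)
    return pairs, stats
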