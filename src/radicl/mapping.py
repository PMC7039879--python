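"""Exact tag mapping against fixture genomes, pairing, and import of
externally aligned tag tables.

The exact mapper is the deterministic test-harness counterpart of a real
short-read aligner: a unique exact hit gets MAPQ 37 (the aligner's unique
code), two or more exact hits get MAPQ 0, no hit is unmapped. Real data
enters through :func:`import_aligned_pairs` as a tab-separated table.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import revcomp
from .core import BinScheme, assign_bin, classify_distance, fragment_center

__all__ = [
    "AlignedTag",
    "GenomeIndex",
    "exact_map",
    "map_records",
    "import_aligned_pairs",
    "build_pairs",
    "PAIR_COLUMNS",
]

MAPQ_UNIQUE = 37
MAPQ_MULTI = 0

PAIR_COLUMNS = [
    "read_id",
    "rna_chrom", "rna_start", "rna_end", "rna_strand", "rna_mapq",
    "dna_chrom", "dna_start", "dna_end", "dna_mapq",
]


@dataclass(frozen=True)
class AlignedTag:
    read_id: str
    role: str  # "RNA" or "DNA"
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int


class GenomeIndex:
    """Seed-and-verify exact search: a dictionary of forward-strand seed
    k-mers, verified to the full tag on both strands."""

    def __init__(self, genome: dict[str, str], seed_len: int = 25):
        self.genome = genome
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i:i + seed_len], []).append(
                    (chrom, i))

    def hits(self, tag: str) -> list[tuple[str, int, str]]:
        """All exact full-length occurrences as (chrom, start, strand)."""
        if len(tag) < self.seed_len:
            raise ValueError("tag shorter than the seed length")
        out = []
        for seq, strand in ((tag, "+"), (revcomp(tag), "-")):
            for chrom, pos in self._index.get(seq[:self.seed_len], ()):
                if self.genome[chrom][pos:pos + len(seq)] == seq:
                    out.append((chrom, pos, strand))
        return sorted(set(out))


def exact_map(
    read_id: str, tag: str, index: GenomeIndex, role: str = "RNA"
) -> AlignedTag | None:
    """Map one tag exactly; None when unmapped.

    The RNA strand is the strand of the genome hit matching the tag in
    sense. Multi-mappers report the first hit with MAPQ 0.
    """
    hits = index.hits(tag)
    if not hits:
        return None
    chrom, pos, strand = hits[0]
    mapq = MAPQ_UNIQUE if len(hits) == 1 else MAPQ_MULTI
    return AlignedTag(read_id, role, chrom, pos, pos + len(tag), strand, mapq)


def map_records(
    records: pd.DataFrame, index: GenomeIndex
) -> pd.DataFrame:
    """Map accepted extraction records and pair RNA/DNA tags by read id.

    Returns the raw pair table (PAIR_COLUMNS); unmapped tags appear with
    mapq -1 and empty coordinates so the uniqueness filter drops them.
    """
    rows = []
    acc = records[records["rejection_reason"] == ""]
    for r in acc.itertuples(index=False):
        rna = exact_map(r.read_id, r.rna_seq, index, "RNA")
        dna = exact_map(r.read_id, r.dna_seq, index, "DNA")
        rows.append((
            r.read_id,
            rna.chrom if rna else "", rna.start if rna else -1,
            rna.end if rna else -1, rna.strand if rna else ".",
            rna.mapq if rna else -1,
            dna.chrom if dna else "", dna.start if dna else -1,
            dna.end if dna else -1, dna.mapq if dna else -1,
        ))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def build_pairs(
    raw: pd.DataFrame, bins: BinScheme, mapq_min: int = MAPQ_UNIQUE
) -> tuple[pd.DataFrame, dict]:
    """Apply the uniqueness filter and derive centers, bins and distance
    classes. Returns (pairs, stats)."""
    n_in = len(raw)
    keep = (raw["rna_mapq"] >= mapq_min) & (raw["dna_mapq"] >= mapq_min)
    df = raw[keep].copy().reset_index(drop=True)
    if len(df):
        df["rna_center"] = (
            df["rna_start"] + (df["rna_end"] - df["rna_start"] - 1) // 2
        )
        df["dna_center"] = (
            df["dna_start"] + (df["dna_end"] - df["dna_start"] - 1) // 2
        )
        df["rna_bin"] = [
            assign_bin(bins, c, p)
            for c, p in zip(df["rna_chrom"], df["rna_center"])
        ]
        df["dna_bin"] = [
            assign_bin(bins, c, p)
            for c, p in zip(df["dna_chrom"], df["dna_center"])
        ]
        cis = (df["rna_chrom"] == df["dna_chrom"]).to_numpy()
        dist = np.abs(df["rna_center"] - df["dna_center"]).to_numpy()
        df["distance"] = np.where(cis, dist, -1)
        df["distance_class"] = [
            classify_distance(rc, dc, rch, dch).value
            for rc, dc, rch, dch in zip(
                df["rna_center"], df["dna_center"],
                df["rna_chrom"], df["dna_chrom"])
        ]
    else:
        for col in ("rna_center", "dna_center", "rna_bin", "dna_bin",
                    "distance"):
            df[col] = pd.Series(dtype=int)
        df["distance_class"] = pd.Series(dtype=str)
    stats = {"input": n_in, "kept": len(df),
             "dropped_mapq": int(n_in - len(df))}
    return df, stats


def import_aligned_pairs(
    path: str | Path, bins: BinScheme, mapq_min: int = MAPQ_UNIQUE
) -> tuple[pd.DataFrame, dict]:
    """Read a tab-separated aligned-pairs table (documented header =
    PAIR_COLUMNS, 0-based half-open) and apply the uniqueness filter.

    Malformed rows raise with their line number. An empty file yields an
    empty pair set and a warning counter in the stats.
    """
    import warnings

    rows = []
    with open(path) as fh:
        header = fh.readline()
        if header and header.rstrip("\n").split("\t") != PAIR_COLUMNS:
            raise ValueError(f"{path}: line 1: unexpected header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(PAIR_COLUMNS):
                raise ValueError(
                    f"{path}: line {ln}: expected "
                    f"{len(PAIR_COLUMNS)} fields, got {len(fields)}")
            try:
                rows.append((
                    fields[0], fields[1], int(fields[2]), int(fields[3]),
                    fields[4], int(fields[5]), fields[6], int(fields[7]),
                    int(fields[8]), int(fields[9]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from None
    raw = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if raw.empty:
        warnings.warn(f"{path}: no aligned pairs found")
    return build_pairs(raw, bins, mapq_min=mapq_min)


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
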