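"""Shared genomic primitives: builds, intervals, bins, distance classes.

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based closed) is converted on read by :mod:`radicl.annotate`.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "Interval",
    "BinScheme",
    "DistanceClass",
    "make_bins",
    "fragment_center",
    "assign_bin",
    "classify_distance",
    "normalize_cpm",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome names and lengths for one assembly."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class DistanceClass(str, enum.Enum):
    """Six-way classification of RNA-DNA pair separation.

    Cis pairs are split by linear distance d:
    local d <= 10 kb; short 10 kb < d <= 100 kb; medium 100 kb < d <= 1 Mb;
    long 1 Mb < d <= 10 Mb; extreme d > 10 Mb. Pairs on different
    chromosomes are trans.
    """

    LOCAL = "local"
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"
    EXTREME = "extreme"
    TRANS = "trans"


# upper bounds (inclusive) for the cis classes, in order
_CIS_BOUNDS: tuple[tuple[int, DistanceClass], ...] = (
    (10_000, DistanceClass.LOCAL),
    (100_000, DistanceClass.SHORT),
    (1_000_000, DistanceClass.MEDIUM),
    (10_000_000, DistanceClass.LONG),
)


@dataclass(frozen=True)
class BinScheme:
    """Fixed-width tiling of a genome, last bin per chromosome truncated.

    Bins carry a single global index; ``bin_offset[chrom]`` gives the index
    of that chromosome's first bin.
    """

    genome: GenomeBuild
    width: int
    n_bins_per_chrom: dict[str, int] = field(default_factory=dict)
    bin_offset: dict[str, int] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_per_chrom.values())

    def bin_interval(self, bin_id: int) -> Interval:
        """Genomic interval covered by a global bin index."""
        for chrom in self.genome.chrom_names:
            off = self.bin_offset[chrom]
            n = self.n_bins_per_chrom[chrom]
            if off <= bin_id < off + n:
                local = bin_id - off
                start = local * self.width
                end = min(start + self.width, self.genome.lengths[chrom])
                return Interval(chrom, start, end)
        raise IndexError(f"bin id {bin_id} out of range")

    def bin_label(self, bin_id: int) -> str:
        iv = self.bin_interval(bin_id)
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    def iter_bins(self) -> Iterable[tuple[int, Interval]]:
        for b in range(self.n_bins):
            yield b, self.bin_interval(b)


def make_bins(genome: GenomeBuild, width: int = 25_000) -> BinScheme:
    """Tile each chromosome with fixed-width bins (last bin truncated)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    n_per: dict[str, int] = {}
    offsets: dict[str, int] = {}
    off = 0
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        n = -(-length // width)  # ceil division
        n_per[chrom] = n
        offsets[chrom] = off
        off += n
    return BinScheme(genome, width, n_per, offsets)


def fragment_center(iv: Interval) -> int:
    """Single-nucleotide center of a fragment.

    Even lengths take the left-of-middle base, so the result is always a
    position covered by the interval.
    """
    return iv.start + (len(iv) - 1) // 2


def assign_bin(scheme: BinScheme, chrom: str, pos: int) -> int:
    """Global bin index containing position ``pos`` on ``chrom``."""
    if chrom not in scheme.genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not (0 <= pos < scheme.genome.lengths[chrom]):
        raise ValueError(f"position {pos} outside {chrom}")
    return scheme.bin_offset[chrom] + pos // scheme.width


def classify_distance(
    rna_center: int, dna_center: int, rna_chrom: str, dna_chrom: str
) -> DistanceClass:
    """Distance class of a pair from tag centers (center-to-center)."""
    if rna_chrom != dna_chrom:
        return DistanceClass.TRANS
    d = abs(rna_center - dna_center)
    for bound, cls in _CIS_BOUNDS:
        if d <= bound:
            return cls
    return DistanceClass.EXTREME


def classify_distance_array(distances: np.ndarray) -> np.ndarray:
    """Vectorized cis classification; callers handle trans separately."""
    d = np.asarray(distances)
    bounds = [b for b, _ in _CIS_BOUNDS]
    labels = np.array(
        [c.value for _, c in _CIS_BOUNDS] + [DistanceClass.EXTREME.value]
    )
    return labels[np.searchsorted(bounds, d, side="left")]


def normalize_cpm(counts, library_size: int):
    """Counts per million given a total library size."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


# ---------------------------------------------------------------------------
# plain-text I/O


def read_chrom_sizes(path: str | Path) -> GenomeBuild:
    """Two-column ``chrom<TAB>length`` file -> GenomeBuild."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeBuild(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED6 -> DataFrame with chrom/start/end and optional name,
    score, strand columns."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def intervals_from_bed(df: pd.DataFrame) -> list[Interval]:
    strands = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        Interval(c, int(s), int(e), st)
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strands)
    ]
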