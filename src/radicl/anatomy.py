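"""The chimeric-read construct model shared by the simulator and extractor.

A sequenced molecule reads, 5' to 3':

    [RNA tag 25-27 nt, transcript sense]
    [bridge adapter top strand, 50 nt]
    [DNA tag 25-27 nt]
    [sequencing-linker stub]
    [6-nt multiplexing barcode]
    [filler to read length]

and appears on the flow cell in either orientation with equal probability.
The bridge adapter carries one EcoP15I recognition site (CAGCAG) near each
end, one per strand; EcoP15I cleaves 25-27 nt away from its site, which is
what fixes the tag lengths.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ADAPTER_TOP",
    "ADAPTER_BOTTOM",
    "YLINKER_UPPER",
    "INDEX_RV_PRIMER",
    "ECOP15I_SITE",
    "DEFAULT_BARCODES",
    "ReadAnatomy",
    "revcomp",
    "hamming",
    "ecop15i_sites",
    "barcode_placeholder_length",
]

# Bridge adapter, 5' pre-adenylated top strand and biotinylated bottom strand.
ADAPTER_TOP = "CTGCTGCTCCTTCCCTTTCCCCTTTTGGTCCGACGGTCCAAGTCAGCAGT"
ADAPTER_BOTTOM = "CTGCTGACTTGGACCGTCGGACC"

# Y-shaped sequencing linker, upper strand; the stub that precedes the
# barcode in read-through is its 5' portion.
YLINKER_UPPER = "GATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

# Indexed reverse PCR primer template; BBBBBB is the library barcode.
INDEX_RV_PRIMER = (
    "CAAGCAGAAGACGGCATACGAGATBBBBBBCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT"
)

ECOP15I_SITE = "CAGCAG"

# Default multiplexing barcodes (pairwise Hamming distance >= 3).
DEFAULT_BARCODES = ("ATCACG", "CGATGT", "TTAGGC", "TGACCA")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def ecop15i_sites(seq: str, site: str = ECOP15I_SITE) -> list[tuple[int, str]]:
    """Occurrences of an enzyme recognition site on either strand.

    Returns ``(position_on_forward, strand)`` tuples; a minus-strand site at
    forward position p means ``revcomp(site)`` starts at p.
    """
    hits = [(m.start(), "+") for m in re.finditer(f"(?={site})", seq)]
    rc = revcomp(site)
    hits += [(m.start(), "-") for m in re.finditer(f"(?={rc})", seq)]
    return sorted(hits)


def barcode_placeholder_length(primer: str = INDEX_RV_PRIMER) -> int:
    """Length of the longest run of 'B' placeholder bases in a primer
    template (0 if none)."""
    runs = re.findall(r"B+", primer)
    return max((len(r) for r in runs), default=0)


@dataclass(frozen=True)
class ReadAnatomy:
    """Adapter/linker/barcode layout plus matching tolerances.

    tag_len_range is the EcoP15I cleavage window; flanks shorter than its
    lower bound are rejected, flanks longer than the upper bound keep only
    the adapter-proximal bases.
    """

    adapter_top: str = ADAPTER_TOP
    adapter_bottom: str = ADAPTER_BOTTOM
    linker_stub: str = YLINKER_UPPER[:12]
    tag_len_range: tuple[int, int] = (25, 27)
    barcode_length: int = 6
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    max_adapter_mismatches: int = 2
    max_barcode_mismatches: int = 1
    max_linker_mismatches: int = 2

    def __post_init__(self) -> None:
        if len(self.adapter_top) != 50:
            raise ValueError("bridge-adapter top strand must be 50 nt")
        if len(ecop15i_sites(self.adapter_top)) != 2:
            raise ValueError("adapter must carry two EcoP15I sites")
        if any(len(b) != self.barcode_length for b in self.barcodes):
            raise ValueError("barcode length mismatch with whitelist")

    @property
    def adapter_len(self) -> int:
        return len(self.adapter_top)

    def min_read_length(self, read_len: int = 150) -> int:
        """Smallest read that can hold the full construct."""
        lo, hi = self.tag_len_range
        return hi + self.adapter_len + hi + len(self.linker_stub) + self.barcode_length

    def match_barcode(self, observed: str) -> str | None:
        """Closest whitelist barcode within max_barcode_mismatches, or None
        (ties are rejected)."""
        if len(observed) != self.barcode_length:
            return None
        dists = sorted((hamming(observed, b), b) for b in self.barcodes)
        best_d, best = dists[0]
        if best_d > self.max_barcode_mismatches:
            return None
        if len(dists) > 1 and dists[1][0] == best_d:
            return None
        return best
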