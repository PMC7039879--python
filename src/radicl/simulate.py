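"""Synthetic fixture generator: genome, annotation, contacts, and reads.

Everything downstream of the sequencer can be exercised without external
data: a small random genome with annotated genes, TADs, repeats, peaks,
blacklist intervals and A/B compartments; a ground-truth RNA-DNA contact
table sampled from a nascent / cis-decay / trans mixture; and single-end
FASTQ reads carrying the full chimeric construct anatomy, with optional PCR
duplicates, rRNA contaminants and substitution errors.

Cis contacts decay as P(d) proportional to (d + d0)^-alpha, the canonical
power-law distance decay of chromatin contact data; a configurable fraction
of contacts is nascent-like (RNA caught at its own transcription site,
distance < 1 kb) and another fraction is trans (a different chromosome).
"""
from __future__ import annotations

import textwrap
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import DEFAULT_BARCODES, ReadAnatomy, revcomp
from .annotate import GeneModel
from .core import BinScheme, GenomeBuild, make_bins

__all__ = ["SimConfig", "Fixture", "build_fixture", "sample_contacts",
           "synthesize_reads", "write_fastq"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# representative concrete biotype strings per group, sampled per gene
_GROUP_BIOTYPES = {
    "protein_coding": ("protein_coding",),
    "long_ncRNA": ("lincRNA", "antisense"),
    "ncRNA": ("snRNA", "miRNA", "snoRNA"),
    "other": ("TEC", "processed_pseudogene"),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated library."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 300_000
    n_genes: int = 40
    exons_per_gene: int = 3
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    biotype_mix: tuple[tuple[str, float], ...] = (
        ("protein_coding", 0.5), ("long_ncRNA", 0.2),
        ("ncRNA", 0.15), ("other", 0.15),
    )
    n_contacts: int = 20_000
    cis_decay_alpha: float = 1.0
    d0: float = 1_000.0
    frac_trans: float = 0.05
    frac_nascent: float = 0.25
    enriched: tuple[tuple[str, int, float], ...] = ()  # (gene_id, bin, fold)
    dup_rate: float = 0.0
    rrna_rate: float = 0.0
    seq_error_rate: float = 0.0
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    tag_len_range: tuple[int, int] = (25, 27)
    read_length: int = 150
    bin_width: int = 25_000
    expr_sigma: float = 1.0  # log-normal sd of gene expression weights
    plant_repeat: bool = True
    repeat_length: int = 500
    repeat_copies: int = 2
    n_peaks: int = 50
    peak_length: int = 500
    n_blacklist: int = 2
    tad_size_range: tuple[int, int] = (20_000, 60_000)
    compartment_block: int = 50_000
    rrna_length: int = 5_000

    def __post_init__(self) -> None:
        for name in ("frac_trans", "frac_nascent", "dup_rate", "rrna_rate",
                     "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_trans + self.frac_nascent > 1.0:
            raise ValueError("frac_trans + frac_nascent exceeds 1")
        if any(fold < 1 for _, _, fold in self.enriched):
            raise ValueError("enrichment fold must be >= 1")
        lo, hi = self.tag_len_range
        anatomy = ReadAnatomy(barcodes=self.barcodes,
                              tag_len_range=self.tag_len_range)
        if anatomy.min_read_length() > self.read_length:
            raise ValueError("tag_len_range exceeds read capacity")


@dataclass
class Fixture:
    """In-memory synthetic reference set."""

    config: SimConfig
    genome: dict[str, str]
    build: GenomeBuild
    bins: BinScheme
    genes: list[GeneModel]
    expression: pd.Series  # gene_id -> sampling weight (expression proxy)
    tads: pd.DataFrame
    repeats: pd.DataFrame
    peaks: pd.DataFrame
    blacklist: pd.DataFrame
    compartments: pd.DataFrame
    rrna: str

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}

    # ---------------- text serialization ----------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/GTF/BED/TSV files; byte-deterministic."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["genome"] = out / "genome.fa"
        with open(paths["genome"], "w") as fh:
            for chrom in self.build.chrom_names:
                fh.write(f">{chrom}\n")
                fh.write(textwrap.fill(self.genome[chrom], 80) + "\n")

        paths["rrna"] = out / "rrna.fa"
        with open(paths["rrna"], "w") as fh:
            fh.write(">rRNA_repeating_unit_synthetic\n")
            fh.write(textwrap.fill(self.rrna, 80) + "\n")

        paths["gtf"] = out / "genes.gtf"
        with open(paths["gtf"], "w") as fh:
            for g in self.genes:
                attrs = (f'gene_id "{g.gene_id}"; gene_type "{g.biotype}"; '
                         f'gene_name "{g.name}";')
                fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
                tid = f'{attrs} transcript_id "{g.gene_id}.1";'
                fh.write(f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}"
                         f"\t.\t{g.strand}\t.\t{tid}\n")
                for s, e in g.exons:
                    fh.write(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t"
                             f"{g.strand}\t.\t{tid}\n")

        for key in ("tads", "repeats", "peaks", "blacklist", "compartments"):
            df = getattr(self, key)
            paths[key] = out / f"{key}.bed"
            df.to_csv(paths[key], sep="\t", header=False, index=False)

        paths["chrom_sizes"] = out / "chrom.sizes"
        with open(paths["chrom_sizes"], "w") as fh:
            for name, length in zip(self.build.chrom_names,
                                    self.build.chrom_lengths):
                fh.write(f"{name}\t{length}\n")

        paths["expression"] = out / "expression.tsv"
        self.expression.rename("weight").to_csv(paths["expression"], sep="\t")
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _place_genes(rng, config: SimConfig, chrom_names) -> list[GeneModel]:
    """Non-overlapping gene placement with random gaps, split over chroms."""
    lo, hi = config.gene_length_range
    margin = 5_000
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    groups = [g for g, _ in config.biotype_mix]
    probs = np.array([f for _, f in config.biotype_mix], dtype=float)
    probs /= probs.sum()
    genes = []
    idx = 0
    for chrom, gene_ids in zip(chrom_names, per_chrom):
        n = len(gene_ids)
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        avail = config.chrom_length - 2 * margin
        slack = avail - int(lengths.sum())
        if slack < 0:
            raise ValueError("infeasible packing: too many genes for genome")
        u = rng.random(n + 1)
        gaps = np.floor(slack * u / u.sum()).astype(int)
        pos = margin
        for i in range(n):
            pos += gaps[i]
            start, end = pos, pos + int(lengths[i])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            group = groups[rng.choice(len(groups), p=probs)]
            biotype = _GROUP_BIOTYPES[group][
                rng.integers(len(_GROUP_BIOTYPES[group]))
            ]
            # split span into alternating exon/intron segments
            k = config.exons_per_gene
            if k > 1:
                cuts = np.sort(rng.choice(
                    np.arange(start + 50, end - 50), size=2 * k - 2,
                    replace=False,
                ))
                edges = [start, *cuts.tolist(), end]
            else:
                edges = [start, end]
            exons = tuple(
                (edges[j], edges[j + 1]) for j in range(0, len(edges) - 1, 2)
            )
            genes.append(GeneModel(
                gene_id=f"G{idx:04d}", name=f"gene{idx:04d}", chrom=chrom,
                start=start, end=end, strand=strand, biotype=biotype,
                exons=exons,
            ))
            idx += 1
    return genes


def build_fixture(config: SimConfig) -> Fixture:
    """Deterministically generate the full reference set for one seed."""
    rng = np.random.default_rng(config.seed)
    chrom_names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    build = GenomeBuild(chrom_names,
                        (config.chrom_length,) * config.n_chroms)
    genome = {c: _random_seq(rng, config.chrom_length) for c in chrom_names}
    genes = _place_genes(rng, config, chrom_names)

    # plant a multi-copy repeat in intergenic space (identical sequence at
    # >= 2 loci) to exercise mappability, plus single-copy annotated repeats
    rep_rows = []
    if config.plant_repeat and config.repeat_copies >= 2:
        rep_seq = _random_seq(rng, config.repeat_length)
        gene_spans = {c: [(g.start, g.end) for g in genes if g.chrom == c]
                      for c in chrom_names}
        placed = 0
        attempts = 0
        while placed < config.repeat_copies and attempts < 1000:
            attempts += 1
            chrom = chrom_names[rng.integers(config.n_chroms)]
            start = int(rng.integers(
                1000, config.chrom_length - config.repeat_length - 1000))
            end = start + config.repeat_length
            if any(s < end and start < e for s, e in gene_spans[chrom]):
                continue
            if any(r[0] == chrom and r[1] < end + 100 and start - 100 < r[2]
                   for r in rep_rows):
                continue
            genome[chrom] = (genome[chrom][:start] + rep_seq
                             + genome[chrom][end:])
            rep_rows.append([chrom, start, end, "SINE",
                             0, "+" if placed % 2 == 0 else "-"])
            placed += 1
        if placed < config.repeat_copies:
            raise ValueError("could not place the multi-copy repeat")
    # annotation-only single-copy repeats for family intersection tests
    for fam in ("LINE", "LTR"):
        chrom = chrom_names[rng.integers(config.n_chroms)]
        start = int(rng.integers(1000, config.chrom_length - 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        rep_rows.append([chrom, start, start + 1000, fam, 0, strand])
    repeats = pd.DataFrame(
        rep_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    # TADs: non-overlapping blocks over the central part of each chromosome,
    # leaving room so the 3x metaprofile window fits
    tad_rows = []
    lo, hi = config.tad_size_range
    for chrom in chrom_names:
        pos = config.chrom_length // 5
        stop = 4 * config.chrom_length // 5
        while True:
            size = int(rng.integers(lo, hi + 1))
            if pos + size > stop:
                break
            tad_rows.append([chrom, pos, pos + size,
                             f"TAD_{chrom}_{pos}", 0, "."])
            pos += size
    tads = pd.DataFrame(
        tad_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    peak_rows = []
    for i in range(config.n_peaks):
        chrom = chrom_names[rng.integers(config.n_chroms)]
        start = int(rng.integers(
            0, config.chrom_length - config.peak_length))
        peak_rows.append([chrom, start, start + config.peak_length,
                          f"peak{i}", 0, "."])
    peaks = pd.DataFrame(
        peak_rows,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    bl_rows = []
    for i in range(config.n_blacklist):
        chrom = chrom_names[rng.integers(config.n_chroms)]
        start = int(rng.integers(0, config.chrom_length - 5_000))
        bl_rows.append([chrom, start, start + 5_000, f"blacklist{i}", 0, "."])
    blacklist = pd.DataFrame(
        bl_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    comp_rows = []
    for chrom in chrom_names:
        pos, flag = 0, 0
        while pos < config.chrom_length:
            end = min(pos + config.compartment_block, config.chrom_length)
            comp_rows.append([chrom, pos, end, "A" if flag == 0 else "B",
                              0, "."])
            pos, flag = end, 1 - flag
    compartments = pd.DataFrame(
        comp_rows,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )

    # log-normal expression weights: realistic heavy-tailed quartiles
    weights = rng.lognormal(mean=0.0, sigma=config.expr_sigma,
                            size=len(genes))
    expression = pd.Series(
        weights / weights.sum(), index=[g.gene_id for g in genes],
        name="weight",
    )

    rrna = _random_seq(rng, config.rrna_length)
    bins = make_bins(build, config.bin_width)
    return Fixture(config, genome, build, bins, genes, expression, tads,
                   repeats, peaks, blacklist, compartments, rrna)


# ---------------------------------------------------------------------------
# contact sampling


def _sample_decay_distance(rng, n, alpha, d0, dmax):
    """Inverse-CDF sample of d in [0, dmax] with density (d + d0)^-alpha."""
    u = rng.random(n)
    if alpha == 0:
        return u * dmax
    r = 1.0 + dmax / d0
    if abs(alpha - 1.0) < 1e-12:
        return d0 * (np.power(r, u) - 1.0)
    p = 1.0 - alpha
    return d0 * (np.power((np.power(r, p) - 1.0) * u + 1.0, 1.0 / p) - 1.0)


def sample_contacts(fixture: Fixture, config: SimConfig | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the ground-truth contact table from the configured mixture.

    Returns one row per contact with RNA tag interval/strand, DNA tag
    interval and the mixture component it was drawn from.
    """
    config = config or fixture.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_contacts
    L = config.chrom_length
    lo_t, hi_t = config.tag_len_range
    margin = hi_t  # keep tag intervals inside the chromosome

    gene_ids = fixture.expression.index.to_numpy()
    gidx = rng.choice(len(gene_ids), size=n, p=fixture.expression.to_numpy())
    genes = [fixture.genes[i] for i in gidx]

    rna_len = rng.integers(lo_t, hi_t + 1, size=n)
    rna_start = np.array([
        rng.integers(g.start, g.end - rl + 1)
        for g, rl in zip(genes, rna_len)
    ])
    rna_end = rna_start + rna_len
    rna_center = rna_start + (rna_len - 1) // 2
    rna_chrom = np.array([g.chrom for g in genes])
    rna_strand = np.array([g.strand for g in genes])

    u = rng.random(n)
    is_trans = u < config.frac_trans
    is_nascent = (~is_trans) & (u < config.frac_trans + config.frac_nascent)
    component = np.where(
        is_trans, "trans", np.where(is_nascent, "nascent", "cis_decay"))

    dna_chrom = rna_chrom.copy()
    dna_center = np.zeros(n, dtype=np.int64)

    # trans: uniform position on a uniformly chosen other chromosome
    ti = np.flatnonzero(is_trans)
    if ti.size:
        others = []
        for i in ti:
            cands = [c for c in fixture.build.chrom_names
                     if c != rna_chrom[i]]
            others.append(cands[rng.integers(len(cands))])
        dna_chrom[ti] = others
        dna_center[ti] = rng.integers(margin, L - margin, size=ti.size)

    # nascent: |d| < 1 kb around the RNA tag center
    ni = np.flatnonzero(is_nascent)
    if ni.size:
        d = rng.integers(-999, 1000, size=ni.size)
        dna_center[ni] = np.clip(rna_center[ni] + d, margin, L - margin - 1)

    # cis decay: signed power-law distance, redrawn while out of range
    ci = np.flatnonzero(~is_trans & ~is_nascent)
    pending = ci.copy()
    while pending.size:
        d = _sample_decay_distance(
            rng, pending.size, config.cis_decay_alpha, config.d0, L)
        sign = np.where(rng.random(pending.size) < 0.5, -1.0, 1.0)
        cand = (rna_center[pending] + sign * d).astype(np.int64)
        ok = (cand >= margin) & (cand < L - margin)
        dna_center[pending[ok]] = cand[ok]
        pending = pending[~ok]

    contacts = pd.DataFrame({
        "contact_id": [f"C{i:07d}" for i in range(n)],
        "gene_id": gene_ids[gidx],
        "rna_chrom": rna_chrom,
        "rna_start": rna_start,
        "rna_end": rna_end,
        "rna_strand": rna_strand,
        "dna_chrom": dna_chrom,
        "dna_center": dna_center,
        "component": component,
    })

    # enrichment: the target bin's mass is scaled fold-x and renormalized
    for gene_id, bin_id, fold in config.enriched:
        contacts = _apply_enrichment(
            contacts, fixture, config, rng, gene_id, int(bin_id), float(fold))

    dna_len = rng.integers(lo_t, hi_t + 1, size=n)
    contacts["dna_start"] = (
        contacts["dna_center"].to_numpy() - (dna_len - 1) // 2
    )
    contacts["dna_end"] = contacts["dna_start"] + dna_len
    return contacts.drop(columns="dna_center")


def _apply_enrichment(contacts, fixture, config, rng, gene_id, bin_id, fold):
    """Reassign part of one gene's contacts into the enriched bin so that
    the bin carries fold-times its background mass, renormalized:
    p* = fold q / (1 + (fold - 1) q)."""
    from .core import assign_bin

    iv = fixture.bins.bin_interval(bin_id)
    mask = (contacts["gene_id"] == gene_id).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return contacts
    in_bin = np.array([
        contacts["dna_chrom"].iat[i] == iv.chrom
        and iv.start <= contacts["dna_center"].iat[i] < iv.end
        for i in idx
    ])
    q = max(in_bin.mean(), 1.0 / (2 * idx.size))
    p_star = fold * q / (1.0 + (fold - 1.0) * q)
    move_p = max(0.0, (p_star - q) / (1.0 - q)) if q < 1.0 else 0.0
    movers = idx[~in_bin][rng.random((~in_bin).sum()) < move_p]
    if movers.size:
        lo = max(iv.start, config.tag_len_range[1])
        hi = iv.end - config.tag_len_range[1]
        contacts.loc[movers, "dna_chrom"] = iv.chrom
        contacts.loc[movers, "dna_center"] = rng.integers(
            lo, hi, size=movers.size)
        contacts.loc[movers, "component"] = "enriched"
    return contacts


# ---------------------------------------------------------------------------
# read synthesis


def synthesize_reads(
    contacts: pd.DataFrame,
    fixture: Fixture,
    config: SimConfig | None = None,
    anatomy: ReadAnatomy | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit (read_id, sequence) tuples plus the ground-truth table.

    The truth table stores the emitted (post-error) tag and barcode
    sequences alongside the true genomic intervals, so extractor accuracy
    can be scored under sequencing error.
    """
    config = config or fixture.config
    anatomy = anatomy or ReadAnatomy(barcodes=config.barcodes,
                                     tag_len_range=config.tag_len_range)
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(contacts)
    rl = config.read_length
    adapter = anatomy.adapter_top
    stub = anatomy.linker_stub

    is_rrna = rng.random(n) < config.rrna_rate
    barcode_idx = rng.integers(len(config.barcodes), size=n)
    reverse = rng.random(n) < 0.5

    layouts = []  # (rna_len, dna_len) per read, in forward construct order
    seqs = np.empty((n, rl), dtype=np.uint8)
    for i, row in enumerate(contacts.itertuples(index=False)):
        rna_len = row.rna_end - row.rna_start
        if is_rrna[i]:
            start = rng.integers(0, len(fixture.rrna) - rna_len + 1)
            rna_seq = fixture.rrna[start:start + rna_len]
        else:
            rna_seq = fixture.genome[row.rna_chrom][row.rna_start:row.rna_end]
            if row.rna_strand == "-":
                rna_seq = revcomp(rna_seq)
        dna_seq = fixture.genome[row.dna_chrom][row.dna_start:row.dna_end]
        barcode = config.barcodes[barcode_idx[i]]
        construct = rna_seq + adapter + dna_seq + stub + barcode
        pad = _random_seq(rng, rl - len(construct))
        read = construct + pad
        if reverse[i]:
            read = revcomp(read)
        seqs[i] = np.frombuffer(read.encode(), dtype=np.uint8)
        layouts.append((rna_len, len(dna_seq)))

    # substitution errors over the whole read
    if config.seq_error_rate > 0:
        err = rng.random((n, rl)) < config.seq_error_rate
        shift = rng.integers(1, 4, size=int(err.sum()))
        base_idx = np.searchsorted(_BASES, seqs[err])
        seqs[err] = _BASES[(base_idx + shift) % 4]

    read_strs = [s.tobytes().decode() for s in seqs]

    # recover emitted sub-sequences from the (possibly mutated) reads
    truth_rows = []
    for i, row in enumerate(contacts.itertuples(index=False)):
        rna_len, dna_len = layouts[i]
        fwd = revcomp(read_strs[i]) if reverse[i] else read_strs[i]
        a0 = rna_len
        d0_ = a0 + len(adapter)
        b0 = d0_ + dna_len + len(stub)
        truth_rows.append({
            "read_id": f"R{i:07d}",
            "contact_id": row.contact_id,
            "gene_id": row.gene_id,
            "rna_chrom": row.rna_chrom, "rna_start": row.rna_start,
            "rna_end": row.rna_end, "rna_strand": row.rna_strand,
            "dna_chrom": row.dna_chrom, "dna_start": row.dna_start,
            "dna_end": row.dna_end,
            "barcode": config.barcodes[barcode_idx[i]],
            "orientation": "R" if reverse[i] else "F",
            "rna_seq": fwd[:a0],
            "dna_seq": fwd[d0_:d0_ + dna_len],
            "barcode_seq": fwd[b0:b0 + anatomy.barcode_length],
            "rrna_contaminant": bool(is_rrna[i]),
            "duplicate": False,
            "dup_of": "",
        })

    reads = [(t["read_id"], read_strs[i]) for i, t in enumerate(truth_rows)]

    # PCR duplicates: exact copies of already-emitted reads
    if config.dup_rate > 0:
        n_dup = int(round(n * config.dup_rate / (1.0 - config.dup_rate)))
        src = rng.integers(0, n, size=n_dup)
        for j, s in enumerate(src):
            rid = f"R{n + j:07d}"
            orig = truth_rows[s]
            dup = dict(orig)
            dup.update(read_id=rid, duplicate=True, dup_of=orig["read_id"])
            truth_rows.append(dup)
            reads.append((rid, read_strs[s]))

    truth = pd.DataFrame(truth_rows)
    return reads, truth


def write_fastq(reads, path: str | Path, quality: str = "I") -> None:
    """Write (read_id, sequence) tuples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Minimal 4-line FASTQ reader returning (read_id, sequence)."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header[1:].split()[0], seq))
    return out
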