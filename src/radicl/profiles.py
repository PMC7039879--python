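"""Downstream summaries: reproducibility, expression correlation, distance
decay, TAD metaprofiles, peak density, repeat enrichment and cross-library
comparisons.

Functions take the pair tables produced by :mod:`radicl.mapping` (plus
annotation columns added by the caller) and plain BED-style DataFrames for
structural features, and return DataFrames / arrays ready for tabular
output.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .annotate import GeneModel
from .core import BinScheme, Interval, normalize_cpm

__all__ = [
    "MetaProfile",
    "replicate_correlation",
    "expression_correlation",
    "distance_decay",
    "fraction_below",
    "meta_profile",
    "inside_outside_profile",
    "peak_density_profile",
    "repeat_interval_proportions",
    "binding_profiles",
    "jaccard_vs_capture",
    "promoter_log2ratio",
    "unique_targets",
    "compartment_segregation",
    "shared_trans",
    "top_k_overlap",
    "dominant_class_matrix",
]

REGION_ORDER = ("exon", "intron", "intergenic")
CLASS_ORDER = ("protein_coding", "long_ncRNA", "ncRNA", "other")
DISTANCE_ORDER = ("local", "short", "medium", "long", "extreme", "trans")


# ---------------------------------------------------------------------------
# reproducibility and expression


def replicate_correlation(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson r between replicate count tables.

    Each table has columns (rna_id, bin, count). Following the
    complete-observations convention, the correlation is computed only on
    (rna, bin) units observed (count > 0) in every table.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    merged = None
    for i, t in enumerate(tables):
        cur = t.rename(columns={"count": f"count_{i}"})
        merged = cur if merged is None else merged.merge(
            cur, on=["rna_id", "bin"], how="inner")
    count_cols = [c for c in merged.columns if c.startswith("count_")]
    merged = merged[(merged[count_cols] > 0).all(axis=1)]
    k = len(tables)
    out = pd.DataFrame(np.eye(k), columns=range(k), index=range(k))
    for i, j in itertools.combinations(range(k), 2):
        if len(merged) < 2:
            r = float("nan")  # fewer than two complete units
        else:
            r = np.corrcoef(merged[f"count_{i}"],
                            merged[f"count_{j}"])[0, 1]
        out.iloc[i, j] = out.iloc[j, i] = r
    return out


def expression_correlation(
    counts: pd.Series,
    lengths_bp: pd.Series,
    tpm: pd.Series,
    threshold: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation between interaction counts and
    expression.

    Counts are normalized to reads per kilobase (RPK); genes with
    RPK >= threshold and TPM >= threshold are retained and r^2 is taken
    on log10 values. Returns (r_squared, retained table).
    """
    shared = counts.index.intersection(lengths_bp.index).intersection(
        tpm.index)
    rpk = counts[shared] / (lengths_bp[shared] / 1000.0)
    keep = (rpk >= threshold) & (tpm[shared] >= threshold)
    if not keep.any():
        raise ValueError("no genes survive the RPK/TPM thresholds")
    df = pd.DataFrame({"rpk": rpk[keep], "tpm": tpm[shared][keep]})
    if len(df) < 2:
        return float("nan"), df
    r = np.corrcoef(np.log10(df["rpk"]), np.log10(df["tpm"]))[0, 1]
    return float(r * r), df


# ---------------------------------------------------------------------------
# distance structure


def _edge_distance(center: np.ndarray, start: np.ndarray,
                   end: np.ndarray) -> np.ndarray:
    """Distance from a DNA center to the nearest gene-span edge, zero
    inside the span."""
    below = np.clip(start - center, 0, None)
    above = np.clip(center - (end - 1), 0, None)
    return below + above


def distance_decay(
    pairs: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    expression: pd.Series,
    n_quartiles: int = 4,
    n_dist_bins: int = 20,
) -> pd.DataFrame:
    """Per-expression-quartile distance-decay curves.

    Cis pairs annotated with a source gene are binned by the distance from
    the DNA tag center to the nearest edge of the gene span (0 inside the
    gene body), on log-spaced bins; each quartile's curve is normalized to
    sum to 1. Quartile I is the lowest-expressed.
    """
    cis = pairs[
        (pairs["rna_chrom"] == pairs["dna_chrom"])
        & pairs["gene_id"].notna()
    ].copy()
    g_start = cis["gene_id"].map(lambda g: genes[g].start).to_numpy()
    g_end = cis["gene_id"].map(lambda g: genes[g].end).to_numpy()
    dist = _edge_distance(cis["dna_center"].to_numpy(), g_start, g_end)
    expr = expression[expression.index.intersection(
        cis["gene_id"].unique())]
    labels = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
    quart = pd.qcut(expr.rank(method="first"), n_quartiles,
                    labels=list(labels[:n_quartiles]))
    cis["quartile"] = cis["gene_id"].map(quart)
    dmax = max(dist.max(), 10)
    edges = np.concatenate([[0.0, 10.0],
                            np.geomspace(10.0, dmax + 1, n_dist_bins)[1:]])
    cis["dist_bin"] = pd.cut(dist, edges, right=False, include_lowest=True)
    table = (
        cis.groupby(["dist_bin", "quartile"], observed=False)
        .size().unstack("quartile", fill_value=0)
    )
    return table / table.sum(axis=0)


def fraction_below(pairs: pd.DataFrame, d: int = 1000) -> tuple[float, float]:
    """Fraction of pairs closer than ``d`` bp (nascent-transcription
    proxy): over all pairs, and restricted to cis pairs."""
    if len(pairs) == 0:
        return 0.0, 0.0
    cis = pairs["distance"] >= 0
    near = cis & (pairs["distance"] < d)
    frac_all = near.sum() / len(pairs)
    frac_cis = near.sum() / cis.sum() if cis.any() else 0.0
    return float(frac_all), float(frac_cis)


# ---------------------------------------------------------------------------
# metaprofiles and density


@dataclass(frozen=True)
class MetaProfile:
    """Mean per-bp tag rate over regions extended by their own width on
    both sides, chopped into ``n_bins`` position bins. The region proper
    occupies the central third (bins 100-199 for 300 bins)."""

    values: np.ndarray
    n_regions: int
    n_bins: int = 300


def _centers_by_chrom(centers: pd.DataFrame,
                      col: str = "pos") -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(sub[col].to_numpy())
        for chrom, sub in centers.groupby("chrom")
    }


def meta_profile(
    centers: pd.DataFrame,
    regions: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_bins: int = 300,
) -> MetaProfile:
    """Average tag-density profile around regions.

    ``centers`` has columns (chrom, pos); ``regions`` is BED-like. Each
    region [s, e) of width L defines the window [s - L, e + L); regions
    whose window leaves the chromosome are dropped. Counts per position
    bin are scaled to a per-bp rate, then averaged across regions.
    """
    by_chrom = _centers_by_chrom(centers)
    acc = np.zeros(n_bins)
    used = 0
    for row in regions.itertuples(index=False):
        L = row.end - row.start
        w0, w1 = row.start - L, row.end + L
        if w0 < 0 or w1 > chrom_lengths[row.chrom]:
            continue
        pos = by_chrom.get(row.chrom)
        if pos is None:
            counts = np.zeros(n_bins)
        else:
            edges = np.linspace(w0, w1, n_bins + 1)
            counts, _ = np.histogram(pos, bins=edges)
        acc += counts / (3.0 * L / n_bins)
        used += 1
    if used == 0:
        raise ValueError("no usable regions (all windows out of bounds)")
    return MetaProfile(acc / used, used, n_bins)


def inside_outside_profile(
    pairs: pd.DataFrame,
    tads: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_bins: int = 300,
) -> tuple[MetaProfile, MetaProfile]:
    """DNA-tag metaprofiles around TADs split by RNA origin.

    Processed TAD-by-TAD: for each TAD, pairs whose RNA tag center lies
    inside the TAD interval (half-open) feed the inside profile, all
    remaining pairs feed the outside profile, and both are aggregated over
    the TAD's 3x window like :func:`meta_profile`.
    """
    if len(tads) == 0:
        raise ValueError("no TADs supplied")
    acc = {"inside": np.zeros(n_bins), "outside": np.zeros(n_bins)}
    used = 0
    rna_chrom = pairs["rna_chrom"].to_numpy()
    rna_center = pairs["rna_center"].to_numpy()
    for row in tads.itertuples(index=False):
        L = row.end - row.start
        w0, w1 = row.start - L, row.end + L
        if w0 < 0 or w1 > chrom_lengths[row.chrom]:
            continue
        inside = (
            (rna_chrom == row.chrom)
            & (rna_center >= row.start) & (rna_center < row.end)
        )
        edges = np.linspace(w0, w1, n_bins + 1)
        for key, mask in (("inside", inside), ("outside", ~inside)):
            sub = pairs[mask]
            sub = sub[sub["dna_chrom"] == row.chrom]
            counts, _ = np.histogram(sub["dna_center"], bins=edges)
            acc[key] += counts / (3.0 * L / n_bins)
        used += 1
    if used == 0:
        raise ValueError("no usable TADs (all windows out of bounds)")
    return (MetaProfile(acc["inside"] / used, used, n_bins),
            MetaProfile(acc["outside"] / used, used, n_bins))


def peak_density_profile(
    centers: pd.DataFrame,
    peaks: pd.DataFrame,
    half_window: int = 5000,
    baseline: str = "window_mean",
) -> np.ndarray:
    """Per-bp tag density around peak centers, baseline-aligned.

    Counts at each offset in [-half_window, +half_window] are aggregated
    over all peaks and divided by the mean over the window (or over its
    outer 10% with ``baseline="edges"``) to align baselines.
    """
    by_chrom = _centers_by_chrom(centers)
    width = 2 * half_window + 1
    acc = np.zeros(width)
    for row in peaks.itertuples(index=False):
        pc = row.start + (row.end - row.start - 1) // 2
        pos = by_chrom.get(row.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, pc - half_window)
        hi = np.searchsorted(pos, pc + half_window, side="right")
        offs = pos[lo:hi] - pc + half_window
        acc += np.bincount(offs, minlength=width)[:width]
    if baseline == "window_mean":
        base = acc.mean()
    elif baseline == "edges":
        k = max(1, width // 10)
        base = np.concatenate([acc[:k], acc[-k:]]).mean()
    else:
        raise ValueError("baseline must be 'window_mean' or 'edges'")
    return acc / base if base > 0 else acc


def random_regions(
    peaks: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Random control regions matched in number and size to the peaks."""
    rows = []
    chroms = list(chrom_lengths)
    for row in peaks.itertuples(index=False):
        size = row.end - row.start
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_lengths[chrom] - size))
        rows.append((chrom, start, start + size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# repeats


def repeat_interval_proportions(
    pairs: pd.DataFrame,
    family_col: str = "repeat_family",
    interval_col: str = "distance_class",
    replicate_col: str = "replicate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of significant interactions per repeat family and
    distance interval, with per-interval t-tests against NR.

    The percentage divides the number of interactions of a family in a
    distance interval by the family's total RNA-tag count (per replicate,
    then averaged). Tests are two-sided equal-variance Student's t across
    replicate-level proportions, family vs the non-repeat (NR) class.
    Self-interactions must already be removed by the caller.
    """
    counts = (
        pairs.groupby([replicate_col, family_col, interval_col],
                      observed=False).size().rename("k").reset_index()
    )
    totals = (
        pairs.groupby([replicate_col, family_col], observed=False)
        .size().rename("total").reset_index()
    )
    merged = counts.merge(totals, on=[replicate_col, family_col])
    merged = merged[merged["total"] > 0]
    merged["pct"] = 100.0 * merged["k"] / merged["total"]
    pct = (
        merged.groupby([family_col, interval_col], observed=False)["pct"]
        .mean().unstack(interval_col, fill_value=0.0)
    )
    order = [c for c in DISTANCE_ORDER if c in pct.columns]
    pct = pct[order + [c for c in pct.columns if c not in order]]

    tests = []
    families = [f for f in pct.index if f != "NR"]
    for fam in families:
        for interval in pct.columns:
            a = _replicate_props(merged, replicate_col, family_col,
                                 interval_col, fam, interval)
            b = _replicate_props(merged, replicate_col, family_col,
                                 interval_col, "NR", interval)
            t, p = _student_t(a, b)
            tests.append((fam, interval, t, p))
    tests = pd.DataFrame(
        tests, columns=["family", "interval", "t", "p_value"])
    return pct, tests


def _replicate_props(merged, rep_col, fam_col, int_col, fam, interval):
    sub = merged[(merged[fam_col] == fam) & (merged[int_col] == interval)]
    reps = merged.loc[merged[fam_col] == fam, rep_col].unique()
    by_rep = sub.set_index(rep_col)["pct"]
    return np.array([by_rep.get(r, 0.0) for r in sorted(reps)])


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) == 0 or len(b) == 0:
        return float("nan"), float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance case: equal means are a non-result
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# cross-library comparisons


def binding_profiles(
    pairs: pd.DataFrame, bins5k: BinScheme, gene_col: str = "gene_id"
) -> dict[str, frozenset]:
    """Per-gene binary DNA-binding profiles: the set of 5-kb bins holding
    at least one DNA tag."""
    from .core import assign_bin

    df = pairs[pairs[gene_col].notna()]
    out: dict[str, set] = {}
    for gene, chrom, pos in zip(df[gene_col], df["dna_chrom"],
                                df["dna_center"]):
        out.setdefault(gene, set()).add(assign_bin(bins5k, chrom, int(pos)))
    return {g: frozenset(s) for g, s in out.items()}


def jaccard_vs_capture(
    binding_a: Mapping[str, frozenset],
    binding_b: Mapping[str, frozenset],
    counts_a: pd.Series,
    counts_b: pd.Series,
) -> pd.DataFrame:
    """Per-gene Jaccard distance between binary binding profiles and
    capture-rate difference (% of the maximum across conditions)."""
    genes = sorted(set(binding_a) | set(binding_b)
                   | set(counts_a.index) | set(counts_b.index))
    rows = []
    for g in genes:
        sa = binding_a.get(g, frozenset())
        sb = binding_b.get(g, frozenset())
        union = len(sa | sb)
        jd = 1.0 - len(sa & sb) / union if union else 0.0
        a = float(counts_a.get(g, 0.0))
        b = float(counts_b.get(g, 0.0))
        m = max(a, b)
        diff = abs(a - b) / m * 100.0 if m > 0 else 0.0
        rows.append((g, jd, diff))
    return pd.DataFrame(
        rows, columns=["gene_id", "jaccard_distance", "capture_diff_pct"]
    ).set_index("gene_id")


def _promoter_counts(pairs: pd.DataFrame,
                     promoters: Mapping[str, Interval]) -> pd.Series:
    trees: dict[str, IntervalTree] = {}
    for gene, iv in promoters.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, gene)
    counts = {g: 0 for g in promoters}
    for chrom, pos in zip(pairs["dna_chrom"], pairs["dna_center"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.at(int(pos)):
            counts[hit.data] += 1
    return pd.Series(counts, dtype=float)


def promoter_log2ratio(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    promoters: Mapping[str, Interval],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 ratio of library-size-normalized DNA tag counts in
    promoter windows between two libraries."""
    ca = _promoter_counts(pairs_a, promoters)
    cb = _promoter_counts(pairs_b, promoters)
    na = normalize_cpm(ca.to_numpy(), max(len(pairs_a), 1))
    nb = normalize_cpm(cb.to_numpy(), max(len(pairs_b), 1))
    return pd.Series(
        np.log2((na + pseudocount) / (nb + pseudocount)), index=ca.index,
        name="log2_ratio")


def unique_targets(matrix) -> pd.Series:
    """Number of distinct contacted bins per RNA (U)."""
    return matrix.unique_bins


def compartment_segregation(
    pairs: pd.DataFrame, compartments: pd.DataFrame
) -> tuple[float, dict]:
    """Fraction of pairs whose RNA and DNA tags fall in the same A/B
    compartment; unlabelled tags are excluded and counted."""
    trees: dict[str, IntervalTree] = {}
    for row in compartments.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            int(row.start), int(row.end), row.name)

    def label(chrom, pos):
        tree = trees.get(chrom)
        if tree is None:
            return None
        hits = tree.at(int(pos))
        return next(iter(hits)).data if hits else None

    same = labelled = excluded = 0
    for row in pairs.itertuples(index=False):
        la = label(row.rna_chrom, row.rna_center)
        lb = label(row.dna_chrom, row.dna_center)
        if la is None or lb is None:
            excluded += 1
            continue
        labelled += 1
        same += la == lb
    frac = same / labelled if labelled else 0.0
    return float(frac), {"labelled": labelled, "excluded": excluded,
                         "same_compartment": same}


def shared_trans(
    keys_a: Iterable[tuple], keys_b: Iterable[tuple]
) -> tuple[int, float]:
    """Shared (RNA, DNA-bin) pairs between two significant sets: count and
    percentage of the union."""
    a, b = set(keys_a), set(keys_b)
    union = a | b
    shared = len(a & b)
    pct = 100.0 * shared / len(union) if union else 0.0
    return shared, pct


def top_k_overlap(
    ranked_a: pd.Series, ranked_b: pd.Series, k: int = 10_000
) -> dict:
    """Overlap of the top-k genes of two rankings by normalized count;
    ties at rank k break by gene id. Returns Venn counts."""

    def topk(s: pd.Series) -> set:
        order = sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))
        return {g for g, _ in order[:min(k, len(order))]}

    ta, tb = topk(ranked_a), topk(ranked_b)
    return {
        "overlap": len(ta & tb),
        "a_only": len(ta - tb),
        "b_only": len(tb - ta),
    }


def dominant_class_matrix(
    pairs: pd.DataFrame,
    region_col: str = "region",
    class_col: str = "rna_class",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dominant RNA region and RNA class per (RNA source bin, DNA bin).

    The mode is taken per bin pair; ties break by the fixed label orders
    exon < intron < intergenic and protein_coding < long_ncRNA < ncRNA <
    other. Also returns the six-distance-class composition tables for
    regions and classes.
    """

    def dominant(col, order):
        rank = {label: i for i, label in enumerate(order)}
        counts = (
            pairs.groupby(["rna_bin", "dna_bin", col], observed=False)
            .size().rename("n").reset_index()
        )
        counts["rank"] = counts[col].map(rank)
        counts = counts.sort_values(
            ["rna_bin", "dna_bin", "n", "rank"],
            ascending=[True, True, False, True])
        return counts.drop_duplicates(["rna_bin", "dna_bin"]).set_index(
            ["rna_bin", "dna_bin"])[col]

    dom = pd.DataFrame({
        "region": dominant(region_col, REGION_ORDER),
        "rna_class": dominant(class_col, CLASS_ORDER),
    })

    def composition(col, order):
        t = (
            pairs.groupby(["distance_class", col], observed=False)
            .size().unstack(col, fill_value=0)
        )
        t = t.reindex([c for c in DISTANCE_ORDER if c in t.index])
        return 100.0 * t.div(t.sum(axis=1), axis=0).fillna(0.0)

    return (dom, composition(region_col, REGION_ORDER),
            composition(class_col, CLASS_ORDER))
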