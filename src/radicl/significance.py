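"""Significant RNA-chromatin interaction calling.

For each (RNA, genomic bin) pair with observed count k, the null model is
a one-sided cumulative binomial test with N trials and success probability
P, where N is the RNA's total interaction count genome-wide and P = 1/U
with U the number of distinct bins the RNA is seen to contact. p-values
are corrected over the full interaction list with the Benjamini-Hochberg
step-up procedure; interactions with adjusted p < alpha are significant,
and significant contacts falling in blacklisted regions are removed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .core import BinScheme

__all__ = [
    "ContactMatrix",
    "aggregate_matrix",
    "binom_pvalue",
    "bh_adjust",
    "call_significant",
]


@dataclass
class ContactMatrix:
    """Sparse RNA x bin counts with per-RNA totals.

    ``df`` has columns (rna_id, bin, count). N(r) is the RNA's genome-wide
    total, U(r) its number of distinct contacted bins (cis + trans alike).
    """

    df: pd.DataFrame
    bins: BinScheme | None = None

    def __post_init__(self) -> None:
        if len(self.df) and (self.df["count"] <= 0).any():
            raise ValueError("counts must be positive integers")

    @property
    def totals(self) -> pd.Series:
        """N(r): total interactions per RNA."""
        return self.df.groupby("rna_id")["count"].sum()

    @property
    def unique_bins(self) -> pd.Series:
        """U(r): distinct contacted bins per RNA."""
        return self.df.groupby("rna_id")["bin"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def to_triplets(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_triplets(cls, path, bins: BinScheme | None = None):
        return cls(pd.read_csv(path, sep="\t"), bins)


def aggregate_matrix(
    pairs: pd.DataFrame,
    bins: BinScheme | None = None,
    feature_col: str = "gene_id",
    bin_col: str = "dna_bin",
) -> ContactMatrix:
    """Count pairs per (RNA feature, DNA bin).

    ``feature_col`` selects the RNA feature level: a gene-assignment
    column for transcript-level calling, or ``rna_bin`` for source-bin
    level. Rows with a null feature (intergenic tags) are dropped.
    """
    if pairs.empty:
        return ContactMatrix(
            pd.DataFrame(columns=["rna_id", "bin", "count"]), bins)
    df = pairs[[feature_col, bin_col]].dropna()
    counts = (
        df.groupby([feature_col, bin_col], sort=True)
        .size()
        .reset_index(name="count")
        .rename(columns={feature_col: "rna_id", bin_col: "bin"})
    )
    return ContactMatrix(counts, bins)


def _log_tail(k: int, n: int, p: float) -> float:
    """log P(X >= k) by pmf summation in log space, with geometric
    early termination. Only valid (and only used) above the mode, where
    successive term ratios are < 1."""
    from math import exp, lgamma, log, log1p

    lp0 = (lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)
           + k * log(p) + (n - k) * log1p(-p))
    s = t = 1.0
    for i in range(k, n):
        t *= (n - i) / (i + 1) * p / (1.0 - p)
        s += t
        if t < s * 1e-18:
            break
    return lp0 + log(s)


def binom_pvalue(k, n, p):
    """One-sided cumulative binomial p-value P(X >= k | n, p).

    Computed through the survival function, which is numerically stable
    except very deep in the tail; values below 1e-50 are recomputed by
    direct log-space pmf summation to keep full relative accuracy.
    Vectorized over k and n.
    """
    from math import exp

    k = np.asarray(k)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if np.any((k < 0) | (k > n)):
        raise ValueError("k must satisfy 0 <= k <= N")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P must be in (0, 1]")
    out = np.asarray(sps.binom.sf(k - 1, n, p), dtype=float)
    deep = out < 1e-50
    if deep.any():
        kb, nb, pb = np.broadcast_arrays(k, n, p)
        flat = out.reshape(-1)
        for idx in np.flatnonzero(deep.reshape(-1)):
            ki = int(kb.reshape(-1)[idx])
            ni = int(nb.reshape(-1)[idx])
            pi = float(pb.reshape(-1)[idx])
            if pi < 1.0 and ki > 0:
                flat[idx] = exp(_log_tail(ki, ni, pi))
        out = flat.reshape(out.shape)
    return out if out.ndim else float(out)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending ordering, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _blacklist_trees(blacklist: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in blacklist.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            int(row.start), int(row.end))
    return trees


def call_significant(
    matrix: ContactMatrix,
    alpha: float = 0.05,
    blacklist: pd.DataFrame | None = None,
    blacklist_on: str = "bin",
    pair_centers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every observed (RNA, bin) pair and flag significant ones.

    BH correction runs jointly over the full interaction list. Blacklist
    filtering is applied to the significant set after correction: with
    ``blacklist_on="bin"`` a significant interaction is removed when its
    DNA bin interval intersects any blacklist interval; with
    ``blacklist_on="centers"`` removal keys on the raw tag centers given
    in ``pair_centers`` (columns rna_id, bin, rna_chrom, rna_center,
    dna_chrom, dna_center).

    Returns a table with k, N, P = 1/U, p_value, p_adjusted, blacklisted
    and significant columns.
    """
    df = matrix.df.copy()
    if df.empty:
        for col in ("N", "U", "P", "p_value", "p_adjusted"):
            df[col] = pd.Series(dtype=float)
        df["blacklisted"] = pd.Series(dtype=bool)
        df["significant"] = pd.Series(dtype=bool)
        return df
    totals = matrix.totals
    uniques = matrix.unique_bins
    df["N"] = df["rna_id"].map(totals).astype(int)
    df["U"] = df["rna_id"].map(uniques).astype(int)
    df["P"] = 1.0 / df["U"]
    df["p_value"] = binom_pvalue(
        df["count"].to_numpy(), df["N"].to_numpy(), df["P"].to_numpy())
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())

    blacklisted = np.zeros(len(df), dtype=bool)
    if blacklist is not None and len(blacklist):
        trees = _blacklist_trees(blacklist)
        if blacklist_on == "bin":
            if matrix.bins is None:
                raise ValueError("bin-level blacklisting needs a BinScheme")
            flagged = {}
            for b in df["bin"].unique():
                iv = matrix.bins.bin_interval(int(b))
                tree = trees.get(iv.chrom)
                flagged[b] = bool(tree and tree.overlap(iv.start, iv.end))
            blacklisted = df["bin"].map(flagged).to_numpy()
        elif blacklist_on == "centers":
            if pair_centers is None:
                raise ValueError("center-level blacklisting needs centers")
            hit_keys = set()
            for row in pair_centers.itertuples(index=False):
                for chrom, pos in ((row.rna_chrom, row.rna_center),
                                   (row.dna_chrom, row.dna_center)):
                    tree = trees.get(chrom)
                    if tree and tree.overlaps(pos):
                        hit_keys.add((row.rna_id, row.bin))
                        break
            blacklisted = np.array([
                (r, b) in hit_keys
                for r, b in zip(df["rna_id"], df["bin"])
            ])
        else:
            raise ValueError("blacklist_on must be 'bin' or 'centers'")
    df["blacklisted"] = blacklisted
    df["significant"] = (df["p_adjusted"] < alpha) & ~df["blacklisted"]
    return df
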