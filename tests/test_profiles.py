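import numpy as np
import pandas as pd
import pytest

from radicl.annotate import GeneModel
from radicl.core import GenomeBuild, Interval, make_bins
from radicl.profiles import (binding_profiles, compartment_segregation,
                             distance_decay, dominant_class_matrix,
                             expression_correlation, fraction_below,
                             inside_outside_profile, jaccard_vs_capture,
                             meta_profile, peak_density_profile,
                             promoter_log2ratio, repeat_interval_proportions,
                             replicate_correlation, shared_trans,
                             top_k_overlap, unique_targets)
from radicl.significance import ContactMatrix


def count_table(entries):
    return pd.DataFrame(entries, columns=["rna_id", "bin", "count"])


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"][:len(rows[0])])


class TestReplicateCorrelation:
    t1 = count_table([("a", 1, 5), ("a", 2, 3), ("b", 1, 8)])

    def test_identical_tables(self):
        r = replicate_correlation([self.t1, self.t1.copy()])
        assert r.iloc[0, 1] == pytest.approx(1.0)

    def test_scale_invariance(self):
        t2 = self.t1.assign(count=self.t1["count"] * 2)
        assert replicate_correlation([self.t1, t2]).iloc[0, 1] == (
            pytest.approx(1.0))

    def test_restricted_to_complete_observations(self):
        t2 = count_table([("a", 1, 5), ("c", 9, 100)])
        r = replicate_correlation([self.t1, t2])
        # only ("a", 1) is shared; a single point has undefined r
        assert np.isnan(r.iloc[0, 1])

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(0)
        n = 4000
        ta = count_table([("r", b, k) for b, k in
                          enumerate(rng.poisson(10, n) + 1)])
        tb = count_table([("r", b, k) for b, k in
                          enumerate(rng.poisson(10, n) + 1)])
        r = replicate_correlation([ta, tb]).iloc[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_needs_two_tables(self):
        with pytest.raises(ValueError):
            replicate_correlation([self.t1])


class TestExpressionCorrelation:
    def test_rpk_math_and_threshold(self):
        counts = pd.Series({"g1": 500, "g2": 1})
        lengths = pd.Series({"g1": 2_000, "g2": 2_000})  # g2: RPK 0.5
        tpm = pd.Series({"g1": 250.0, "g2": 100.0})
        r2, df = expression_correlation(counts, lengths, tpm)
        assert df["rpk"]["g1"] == 250.0
        assert "g2" not in df.index

    def test_identical_vectors_give_r2_one(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(3, 1, 50) + 1
        counts = pd.Series(vals * 2, index=[f"g{i}" for i in range(50)])
        lengths = pd.Series(2_000.0, index=counts.index)
        tpm = counts / (lengths / 1000)  # TPM == RPK
        r2, _ = expression_correlation(counts, lengths, tpm)
        assert r2 == pytest.approx(1.0)

    def test_no_survivors_is_an_error(self):
        with pytest.raises(ValueError):
            expression_correlation(
                pd.Series({"g": 1}), pd.Series({"g": 10_000}),
                pd.Series({"g": 0.1}))


class TestDistanceDecay:
    def make_pairs(self, gene_dists):
        rows = []
        for g, dists in gene_dists.items():
            for d in dists:
                rows.append(("r", "chr1", "chr1", g, 10_000 + d))
        return pd.DataFrame(rows, columns=[
            "read_id", "rna_chrom", "dna_chrom", "gene_id", "dna_center"])

    genes = {f"g{i}": GeneModel(f"g{i}", f"g{i}", "chr1", 9_000, 10_000,
                                "+", "protein_coding", ((9_000, 10_000),))
             for i in range(4)}

    def test_quartile_assignment_and_normalization(self):
        expr = pd.Series({"g0": 1.0, "g1": 2.0, "g2": 3.0, "g3": 4.0})
        pairs = self.make_pairs({g: [100, 1000] for g in expr.index})
        table = distance_decay(pairs, self.genes, expr)
        assert list(table.columns) == ["I", "II", "III", "IV"]
        assert np.allclose(table.sum(axis=0), 1.0)

    def test_zero_distance_mass_in_first_bin(self):
        expr = pd.Series({"g0": 1.0, "g1": 2.0, "g2": 3.0, "g3": 4.0})
        pairs = self.make_pairs({g: [-500] * 3 for g in expr.index})
        table = distance_decay(pairs, self.genes, expr)  # inside gene body
        assert np.allclose(table.iloc[0], 1.0)

    def test_recovers_decay_rank_order(self):
        """Steeper simulated decay for low-expression genes shows up as
        more short-range mass in low quartiles."""
        rng = np.random.default_rng(2)
        expr = pd.Series({"g0": 1.0, "g1": 2.0, "g2": 3.0, "g3": 4.0})
        alphas = {"g0": 4.0, "g1": 2.0, "g2": 1.0, "g3": 0.5}
        gene_dists = {
            g: (1_000 * (np.power(rng.random(3_000), -1 / a) - 1))
            .astype(int)
            for g, a in alphas.items()
        }
        pairs = self.make_pairs(
            {g: d[(d >= 0) & (d < 200_000)] for g, d in gene_dists.items()})
        table = distance_decay(pairs, self.genes, expr)
        short_mass = table.iloc[:6].sum(axis=0)
        assert (short_mass["I"] > short_mass["II"] > short_mass["III"]
                > short_mass["IV"])


class TestFractionBelow:
    def test_mixed(self):
        pairs = pd.DataFrame({"distance": [500, 2_000]})
        assert fraction_below(pairs) == (0.5, 0.5)

    def test_all_trans(self):
        pairs = pd.DataFrame({"distance": [-1, -1]})
        assert fraction_below(pairs) == (0.0, 0.0)

    def test_trans_dilutes_total_only(self):
        pairs = pd.DataFrame({"distance": [500, -1]})
        frac_all, frac_cis = fraction_below(pairs)
        assert (frac_all, frac_cis) == (0.5, 1.0)


CHROMS = {"chr1": 1_000_000}


class TestMetaProfile:
    def test_window_arithmetic_drops_unfit_regions(self):
        centers = pd.DataFrame({"chrom": ["chr1"], "pos": [5_000]})
        regions = bed([("chr1", 1_000, 4_000),      # window [-2000, 7000)
                       ("chr1", 10_000, 13_000)])   # fits
        prof = meta_profile(centers, regions, CHROMS)
        assert prof.n_regions == 1
        with pytest.raises(ValueError):
            meta_profile(centers, bed([("chr1", 1_000, 4_000)]), CHROMS)

    def test_uniform_coverage_is_flat(self):
        rng = np.random.default_rng(3)
        n = 200_000
        centers = pd.DataFrame({
            "chrom": "chr1", "pos": rng.integers(0, CHROMS["chr1"], n)})
        regions = bed([("chr1", s, s + 3_000)
                       for s in range(100_000, 400_000, 30_000)])
        prof = meta_profile(centers, regions, CHROMS)
        rho = n / CHROMS["chr1"]
        w = 3 * 3_000 / 300
        sd = np.sqrt(rho / (prof.n_regions * w))
        frac_within = np.mean(np.abs(prof.values - rho) < 3 * sd)
        assert frac_within >= 0.99

    def test_signal_inside_regions_fills_central_bins_only(self):
        rng = np.random.default_rng(4)
        regions = bed([("chr1", 100_000, 103_000),
                       ("chr1", 200_000, 203_000)])
        pos = np.concatenate([
            rng.integers(r.start, r.end, 2_000)
            for r in regions.itertuples(index=False)])
        centers = pd.DataFrame({"chrom": "chr1", "pos": pos})
        prof = meta_profile(centers, regions, CHROMS)
        assert prof.values[:100].sum() == 0
        assert prof.values[200:].sum() == 0
        assert prof.values[100:200].min() > 0


class TestInsideOutsideProfile:
    def test_confined_interactions_split_cleanly(self):
        """DNA tags confined to the RNA's own TAD appear only in the
        central bins of the inside profile; the outside profile stays
        empty."""
        rng = np.random.default_rng(5)
        tads = bed([("chr1", 100_000, 110_000),
                    ("chr1", 500_000, 510_000)])
        rows = []
        for t in tads.itertuples(index=False):
            for _ in range(1_000):
                rows.append(("chr1", rng.integers(t.start, t.end),
                             "chr1", rng.integers(t.start, t.end)))
        pairs = pd.DataFrame(rows, columns=[
            "rna_chrom", "rna_center", "dna_chrom", "dna_center"])
        inside, outside = inside_outside_profile(pairs, tads, CHROMS)
        assert inside.values[100:200].sum() > 0
        assert inside.values[:100].sum() == 0
        assert inside.values[200:].sum() == 0
        # every pair is inside one of the two distant TADs, so the other
        # TAD's outside profile sees nothing within its window
        assert outside.values.sum() == 0

    def test_no_tads_is_an_error(self):
        pairs = pd.DataFrame(columns=["rna_chrom", "rna_center",
                                      "dna_chrom", "dna_center"])
        with pytest.raises(ValueError):
            inside_outside_profile(pairs, bed([("chr1", 0, 1)]).iloc[:0],
                                   CHROMS)

    def test_boundary_rna_belongs_to_halfopen_interval(self):
        tads = bed([("chr1", 100_000, 110_000)])
        pairs = pd.DataFrame({
            "rna_chrom": ["chr1", "chr1"],
            "rna_center": [100_000, 110_000],  # start in, end out
            "dna_chrom": ["chr1", "chr1"],
            "dna_center": [105_000, 105_000]})
        inside, outside = inside_outside_profile(pairs, tads, CHROMS)
        assert inside.values.sum() > 0 and outside.values.sum() > 0


class TestPeakDensity:
    def test_uniform_tags_give_flat_unit_profile(self):
        rng = np.random.default_rng(6)
        centers = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(0, CHROMS["chr1"], 500_000)})
        peaks = bed([("chr1", s, s + 500)
                     for s in range(100_000, 300_000, 20_000)])
        prof = peak_density_profile(centers, peaks)
        assert prof.mean() == pytest.approx(1.0)
        assert prof.std() < 1.0  # no systematic structure

    def test_tags_at_peak_centers_spike_at_zero(self):
        peaks = bed([("chr1", 1_000, 1_101), ("chr1", 5_000, 5_101)])
        centers = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                "pos": [1_050, 5_050]})
        prof = peak_density_profile(centers, peaks)
        assert prof.argmax() == 5_000  # offset 0


class TestRepeatProportions:
    def make_pairs(self, spec):
        # spec: {(replicate, family): {interval: count}}
        rows = []
        for (rep, fam), intervals in spec.items():
            for interval, k in intervals.items():
                rows += [(rep, fam, interval)] * k
        return pd.DataFrame(rows, columns=["replicate", "repeat_family",
                                           "distance_class"])

    def test_stated_percentage_formula(self):
        pairs = self.make_pairs({
            (1, "LINE"): {"local": 10, "long": 90},
            (1, "NR"): {"local": 50, "long": 50},
        })
        pct, _ = repeat_interval_proportions(pairs)
        assert pct.loc["LINE", "local"] == pytest.approx(10.0)

    def test_identical_groups_give_null_t(self):
        pairs = self.make_pairs({
            (1, "LINE"): {"local": 10, "long": 90},
            (2, "LINE"): {"local": 10, "long": 90},
            (1, "NR"): {"local": 10, "long": 90},
            (2, "NR"): {"local": 10, "long": 90},
        })
        _, tests = repeat_interval_proportions(pairs)
        row = tests.set_index(["family", "interval"]).loc[("LINE", "local")]
        assert (row["t"], row["p_value"]) == (0.0, 1.0)

    def test_planted_long_range_family_detected(self):
        rng = np.random.default_rng(7)
        spec = {}
        for rep in (1, 2, 3):
            j = int(rng.integers(0, 3))
            spec[(rep, "LINE")] = {"long": 80 + j, "local": 20 - j}
            spec[(rep, "NR")] = {"long": 20 + j, "local": 80 - j}
        _, tests = repeat_interval_proportions(self.make_pairs(spec))
        row = tests.set_index(["family", "interval"]).loc[("LINE", "long")]
        assert row["p_value"] < 0.01 and row["t"] > 0


class TestJaccardCapture:
    def test_identical_profiles(self):
        prof = {"g": frozenset({1, 2, 3})}
        df = jaccard_vs_capture(prof, prof, pd.Series({"g": 10.0}),
                                pd.Series({"g": 10.0}))
        assert df.loc["g"].tolist() == [0.0, 0.0]

    def test_disjoint_profiles(self):
        df = jaccard_vs_capture({"g": frozenset({1})},
                                {"g": frozenset({2})},
                                pd.Series({"g": 1.0}),
                                pd.Series({"g": 1.0}))
        assert df.loc["g", "jaccard_distance"] == 1.0

    def test_worked_example(self):
        df = jaccard_vs_capture(
            {"g": frozenset({1, 2, 3})}, {"g": frozenset({2, 3, 4})},
            pd.Series({"g": 80.0}), pd.Series({"g": 100.0}))
        assert df.loc["g", "jaccard_distance"] == pytest.approx(0.5)
        assert df.loc["g", "capture_diff_pct"] == pytest.approx(20.0)

    def test_both_empty_is_zero_distance(self):
        df = jaccard_vs_capture({}, {}, pd.Series({"g": 0.0}),
                                pd.Series({"g": 0.0}))
        assert df.loc["g"].tolist() == [0.0, 0.0]

    def test_binding_profiles_are_binary_sets(self):
        genome = GenomeBuild(("chr1",), (20_000,))
        bins5k = make_bins(genome, 5_000)
        pairs = pd.DataFrame({
            "gene_id": ["g", "g", "g"],
            "dna_chrom": ["chr1"] * 3,
            "dna_center": [100, 200, 7_000]})  # two tags in bin 0
        prof = binding_profiles(pairs, bins5k)
        assert prof["g"] == frozenset({0, 1})


class TestPromoterRatio:
    promoters = {"g": Interval("chr1", 8_000, 12_000)}

    def pairs_at(self, positions):
        return pd.DataFrame({"dna_chrom": "chr1",
                             "dna_center": positions})

    def test_equal_counts_give_zero(self):
        a = self.pairs_at([9_000, 10_000])
        assert promoter_log2ratio(a, a.copy(), self.promoters)["g"] == 0.0

    def test_double_counts_give_one(self):
        a = self.pairs_at([9_000, 9_500, 10_000, 10_500])
        b = self.pairs_at([9_000, 9_500, 50_000, 60_000])
        ratio = promoter_log2ratio(a, b, self.promoters, pseudocount=0.0)
        assert ratio["g"] == pytest.approx(1.0)


class TestUniqueTargetsAndOverlap:
    def test_unique_targets(self):
        m = ContactMatrix(pd.DataFrame(
            [("R", 7, 3), ("R", 9, 1)], columns=["rna_id", "bin", "count"]))
        assert unique_targets(m)["R"] == 2

    def test_shared_identical(self):
        assert shared_trans({("r", 1)}, {("r", 1)}) == (1, 100.0)

    def test_shared_disjoint(self):
        assert shared_trans({("r", 1)}, {("q", 2)}) == (0, 0.0)

    def test_shared_partial(self):
        shared, pct = shared_trans(
            {("r1", "b1"), ("r2", "b2")}, {("r1", "b1"), ("r3", "b3")})
        assert shared == 1 and pct == pytest.approx(100 / 3)

    def test_topk_identical(self):
        s = pd.Series({f"g{i}": float(i) for i in range(20)})
        assert top_k_overlap(s, s, k=10)["overlap"] == 10

    def test_topk_disjoint_halves(self):
        a = pd.Series({f"g{i}": float(i) for i in range(10)})
        b = pd.Series({f"g{i}": 10.0 - i for i in range(10)})
        out = top_k_overlap(a, b, k=5)
        assert out["overlap"] == 0 and out["a_only"] == 5

    def test_topk_ties_break_by_gene_id(self):
        s = pd.Series({"b": 1.0, "a": 1.0, "c": 1.0})
        out_ab = top_k_overlap(s, pd.Series({"a": 1.0, "b": 2.0}), k=2)
        assert out_ab["overlap"] == 2  # picks {a, b} from the tie


class TestCompartments:
    comp = bed([("chr1", 0, 50_000, "A"), ("chr1", 50_000, 100_000, "B")])

    def make_pairs(self, coords):
        return pd.DataFrame(coords, columns=[
            "rna_chrom", "rna_center", "dna_chrom", "dna_center"])

    def test_all_within_one_compartment(self):
        pairs = self.make_pairs([("chr1", 10, "chr1", 20)] * 5)
        frac, info = compartment_segregation(pairs, self.comp)
        assert frac == 1.0 and info["excluded"] == 0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(8)
        pairs = self.make_pairs([
            ("chr1", rng.integers(0, 100_000),
             "chr1", rng.integers(0, 100_000))
            for _ in range(2_000)])
        frac, _ = compartment_segregation(pairs, self.comp)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2_000)

    def test_unlabelled_excluded_and_counted(self):
        pairs = self.make_pairs([("chr1", 10, "chr2", 20)])
        frac, info = compartment_segregation(pairs, self.comp)
        assert info["excluded"] == 1


class TestDominantClass:
    def make_pairs(self, labels):
        rows = [(1, 2, region, cls, "local") for region, cls in labels]
        return pd.DataFrame(rows, columns=[
            "rna_bin", "dna_bin", "region", "rna_class", "distance_class"])

    def test_mode_wins(self):
        pairs = self.make_pairs([("intron", "other")] * 3
                                + [("exon", "protein_coding")])
        dom, _, _ = dominant_class_matrix(pairs)
        assert dom.loc[(1, 2), "region"] == "intron"

    def test_tie_breaks_by_fixed_order(self):
        pairs = self.make_pairs(
            [("exon", "ncRNA")] * 2 + [("intron", "long_ncRNA")] * 2)
        dom, _, _ = dominant_class_matrix(pairs)
        assert dom.loc[(1, 2), "region"] == "exon"
        assert dom.loc[(1, 2), "rna_class"] == "long_ncRNA"

    def test_single_interaction_keeps_own_label(self):
        dom, _, _ = dominant_class_matrix(
            self.make_pairs([("intergenic", "other")]))
        assert dom.loc[(1, 2), "region"] == "intergenic"

    def test_composition_rows_sum_to_100(self, processed):
        pairs, _ = processed
        genic = pairs[pairs["rna_class"].notna()]
        _, by_region, by_class = dominant_class_matrix(genic)
        assert np.allclose(by_region.sum(axis=1), 100.0, atol=1e-9)
        assert np.allclose(by_class.sum(axis=1), 100.0, atol=1e-9)
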