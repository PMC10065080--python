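"""Accessibility classification, nearest-DEG linking, transition proportions,
and the proportion / rank statistics, against brute-force and closed-form
oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gatarescue import chromatin
from gatarescue.chromatin import (
    classify_transitions,
    differential_peaks,
    link_to_nearest_deg,
    promoter_signal,
    promoter_window,
    proportion_test,
    rank_tests,
)


def _annotation(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "length"])
    return df.set_index("gene_id", drop=False)


def _peaks(rows):
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])


class TestDifferentialPeaks:
    def test_strict_threshold_excludes_near_boundary(self, rng):
        # true fold change just under 2x: log2FC below 1 -> unchanged even
        # when highly significant
        n = 60
        base = rng.integers(300, 800, size=n).astype(float)
        cols = {f"a{j}": rng.poisson(base) for j in range(4)}
        cols.update({f"b{j}": rng.poisson(base * 1.9) for j in range(4)})
        counts = pd.DataFrame(cols)
        sf = pd.Series(1.0, index=counts.columns)
        res = differential_peaks(
            counts, [f"a{j}" for j in range(4)], [f"b{j}" for j in range(4)],
            size_factors_=sf,
        )
        below = res["log2fc"] <= 1.0
        assert (res.loc[below, "class"] == "unchanged").all()

    def test_power_at_strong_shift(self, rng):
        """Peaks with a true 4-fold opening at baseline 200 are classified
        opening in at least 95% of 500 simulated peaks."""
        n = 500
        size = 1 / 0.05
        mu_a = np.full(n, 200.0)
        mu_b = mu_a * 4.0
        cols = {f"a{j}": rng.negative_binomial(size, size / (size + mu_a)) for j in range(4)}
        cols.update(
            {f"b{j}": rng.negative_binomial(size, size / (size + mu_b)) for j in range(4)}
        )
        counts = pd.DataFrame(cols)
        sf = pd.Series(1.0, index=counts.columns)
        res = differential_peaks(
            counts, [f"a{j}" for j in range(4)], [f"b{j}" for j in range(4)],
            size_factors_=sf,
        )
        assert (res["class"] == "opening").mean() >= 0.95


class TestNearestLink:
    def test_peak_at_tss_links_with_zero_distance(self):
        ann = _annotation([("gA", "chr1", "+", 5000, 1000)])
        peaks = _peaks([("p1", "chr1", 4800, 5200)])
        links = link_to_nearest_deg(peaks, {"gA"}, ann)
        assert links.loc[0, "gene_id"] == "gA"
        assert links.loc[0, "distance"] == 0

    def test_equidistant_tie_breaks_to_smaller_id(self):
        ann = _annotation(
            [("gB", "chr1", "+", 10000, 1000), ("gA", "chr1", "+", 20000, 1000)]
        )
        peaks = _peaks([("p1", "chr1", 14800, 15200)])  # midpoint 15000
        links = link_to_nearest_deg(peaks, {"gA", "gB"}, ann)
        assert links.loc[0, "gene_id"] == "gA"

    def test_strand_aware_signed_distance(self):
        ann = _annotation(
            [("plus", "chr1", "+", 1000, 500), ("minus", "chr2", "-", 1000, 500)]
        )
        peaks = _peaks([("p1", "chr1", 1400, 1600), ("p2", "chr2", 1400, 1600)])
        links = link_to_nearest_deg(peaks, {"plus", "minus"}, ann).set_index("peak_id")
        assert links.loc["p1", "distance"] == 500   # downstream of plus gene
        assert links.loc["p2", "distance"] == -500  # upstream of minus gene

    def test_cap_and_missing_chromosome_unlink(self):
        ann = _annotation([("gA", "chr1", "+", 0, 1000)])
        peaks = _peaks([("far", "chr1", 200000, 200400), ("other", "chr9", 0, 400)])
        links = link_to_nearest_deg(peaks, {"gA"}, ann, max_dist=100_000)
        assert links["gene_id"].isna().all()

    def test_matches_brute_force_on_random_instances(self, rng):
        n_genes, n_peaks = 120, 250
        chroms = ["chr1", "chr2"]
        ann = _annotation(
            [
                (f"g{i:03d}", chroms[i % 2], "+", int(rng.integers(0, 10**6)), 1000)
                for i in range(n_genes)
            ]
        )
        degs = set(rng.choice(ann["gene_id"].to_numpy(), size=40, replace=False))
        starts = rng.integers(0, 10**6, size=n_peaks)
        peaks = _peaks(
            [
                (f"p{i:03d}", chroms[int(rng.integers(2))], int(s), int(s) + 400)
                for i, s in enumerate(starts)
            ]
        )
        links = link_to_nearest_deg(peaks, degs, ann).set_index("peak_id")
        deg_ann = ann[ann["gene_id"].isin(degs)]
        for _, peak in peaks.iterrows():
            mid = (peak["start"] + peak["end"]) // 2
            best = None
            for _, gene in deg_ann.iterrows():
                if gene["chrom"] != peak["chrom"]:
                    continue
                d = abs(gene["tss"] - mid)
                if best is None or d < best[0] or (d == best[0] and gene["gene_id"] < best[1]):
                    best = (d, gene["gene_id"])
            got = links.loc[peak["peak_id"], "gene_id"]
            if best is None:
                assert pd.isna(got)
            else:
                assert got == best[1]


class TestTransitions:
    def test_mixed_gene_counts_in_both_numerators(self):
        links = pd.DataFrame(
            {"peak_id": ["p1", "p2"], "gene_id": ["g", "g"], "distance": [0, 0],
             "abs_distance": [0, 0]}
        )
        classes = {"p1": "opening", "p2": "closing"}
        _, props = classify_transitions(links, classes, {"cohort": {"g"}})
        row = props.iloc[0]
        assert row["n_opening"] == 1 and row["n_closing"] == 1
        assert row["pct_opening"] == 100.0 and row["pct_closing"] == 100.0

    def test_empty_cohort_undefined_not_zero(self):
        links = pd.DataFrame(columns=["peak_id", "gene_id", "distance", "abs_distance"])
        _, props = classify_transitions(links, {}, {"empty": set()})
        assert math.isnan(props.iloc[0]["pct_opening"])


class TestProportionTest:
    def test_equal_proportions_p_one(self):
        z, p = proportion_test(30, 100, 30, 100)
        assert z == 0.0 and p == 1.0

    def test_matches_textbook_formula(self):
        x1, n1, x2, n2 = 35, 100, 40, 100
        z, p = proportion_test(x1, n1, x2, n2)
        # independent closed-form computation
        from scipy.stats import norm

        p1, p2 = x1 / n1, x2 / n2
        pbar = (x1 + x2) / (n1 + n2)
        se = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        cc = 0.5 * (1 / n1 + 1 / n2)
        z_ref = (abs(p1 - p2) - cc) / se
        assert z == pytest.approx(z_ref, abs=1e-10)
        assert p == pytest.approx(2 * norm.sf(z_ref), abs=1e-10)

    def test_correction_floors_statistic(self):
        z, p = proportion_test(50, 1000, 51, 1000)
        assert z == 0.0 and p == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            proportion_test(1, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_test(11, 10, 1, 10)


class TestRankTests:
    def test_signed_rank_exact_constant_shift(self):
        _, p = rank_tests(np.ones(6), np.zeros(6), kind="signed_rank_paired")
        assert p == pytest.approx(2 / 64)

    def test_one_sample_vs_zero_shift(self):
        _, p = rank_tests(np.ones(6), kind="rank_sum_vs_zero_shift")
        assert p == pytest.approx(2 / 64)

    def test_identical_samples_p_one(self):
        x = np.arange(30, dtype=float)
        _, p = rank_tests(x, x, kind="mann_whitney_two_sample")
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_warn_p_one(self):
        with pytest.warns(UserWarning):
            _, p = rank_tests(np.zeros(8), kind="rank_sum_vs_zero_shift")
        assert p == 1.0

    def test_exact_vs_normal_approximation_near_agreement(self, rng):
        """At n = 20 per group the exact and asymptotic Mann-Whitney p-values
        differ by less than 0.01 on random tie-free instances."""
        for _ in range(25):
            x = rng.normal(size=20)
            y = rng.normal(0.3, size=20)
            _, p_exact = rank_tests(x, y, kind="mann_whitney_two_sample", exact_max=25)
            _, p_norm = rank_tests(x, y, kind="mann_whitney_two_sample", exact_max=5)
            assert abs(p_exact - p_norm) < 0.01

    def test_small_sample_exact_enumeration_oracle(self, rng):
        """Mann-Whitney at n=5 vs 5: p equals full enumeration over all
        C(10,5) group assignments."""
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            _, p = rank_tests(x, y, kind="mann_whitney_two_sample")
            pooled = np.concatenate([x, y])
            u_obs = sum(1 for xi in x for yi in y if xi > yi)
            n = len(pooled)
            us = []
            for comb in itertools.combinations(range(n), 5):
                xs = pooled[list(comb)]
                ys = np.delete(pooled, list(comb))
                us.append(sum(1 for xi in xs for yi in ys if xi > yi))
            us = np.array(us)
            mean_u = 12.5
            p_ref = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
            assert p == pytest.approx(p_ref, abs=1e-8)


class TestPromoter:
    def test_window_coordinates_plus_and_minus(self):
        assert promoter_window(10_000, "+") == (8_000, 10_100)
        assert promoter_window(10_000, "-") == (9_900, 12_000)

    def test_aggregation_matches_brute_force(self, rng):
        n_genes, n_peaks = 30, 80
        ann = _annotation(
            [
                (f"g{i:02d}", "chr1", rng.choice(["+", "-"]), int(rng.integers(5000, 100000)), 1000)
                for i in range(n_genes)
            ]
        )
        starts = rng.integers(0, 100000, size=n_peaks)
        peaks = pd.DataFrame(
            {
                "peak_id": [f"p{i}" for i in range(n_peaks)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + 300,
            }
        ).set_index("peak_id", drop=False)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(n_peaks, 3)),
            index=peaks.index,
            columns=["s1", "s2", "s3"],
        )
        got = promoter_signal(peaks, counts, ann)
        for gene_id, strand, tss in zip(ann["gene_id"], ann["strand"], ann["tss"]):
            w0, w1 = promoter_window(int(tss), strand)
            expected = np.zeros(3)
            for pid, s, e in zip(peaks["peak_id"], peaks["start"], peaks["end"]):
                if s < w1 and e > w0:
                    expected += counts.loc[pid].to_numpy()
            assert np.allclose(got.loc[gene_id].to_numpy(), expected)
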