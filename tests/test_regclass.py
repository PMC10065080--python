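"""Regulatory catalog definitions, printed-style percentage arithmetic,
rescue fractions, retained activity, robustness scans and z-scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatarescue import regclass
from gatarescue.diffexpr import DEGSet
from gatarescue.regclass import (
    build_catalog,
    category_counts,
    cutoff_robustness_scan,
    expressed_filter,
    percent,
    percent_max_regulation,
    rescue_fraction,
    retained_activity,
    summarize_fractions,
    venn_counts,
    zscore_expression,
)


def _contrast(genes, lfc, padj=None, tpm_a=None, tpm_b=None):
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": lfc,
            "padj": padj if padj is not None else [1e-9] * len(genes),
        }
    )
    return df.set_index("gene_id", drop=False)


class TestCatalog:
    def test_category_definitions(self):
        empty = DEGSet({})
        cat = build_catalog(empty, DEGSet({"g": "activated"}), empty)
        assert cat.loc["g", "category"] == "I.II"
        cat = build_catalog(
            empty, DEGSet({"g": "activated"}), DEGSet({"g": "activated"})
        )
        assert cat.loc["g", "category"] == "I.I"
        cat = build_catalog(empty, empty, DEGSet({"g": "activated"}))
        assert cat.loc["g", "category"] == "III"
        cat = build_catalog(empty, DEGSet({"g": "repressed"}), DEGSet({"g": "repressed"}))
        assert cat.loc["g", "category"] == "II.I"
        cat = build_catalog(empty, empty, DEGSet({"g": "repressed"}))
        assert cat.loc["g", "category"] == "IV"

    def test_discordant_gene_labeled_per_contrast(self):
        cat = build_catalog(
            DEGSet({}), DEGSet({"g": "activated"}), DEGSet({"g": "repressed"})
        )
        row = cat.loc["g"]
        assert row["category"] == "discordant"
        assert row["category_activated"] == "I.II"
        assert row["category_repressed"] == "IV"
        assert row["discordant"]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_partition_identities_on_random_deg_sets(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(60)]

        def random_degs():
            out = {}
            for g in genes:
                u = rng.random()
                if u < 0.25:
                    out[g] = "activated"
                elif u < 0.5:
                    out[g] = "repressed"
            return DEGSet(out)

        enh, res, var = random_degs(), random_degs(), random_degs()
        cat = build_catalog(enh, res, var)
        counts = category_counts(cat)
        assert counts["I"] == counts["I.I"] + counts["I.II"]
        assert counts["II"] == counts["II.I"] + counts["II.II"]
        if len(cat):
            act = cat["category_activated"]
            assert set(cat.loc[act == "I.I", "gene_id"]) == res.activated & var.activated
            assert set(cat.loc[act == "I.II", "gene_id"]) == res.activated - var.activated
            assert set(cat.loc[act == "III", "gene_id"]) == var.activated - res.activated
        # Venn-region counts per side sum to the union of that side's DEGs
        for side, sets in (
            ("activated", (enh.activated, res.activated, var.activated)),
            ("repressed", (enh.repressed, res.repressed, var.repressed)),
        ):
            assert sum(venn_counts(cat, side).values()) == len(set().union(*sets))


class TestPercentArithmetic:
    @pytest.mark.parametrize(
        "x, n, decimals, expected",
        [
            (1061 - 144, 1061, 1, 86.4),
            (1077 - 381, 1077, 1, 64.6),
            (144, 1061, 0, 14),
            (381, 1077, 0, 35),
            (4768, 7258, 0, 66),
            (4541, 6724, 0, 68),
            (0, 10, 1, 0.0),
        ],
    )
    def test_half_up_percentages(self, x, n, decimals, expected):
        assert percent(x, n, decimals) == expected

    def test_zero_denominator_is_undefined(self):
        assert math.isnan(percent(5, 0))

    def test_summary_table_from_class_counts(self):
        counts = {"I": 1061, "I.I": 144, "II": 1077, "II.I": 381}
        table = summarize_fractions(counts).set_index("side")
        assert table.loc["activated", "pct_not_shared"] == 86.4
        assert table.loc["activated", "pct_shared"] == 14
        assert table.loc["repressed", "pct_not_shared"] == 64.6
        assert table.loc["repressed", "pct_shared"] == 35


class TestRescueFraction:
    def test_self_concordance(self, rng):
        genes = [f"g{i}" for i in range(200)]
        lfc = rng.normal(size=200)
        lfc[lfc == 0] = 0.1
        c = _contrast(genes, lfc)
        out = rescue_fraction(c, c)
        assert out["activated"]["fraction"] == 1.0
        assert out["repressed"]["fraction"] == 1.0

    def test_independent_signs_give_half(self, rng):
        n = 4000
        genes = [f"g{i}" for i in range(n)]
        a = _contrast(genes, rng.choice([-1.0, 1.0], size=n))
        b = _contrast(genes, rng.choice([-1.0, 1.0], size=n))
        out = rescue_fraction(a, b)
        for side in ("activated", "repressed"):
            frac, nn = out[side]["fraction"], out[side]["n"]
            sd = math.sqrt(0.25 / nn)
            assert abs(frac - 0.5) <= 3 * sd

    def test_printed_count_formatting(self):
        assert percent(4768, 7258, 0) == 66


class TestRetainedActivity:
    @staticmethod
    def _tpm(genes, samples, value=10.0):
        return pd.DataFrame(value, index=genes, columns=samples)

    def test_identical_contrasts_give_full_retention(self):
        genes = [f"g{i}" for i in range(20)]
        lfc = np.linspace(1.0, 3.0, 20)
        c = _contrast(genes, lfc)
        tpm = self._tpm(genes, ["r1", "r2", "e1", "e2"])
        out = retained_activity(
            c, c, tpm, {"activated": ["r1", "r2"], "repressed": ["e1", "e2"]}
        )
        assert out["activated"]["median_retained_pct"] == pytest.approx(100.0)

    def test_half_effect_is_fifty_percent_log_scale(self):
        c_res = _contrast(["g"], [2.0])
        c_var = _contrast(["g"], [1.0])
        tpm = self._tpm(["g"], ["r1", "e1"])
        fs = {"activated": ["r1"], "repressed": ["e1"]}
        out = retained_activity(c_res, c_var, tpm, fs)
        assert out["activated"]["table"]["retained_pct"].iloc[0] == pytest.approx(50.0)
        lin = retained_activity(c_res, c_var, tpm, fs, scale="linear")
        assert lin["activated"]["table"]["retained_pct"].iloc[0] == pytest.approx(
            100 * (2**1 - 1) / (2**2 - 1)
        )

    def test_tpm_filter_excludes_and_logs(self):
        genes = ["g1", "g2"]
        c = _contrast(genes, [2.0, 2.0])
        tpm = pd.DataFrame({"r1": [5.0, 0.5], "e1": [5.0, 5.0]}, index=genes)
        out = retained_activity(c, c, tpm, {"activated": ["r1"], "repressed": ["e1"]})
        assert out["activated"]["count"] == 1
        assert out["activated"]["dropped_by_tpm"] == 1

    def test_simulation_recovery_of_sixty_percent(self, rng):
        n = 400
        genes = [f"g{i}" for i in range(n)]
        res_lfc = rng.uniform(1.7, 3.5, size=n)
        var_lfc = 0.6 * res_lfc + rng.normal(0, 0.05, size=n)
        c_res = _contrast(genes, res_lfc)
        c_var = _contrast(genes, var_lfc)
        tpm = self._tpm(genes, ["r1", "e1"])
        out = retained_activity(
            c_res, c_var, tpm, {"activated": ["r1"], "repressed": ["e1"]}
        )
        assert abs(out["activated"]["median_retained_pct"] - 60.0) <= 5.0


class TestRobustnessScan:
    def test_identical_contrasts_give_zero_ectopic(self, rng):
        n = 300
        genes = [f"g{i}" for i in range(n)]
        lfc = rng.normal(0, 2, size=n)
        padj = rng.random(size=n) * 0.2
        c = _contrast(genes, lfc, padj)
        scan = cutoff_robustness_scan(c, c, mode="ectopic")
        assert len(scan.table) == 10
        pct = scan.table[["pct_activated", "pct_repressed"]].to_numpy(dtype=float)
        assert np.nansum(pct) == 0.0

    def test_complete_separation_gives_exact_mannwhitney_p(self):
        """Constant impairment percentages with every activated value above
        every repressed value: the two-sided exact p at n=10 vs 10 is
        2/C(20,10) = 2/184,756."""
        genes_act = [f"a{i}" for i in range(10)]
        genes_rep = [f"r{i}" for i in range(10)]
        # activated: 10 rescue DEGs, 5 variant DEGs -> impairment 50%
        # repressed: 10 rescue DEGs, 9 variant DEGs -> impairment 10%
        res = _contrast(
            genes_act + genes_rep, [2.0] * 10 + [-2.0] * 10, [1e-9] * 20
        )
        var = _contrast(
            genes_act + genes_rep,
            [2.0] * 5 + [0.0] * 5 + [-2.0] * 9 + [0.0],
            [1e-9] * 20,
        )
        scan = cutoff_robustness_scan(res, var, mode="impairment")
        assert (scan.table["pct_activated"] == 50.0).all()
        assert (scan.table["pct_repressed"] == 10.0).all()
        assert scan.mannwhitney_p == pytest.approx(2 / math.comb(20, 10))

    def test_requires_two_cutoffs(self):
        c = _contrast(["g"], [2.0], [0.01])
        with pytest.raises(ValueError):
            cutoff_robustness_scan(c, c, cutoffs=[0.05])


class TestPercentMax:
    def test_endpoints_and_midpoint(self):
        expr = pd.DataFrame(
            {"empty": [10.0], "full_rescue": [50.0], "v_full": [50.0],
             "v_none": [10.0], "v_mid": [30.0]},
            index=["g"],
        )
        out = percent_max_regulation(expr, "activation")
        assert out.loc["g", "v_full"] == pytest.approx(100.0)
        assert out.loc["g", "v_none"] == pytest.approx(0.0)
        assert out.loc["g", "v_mid"] == pytest.approx(50.0)
        assert out.loc["g", "v_mid_retained"]  # exactly 50% counts as retained

    def test_zero_dynamic_range_excluded(self):
        expr = pd.DataFrame(
            {"empty": [10.0, 5.0], "full_rescue": [10.0, 20.0], "v": [12.0, 10.0]},
            index=["flat", "ok"],
        )
        out = percent_max_regulation(expr, "activation")
        assert list(out.index) == ["ok"]

    def test_repression_direction(self):
        expr = pd.DataFrame(
            {"empty": [40.0], "full_rescue": [10.0], "v": [25.0]}, index=["g"]
        )
        out = percent_max_regulation(expr, "repression")
        assert out.loc["g", "v"] == pytest.approx(50.0)


class TestZscoreAndFilter:
    def test_constant_row_zero(self):
        f = pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]})
        assert (zscore_expression(f) == 0).all().all()

    def test_zero_fpkm_finite(self):
        f = pd.DataFrame({"a": [0.0], "b": [0.0]})
        z = zscore_expression(f)
        assert np.isfinite(z).all().all()
        assert (z == 0).all().all()

    def test_normalization_identity(self, rng):
        f = pd.DataFrame(rng.random(size=(30, 8)) * 100)
        z = zscore_expression(f)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_expressed_filter_boundary_and_scope(self):
        tpm = pd.DataFrame(
            {"c1_r1": [1.0, 0.99, 2.0], "c1_r2": [1.0, 2.0, 2.0], "c2_r1": [1.0, 2.0, 0.0]},
            index=["boundary", "low_rep", "low_cond"],
        )
        assert expressed_filter(tpm, scope="all_conditions") == {"boundary"}
        got = expressed_filter(
            tpm, scope="all_replicates_of_condition", samples=["c1_r1", "c1_r2"]
        )
        assert got == {"boundary", "low_cond"}

    def test_expressed_filter_constructed_cohort(self, rng):
        genes = [f"ets{i}" for i in range(26)]
        tpm = pd.DataFrame(rng.uniform(1, 50, size=(26, 6)), index=genes)
        failing = rng.choice(26, size=11, replace=False)
        tpm.iloc[failing, 2] = 0.2
        got = expressed_filter(tpm, scope="all_conditions")
        expected = set(np.delete(np.array(genes, dtype=object), failing))
        assert got == expected
        assert len(got) == 15
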