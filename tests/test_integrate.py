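"""Mark tiers, correlation groups, enrichment, category summaries, K9 domains."""

import math

import numpy as np
import pandas as pd
import pytest

from chromtx.integrate import (
    assign_groups,
    call_k9_domains,
    category_enrichment,
    category_mark_summary,
    cluster_flanking,
    deregulation_fractions,
    split_by_mark,
)
from chromtx.tracks import BinnedTrack


def hypergeom_upper_tail(k, N, K, n) -> float:
    """Independent closed-form tail sum via exact binomial coefficients."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / denom


class TestSplitByMark:
    def test_boundary_value_goes_low(self):
        levels = pd.Series({"a": 5.0, "b": 5.01, "c": 4.0})
        tier = split_by_mark(levels, mark="H3K4me3")
        assert tier["a"] == "low" and tier["b"] == "high" and tier["c"] == "low"

    def test_k36_threshold_default(self):
        tier = split_by_mark(pd.Series({"a": 2.0, "b": 2.5}), mark="H3K36me3")
        assert tier.tolist() == ["low", "high"]

    def test_masked_gene_excluded_and_reported(self):
        levels = pd.Series({"a": 6.0, "b": np.nan})
        tier = split_by_mark(levels, mark="H3K4me3")
        assert "b" not in tier.index
        assert tier.attrs["skipped"] == ["b"]

    def test_unknown_mark_without_threshold_rejected(self):
        with pytest.raises(ValueError, match="H3K4me3"):
            split_by_mark(pd.Series({"a": 1.0}), mark="H3K27me3")


class TestAssignGroups:
    @pytest.mark.parametrize(
        "tier,call,expect",
        [
            ("low", "up_in_WT", "G1"),
            ("low", "up_in_mutant", "G2"),
            ("high", "up_in_WT", "G3"),
            ("high", "up_in_mutant", "G4"),
        ],
    )
    def test_group_table(self, tier, call, expect):
        out = assign_groups(pd.Series({"g": tier}), pd.Series({"g": call}))
        assert out.loc["g", "group"] == expect

    def test_ns_gets_no_group_and_sm_base_offsets(self):
        out = assign_groups(pd.Series({"g": "low"}), pd.Series({"g": "ns"}), base=5)
        assert pd.isna(out.loc["g", "group"])
        out2 = assign_groups(
            pd.Series({"g": "high"}), pd.Series({"g": "up_in_mutant"}), base=5
        )
        assert out2.loc["g", "group"] == "G8"

    def test_groups_partition_de_called_genes(self):
        rng = np.random.default_rng(0)
        n = 300
        tiers = pd.Series(rng.choice(["low", "high"], n), index=[f"g{i}" for i in range(n)])
        calls = pd.Series(
            rng.choice(["up_in_WT", "up_in_mutant", "ns"], n), index=tiers.index
        )
        out = assign_groups(tiers, calls)
        n_called = (calls != "ns").sum()
        assert out["group"].notna().sum() == n_called
        assert out.groupby("group").size().sum() == n_called


class TestCategoryEnrichment:
    def test_empty_set_p_one(self):
        cats = pd.Series({"a": "SM", "b": "CSF", "c": "CSF"})
        assert category_enrichment([], cats, "SM").p == 1.0

    def test_worked_example_exact_fraction(self):
        # N=20, K=5, n=4, k=3 -> [C(5,3)C(15,1)+C(5,4)C(15,0)] / C(20,4)
        cats = pd.Series(
            {f"g{i}": ("SM" if i < 5 else "CSF") for i in range(20)}
        )
        gene_set = ["g0", "g1", "g2", "g5"]
        res = category_enrichment(gene_set, cats, "SM")
        assert res.k == 3 and res.K == 5 and res.n == 4 and res.N == 20
        assert res.p == pytest.approx(155 / 4845, abs=1e-15)

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            N = int(rng.integers(2, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(0, N + 1))
            cats = pd.Series(
                {f"g{i}": ("SM" if i < K else "CSF") for i in range(N)}
            )
            chosen = list(rng.choice(N, n, replace=False))
            gene_set = [f"g{i}" for i in chosen]
            k = sum(i < K for i in chosen)
            res = category_enrichment(gene_set, cats, "SM")
            assert res.p == pytest.approx(hypergeom_upper_tail(k, N, K, n), rel=1e-12)

    def test_genome_scale_counts_highly_significant(self):
        # 97 of 149 SM vs 401 of 5676 CSF genes down in the mutant at 48 h
        cats = pd.Series(
            ["SM"] * 149 + ["CSF"] * 5676,
            index=[f"g{i}" for i in range(5825)],
        )
        down = [f"g{i}" for i in range(97)] + [f"g{i}" for i in range(149, 149 + 401)]
        res = category_enrichment(down, cats, "SM")
        assert res.k == 97 and res.n == 498 and res.N == 5825
        assert res.p < 1e-10

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError):
            category_enrichment(["a"], pd.Series({"a": "CSF"}), "SM")


class TestDeregulationFractions:
    def test_reported_counts_arithmetic(self):
        calls = pd.Series(
            ["up_in_WT"] * 97 + ["up_in_mutant"] * 22 + ["ns"] * 30,
            index=[f"g{i}" for i in range(149)],
        )
        cats = pd.Series("SM", index=calls.index)
        row = deregulation_fractions(calls, cats).loc["SM"]
        assert row["pct_deregulated"] == pytest.approx(100 * 119 / 149)
        assert row["pct_down"] == pytest.approx(100 * 97 / 149)

    def test_no_deregulation_is_zero(self):
        calls = pd.Series(["ns"] * 10, index=[f"g{i}" for i in range(10)])
        cats = pd.Series("CSF", index=calls.index)
        assert deregulation_fractions(calls, cats).loc["CSF", "pct_deregulated"] == 0.0

    def test_one_in_ten_up(self):
        calls = pd.Series(["up_in_mutant"] + ["ns"] * 9, index=[f"g{i}" for i in range(10)])
        cats = pd.Series("CSF", index=calls.index)
        assert deregulation_fractions(calls, cats).loc["CSF", "pct_up"] == 10.0


class TestCategoryMarkSummary:
    def test_single_gene_category_quartiles_collapse(self):
        levels = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0})
        cats = pd.Series({"a": "SM", "b": "CSF", "c": "CSF"})
        out = category_mark_summary(levels, cats)
        assert out.loc["SM", ["q25", "median", "q75"]].tolist() == [3.0, 3.0, 3.0]

    def test_null_rank_sum_p_roughly_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            levels = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
            cats = pd.Series(["CSF"] * 40 + ["SM"] * 20, index=levels.index)
            out = category_mark_summary(levels, cats)
            ps.append(out.attrs["mannwhitney_p"])
        # identical distributions: p below 0.05 about 5% of the time
        assert 0.005 < np.mean(np.asarray(ps) < 0.05) < 0.12

    def test_planted_eightfold_difference_detected(self):
        rng = np.random.default_rng(3)
        csf = rng.normal(6, 0.5, 200)
        sm = rng.normal(6 - 3, 0.5, 30)  # 1/8 in linear scale = -3 in log2
        levels = pd.Series(
            np.concatenate([csf, sm]), index=[f"g{i}" for i in range(230)]
        )
        cats = pd.Series(["CSF"] * 200 + ["SM"] * 30, index=levels.index)
        out = category_mark_summary(levels, cats)
        assert out.loc["CSF", "median"] > out.loc["SM", "median"]
        assert out.attrs["mannwhitney_p"] < 0.01


class TestK9Domains:
    def _track(self, arr, step=10):
        return BinnedTrack({"chr1": np.asarray(arr, float)}, bin_size=step, step=step,
                           genome_lengths={"chr1": len(arr) * step})

    def test_flat_zero_no_domains(self):
        assert call_k9_domains(self._track(np.zeros(500)), threshold_cpm=1.0).empty

    def test_single_rectangle_single_domain(self):
        arr = np.zeros(1000)
        arr[100:600] = 8.0  # 5 kb at 10-bp bins
        doms = call_k9_domains(self._track(arr), threshold_cpm=4.0)
        assert len(doms) == 1
        assert doms.iloc[0]["start"] == 1000 and doms.iloc[0]["end"] == 6000

    def test_gap_merging_rule(self):
        arr = np.zeros(1000)
        arr[0:150] = 8.0     # 1.5 kb
        arr[180:330] = 8.0   # 300 bp gap, then 1.5 kb
        doms = call_k9_domains(self._track(arr), threshold_cpm=4.0,
                               min_len=2000, merge_gap=500)
        assert len(doms) == 1
        assert doms.iloc[0]["end"] - doms.iloc[0]["start"] == 3300

    def test_min_length_filter(self):
        arr = np.zeros(1000)
        arr[0:150] = 8.0
        doms = call_k9_domains(self._track(arr), threshold_cpm=4.0, min_len=2000)
        assert doms.empty


class TestClusterFlanking:
    def _ann(self):
        from chromtx.annotation import GenomeAnnotation

        genes = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [20_000, 22_000, 24_000],
                "end": [21_500, 23_500, 25_500],
                "strand": ["+", "-", "+"],
                "category": ["SM"] * 3,
                "cluster_id": [0.0, 0.0, 0.0],
            },
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        return GenomeAnnotation(genes, {"chr1": 100_000})

    def test_abutting_both_sides(self):
        doms = pd.DataFrame(
            [{"chrom": "chr1", "start": 15_000, "end": 20_000, "mean_cpm": 9.0},
             {"chrom": "chr1", "start": 25_500, "end": 30_000, "mean_cpm": 9.0}]
        )
        rep = cluster_flanking(doms, self._ann(), max_gap=5000)
        assert rep.iloc[0]["classification"] == "both"
        assert rep.iloc[0]["dist_left"] == 0 and rep.iloc[0]["dist_right"] == 0

    def test_left_only(self):
        doms = pd.DataFrame(
            [{"chrom": "chr1", "start": 14_000, "end": 18_000, "mean_cpm": 9.0}]
        )
        rep = cluster_flanking(doms, self._ann(), max_gap=5000)
        assert rep.iloc[0]["classification"] == "one"
        assert rep.iloc[0]["flanked_left"] and not rep.iloc[0]["flanked_right"]

    def test_far_domain_is_none(self):
        doms = pd.DataFrame(
            [{"chrom": "chr1", "start": 60_000, "end": 70_000, "mean_cpm": 9.0}]
        )
        rep = cluster_flanking(doms, self._ann(), max_gap=5000)
        assert rep.iloc[0]["classification"] == "none"

    def test_mirror_invariance(self):
        ann = self._ann()
        doms = pd.DataFrame(
            [{"chrom": "chr1", "start": 14_000, "end": 18_000, "mean_cpm": 9.0}]
        )
        rep = cluster_flanking(doms, ann, max_gap=5000)
        L = 100_000
        m_doms = pd.DataFrame(
            [{"chrom": "chr1", "start": L - 18_000, "end": L - 14_000, "mean_cpm": 9.0}]
        )
        m_rep = cluster_flanking(m_doms, ann.mirrored(), max_gap=5000)
        assert rep.iloc[0]["classification"] == m_rep.iloc[0]["classification"]
        assert rep.iloc[0]["dist_left"] == m_rep.iloc[0]["dist_right"]
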