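"""Tajima's D, window classes, constraint binning, nearest-neighbor pairing,
damaging fractions and enrichment tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cosnp import strata as st


def oracle_tajimas_d(genotypes):
    """Independent re-implementation with the published constants."""
    g = np.asarray(genotypes)
    n = g.shape[0]
    counts = g.sum(0)
    counts = counts[(counts > 0) & (counts < n)]
    s = counts.size
    pi = sum(2 * c * (n - c) for c in counts) / (n * (n - 1) / 1)
    pi = pi / 1
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


class TestTajimasD:
    def test_five_haplotypes_one_singleton(self):
        g = np.zeros((5, 1), dtype=int)
        g[0, 0] = 1
        d = st.tajimas_d(g)
        # hand computation: pi = 0.4, theta_W = 1/a1 = 0.48, sqrt(var) = 0.0979796
        assert d == pytest.approx(-0.81649658, abs=1e-6)
        assert d == pytest.approx(oracle_tajimas_d(g), abs=1e-9)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 12))
            s = int(rng.integers(1, 20))
            g = (rng.random((n, s)) < rng.uniform(0.1, 0.9)).astype(int)
            if not (((g.sum(0) > 0) & (g.sum(0) < n)).any()):
                continue
            assert st.tajimas_d(g) == pytest.approx(oracle_tajimas_d(g), abs=1e-9)

    def test_zero_when_pi_equals_theta_w(self):
        # n=4: a1 = 11/6; one site at frequency 2/4 gives pi = 8/12 = 2/3.
        # choose S sites so pi == S/a1: with all sites at count 2, pi = 2S/3,
        # theta_W = 6S/11 -> never equal; instead verify permutation invariance
        g = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 0], [1, 0, 1]])
        d1 = st.tajimas_d(g)
        d2 = st.tajimas_d(g[::-1])
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            st.tajimas_d(np.zeros((3, 5), dtype=int))
        with pytest.raises(ValueError):
            st.tajimas_d(np.zeros((6, 5), dtype=int))


class TestWindowClasses:
    def test_dominance_hierarchy(self):
        cosnps = pd.DataFrame(
            {
                "chrom": ["c1"] * 4,
                "coord": [10, 50, 150_000, 250_000],
                "degeneracy": ["four", "zero", "four", "two_three"],
            }
        )
        win = st.classify_cosnp_windows(cosnps, width=100_000)
        by_win = win.set_index("window")["cosnp_class"]
        assert by_win[0] == "cosnp_i0"        # zero-fold dominates the four-fold
        assert by_win[1] == "cosnp_i4"
        assert by_win[2] == "cosnp_i23"

    def test_classes_partition_windows_with_cosnps(self, rng):
        cosnps = pd.DataFrame(
            {
                "chrom": rng.choice(["c1", "c2"], 200),
                "coord": rng.integers(0, 1_000_000, 200),
                "degeneracy": rng.choice(["zero", "two_three", "four"], 200),
            }
        )
        win = st.classify_cosnp_windows(cosnps, width=100_000)
        # recount oracle
        cosnps = cosnps.assign(window=cosnps["coord"] // 100_000)
        expected = {}
        for (chrom, w), grp in cosnps.groupby(["chrom", "window"]):
            degs = set(grp["degeneracy"])
            if "zero" in degs:
                expected[(chrom, w)] = "cosnp_i0"
            elif "two_three" in degs:
                expected[(chrom, w)] = "cosnp_i23"
            else:
                expected[(chrom, w)] = "cosnp_i4"
        got = {(r["chrom"], r["window"]): r["cosnp_class"] for _, r in win.iterrows()}
        assert got == expected

    def test_window_class_comparisons_run(self, rng):
        windows = pd.DataFrame(
            {
                "cosnp_class": ["cosnp_i0"] * 40 + ["cosnp_i4"] * 40,
                "tajimas_d": rng.normal(0, 1, 80),
            }
        )
        out = st.compare_window_classes(windows)
        assert (out["p_value"] > 0).all()
        assert (out["test"] == "chi2_equal_proportions").any()


class TestEqualSizeGroups:
    def test_distinct_scores_even_split(self):
        labels = st.equal_size_groups(np.arange(1, 11), 5)
        assert [list(labels).count(g) for g in range(5)] == [2] * 5

    def test_ties_to_lower_bin_and_partition(self):
        scores = np.array([1, 1, 1, 2, 2, 3, 4, 5, 6, 7])
        labels = st.equal_size_groups(scores, 5)
        assert len(labels) == len(scores)
        assert (labels[scores == 1] == labels[scores == 1][0]).all()
        assert (labels[scores == 2] == labels[scores == 2][0]).all()

    def test_singletons_and_degenerate(self, caplog):
        assert list(st.equal_size_groups(np.array([3.0, 1.0, 2.0]), 3)) == [2, 0, 1]
        with caplog.at_level("WARNING", logger="cosnp"):
            labels = st.equal_size_groups(np.ones(5), 2)
        assert (labels == 0).all()
        with pytest.raises(ValueError):
            st.equal_size_groups(np.arange(3), 5)


class TestGroupTrend:
    @staticmethod
    def counts_from_oe(oes):
        rows = []
        for i, oe in enumerate(oes):
            n_sites, n_a, n_b = 100_000, 1000, 1000
            n_co = round(oe * n_a * n_b / n_sites)
            rows.append({"group": i, "n_sites": n_sites, "n_a": n_a,
                         "n_b": n_b, "n_co": n_co})
        return pd.DataFrame(rows)

    def test_monotone_extremes(self):
        _, rho, p = st.group_oe_trend(self.counts_from_oe([1, 2, 3, 4, 5]))
        assert rho == pytest.approx(1.0)
        assert p < 0.05
        _, rho, p = st.group_oe_trend(self.counts_from_oe([5, 4, 3, 2, 1]))
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        oes = [1.2, 3.4, 2.2, 4.0, 2.8, 3.9]
        table, rho, _ = st.group_oe_trend(self.counts_from_oe(oes),
                                          alternative="two-sided")
        oracle = sps.spearmanr(np.arange(len(oes)), table["oe"]).statistic
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_undefined_group_dropped(self):
        counts = self.counts_from_oe([1, 2, 3, 4])
        counts.loc[1, ["n_a", "n_co"]] = 0
        table, rho, _ = st.group_oe_trend(counts)
        assert len(table) == 3
        assert rho == pytest.approx(1.0)


class TestNearestNeighbor:
    def test_distance_and_tie_rules(self):
        focal = pd.DataFrame({"gene_id": ["g"], "coord_a": [100], "score": [1.0]})
        cands = pd.DataFrame(
            {"gene_id": ["g"] * 3, "coord_a": [93, 105, 107], "score": [2.0, 3.0, 4.0]}
        )
        out = st.nearest_neighbor_match(focal, cands)
        assert out.loc[0, "match_coord"] == 105  # distance 5 beats 7
        cands_tie = pd.DataFrame(
            {"gene_id": ["g"] * 2, "coord_a": [96, 104], "score": [2.0, 3.0]}
        )
        out = st.nearest_neighbor_match(focal, cands_tie)
        assert out.loc[0, "match_coord"] == 96   # equidistant -> lower coordinate

    def test_missing_candidates_dropped(self, caplog):
        focal = pd.DataFrame({"gene_id": ["g1", "g2"], "coord_a": [5, 9]})
        cands = pd.DataFrame({"gene_id": ["g1"], "coord_a": [7]})
        with caplog.at_level("INFO", logger="cosnp"):
            out = st.nearest_neighbor_match(focal, cands)
        assert list(out["gene_id"]) == ["g1"]

    def test_invariant_to_input_order(self, rng):
        focal = pd.DataFrame(
            {"gene_id": rng.choice(["g1", "g2"], 20),
             "coord_a": rng.choice(10_000, 20, replace=False)}
        )
        cands = pd.DataFrame(
            {"gene_id": rng.choice(["g1", "g2"], 40),
             "coord_a": rng.choice(10_000, 40, replace=False)}
        )
        a = st.nearest_neighbor_match(focal, cands)
        b = st.nearest_neighbor_match(
            focal.sample(frac=1, random_state=1),
            cands.sample(frac=1, random_state=2),
        )
        pd.testing.assert_frame_equal(a, b)

    def test_paired_test_variants(self, rng):
        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0.5, 0.3, 50)
        t_stat, t_p = st.paired_score_test(x, y, method="t")
        oracle = sps.ttest_rel(x, y)
        assert t_stat == pytest.approx(oracle.statistic)
        w_stat, w_p = st.paired_score_test(x, y, method="wilcoxon")
        assert w_p < 0.01


class TestDamagingAndEnrichment:
    def test_threshold_boundaries(self):
        scores = pd.DataFrame(
            {"sift": [0.05, 0.051], "grantham": [100.0, 101.0],
             "polyphen": ["possibly", "benign"]}
        )
        frac = st.damaging_fraction(scores)
        assert frac["sift"] == 0.5        # 0.05 inclusive
        assert frac["grantham"] == 0.5    # 100 is not damaging, 101 is
        assert frac["polyphen"] == 0.5

    def test_fisher_matches_enumeration(self):
        g1 = pd.DataFrame({"sift": [0.01] * 6 + [0.5] * 14})
        g2 = pd.DataFrame({"sift": [0.01] * 2 + [0.5] * 18})
        out = st.compare_damaging(g1, g2)
        row = out[out["metric"] == "sift"].iloc[0]
        oracle = sps.fisher_exact([[6, 14], [2, 18]])[1]
        assert row["p_value"] == pytest.approx(oracle, rel=1e-12)

    def test_two_by_two_enrichment(self):
        odds, p = st.two_by_two_enrichment((10, 90), (5, 95))
        assert odds == pytest.approx((10 * 95) / (90 * 5))
        # enumeration oracle for the two-tailed exact p
        n1, n2, k_total = 100, 100, 15
        obs = math.comb(n1, 10) * math.comb(n2, 5) / math.comb(n1 + n2, k_total)
        total = sum(
            math.comb(n1, k) * math.comb(n2, k_total - k)
            for k in range(0, k_total + 1)
        )
        oracle = sum(
            math.comb(n1, k) * math.comb(n2, k_total - k)
            for k in range(0, k_total + 1)
            if math.comb(n1, k) * math.comb(n2, k_total - k)
            / math.comb(n1 + n2, k_total) <= obs * (1 + 1e-12)
        ) / math.comb(n1 + n2, k_total)
        assert p == pytest.approx(oracle, rel=1e-9)
        # equal proportions -> OR 1
        odds, p = st.two_by_two_enrichment((10, 90), (20, 180))
        assert odds == pytest.approx(1.0)
        with pytest.raises(ValueError):
            st.two_by_two_enrichment((0, 0), (1, 1))

    def test_equal_proportions(self):
        stat, p = st.equal_proportions_test([10, 20], [100, 200])
        assert stat == pytest.approx(0.0, abs=1e-12)
        # two classes reduce to the 2x2 chi-square
        stat, p = st.equal_proportions_test([12, 20], [100, 200])
        oracle = sps.chi2_contingency(
            [[12, 88], [20, 180]], correction=False
        )
        assert stat == pytest.approx(oracle.statistic, rel=1e-12)
        # three-class formula oracle
        succ, tot = np.array([5, 9, 14]), np.array([50, 60, 70])
        stat, _ = st.equal_proportions_test(succ, tot)
        p_pool = succ.sum() / tot.sum()
        oracle_stat = np.sum(
            (succ - tot * p_pool) ** 2 / (tot * p_pool)
            + ((tot - succ) - tot * (1 - p_pool)) ** 2 / (tot * (1 - p_pool))
        )
        assert stat == pytest.approx(oracle_stat, rel=1e-12)
        with pytest.raises(ValueError):
            st.equal_proportions_test([1], [10])
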