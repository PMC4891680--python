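"""coSNP matching, O/E ratio, independence test, patterns, SFS, rare variants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from cosnp import stats as cs
from cosnp.stats import CoSNPCounts


def make_sites(n):
    return pd.DataFrame(
        {
            "gene_id": "g",
            "chrom_a": "c1",
            "coord_a": np.arange(n),
            "degeneracy": "zero",
            "cpg_a": False,
            "cpg_b": False,
            "masked": False,
        }
    )


def make_variants(site_idx, species, allele_ref="A", allele_alt="G", maf=0.1):
    site_idx = list(site_idx)
    return pd.DataFrame(
        {
            "site": site_idx,
            "species": species,
            "allele_ref": allele_ref,
            "allele_alt": allele_alt,
            "maf": maf,
        }
    )


class TestClassifyAndCounts:
    def test_partition_of_toy_layout(self):
        sites = make_sites(10)
        va = make_variants([0, 3, 7], "A")
        vb = make_variants([3, 5], "B")
        classes = cs.classify_sites(va, vb, sites)
        counts = classes.value_counts()
        assert counts["cosnp"] == 1
        assert counts["nonco_a_only"] == 2
        assert counts["nonco_b_only"] == 1
        assert counts["nonsnp"] == 6

    def test_masked_and_duplicate_sites_excluded(self, caplog):
        sites = make_sites(10)
        sites.loc[9, "masked"] = True
        va = make_variants([0, 0, 9], "A")  # duplicate record at site 0
        vb = make_variants([1], "B")
        with caplog.at_level("INFO", logger="cosnp"):
            classes = cs.classify_sites(va, vb, sites)
        assert pd.isna(classes[0])          # multi-record site leaves universe
        assert pd.isna(classes[9])          # masked site not examined
        assert classes[1] == "nonco_b_only"

    def test_counts_invariant_enforced(self):
        with pytest.raises(ValueError):
            CoSNPCounts("x", n_sites=10, n_a=3, n_b=2, n_co=4)


class TestCosnpOE:
    @pytest.mark.parametrize(
        "n_sites,n_a,n_b,n_co,expected",
        [(100, 10, 10, 1, 1.0), (1000, 50, 40, 8, 4.0), (1000, 50, 40, 0, 0.0)],
    )
    def test_arithmetic(self, n_sites, n_a, n_b, n_co, expected):
        assert cs.cosnp_oe(CoSNPCounts("x", n_sites, n_a, n_b, n_co)) == expected

    def test_undefined_without_snps(self):
        with pytest.raises(ValueError):
            cs.cosnp_oe(CoSNPCounts("x", 10, 0, 2, 0))

    def test_matches_brute_force_recount_on_random_inputs(self, rng):
        """O/E from the pipeline equals a set-intersection recount, 100 toys."""
        for _ in range(100):
            n = int(rng.integers(20, 200))
            sites = make_sites(n)
            a_pos = rng.choice(n, size=rng.integers(1, n // 2), replace=False)
            b_pos = rng.choice(n, size=rng.integers(1, n // 2), replace=False)
            classes = cs.classify_sites(
                make_variants(np.sort(a_pos), "A"),
                make_variants(np.sort(b_pos), "B"), sites
            )
            counts = cs.count_sites(classes)
            shared = len(set(a_pos) & set(b_pos))
            expected = shared * n / (len(a_pos) * len(b_pos))
            assert cs.cosnp_oe(counts) == pytest.approx(expected)

    @given(
        n_extra=hst.integers(0, 50),
        n_a=hst.integers(1, 30),
        n_b=hst.integers(1, 30),
        n_co=hst.integers(0, 29),
    )
    @settings(max_examples=60, deadline=None)
    def test_adding_a_cosnp_never_decreases_oe(self, n_extra, n_a, n_b, n_co):
        n_co = min(n_co, n_a - 1, n_b - 1)
        if n_co < 0:
            return
        n_sites = n_a + n_b - n_co + n_extra
        before = cs.cosnp_oe(CoSNPCounts("x", n_sites, n_a, n_b, n_co))
        # one previously single-species pair of SNPs becomes coincident
        after = cs.cosnp_oe(CoSNPCounts("x", n_sites, n_a, n_b, n_co + 1))
        assert after > before


class TestChiSquare:
    def test_exactly_independent_margins(self):
        counts = CoSNPCounts("x", 1000, 100, 50, 5)  # 5 = 100*50/1000
        stat, p, _ = cs.chisq_independence(counts)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_against_textbook_formula(self):
        counts = CoSNPCounts("x", 1000, 50, 40, 8)
        stat, p, low = cs.chisq_independence(counts)
        table = np.array([[8, 42], [32, 918]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(oracle, 1), rel=1e-12)

    def test_against_permutation_null(self, rng):
        """Asymptotic p agrees with a Monte-Carlo permutation p.

        Permuting which sites are species-B-polymorphic while holding the
        margins makes the shared count hypergeometric.
        """
        counts = CoSNPCounts("x", 2000, 120, 100, 11)
        _, p_asym, _ = cs.chisq_independence(counts)
        draws = rng.hypergeometric(counts.n_a, counts.n_sites - counts.n_a,
                                   counts.n_b, size=10_000)
        expected = counts.n_a * counts.n_b / counts.n_sites
        p_perm = np.mean(np.abs(draws - expected) >= abs(counts.n_co - expected))
        assert p_asym == pytest.approx(p_perm, abs=0.02)


class TestPatternOE:
    def test_degenerate_single_pattern(self):
        sites = make_sites(20)
        va = make_variants([0, 1, 2], "A", allele_ref="C", allele_alt="T")
        vb = make_variants([0, 5], "B", allele_ref="C", allele_alt="T")
        classes = cs.classify_sites(va, vb, sites)
        table = cs.pattern_oe(classes, va, vb)
        assert len(table) == 1
        assert table.iloc[0]["oe"] == pytest.approx(1.0)
        assert bool(table.iloc[0]["same_pattern"])

    def test_against_exhaustive_tally(self, rng):
        n = 400
        sites = make_sites(n)
        pats = ["A/G", "C/T", "A/C", "G/T"]

        def draw(species, k):
            pos = np.sort(rng.choice(n, size=k, replace=False))
            chosen = rng.choice(pats, size=k)
            ref = [p[0] for p in chosen]
            alt = [p[2] for p in chosen]
            return pd.DataFrame({"site": pos, "species": species,
                                 "allele_ref": ref, "allele_alt": alt, "maf": 0.2})

        va, vb = draw("A", 120), draw("B", 100)
        classes = cs.classify_sites(va, vb, sites)
        table = cs.pattern_oe(classes, va, vb)
        co = set(classes[classes == "cosnp"].index)
        pa = dict(zip(va["site"], [cs.pattern_of(r, a) for r, a in
                                   zip(va["allele_ref"], va["allele_alt"])]))
        pb = dict(zip(vb["site"], [cs.pattern_of(r, a) for r, a in
                                   zip(vb["allele_ref"], vb["allele_alt"])]))
        for _, row in table.iterrows():
            obs = sum(1 for s in co
                      if pa[s] == row["pattern_a"] and pb[s] == row["pattern_b"])
            frac_a = sum(1 for v in pa.values() if v == row["pattern_a"]) / len(pa)
            frac_b = sum(1 for v in pb.values() if v == row["pattern_b"]) / len(pb)
            assert row["observed"] == pytest.approx(obs / len(co))
            assert row["expected"] == pytest.approx(frac_a * frac_b)
        # observed fractions are a normalised distribution over cells
        assert table["observed"].sum() == pytest.approx(1.0)


class TestSFSAndRareVariants:
    def test_top_bin_mass(self):
        sfs = cs.site_frequency_spectrum(np.full(50, 0.5))
        assert sfs["proportion"].iloc[-1] == pytest.approx(1.0)
        assert sfs["proportion"].sum() == pytest.approx(1.0)

    def test_histogram_matches_hand_count(self):
        maf = np.array([0.01, 0.02, 0.06, 0.12, 0.49, 0.5])
        sfs = cs.site_frequency_spectrum(maf, bin_edges=np.array([0, 0.05, 0.25, 0.5]))
        assert list(sfs["proportion"]) == pytest.approx([2 / 6, 2 / 6, 2 / 6])

    def test_neutral_spectrum_monotone_decreasing(self, rng):
        """Folded 1/x-density MAFs give a decreasing spectrum."""
        two_n = 100
        j = np.arange(1, 50 + 1)
        w = 1.0 / j
        maf = rng.choice(j / two_n, size=20_000, p=w / w.sum())
        sfs = cs.site_frequency_spectrum(maf, bin_edges=np.linspace(0, 0.5, 6))
        props = sfs["proportion"].to_numpy()
        assert (np.diff(props) < 0).all()

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            cs.site_frequency_spectrum(np.array([0.6]))
        with pytest.raises(ValueError):
            cs.site_frequency_spectrum(np.array([]))

    def test_ks_trivial_and_ecdf_oracle(self, rng):
        x = rng.uniform(0.0, 0.5, 40)
        assert cs.compare_sfs(x, x)[0] == 0.0
        lo = rng.uniform(0.0, 0.2, 30)
        hi = rng.uniform(0.3, 0.5, 30)
        assert cs.compare_sfs(lo, hi)[0] == pytest.approx(1.0)
        y = rng.uniform(0.1, 0.5, 25)
        stat, _ = cs.compare_sfs(x, y)
        grid = np.concatenate([x, y])
        ecdf_diff = max(
            abs(np.mean(x <= t) - np.mean(y <= t)) for t in grid
        )
        assert stat == pytest.approx(ecdf_diff)

    def test_rare_fraction(self):
        assert cs.rare_variant_fraction(np.full(10, 0.3)) == 0.0
        maf = np.array([0.001] * 3 + [0.2] * 7)
        assert cs.rare_variant_fraction(maf) == pytest.approx(0.3)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        maf1 = np.array([0.001] * 6 + [0.3] * 14)
        maf2 = np.array([0.001] * 2 + [0.3] * 18)
        *_, p = cs.compare_rare_fraction(maf1, maf2)
        # two-tailed exact p: sum of point probabilities <= observed one
        n1 = n2 = 20
        k_total, k1 = 8, 6
        probs = [
            math.comb(n1, k) * math.comb(n2, k_total - k)
            / math.comb(n1 + n2, k_total)
            for k in range(max(0, k_total - n2), min(n1, k_total) + 1)
        ]
        obs = math.comb(n1, k1) * math.comb(n2, k_total - k1) / math.comb(n1 + n2, k_total)
        oracle = sum(pr for pr in probs if pr <= obs * (1 + 1e-12))
        assert p == pytest.approx(oracle, rel=1e-9)


def test_independent_uniform_placement_gives_mean_oe_one(rng):
    """The null of the whole method: random placement makes coSNP_O/E ~ 1."""
    n, p = 20_000, 0.03
    oes = []
    for _ in range(120):
        a = rng.random(n) < p
        b = rng.random(n) < p
        counts = CoSNPCounts("null", n, int(a.sum()), int(b.sum()),
                             int((a & b).sum()))
        oes.append(cs.cosnp_oe(counts))
    se = np.std(oes, ddof=1) / np.sqrt(len(oes))
    assert abs(np.mean(oes) - 1.0) < 3 * se + 1e-9


def test_shared_rate_field_elevates_oe_to_one_plus_cv2(rng):
    """Closed form: hit rates proportional to a shared field give 1 + CV^2."""
    n, d = 40_000, 0.02
    for cv2, band in ((0.5, 0.06), (1.0, 0.08)):
        oes = []
        for _ in range(60):
            r = rng.gamma(1.0 / cv2, cv2, size=n)
            pvec = np.minimum(d * r, 0.4)
            a = rng.random(n) < pvec
            b = rng.random(n) < pvec
            oes.append(cs.cosnp_oe(
                CoSNPCounts("f", n, int(a.sum()), int(b.sum()), int((a & b).sum()))
            ))
        assert np.mean(oes) == pytest.approx(1.0 + cv2, rel=band)


def test_tolerant_fraction_elevates_oe_to_one_over_f(rng):
    """Closed form: SNPs confined to a shared tolerant fraction f give 1/f."""
    n, d, f = 40_000, 0.02, 0.25
    tol = rng.random(n) < f
    pvec = np.where(tol, d / f, 0.0)
    oes = []
    for _ in range(60):
        a = rng.random(n) < pvec
        b = rng.random(n) < pvec
        oes.append(cs.cosnp_oe(
            CoSNPCounts("f", n, int(a.sum()), int(b.sum()), int((a & b).sum()))
        ))
    assert np.mean(oes) == pytest.approx(1.0 / f, rel=0.08)
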