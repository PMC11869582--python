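"""HLA frequencies, multiple testing, diversity, and haplotype EM."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from paleokin import hla, kinship, simulate
from paleokin.hla import (allele_frequencies, downsampled_comparison, dunn_test,
                          exclude_first_degree, fisher_comparison, haplotype_em,
                          holm_sidak_adjust, shannon_index,
                          shannon_resampling_compare, tsbh_adjust)


def geno_rows(sample, **loci):
    rows = []
    for locus, (a1, a2) in loci.items():
        rows.append({"sample_id": sample, "locus": locus,
                     "allele1": a1, "allele2": a2})
    return rows


# ---------------------------------------------------------------------------
# frequencies and relative exclusion
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_two_individual_worked_example(self):
        table = pd.DataFrame(
            geno_rows("S1", DQB1=("DQB1*04:02", "DQB1*04:02"))
            + geno_rows("S2", DQB1=("DQB1*04:02", "DQB1*06:03")))
        out = allele_frequencies(table).set_index("allele")
        assert out.loc["DQB1*04:02", "frequency"] == 0.75
        assert out.loc["DQB1*06:03", "frequency"] == 0.25
        assert out.loc["DQB1*04:02", "count"] == 3      # homozygote counts twice
        assert (out["n_alleles_typed"] == 4).all()

    def test_per_locus_missingness(self):
        table = pd.DataFrame(
            geno_rows("S1", DQB1=("DQB1*04:02", "DQB1*04:02"),
                      A=("A*02:01", "A*01:01"))
            + geno_rows("S2", DQB1=("DQB1*06:03", "DQB1*06:03")))
        out = allele_frequencies(table)
        assert out.loc[out["locus"] == "A", "n_alleles_typed"].iloc[0] == 2
        assert out.loc[out["locus"] == "DQB1", "n_alleles_typed"].iloc[0] == 4

    def test_frequencies_sum_to_one_per_locus(self, planted_hla):
        table, _ = planted_hla
        out = allele_frequencies(table)
        sums = out.groupby("locus")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestExcludeFirstDegree:
    def kin(self, a, b, degree="first"):
        return kinship.KinshipResult((a, b), 0.2, 10_000, 0.5, (0.45, 0.55),
                                     degree, 0.26)

    def table(self, typed):
        rows = []
        loci = ["A", "B", "C", "DPB1", "DQB1", "DRB1"]
        for sample, n in typed.items():
            for locus in loci[:n]:
                rows += geno_rows(sample, **{locus: (f"{locus}*01:01", f"{locus}*01:01")})
        return pd.DataFrame(rows)

    def test_most_complete_profile_kept(self):
        t = self.table({"S1": 6, "S2": 4})
        out = exclude_first_degree(t, [self.kin("S1", "S2")])
        assert set(out["sample_id"]) == {"S1"}

    def test_no_relatives_identity(self):
        t = self.table({"S1": 3, "S2": 3})
        out = exclude_first_degree(t, [self.kin("S1", "S2", degree="unrelated")])
        assert set(out["sample_id"]) == {"S1", "S2"}

    def test_sibling_triplet_keeps_one(self):
        t = self.table({"S1": 4, "S2": 4, "S3": 4})
        res = [self.kin("S1", "S2"), self.kin("S2", "S3")]
        out = exclude_first_degree(t, res)
        assert set(out["sample_id"]) == {"S1"}   # tie broken by smallest id


# ---------------------------------------------------------------------------
# Fisher comparison and TSBH
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(k1, n1, k2, n2):
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    K = k1 + k2
    N = n1 + n2
    obs = hypergeom.pmf(k1, N, K, n1)
    p = 0.0
    for x in range(max(0, K - n2), min(K, n1) + 1):
        px = hypergeom.pmf(x, N, K, n1)
        if px <= obs * (1 + 1e-12):
            p += px
    return min(p, 1.0)


def tsbh_oracle(pvals, alpha=0.05):
    """Hand-executed two-stage BH: stage-1 BH at alpha/(1+alpha) estimates m0,
    stage-2 BH adjusted p-values use m0 in place of m."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    sp = [pvals[i] for i in order]
    a1 = alpha / (1 + alpha)
    r1 = 0
    for k in range(m, 0, -1):
        if sp[k - 1] <= k * a1 / m:
            r1 = k
            break
    m0 = max(m - r1, 1)
    adj = [None] * m
    best = 1.0
    for k in range(m, 0, -1):
        best = min(best, sp[k - 1] * m0 / k)
        adj[k - 1] = min(best, 1.0)
    out = [None] * m
    for rank, i in enumerate(order):
        out[i] = adj[rank]
    return out


class TestFisherComparison:
    def freq_tables(self, counts_a, n_a, counts_b, n_b, locus="DQB1"):
        def tbl(counts, n):
            rows = [{"locus": locus, "allele": al, "count": c,
                     "frequency": c / n, "n_alleles_typed": n}
                    for al, c in counts.items()]
            return pd.DataFrame(rows)
        return tbl(counts_a, n_a), tbl(counts_b, n_b)

    def test_identical_tables_p_one(self):
        a, b = self.freq_tables({"DQB1*04:02": 10, "DQB1*06:03": 10}, 20,
                                {"DQB1*04:02": 10, "DQB1*06:03": 10}, 20)
        out = fisher_comparison(a, b)
        assert (out["p_raw"] == 1.0).all()
        assert not out["significant"].any()

    def test_matches_enumeration_oracle(self):
        a, b = self.freq_tables({"DQB1*04:02": 10, "DQB1*06:03": 10}, 20,
                                {"DQB1*06:03": 20}, 20)
        out = fisher_comparison(a, b).set_index("allele")
        p = out.loc["DQB1*04:02", "p_raw"]
        assert p == pytest.approx(fisher_two_sided_oracle(10, 20, 0, 20), abs=1e-12)

    def test_significance_needs_both_p_and_effect(self):
        # large counts, significant p but frequency difference below 0.1
        a, b = self.freq_tables({"DQB1*04:02": 500, "DQB1*06:03": 500}, 1000,
                                {"DQB1*04:02": 430, "DQB1*06:03": 570}, 1000)
        out = fisher_comparison(a, b).set_index("allele")
        row = out.loc["DQB1*04:02"]
        assert row["p_adjusted"] <= 0.05
        assert not row["significant"]


class TestTsbh:
    def test_all_ones(self):
        np.testing.assert_array_equal(tsbh_adjust(np.ones(5)), np.ones(5))

    def test_empty(self):
        assert tsbh_adjust(np.array([])).size == 0

    def test_matches_hand_oracle_on_fixture(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        np.testing.assert_allclose(tsbh_adjust(np.array(p)), tsbh_oracle(p),
                                   atol=1e-12)

    def test_single_p(self):
        for p in (0.01, 0.2, 0.9):
            assert tsbh_adjust(np.array([p]))[0] == pytest.approx(
                tsbh_oracle([p])[0], abs=1e-12)

    def test_rejections_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, 15) ** 2
            ours = tsbh_adjust(p, alpha=0.05) <= 0.05
            theirs = multipletests(p, alpha=0.05, method="fdr_tsbh")[0]
            np.testing.assert_array_equal(ours, theirs)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_invariance_and_monotonicity(self, pvals):
        p = np.array(pvals)
        adj = tsbh_adjust(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(tsbh_adjust(p[perm]), adj[perm], atol=1e-12)
        # monotone in input ranks
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= 0) and np.all(adj <= 1)


# ---------------------------------------------------------------------------
# resampling comparison
# ---------------------------------------------------------------------------

class TestDownsampledComparison:
    def test_same_individuals_nothing_significant(self, planted_hla):
        table, _ = planted_hla
        out = downsampled_comparison(table, table, n_resamples=50,
                                     rng=np.random.default_rng(1))
        assert (out["p_adjusted"] > 0.05).all()

    def test_fixed_vs_absent_minimal_p(self):
        rows = []
        for i in range(10):
            rows += geno_rows(f"A{i}", DQB1=("DQB1*04:02", "DQB1*04:02"))
        for i in range(10):
            rows += geno_rows(f"B{i}", DQB1=("DQB1*06:03", "DQB1*06:03"))
        t = pd.DataFrame(rows)
        out = downsampled_comparison(t[t.sample_id.str.startswith("A")],
                                     t[t.sample_id.str.startswith("B")],
                                     n_resamples=50,
                                     rng=np.random.default_rng(2))
        out = out.set_index("allele")
        assert out.loc["DQB1*04:02", "p_adjusted"] < 1e-6

    def test_resample_means_track_full_frequencies(self, planted_hla):
        table, _ = planted_hla
        full = allele_frequencies(table).set_index(["locus", "allele"])
        out = downsampled_comparison(table, table, n_resamples=100,
                                     rng=np.random.default_rng(3))
        for _, row in out.iterrows():
            f = full.loc[(row["locus"], row["allele"]), "frequency"]
            if f >= 0.1:
                assert row["mean_freq_a"] == pytest.approx(f, abs=0.03)

    def test_tiny_group_rejected(self):
        t = pd.DataFrame(geno_rows("S1", DQB1=("DQB1*04:02", "DQB1*04:02")))
        with pytest.raises(ValueError):
            downsampled_comparison(t, t)


# ---------------------------------------------------------------------------
# Shannon diversity
# ---------------------------------------------------------------------------

class TestShannon:
    def test_exact_values(self):
        assert shannon_index([1.0]) == 0.0
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)
        assert shannon_index([0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([1.2, -0.2])

    def test_uniform_vs_degenerate_populations(self):
        pops = {"rich": {f"a{i}": 1 / 8 for i in range(8)},
                "poor": {"a0": 1.0}}
        out = shannon_resampling_compare(pops, {"rich": 60, "poor": 60},
                                         n_resamples=100,
                                         rng=np.random.default_rng(4))
        h_rich = out["shannon"]["rich"].h_values
        h_poor = out["shannon"]["poor"].h_values
        assert (h_poor == 0).all()
        assert h_rich.min() > 0
        assert (h_rich <= math.log(8) + 1e-12).all()
        dunn = out["dunn"].iloc[0]
        assert dunn["p_adjusted"] < 0.01

    def test_resampled_h_bounded_by_pool_size(self):
        pops = {"p": {f"a{i}": 1 / 5 for i in range(5)}}
        out = shannon_resampling_compare(pops, {"p": 40}, n_resamples=50,
                                         rng=np.random.default_rng(5))
        assert (out["shannon"]["p"].h_values <= math.log(5) + 1e-12).all()


def test_dunn_test_detects_shifted_group():
    rng = np.random.default_rng(6)
    groups = {"a": rng.normal(0, 1, 60), "b": rng.normal(0, 1, 60),
              "c": rng.normal(3, 1, 60)}
    out = dunn_test(groups).set_index(["group_a", "group_b"])
    assert out.loc[("a", "c"), "p_adjusted"] < 1e-4
    assert out.loc[("b", "c"), "p_adjusted"] < 1e-4
    assert out.loc[("a", "b"), "p_adjusted"] > 0.05


def test_holm_sidak_adjust_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(7)
    p = rng.uniform(0, 1, 12) ** 2
    ours = holm_sidak_adjust(p)
    theirs = multipletests(p, method="holm-sidak")[1]
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


# ---------------------------------------------------------------------------
# haplotype EM
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_hla():
    """n = 90 individuals, DRB1*08:01-DQB1*04:02 planted at frequency 0.20."""
    freqs = {("DRB1*08:01", "DQB1*04:02"): 0.20,
             ("DRB1*13:01", "DQB1*06:03"): 0.30,
             ("DRB1*01:01", "DQB1*05:01"): 0.35,
             ("DRB1*07:01", "DQB1*02:02"): 0.15}
    table = simulate.simulate_hla_from_haplotypes(freqs, 90,
                                                  np.random.default_rng(90))
    return table, freqs


def em_loglik_oracle(table, locus_a, locus_b, freqs):
    """Observed-data log-likelihood by exhaustive enumeration of ordered
    haplotype pairs consistent with each two-locus genotype."""
    ga = table[table["locus"] == locus_a].set_index("sample_id")
    gb = table[table["locus"] == locus_b].set_index("sample_id")
    shared = sorted(set(ga.index) & set(gb.index))
    haps = list(freqs)
    ll = 0.0
    for s in shared:
        a_geno = tuple(sorted((ga.loc[s, "allele1"], ga.loc[s, "allele2"])))
        b_geno = tuple(sorted((gb.loc[s, "allele1"], gb.loc[s, "allele2"])))
        lik = 0.0
        for h1, h2 in itertools.product(haps, haps):
            if tuple(sorted((h1[0], h2[0]))) == a_geno and \
               tuple(sorted((h1[1], h2[1]))) == b_geno:
                lik += freqs[h1] * freqs[h2]
        ll += math.log(lik)
    return ll


class TestHaplotypeEM:
    def test_complete_ld_toy(self):
        rows = []
        for i, (d, q) in enumerate([("DRB1*13:01", "DQB1*06:03")] * 3
                                   + [("DRB1*01:01", "DQB1*05:01")] * 5):
            rows += geno_rows(f"S{i}", DRB1=(d, d), DQB1=(q, q))
        out = haplotype_em(pd.DataFrame(rows), "DRB1", "DQB1")
        assert out.frequencies[("DRB1*13:01", "DQB1*06:03")] == pytest.approx(3 / 8, abs=1e-9)
        assert out.converged

    def test_le_counts_are_fixed_point(self):
        """Genotype counts matching exact HWE linkage equilibrium leave the
        product-frequency initialisation unchanged."""
        rows = []
        i = 0
        a_genos = [("DRB1*01:01", "DRB1*01:01")] * 1 + \
                  [("DRB1*01:01", "DRB1*02:01")] * 2 + \
                  [("DRB1*02:01", "DRB1*02:01")] * 1
        b_genos = [("DQB1*05:01", "DQB1*05:01")] * 1 + \
                  [("DQB1*05:01", "DQB1*06:03")] * 2 + \
                  [("DQB1*06:03", "DQB1*06:03")] * 1
        for ag in a_genos:
            for bg in b_genos:
                rows += geno_rows(f"S{i}", DRB1=ag, DQB1=bg)
                i += 1
        out = haplotype_em(pd.DataFrame(rows), "DRB1", "DQB1")
        for f in out.frequencies.values():
            assert f == pytest.approx(0.25, abs=1e-6)
        assert out.n_iterations <= 2

    def test_tiny_instance_matches_enumeration_oracle(self):
        rows = (geno_rows("S1", DRB1=("DRB1*01:01", "DRB1*02:01"),
                          DQB1=("DQB1*05:01", "DQB1*06:03"))
                + geno_rows("S2", DRB1=("DRB1*01:01", "DRB1*01:01"),
                            DQB1=("DQB1*05:01", "DQB1*05:01"))
                + geno_rows("S3", DRB1=("DRB1*02:01", "DRB1*02:01"),
                            DQB1=("DQB1*06:03", "DQB1*06:03"))
                + geno_rows("S4", DRB1=("DRB1*01:01", "DRB1*02:01"),
                            DQB1=("DQB1*05:01", "DQB1*05:01")))
        table = pd.DataFrame(rows)
        out = haplotype_em(table, "DRB1", "DQB1")
        oracle = em_loglik_oracle(table, "DRB1", "DQB1", out.frequencies)
        assert out.loglik == pytest.approx(oracle, abs=1e-10)

    def test_marginals_match_allele_frequencies(self, planted_hla):
        table, _ = planted_hla
        out = haplotype_em(table, "DRB1", "DQB1")
        freqs = allele_frequencies(table).set_index(["locus", "allele"])
        marg_a: dict[str, float] = {}
        for (a, b), f in out.frequencies.items():
            marg_a[a] = marg_a.get(a, 0.0) + f
        for allele, f in marg_a.items():
            assert f == pytest.approx(freqs.loc[("DRB1", allele), "frequency"],
                                      abs=1e-6)
        assert sum(out.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_haplotype_recovered(self, planted_hla):
        table, freqs = planted_hla
        out = haplotype_em(table, "DRB1", "DQB1")
        est = out.frequencies[("DRB1*08:01", "DQB1*04:02")]
        assert est == pytest.approx(0.20, abs=0.04)

    def test_loglik_nondecreasing(self, planted_hla):
        table, _ = planted_hla
        out = haplotype_em(table, "DRB1", "DQB1")
        assert np.all(np.diff(out.loglik_path) >= -1e-9)

    def test_no_joint_individual_rejected(self):
        rows = geno_rows("S1", DRB1=("DRB1*01:01", "DRB1*01:01")) + \
            geno_rows("S2", DQB1=("DQB1*05:01", "DQB1*05:01"))
        with pytest.raises(ValueError, match="typed at both"):
            haplotype_em(pd.DataFrame(rows), "DRB1", "DQB1")
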