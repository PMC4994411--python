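import numpy as np
import pytest
from scipy import stats as sps

from asterion.annotation import AnnotationSet
from asterion.stats import (
    empirical_p,
    intron_length_comparison,
    largest_intron_per_gene,
    rank_sum_test,
    span_size_comparison,
)

from conftest import make_t
from oracles import ranksum_exact_bruteforce


class TestRankSum:
    def test_fully_separated_small_samples(self):
        """a = (1,2,3) below b = (4,5,6): exactly 1 of C(6,3)=20
        arrangements is as extreme, so the exact one-sided p is 1/20."""
        res = rank_sum_test([1, 2, 3], [4, 5, 6], alternative="a_less")
        assert res.method == "exact"
        assert res.statistic_U == 0
        assert res.p_one_sided == pytest.approx(1 / 20)

    def test_identical_multisets(self):
        res = rank_sum_test([1, 2, 3, 4] * 5, [1, 2, 3, 4] * 5)
        assert res.statistic_U == pytest.approx(res.n1 * res.n2 / 2)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact branch equals full enumeration of arrangements for
        n1 + n2 <= 10, both alternatives."""
        for _ in range(60):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            pool = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            a, b = pool[:n1], pool[n1:]
            for alt in ("a_greater", "a_less"):
                res = rank_sum_test(a, b, alternative=alt)
                assert res.method == "exact"
                assert res.p_one_sided == pytest.approx(
                    ranksum_exact_bruteforce(a, b, alternative=alt)
                )

    def test_agrees_with_reference_implementation(self, rng):
        """Cross-check both branches against scipy's Mann-Whitney U."""
        for n, ties in [(6, False), (40, False), (40, True)]:
            for _ in range(20):
                if ties:
                    a = rng.integers(0, 8, size=n).astype(float)
                    b = rng.integers(0, 8, size=n).astype(float)
                else:
                    pool = rng.choice(10_000, size=2 * n, replace=False)
                    a, b = pool[:n].astype(float), pool[n:].astype(float)
                res = rank_sum_test(a, b, alternative="a_greater")
                method = "exact" if not ties and 2 * n <= 16 else "asymptotic"
                ref = sps.mannwhitneyu(a, b, alternative="greater", method=method)
                assert res.statistic_U == pytest.approx(ref.statistic)
                assert res.p_one_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_normal_agree_at_crossover(self, rng):
        """At total n = 16 without ties the two branches agree within 10%
        relative p."""
        for _ in range(30):
            pool = rng.choice(10_000, size=16, replace=False).astype(float)
            a, b = pool[:8], pool[8:]
            exact = rank_sum_test(a, b, alternative="a_greater")
            assert exact.method == "exact"
            approx = sps.mannwhitneyu(
                a, b, alternative="greater", method="asymptotic"
            )
            if 0.05 < exact.p_one_sided < 0.95:
                assert approx.pvalue == pytest.approx(
                    exact.p_one_sided, rel=0.10
                )

    def test_joint_monotone_transform_invariance(self, rng):
        a = rng.random(25)
        b = rng.random(30)
        base = rank_sum_test(a, b, alternative="a_greater")
        trans = rank_sum_test(
            np.exp(3 * a), np.exp(3 * b), alternative="a_greater"
        )
        assert trans.statistic_U == base.statistic_U
        assert trans.p_one_sided == base.p_one_sided

    def test_null_p_is_uniform(self, rng):
        """Under a shared continuous null the one-sided p is U(0,1):
        KS distance < 0.05 at 2,000 simulations."""
        ps = []
        for _ in range(2000):
            a = rng.standard_normal(15)
            b = rng.standard_normal(15)
            ps.append(rank_sum_test(a, b, alternative="a_greater").p_one_sided)
        d = sps.kstest(ps, "uniform").statistic
        assert d < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestLargestIntron:
    def test_max_across_introns_and_isoforms(self):
        aset = AnnotationSet(
            [
                make_t("g1.t1", "+", [(0, 50), (150, 200), (5200, 5300)], gene="g1"),
                make_t("g2.t1", "+", [(0, 100), (400, 500)], gene="g2"),
                make_t("g2.t2", "+", [(0, 100), (800, 900)], gene="g2"),
                make_t("g3.t1", "+", [(0, 300)], gene="g3"),
            ]
        )
        table = largest_intron_per_gene(aset, host_genes={"g1"})
        by_gene = table.set_index("gene_id")["largest_intron"]
        assert by_gene["g1"] == 5000
        assert by_gene["g2"] == 700
        assert by_gene["g3"] == 0
        assert table.set_index("gene_id")["is_host"]["g1"]

    def test_single_exon_genes_excluded_from_comparison(self):
        aset = AnnotationSet(
            [
                make_t("h.t1", "+", [(0, 100), (2000, 2100)], gene="h"),
                make_t("n1.t1", "+", [(0, 100), (300, 400)], gene="n1"),
                make_t("n2.t1", "+", [(0, 500)], gene="n2"),
            ]
        )
        table = largest_intron_per_gene(aset, host_genes={"h"})
        res = intron_length_comparison(table)
        assert res.n1 == 1 and res.n2 == 1  # n2 (intronless) dropped


class TestSpanSize:
    def test_complete_separation_gives_minimal_p(self):
        spans = [100, 110, 120]
        blocks = [10, 20, 30, 40]
        res = span_size_comparison(spans, blocks)
        assert res.method == "exact"
        # minimal attainable one-sided p for n1=3, n2=4
        assert res.p_one_sided == pytest.approx(1 / 35)

    def test_null_calibration(self, rng):
        """Same-distribution spans and blocks: p approximately uniform
        (rejection at 0.05 close to nominal over 400 runs)."""
        rejections = 0
        for _ in range(400):
            spans = rng.lognormal(8, 1, size=13)
            blocks = rng.lognormal(8, 1, size=100)
            if span_size_comparison(spans, blocks).p_one_sided < 0.05:
                rejections += 1
        assert 4 <= rejections <= 40  # ~20 expected

    def test_planted_shift_detected(self, rng):
        """A 2x median shift with n1=13 vs n2=500 is detected (p < 0.05)
        in the majority of simulations."""
        hits = 0
        for _ in range(100):
            spans = 2.0 * rng.lognormal(8, 0.6, size=13)
            blocks = rng.lognormal(8, 0.6, size=500)
            if span_size_comparison(spans, blocks).p_one_sided < 0.05:
                hits += 1
        assert hits > 50


def test_empirical_p_bounds(rng):
    null = rng.integers(0, 50, size=999)
    for obs in (-5, 0, 25, 200):
        for tail in ("high", "low"):
            p = empirical_p(null, obs, tail)
            assert 0 < p <= 1
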