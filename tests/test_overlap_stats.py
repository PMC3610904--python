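import math

import numpy as np
import pytest
from scipy.stats import fisher_exact, nchypergeom_fisher

from hscnet.overlap_stats import (ContingencyTable, bh_adjust, enrich_table,
                                  enrichment_z, expected_overlap, fisher_p,
                                  odds_ratio, overlap_sd)
from oracles import fisher_oracle, fisher_subset_enumeration


class TestMoments:
    def test_expected_overlap_fingerprint_scale(self):
        assert expected_overlap(319, 1000, 20000) == pytest.approx(15.95)

    @pytest.mark.parametrize("K,n,N,expected", [
        (0, 1000, 20000, 0.0),
        (20000, 1000, 20000, 1000.0),   # saturated fixed set
    ])
    def test_expected_overlap_degenerate(self, K, n, N, expected):
        assert expected_overlap(K, n, N) == expected

    def test_expected_requires_valid_universe(self):
        with pytest.raises(ValueError):
            expected_overlap(1, 1, 0)

    def test_sd_hypergeometric_closed_form(self):
        assert overlap_sd(5, 4, 20) == pytest.approx(math.sqrt(12 / 19))

    @pytest.mark.parametrize("K", [0, 20])
    def test_sd_zero_at_margin(self, K):
        assert overlap_sd(K, 4, 20) == 0.0

    def test_sd_zero_when_comparator_is_universe(self):
        assert overlap_sd(5, 20, 20) == 0.0

    def test_sd_binomial_lacks_correction(self):
        hyper = overlap_sd(5, 4, 20, "hypergeometric")
        binom = overlap_sd(5, 4, 20, "binomial")
        assert binom > hyper

    def test_z_worked_example(self):
        assert enrichment_z(3, 1.0, math.sqrt(12 / 19)) == pytest.approx(
            2.5166, abs=1e-4)

    def test_z_zero_when_observed_matches(self):
        assert enrichment_z(5, 5.0, 0.0) == 0.0

    @pytest.mark.parametrize("obs,expected_sign", [(7, 1), (3, -1)])
    def test_z_infinite_flag_with_zero_sd(self, obs, expected_sign):
        z = enrichment_z(obs, 5.0, 0.0)
        assert math.isinf(z) and math.copysign(1, z) == expected_sign

    def test_z_antisymmetric_under_label_swap(self):
        # swapping membership labels: fixed set -> complement, a -> n - a
        N, K, n, a = 500, 40, 60, 12
        z = enrichment_z(a, expected_overlap(K, n, N), overlap_sd(K, n, N))
        z_swap = enrichment_z(n - a, expected_overlap(N - K, n, N),
                              overlap_sd(N - K, n, N))
        assert z_swap == pytest.approx(-z, rel=1e-12)


class TestFisher:
    def test_worked_example_greater(self):
        t = ContingencyTable(3, 2, 1, 14)
        assert fisher_p(t, "greater") == pytest.approx(155 / 4845, abs=1e-15)

    def test_tail_complementarity(self):
        t = ContingencyTable(3, 2, 1, 14)
        point = 150 / 4845  # C(5,3) C(15,1) / C(20,4)
        assert fisher_p(t, "greater") + fisher_p(t, "less") - point == \
            pytest.approx(1.0, abs=1e-12)

    def test_degenerate_margin_gives_one(self):
        t = ContingencyTable(0, 0, 4, 16)  # empty fixed set
        assert fisher_p(t, "greater") == 1.0

    def test_matches_scipy_two_sided(self):
        for cells in [(3, 2, 1, 14), (10, 5, 7, 40), (0, 9, 4, 11)]:
            t = ContingencyTable(*cells)
            _, p_ref = fisher_exact([[t.a, t.b], [t.c, t.d]],
                                    alternative="two-sided")
            assert fisher_p(t, "two_sided") == pytest.approx(p_ref, rel=1e-9)

    def test_matches_scipy_on_large_universe_path(self):
        t = ContingencyTable(30, 289, 983, 18698)  # exercises log-space branch
        _, p_ref = fisher_exact([[t.a, t.b], [t.c, t.d]],
                                alternative="greater")
        assert fisher_p(t, "greater") == pytest.approx(p_ref, rel=1e-9)

    def test_subset_enumeration_oracle_tiny(self):
        # literal enumeration over every comparator draw, N <= 10
        for cells in [(2, 1, 1, 4), (0, 2, 3, 3), (3, 0, 1, 5), (1, 1, 1, 1)]:
            t = ContingencyTable(*cells)
            for side in ("greater", "less", "two_sided"):
                ref = float(fisher_subset_enumeration(*cells, side))
                assert fisher_p(t, side) == pytest.approx(ref, abs=1e-14)

    def test_monotone_decreasing_in_overlap(self):
        # fixed margins N=60, K=12, n=20; p(greater) strictly falls as a grows
        prev = 2.0
        for a in range(0, 13):
            t = ContingencyTable(a, 12 - a, 20 - a, 28 + a)
            p = fisher_p(t, "greater")
            assert p < prev
            prev = p


class TestOddsRatio:
    def test_sample_no_correction(self):
        r = odds_ratio(ContingencyTable(3, 2, 1, 14), "sample")
        assert r.point == pytest.approx(21.0)
        assert not r.corrected

    def test_sample_haldane_correction(self):
        r = odds_ratio(ContingencyTable(2, 0, 1, 7), "sample")
        assert r.point == pytest.approx(25.0)
        assert r.corrected

    def test_cmle_zero_overlap_open_lower(self):
        r = odds_ratio(ContingencyTable(0, 5, 4, 11), "cmle")
        assert r.point == 0.0 and r.open_lower
        assert r.ci_low == 0.0 and r.ci_high > 0

    def test_cmle_maximal_overlap_open_upper(self):
        r = odds_ratio(ContingencyTable(4, 1, 0, 15), "cmle")
        assert math.isinf(r.point) and r.open_upper
        assert math.isinf(r.ci_high) and r.ci_low > 0

    def test_cmle_matches_r_fisher_test(self):
        # independently computed with R: fisher.test(matrix(c(3,1,2,14),2,2))
        r = odds_ratio(ContingencyTable(3, 2, 1, 14), "cmle")
        assert r.point == pytest.approx(16.38831, rel=1e-4)
        assert r.ci_low == pytest.approx(0.8875694, rel=1e-4)
        assert r.ci_high == pytest.approx(1176.971, rel=1e-3)

    def test_cmle_point_maximizes_scipy_conditional_likelihood(self):
        t = ContingencyTable(9, 11, 15, 45)
        r = odds_ratio(t, "cmle")
        N, K, n = t.N, t.K, t.n
        grid = r.point * np.exp(np.linspace(-0.5, 0.5, 41))
        lik = [nchypergeom_fisher.logpmf(t.a, N, K, n, psi) for psi in grid]
        assert np.argmax(lik) == 20  # the center, i.e. our point estimate

    def test_zero_margin_degenerate(self):
        r = odds_ratio(ContingencyTable(0, 0, 4, 16), "cmle")
        assert r.degenerate and math.isnan(r.point)

    def test_ci_orders_around_point(self):
        r = odds_ratio(ContingencyTable(8, 4, 6, 30), "cmle")
        assert r.ci_low < r.point < r.ci_high


class TestBH:
    def test_step_up_rule(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @pytest.mark.parametrize("pvals", [[0.2], [1.0, 1.0]])
    def test_identity_cases(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(pvals)

    def test_adjusted_at_least_raw(self):
        raw = [0.001, 0.04, 0.2, 0.9]
        adj = bh_adjust(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert all(a <= 1 for a in adj)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrich:
    def test_worked_example_end_to_end(self):
        r = enrich_table(ContingencyTable(3, 2, 1, 14), or_method="sample")
        assert r.observed == 3
        assert r.expected == pytest.approx(1.0)
        assert r.z == pytest.approx(2.5166, abs=1e-4)
        assert r.p_greater == pytest.approx(155 / 4845, abs=1e-12)
        assert r.odds_ratio == pytest.approx(21.0)

    def test_identical_sets_flag_open_upper(self, small_universe):
        from hscnet.core_sets import GeneSet
        from hscnet.overlap_stats import enrich
        gs = GeneSet(name="S", symbols=frozenset({"G0", "G1", "G2"}),
                     universe_name="U")
        r = enrich(gs, gs, small_universe)
        assert r.observed == 3 and r.z > 0
        assert r.or_result.open_upper

    def test_cmle_near_one_on_null_tables(self):
        # central hypergeometric tables should give a median cmle OR near 1
        rng = np.random.default_rng(7)
        N, K, n = 2000, 150, 400
        points = []
        for _ in range(100):
            a = int(rng.hypergeometric(K, N - K, n))
            t = ContingencyTable(a, K - a, n - a, N - K - n + a)
            points.append(odds_ratio(t, "cmle").point)
        assert np.median(points) == pytest.approx(1.0, rel=0.10)
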