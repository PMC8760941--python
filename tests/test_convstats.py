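"""Convergence statistics against brute-force and closed-form oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from convloss.convstats import (
    bh_adjust,
    binom_power,
    binom_test_two_sided,
    clopper_pearson,
    convergence_test,
    expected_convergent_prob,
    marginal_loss_prob,
    prop_test,
    subfamily_enrichment,
)
from convloss.gainloss import build_call_table
from convloss.simdata import SimConfig, family_subfamily, truth_clusters


def enumerate_binom_p(x, n, p0):
    """Oracle: direct summation over all outcomes, point-probability rule."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    cut = pmf[x] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf if p <= cut))


class TestBinomTest:
    @pytest.mark.parametrize("p0", [0.1, 0.3, 0.5, 0.9])
    def test_equals_enumeration_for_all_small_grids(self, p0):
        for n in range(1, 13):
            for x in range(n + 1):
                assert binom_test_two_sided(x, n, p0) == pytest.approx(
                    enumerate_binom_p(x, n, p0), rel=1e-9
                )

    def test_degenerate_nulls(self):
        assert binom_test_two_sided(0, 10, 0.0) == 1.0
        assert binom_test_two_sided(3, 10, 0.0) == 0.0
        assert binom_test_two_sided(10, 10, 1.0) == 1.0
        assert binom_test_two_sided(9, 10, 1.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binom_test_two_sided(11, 10, 0.5)
        with pytest.raises(ValueError):
            binom_test_two_sided(-1, 10, 0.5)


class TestClopperPearson:
    def test_boundary_cases(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_monotone_in_x(self):
        lows, highs = zip(*(clopper_pearson(x, 30) for x in range(31)))
        assert list(lows) == sorted(lows)
        assert list(highs) == sorted(highs)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=1, max_value=200), st.data())
    def test_interval_always_brackets_estimate(self, n, data):
        x = data.draw(st.integers(min_value=0, max_value=n))
        lo, hi = clopper_pearson(x, n)
        assert 0.0 <= lo <= x / n <= hi <= 1.0

    def test_interval_contains_point_estimate(self):
        for x, n in [(0, 5), (3, 7), (18, 307), (72, 72)]:
            lo, hi = clopper_pearson(x, n)
            assert lo <= x / n <= hi

    def test_coverage_at_least_nominal(self):
        # 10^4 draws at n=50, p=0.2: exact interval covers >= 94%
        rng = np.random.default_rng(123)
        n, p, B = 50, 0.2, 10_000
        xs = rng.binomial(n, p, size=B)
        alpha = 0.05
        lows = np.where(xs == 0, 0.0, stats.beta.ppf(alpha / 2, xs, n - xs + 1))
        highs = np.where(xs == n, 1.0, stats.beta.ppf(1 - alpha / 2, xs + 1, n - xs))
        # spot-check the vectorized bounds against the scalar implementation
        for x in np.unique(xs)[:5]:
            i = int(np.argmax(xs == x))
            assert clopper_pearson(int(x), n) == pytest.approx(
                (lows[i], highs[i])
            )
        coverage = np.mean((lows <= p) & (p <= highs))
        assert coverage >= 0.94

    def test_tail_duality_with_exact_test(self):
        # at the interval bound, the corresponding binomial tail equals alpha/2
        x, n, alpha = 13, 72, 0.05
        lo, hi = clopper_pearson(x, n, 1 - alpha)
        assert stats.binom.sf(x - 1, n, lo) == pytest.approx(alpha / 2, rel=1e-6)
        assert stats.binom.cdf(x, n, hi) == pytest.approx(alpha / 2, rel=1e-6)


class TestExpectedProb:
    def test_product_and_zero_annihilation(self):
        assert expected_convergent_prob([0.5, 0.5, 0.5]) == 0.125
        assert expected_convergent_prob([0.3, 0.0, 0.9]) == 0.0

    def test_never_exceeds_smallest_marginal(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.uniform(0, 1, size=3)
            assert expected_convergent_prob(m) <= m.min() + 1e-12

    def test_matches_monte_carlo_independent_losses(self):
        marg = (0.25, 0.3, 0.2)
        p = expected_convergent_prob(marg)
        rng = np.random.default_rng(77)
        B = 1_000_000
        hits = np.ones(B, dtype=bool)
        for m in marg:
            hits &= rng.uniform(size=B) < m
        freq = hits.mean()
        se = math.sqrt(p * (1 - p) / B)
        assert abs(freq - p) < 3 * se


class TestPower:
    def test_size_bounded_by_alpha_plus_discreteness(self):
        for n, p0 in [(30, 0.1), (100, 0.3)]:
            assert binom_power(n, p0, p0, alpha=0.05) <= 0.05 + 1e-9

    def test_exact_matches_simulation(self):
        n, p0, p1 = 20, 0.1, 0.5
        exact = binom_power(n, p0, p1, method="exact")
        B = 100_000
        sim = binom_power(n, p0, p1, method="simulate", B=B, seed=8)
        se = math.sqrt(exact * (1 - exact) / B)
        assert abs(exact - sim) < 3 * se

    def test_small_simulation_rejected(self):
        with pytest.raises(ValueError):
            binom_power(20, 0.1, 0.5, method="simulate", B=100)


class TestConvergenceTest:
    def test_assembles_components_consistently(self):
        clusters, cfg = truth_clusters(SimConfig(n_families=120, seed=2))
        table = build_call_table(clusters, cfg)
        res = convergence_test(table, power_method="exact")
        assert res.n == table.n
        assert res.p_obs == res.x / res.n
        prod = math.prod(res.marginals.values())
        assert res.p0 == pytest.approx(prod, abs=1e-12)
        assert res.ci[0] <= res.p_obs <= res.ci[1]
        assert 0 < res.p_value <= 1
        assert 0 <= res.power <= 1
        for sp, m in res.marginals.items():
            assert m == marginal_loss_prob(table, sp)

    def test_extreme_all_convergent(self, config3):
        from test_gainloss import make_cluster

        cl = [
            make_cluster(f"c{i}", {"P1": 0, "H1": 1, "P2": 0, "H2": 1, "P3": 0, "H3": 1})
            for i in range(10)
        ]
        res = convergence_test(build_call_table(cl, config3), power_method=None)
        assert res.p_obs == 1.0
        assert res.p_value <= res.p0**res.n * (1 + 1e-6) or res.p_value < 1e-6

    def test_zero_convergent(self, config3):
        from test_gainloss import make_cluster

        cl = [
            make_cluster("c1", {"P1": 0, "H1": 1, "P2": 1, "H2": 1, "P3": 1, "H3": 1}),
            make_cluster("c2", {"P1": 1, "H1": 1, "P2": 0, "H2": 1, "P3": 1, "H3": 1}),
            make_cluster("c3", {"P1": 1, "H1": 1, "P2": 1, "H2": 1, "P3": 0, "H3": 1}),
        ]
        res = convergence_test(build_call_table(cl, config3), power_method=None)
        assert res.x == 0 and res.p_obs == 0.0


class TestBH:
    def brute_force_bh(self, ps):
        n = len(ps)
        order = sorted(range(n), key=lambda i: ps[i])
        adj = [None] * n
        prev = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, ps[i] * n / rank_from_top)
            adj[i] = val
            prev = val
        return adj

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_textbook_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_step_up_oracle_random(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            ps = list(rng.uniform(size=rng.integers(1, 30)))
            assert bh_adjust(ps) == pytest.approx(self.brute_force_bh(ps))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=25,
        )
    )
    def test_step_up_invariants_hold_for_arbitrary_inputs(self, ps):
        adj = bh_adjust(ps)
        assert all(p - 1e-12 <= a <= 1.0 for a, p in zip(adj, ps))
        assert adj == pytest.approx(self.brute_force_bh(ps))

    def test_order_preserving_and_bounded(self):
        ps = [0.2, 0.001, 0.5, 0.001, 1.0]
        adj = bh_adjust(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(a <= 1 for a in adj)


class TestPropTest:
    def test_identical_proportions(self):
        res = prop_test([5, 5], [10, 10])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_yates_hand_computation(self):
        # 2x2 table (10,0)/(0,10): chi2 = 20*(|100-0|-10)^2 / 10^4 = 16.2
        res = prop_test([10, 0], [10, 10], correction=True)
        assert res.statistic == pytest.approx(16.2)

    def test_three_groups_equal(self):
        res = prop_test([4, 4, 4], [8, 8, 8])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 2

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            prop_test([1, 0], [5, 0])


class TestEnrichment:
    def test_no_convergence_means_p_near_one(self, config3):
        from test_gainloss import make_cluster

        cl = [
            make_cluster(f"c{i}", {"P1": 1, "H1": 1, "P2": 1, "H2": 1, "P3": 1, "H3": 1})
            for i in range(5)
        ]
        table = build_call_table(cl, config3)
        rows = subfamily_enrichment(
            table, {c.cluster_id: "L" for c in cl}, p0=0.0164
        )
        assert len(rows) == 1
        assert rows[0].p_raw > 0.9
        assert rows[0].p_adj == rows[0].p_raw  # single subfamily: BH identity

    def test_enriched_subfamily_detected(self):
        cfg = SimConfig(n_families=240, seed=6)
        clusters, sc = truth_clusters(cfg)
        table = build_call_table(clusters, sc)
        res = convergence_test(table, power_method=None)
        rows = subfamily_enrichment(
            table, {c.cluster_id: c.subfamily for c in clusters}, p0=res.p0
        )
        assert all(r.p_adj >= r.p_raw - 1e-12 for r in rows)
        assert all(r.n >= 1 for r in rows)
        # BH equals the brute-force step-up on the same raw p-values
        raw = [r.p_raw for r in rows]
        assert [r.p_adj for r in rows] == pytest.approx(
            bh_adjust(raw)
        )
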