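"""Behavioral statistics against high-precision and enumeration oracles."""
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import ndtri

from fmtheta.statskit import (
    BehavioralCounts,
    bootstrap_stability,
    cohens_d_from_t,
    dprime,
    ks_two_sample,
    leave_one_out,
    norm_ppf,
    partial_eta_sq,
    rank_sum_test,
    signed_rank_test,
    spearman_corr,
)


class TestNormPpf:
    def test_matches_scipy_to_high_precision(self):
        p = np.concatenate(
            [
                np.linspace(1e-12, 1e-3, 50),
                np.linspace(1e-3, 1 - 1e-3, 200),
                1 - np.linspace(1e-12, 1e-3, 50),
            ]
        )
        err = np.abs(norm_ppf(p) - ndtri(p))
        assert err.max() < 1e-10

    def test_rejects_boundary_probabilities(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                norm_ppf(bad)


class TestDprime:
    def test_symmetric_rates_give_zero(self):
        assert dprime(BehavioralCounts(50, 50, 100, 100)) == pytest.approx(0.0, abs=1e-12)

    def test_known_values_from_quantile_oracle(self):
        # oracle: scipy's independent high-precision normal quantile
        d = dprime(BehavioralCounts(95, 5, 100, 100))
        assert d == pytest.approx(ndtri(95.5 / 101) - ndtri(5.5 / 101), abs=1e-10)
        assert d == pytest.approx(3.206, abs=5e-4)

    def test_perfect_performance_stays_finite(self):
        d = dprime(BehavioralCounts(100, 0, 100, 100))
        assert d == pytest.approx(ndtri(100.5 / 101) - ndtri(0.5 / 101), abs=1e-10)
        assert d == pytest.approx(5.1585, abs=5e-4)

    def test_monotone_in_hits_and_antitone_in_false_alarms(self):
        N = 20
        vals = np.array(
            [[dprime(BehavioralCounts(h, f, N, N)) for f in range(N + 1)] for h in range(N + 1)]
        )
        assert np.all(np.diff(vals, axis=0) > 0)  # increasing in H
        assert np.all(np.diff(vals, axis=1) < 0)  # decreasing in F

    def test_count_validation(self):
        with pytest.raises(ValueError):
            BehavioralCounts(5, 0, 4, 10)
        with pytest.raises(ValueError):
            BehavioralCounts(2.5, 0, 10, 10)


def rank_sum_enumeration_p(x, y, tail):
    """Exhaustive permutation distribution of U over all group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), nx):
        us.append(ranks[list(idx)].sum() - nx * (nx + 1) / 2)
    us = np.array(us)
    mu = nx * len(y) / 2
    if tail == "greater":
        return np.mean(us >= obs - 1e-12)
    if tail == "less":
        return np.mean(us <= obs + 1e-12)
    return np.mean(np.abs(us - mu) >= abs(obs - mu) - 1e-12)


class TestRankSum:
    def test_small_sample_exact_example(self):
        rec = rank_sum_test([1.0, 2.0], [3.0, 4.0], tail="less")
        assert rec.statistic == 0.0
        assert rec.p == pytest.approx(1.0 / 6.0)
        assert rec.effect_size_r == pytest.approx(-1.0)

    def test_identical_samples(self):
        rec = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], tail="two_sided")
        assert rec.effect_size_r == pytest.approx(0.0)
        assert rec.p == pytest.approx(1.0)

    def test_complete_separation(self):
        rec = rank_sum_test([3.0, 4.0, 5.0], [1.0, 2.0], tail="greater")
        assert rec.statistic == 6.0  # n_x * n_y
        assert rec.effect_size_r == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for tail in ("greater", "less", "two_sided"):
            for _ in range(5):
                x = rng.normal(size=rng.integers(3, 7))
                y = rng.normal(size=rng.integers(3, 7))
                rec = rank_sum_test(x, y, tail=tail)
                assert rec.p == pytest.approx(
                    rank_sum_enumeration_p(x, y, tail), abs=1e-12
                )

    def test_normal_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=7) + 0.5
        y = rng.normal(size=6)
        # force the approximate path by duplicating one value (a tie)
        x[0] = y[0]
        rec = rank_sum_test(x, y, tail="greater")
        assert rec.p == pytest.approx(
            rank_sum_enumeration_p(x, y, "greater"), abs=0.03
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=5) + 0.3
        a = rank_sum_test(x, y, tail="greater")
        b = rank_sum_test(np.exp(x), np.exp(y), tail="greater")
        assert a.p == pytest.approx(b.p, abs=1e-12)
        assert a.statistic == b.statistic


class TestSignedRank:
    def test_uniform_shift_exact_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rec = signed_rank_test(x + 0.5, x, tail="greater")
        assert rec.p == pytest.approx(1.0 / 64.0)

    def test_antisymmetric_differences_centre_the_statistic(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        rec = signed_rank_test(d, tail="two_sided")
        n = len(d)
        assert rec.statistic == pytest.approx(n * (n + 1) / 4.0)
        assert rec.p > 0.9

    def test_zero_differences_dropped(self):
        rec = signed_rank_test([1.0, 0.0, 2.0, 0.0, 3.0], [0.0] * 5, tail="greater")
        assert rec.n == (3,)
        with pytest.raises(ValueError):
            signed_rank_test([1.0, 1.0], [1.0, 1.0])

    def test_exact_and_normal_paths_agree_at_boundary_n(self):
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(50):
            d = rng.normal(size=12)
            exact = signed_rank_test(d, tail="two_sided")
            # approximate path: shared implementation formula on the same W
            mu = 12 * 13 / 4.0
            sigma = np.sqrt(12 * 13 * 25 / 24.0)
            z = np.sign(exact.statistic - mu) * max(abs(exact.statistic - mu) - 0.5, 0) / sigma
            p_norm = 2 * stats.norm.sf(abs(z))
            diffs.append(abs(exact.p - p_norm))
        assert max(diffs) < 0.02


class TestKS:
    def test_identical_samples_give_zero_distance(self):
        rec = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rec.statistic == 0.0

    def test_disjoint_supports_give_one(self):
        rec = ks_two_sample([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert rec.statistic == 1.0

    def test_interleaved_half_distance(self):
        rec = ks_two_sample([1.0, 3.0], [2.0, 4.0])
        assert rec.statistic == pytest.approx(0.5)


class TestEffectSizes:
    def test_partial_eta_sq_arithmetic(self):
        assert partial_eta_sq(0.0, 1, 100) == 0.0
        assert partial_eta_sq(10.0, 2, 40) == pytest.approx(20.0 / 60.0)
        with pytest.raises(ValueError):
            partial_eta_sq(-1.0, 1, 10)

    def test_cohens_d_identities(self):
        assert cohens_d_from_t(0.0, 10) == 0.0
        for n in (2, 9, 17):
            assert cohens_d_from_t(np.sqrt(n), n) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 1)


class TestBootstrapStability:
    def test_complete_separation_gives_full_consistency(self):
        x = np.arange(10.0, 20.0)
        y = np.arange(0.0, 8.0)
        bs = bootstrap_stability(x, y, tail="greater", n_resamples=500, seed=0)
        assert bs.direction_consistency == 1.0
        assert bs.ci_low <= bs.ci_high

    def test_identical_groups_split_direction(self):
        # both groups resample the exact same values: the effect direction
        # is a coin flip up to the (small) probability of a tied U
        vals = np.random.default_rng(3).normal(size=17)
        bs = bootstrap_stability(vals, vals.copy(), tail="two_sided", n_resamples=10_000, seed=1)
        assert abs(bs.direction_consistency - 0.5) < 0.05

    def test_reproducible_from_seed(self):
        x = np.random.default_rng(4).normal(size=12)
        y = np.random.default_rng(5).normal(size=9)
        a = bootstrap_stability(x, y, n_resamples=300, seed=7)
        b = bootstrap_stability(x, y, n_resamples=300, seed=7)
        assert a.to_dict() == b.to_dict()

    def test_p_stability_grows_with_shift(self):
        rng = np.random.default_rng(6)
        stabs = []
        for shift in (0.0, 1.0, 2.0):
            vals = []
            for seed in range(3):
                x = rng.normal(size=17) + shift
                y = rng.normal(size=10)
                vals.append(
                    bootstrap_stability(
                        x, y, tail="greater", n_resamples=1000, seed=seed
                    ).p_stability
                )
            stabs.append(np.median(vals))
        assert stabs[0] <= stabs[1] <= stabs[2]
        assert stabs[2] > stabs[0]


class TestLeaveOneOut:
    def test_group_b_iteration_count(self):
        x = np.random.default_rng(0).normal(size=17)
        y = np.random.default_rng(1).normal(size=10)
        recs = leave_one_out(x, y, which="groupB")
        assert len(recs) == 10
        recs_all = leave_one_out(x, y, which="all")
        assert len(recs_all) == 27

    def test_separation_significant_in_every_iteration(self):
        x = np.arange(10.0, 16.0)
        y = np.arange(0.0, 5.0)
        recs = leave_one_out(x, y, which="all", tail="greater")
        assert all(r.p < 0.05 for r in recs)

    def test_deterministic(self):
        x = np.random.default_rng(2).normal(size=8)
        y = np.random.default_rng(3).normal(size=6)
        a = [r.p for r in leave_one_out(x, y)]
        b = [r.p for r in leave_one_out(x, y)]
        assert a == b


class TestSpearman:
    def test_perfect_monotone_relationships(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_corr(x, x**3).statistic == pytest.approx(1.0)
        assert spearman_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rec = spearman_corr(x, y)
        # oracle: enumerate all 120 orderings with scipy's rho
        obs = abs(stats.spearmanr(x, y).statistic)
        count = sum(
            abs(stats.spearmanr(x, np.array(p)).statistic) >= obs - 1e-12
            for p in permutations(y)
        )
        assert rec.p == pytest.approx(count / 120.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
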