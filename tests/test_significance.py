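import itertools
import math
import statistics
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from shortcourse.errors import ParameterError, UsageError
from shortcourse.significance import (
    feature_per_replicate,
    paired_test,
    permutation_test,
    run_screen,
    two_sample_test,
)
from shortcourse.simulate import SimulationSpec, simulate_to_dataset


def naive_welch_t(a, b):
    """Oracle Welch t built on the statistics module, not numpy."""
    va = statistics.variance(a) if len(a) > 1 else 0.0
    vb = statistics.variance(b) if len(b) > 1 else 0.0
    num = statistics.fmean(a) - statistics.fmean(b)
    den = math.sqrt(va / len(a) + vb / len(b))
    if den == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / den


def enumerate_unpaired_p(a, b):
    """Brute-force permutation p: all group relabelings of the pooled sample."""
    pooled = list(a) + list(b)
    t_obs = abs(naive_welch_t(a, b))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(a)):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        count += abs(naive_welch_t(ga, gb)) >= t_obs - 1e-12
        total += 1
    return count / total


def enumerate_paired_p(a, b):
    d = [x - y for x, y in zip(a, b)]

    def tstat(ds):
        if len(set(ds)) == 1 and ds[0] == 0:
            return 0.0
        sd = statistics.stdev(ds)
        if sd == 0:
            return math.copysign(math.inf, statistics.fmean(ds))
        return statistics.fmean(ds) / (sd / math.sqrt(len(ds)))

    t_obs = abs(tstat(d))
    count = total = 0
    for signs in itertools.product((1, -1), repeat=len(d)):
        count += abs(tstat([s * x for s, x in zip(signs, d)])) >= t_obs - 1e-12
        total += 1
    return count / total


def enumerate_mannwhitney_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of relabelings."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(ga, gb):
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    cdf = np.mean(us <= u_obs + 1e-12)
    sf = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(cdf, sf))


class TestTwoSample:
    def test_identical_groups_degenerate(self):
        out = two_sample_test([1.0, 1.0], [1.0, 1.0], "t")
        assert out.statistic == 0.0 and out.pvalue == 1.0 and out.degenerate

    def test_equal_groups_p_one(self):
        out = two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "t")
        assert out.pvalue == pytest.approx(1.0)

    def test_mannwhitney_exact_small(self):
        out = two_sample_test([1.0, 2.0], [3.0, 4.0], "wilcoxon_mw")
        assert out.statistic == 0.0
        assert out.pvalue == pytest.approx(1.0 / 3.0)

    def test_symmetric_under_group_exchange(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        for test in ("t", "wilcoxon_mw"):
            p_ab = two_sample_test(a, b, test).pvalue
            p_ba = two_sample_test(b, a, test).pvalue
            assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_zero_variance_distinct_means(self):
        out = two_sample_test([1.0, 1.0], [2.0, 2.0], "t")
        assert out.pvalue == 0.0 and out.degenerate and math.isinf(out.statistic)

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_mannwhitney_matches_enumeration_oracle(self, data):
        n_a = data.draw(st.integers(1, 6))
        n_b = data.draw(st.integers(1, 8 - n_a) if n_a < 8 else st.just(1))
        vals = data.draw(
            st.lists(
                st.integers(-20, 20).map(float),
                min_size=n_a + n_b, max_size=n_a + n_b, unique=True,
            )
        )
        a, b = vals[:n_a], vals[n_a:]
        got = two_sample_test(a, b, "wilcoxon_mw").pvalue
        assert got == pytest.approx(enumerate_mannwhitney_p(a, b), abs=1e-9)


class TestPaired:
    def test_equal_pairs_p_one(self):
        out = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.pvalue == 1.0 and out.degenerate

    def test_constant_nonzero_difference_degenerate(self):
        out = paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert out.pvalue == 0.0 and out.degenerate and math.isinf(out.statistic)

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            paired_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_signed_rank_drops_zero_differences(self):
        out = paired_test([1.0, 2.0, 5.0, 7.0, 9.0], [1.0, 2.0, 3.0, 4.0, 5.0],
                          "wilcoxon_signed_rank")
        ref = stats.wilcoxon([2.0, 3.0, 4.0])
        assert out.pvalue == pytest.approx(ref.pvalue)


class TestPermutation:
    def test_unpaired_exact_example(self):
        out = permutation_test([1.0, 2.0], [3.0, 4.0], paired=False)
        assert out.pvalue == pytest.approx(1.0 / 3.0)

    def test_paired_exact_example(self):
        # constant differences, 3 pairs: only all-plus and all-minus sign
        # patterns reach |T_obs| among the 2^3 flips
        out = permutation_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], paired=True)
        assert out.pvalue == pytest.approx(2.0 / 8.0)

    def test_identical_groups_p_one(self):
        out = permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert out.pvalue == 1.0

    def test_exact_mode_seed_invariant(self, rng):
        a, b = list(rng.normal(size=4)), list(rng.normal(size=4))
        p1 = permutation_test(a, b, seed=1).pvalue
        p2 = permutation_test(a, b, seed=999).pvalue
        assert p1 == p2

    def test_sampled_converges_to_exact(self, rng):
        a = list(rng.normal(0, 1, 9))
        b = list(rng.normal(1, 1, 9))  # C(18,9)=48620 > exact limit
        exact = enumerate_unpaired_p(a, b)
        sampled = permutation_test(a, b, n_perm=50_000, seed=5).pvalue
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_sampled_p_at_least_floor(self, rng):
        a = list(rng.normal(0, 0.1, 9))
        b = list(rng.normal(50, 0.1, 9))
        out = permutation_test(a, b, n_perm=2000, seed=3)
        assert out.pvalue >= 1.0 / 2001

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_exact_matches_enumeration_oracle(self, data):
        n_a = data.draw(st.integers(2, 4))
        n_b = data.draw(st.integers(2, 8 - n_a))
        vals = data.draw(
            st.lists(st.integers(-10, 10).map(float),
                     min_size=n_a + n_b, max_size=n_a + n_b)
        )
        a, b = vals[:n_a], vals[n_a:]
        got = permutation_test(a, b, paired=False).pvalue
        assert got == pytest.approx(enumerate_unpaired_p(a, b), abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(-10, 10).map(float),
                              st.integers(-10, 10).map(float)),
                    min_size=2, max_size=6))
    def test_paired_exact_matches_enumeration_oracle(self, pairs):
        a = [x for x, _ in pairs]
        b = [y for _, y in pairs]
        got = permutation_test(a, b, paired=True).pvalue
        assert got == pytest.approx(enumerate_paired_p(a, b), abs=1e-12)

    def test_bad_n_perm(self):
        with pytest.raises(ParameterError):
            permutation_test([1.0, 2.0], [3.0, 4.0], n_perm=0)


class TestFeaturePerReplicate:
    def test_one_value_per_covering_replicate(self, dataset):
        vals, labels = feature_per_replicate(dataset, "g1", "alpha", "signed_auc", [0, 24])
        assert labels == [1, 2]
        # rep1: line 1->2 over 24h: auc = 36; rep2: 3->4: auc = 84
        np.testing.assert_allclose(vals, [36.0, 84.0])

    def test_uncovered_replicate_skipped_with_warning(self, dataset):
        # g2 control rep2 only has t=24
        with pytest.warns(UserWarning, match="skipped"):
            vals, labels = feature_per_replicate(
                dataset, "g2", "control", "signed_auc", [0, 24]
            )
        assert labels == [1]

    def test_time_point_measured_value(self, dataset):
        vals, _ = feature_per_replicate(dataset, "g1", "alpha", "time_point", [24])
        np.testing.assert_allclose(vals, [2.0, 4.0])


class TestRunScreen:
    def test_null_pvalues_uniform(self):
        ds, _ = simulate_to_dataset(
            SimulationSpec(n_genes=300, fraction_alternative=0.0, noise_sd=0.3, seed=11)
        )
        results, _, skipped = run_screen(ds, ("control", "alpha"), "signed_auc", [0, 24])
        assert not skipped
        p = np.array([r.pvalue for r in results])
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_flagged_probe_excluded_and_reported(self, dataset):
        # inject a gross outlier replicate for g1 alpha by adding a replicate
        t = np.array([0.0, 24.0])
        dataset.profiles[("g1", "alpha", 3)] = (t, np.array([500.0, 500.0]))
        dataset.profiles[("g1", "control", 3)] = (t, np.array([1.5, 2.5]))
        results, reports, skipped = run_screen(
            dataset, ("alpha", "control"), "signed_auc", [0, 24],
            outlier_method="dixon", outlier_action="remove-gene",
        )
        assert "g1" not in [r.probe for r in results]
        assert any(r.probe == "g1" and 3 in r.flagged for r in reports)
        assert "g1" in skipped

    def test_remove_value_keeps_probe(self, dataset):
        t = np.array([0.0, 24.0])
        dataset.profiles[("g1", "alpha", 3)] = (t, np.array([500.0, 500.0]))
        dataset.profiles[("g1", "control", 3)] = (t, np.array([1.5, 2.5]))
        results, reports, _ = run_screen(
            dataset, ("alpha", "control"), "signed_auc", [0, 24],
            outlier_method="dixon", outlier_action="remove-value",
        )
        g1 = next(r for r in results if r.probe == "g1")
        assert g1.n_a == 2  # outlier replicate removed, probe still tested
        assert reports

    def test_identical_treatments_paired_t_p_one(self):
        ds, _ = simulate_to_dataset(
            SimulationSpec(n_genes=10, fraction_alternative=0.0, noise_sd=0.0,
                           paired=True, seed=2)
        )
        results, _, _ = run_screen(ds, ("control", "alpha"), "signed_auc", [0, 24],
                                   test="paired_t")
        assert all(r.pvalue == 1.0 for r in results)

    def test_same_treatment_twice_rejected(self, dataset):
        with pytest.raises(UsageError):
            run_screen(dataset, ("alpha", "alpha"), "signed_auc", [0, 24])

    def test_paired_test_on_unpaired_rejected(self, dataset):
        dataset.paired = False
        with pytest.raises(UsageError, match="paired"):
            run_screen(dataset, ("alpha", "control"), "signed_auc", [0, 24], test="paired_t")

    def test_type_one_error_near_level(self):
        ds, _ = simulate_to_dataset(
            SimulationSpec(n_genes=400, fraction_alternative=0.0, noise_sd=0.3, seed=5)
        )
        results, _, _ = run_screen(ds, ("control", "alpha"), "signed_auc", [0, 24])
        p = np.array([r.pvalue for r in results])
        err = np.mean(p <= 0.05)
        se = math.sqrt(0.05 * 0.95 / p.size)
        assert abs(err - 0.05) <= 2.5 * se
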