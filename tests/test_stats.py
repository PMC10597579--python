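"""Permutation inference: cluster tests, map tests, post hoc contrasts,
rank correlations."""

import numpy as np
import pytest

from cpmosc.stats import (
    cluster_permutation_tfr,
    permutation_ttest_maps,
    posthoc_paired,
    spearman,
    wilcoxon_ranksum_effect,
)


def _effect_maps(rng, n=17, shape=(30, 40), effect=0.0, region=None):
    maps = rng.standard_normal((n,) + shape)
    if effect and region is not None:
        maps[:, region[0], region[1]] += effect
    return maps


class TestClusterPermutation:
    def test_identical_paired_maps_give_no_significant_cluster(self):
        rng = np.random.default_rng(20)
        a = _effect_maps(rng)
        res = cluster_permutation_tfr(a, a.copy(), paired=True, n_perm=200, seed=0)
        assert res.significant() == []

    def test_injected_effect_found_with_overlapping_cluster(self):
        rng = np.random.default_rng(21)
        region = (slice(10, 20), slice(5, 25))
        b = _effect_maps(rng)
        a = b + rng.standard_normal(b.shape) * 0.5
        a[:, region[0], region[1]] += 1.5
        res = cluster_permutation_tfr(a, b, paired=True, n_perm=300, seed=1)
        sig = res.significant()
        assert sig
        truth = np.zeros((30, 40), bool)
        truth[region] = True
        best = max(sig, key=lambda c: c.mask.sum())
        jac = (best.mask & truth).sum() / (best.mask | truth).sum()
        assert jac >= 0.5

    def test_seed_determinism(self):
        rng = np.random.default_rng(22)
        a, b = _effect_maps(rng), _effect_maps(rng)
        r1 = cluster_permutation_tfr(a, b, paired=True, n_perm=150, seed=5)
        r2 = cluster_permutation_tfr(a, b, paired=True, n_perm=150, seed=5)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_corrected_p_bounded_below_by_resolution(self):
        rng = np.random.default_rng(23)
        b = _effect_maps(rng, n=12)
        a = b + 3.0  # global huge effect
        res = cluster_permutation_tfr(a, b, paired=True, n_perm=200, seed=2)
        assert min(c.p for c in res.clusters) >= 1 / 201

    def test_unequal_paired_sets_rejected(self):
        rng = np.random.default_rng(24)
        with pytest.raises(ValueError):
            cluster_permutation_tfr(
                _effect_maps(rng, n=5), _effect_maps(rng, n=6), paired=True
            )

    def test_low_permutation_count_warns(self):
        rng = np.random.default_rng(25)
        a = _effect_maps(rng, n=6, shape=(5, 5))
        with pytest.warns(UserWarning):
            cluster_permutation_tfr(a, a.copy(), paired=True, n_perm=50, seed=0)

    def test_independent_groups_path(self):
        rng = np.random.default_rng(26)
        a = _effect_maps(rng, n=10, shape=(10, 12))
        b = _effect_maps(rng, n=12, shape=(10, 12)) + 1.2
        res = cluster_permutation_tfr(a, b, paired=False, n_perm=300, seed=3)
        assert res.significant()


class TestPermutationMaps:
    def test_identical_inputs_give_empty_mask(self):
        rng = np.random.default_rng(27)
        a = rng.standard_normal((10, 12))
        res = permutation_ttest_maps(a, a.copy(), paired=True, n_perm=200, seed=0)
        assert not res.mask.any()

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(28)
        a = rng.standard_normal((12, 20))
        b = rng.standard_normal((12, 20))
        b[:, :4] += 1.0
        res = permutation_ttest_maps(a, b, paired=False, n_perm=300, seed=1)
        order = np.argsort(res.p)
        assert np.all(np.diff(res.q[order]) >= -1e-12)
        assert np.all(res.q >= res.p - 1e-12)

    def test_injected_channels_recovered(self):
        rng = np.random.default_rng(29)
        b = rng.standard_normal((17, 12))
        a = b + 0.3 * rng.standard_normal((17, 12))
        a[:, :4] += 2.5  # strong effect on 4 of 12 locations
        res = permutation_ttest_maps(a, b, paired=True, n_perm=400, seed=2)
        assert set(np.nonzero(res.mask)[0]) >= {0, 1, 2, 3}

    def test_seed_determinism(self):
        rng = np.random.default_rng(30)
        a, b = rng.standard_normal((9, 7)), rng.standard_normal((9, 7))
        r1 = permutation_ttest_maps(a, b, paired=True, n_perm=200, seed=9)
        r2 = permutation_ttest_maps(a, b, paired=True, n_perm=200, seed=9)
        np.testing.assert_array_equal(r1.p, r2.p)


class TestPosthoc:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        res = posthoc_paired({"a": x, "b": x.copy(), "c": x + 1}, [("a", "b"), ("a", "c")])
        assert res.p_raw[0] == 1.0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(31)
        vals = {k: rng.standard_normal(12) for k in "abc"}
        res = posthoc_paired(vals, [("a", "b"), ("a", "c")])
        assert np.all(res.p_adjusted >= res.p_raw - 1e-12)

    def test_shifted_pair_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(32)
        base = rng.standard_normal(15)
        vals = {
            "a": base,
            "b": base + 1.5 + 0.2 * rng.standard_normal(15),
            "c": base + 0.05 * rng.standard_normal(15),
        }
        res = posthoc_paired(vals, [("a", "b"), ("a", "c")])
        assert res.p_adjusted[0] < res.p_adjusted[1]

    def test_few_informative_pairs_flagged(self):
        x = np.arange(6.0)
        y = x.copy()
        y[0] += 1.0
        res = posthoc_paired({"a": x, "b": y}, [("a", "b")])
        assert res.small_sample


class TestSpearman:
    def test_monotone_relation_gives_unit_rho(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        rho, _ = spearman(x, np.exp(x / 5.0))
        assert rho == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
        rho, _ = spearman(np.array([1, 2, 3, 4, 5]), np.array([2, 1, 4, 3, 5]))
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_reversal_negates_rho(self):
        rng = np.random.default_rng(33)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(x, -y)
        assert rho1 == pytest.approx(-rho2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))


class TestRankSum:
    def test_effect_size_in_unit_interval(self):
        rng = np.random.default_rng(34)
        for _ in range(20):
            p, r = wilcoxon_ranksum_effect(
                rng.standard_normal(rng.integers(3, 30)),
                rng.standard_normal(rng.integers(3, 30)),
            )
            assert 0.0 <= r <= 1.0 and 0.0 <= p <= 1.0

    def test_complete_separation_attains_closed_form_maximum(self):
        # 17 vs 17 fully separated samples: rank sum of the lower group
        # is 17*18/2, giving |Z| = 144.5 / sqrt(17*17*35/12) and
        # r = |Z| / sqrt(34)
        x = np.arange(17.0)
        y = np.arange(17.0) + 100.0
        p, r = wilcoxon_ranksum_effect(x, y)
        z_max = (17 * 35 / 2 - 17 * 18 / 2) / np.sqrt(17 * 17 * 35 / 12)
        assert r == pytest.approx(z_max / np.sqrt(34), abs=1e-12)
        assert p < 1e-5

    def test_null_effect_concentrates_near_zero(self):
        rng = np.random.default_rng(35)
        rs = [
            wilcoxon_ranksum_effect(rng.standard_normal(17), rng.standard_normal(17))[1]
            for _ in range(100)
        ]
        assert np.median(rs) < 0.25

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum_effect(np.array([]), np.arange(3.0))
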