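"""Stability metrics, baseline criteria, and the study runner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marginalrank.criteria import CriterionFailure
from marginalrank.evaluation import (RankExperiment, baseline_criterion,
                                     kuncheva_index, kuncheva_index_multi,
                                     parse_criterion, run_study)
from marginalrank.simulate import study_spec


class TestKunchevaIndex:
    def test_identical_lists(self):
        lst = list("abcdefghij")
        for k in (1, 3, 5, 9):
            assert kuncheva_index(lst, lst, k) == pytest.approx(1.0)

    def test_single_overlap_formula(self):
        a = list(range(10))
        b = [0, 10 - 1] + [9 - i for i in range(1, 9)]
        # top-2 sets {0,1} vs {0,9}: overlap 1, d=10, k=2
        b = [0, 9, 8, 7, 6, 5, 4, 3, 2, 1]
        assert kuncheva_index(a, b, 2) == pytest.approx((1 - 0.4) / (2 - 0.4))

    def test_chance_level_overlap_is_zero(self):
        # d=4, k=2, overlap 1 = k^2/d: numerator vanishes
        assert kuncheva_index([0, 1, 2, 3], [0, 2, 3, 1], 2) == pytest.approx(0.0)

    def test_k_equal_d_rejected(self):
        with pytest.raises(ValueError):
            kuncheva_index([0, 1, 2], [2, 1, 0], 3)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            kuncheva_index([0, 1, 2], [0, 1, 5], 1)

    def test_multi_list_mean_of_pairs(self):
        a, b, c = [0, 1, 2, 3], [0, 2, 3, 1], [3, 2, 1, 0]
        expected = np.mean([kuncheva_index(x, y, 2)
                            for x, y in [(a, b), (a, c), (b, c)]])
        assert kuncheva_index_multi([a, b, c], 2) == pytest.approx(expected)


@settings(deadline=None, max_examples=40)
@given(perm=st.permutations(list(range(8))),
       k=st.integers(min_value=1, max_value=7))
def test_kuncheva_symmetry_and_bounds(perm, k):
    base = list(range(8))
    val = kuncheva_index(base, perm, k)
    assert val == pytest.approx(kuncheva_index(perm, base, k))
    assert -1.0 <= val <= 1.0 + 1e-12


class TestBaselines:
    def test_pearson_detects_monotone_association(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 300)
        y = (x > np.median(x)).astype(int)
        noise = rng.normal(0, 1, 300)
        _, key_x = baseline_criterion("pearson", x, y)
        _, key_noise = baseline_criterion("pearson", noise, y)
        assert key_x < key_noise    # smaller key = better

    def test_dcor_self_dependence_is_one(self):
        from marginalrank.evaluation import _distance_correlation
        x = np.random.default_rng(22).normal(0, 1, 60)
        stat, _ = baseline_criterion("dcor", x, (x > 0).astype(int))
        assert _distance_correlation(x, x) == pytest.approx(1.0)
        assert 0.0 <= stat <= 1.0

    def test_dcor_matches_naive_double_loop(self):
        """Independent O(n^2) oracle with explicit loops."""
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40).astype(float)

        n = len(x)
        a = np.zeros((n, n))
        b = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                a[i, j] = abs(x[i] - x[j])
                b[i, j] = abs(y[i] - y[j])
        A = np.zeros((n, n))
        B = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                A[i, j] = (a[i, j] - a[i, :].mean() - a[:, j].mean()
                           + a.mean())
                B[i, j] = (b[i, j] - b[i, :].mean() - b[:, j].mean()
                           + b.mean())
        dcov2 = (A * B).mean()
        expected = np.sqrt(dcov2 / np.sqrt((A * A).mean() * (B * B).mean()))

        stat, key = baseline_criterion("dcor", x, y.astype(int))
        assert stat == pytest.approx(expected, rel=1e-10)
        assert key == pytest.approx(-expected, rel=1e-10)

    def test_tests_return_two_sided_pvalues(self):
        rng = np.random.default_rng(24)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        y = np.repeat([0, 1], 50)
        for name in ("ttest", "wilcoxon"):
            stat, p = baseline_criterion(name, x, y)
            assert 0.0 <= p <= 1.0 and p < 0.01

    def test_constant_feature_fails(self):
        y = np.repeat([0, 1], 10)
        for name in ("pearson", "dcor", "ttest"):
            with pytest.raises(CriterionFailure):
                baseline_criterion(name, np.ones(20), y)

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            baseline_criterion("auroc", np.arange(8.0), np.repeat([0, 1], 4))


class TestParseCriterion:
    def test_specs(self):
        assert parse_criterion("cc") == ("cc", None)
        assert parse_criterion("npc:0.05") == ("npc", 0.05)
        assert parse_criterion("NPC:.2") == ("npc", 0.2)
        assert parse_criterion("dcor") == ("dcor", None)

    def test_invalid(self):
        for bad in ("npc", "npc:1.5", "magic"):
            with pytest.raises(ValueError):
                parse_criterion(bad)


class TestRunStudy:
    def test_deterministic_given_seed(self):
        exp = RankExperiment(spec=study_spec("S6"), criteria=("cc", "pearson"),
                             reps=2, seed=33, N=200, B=3)
        a, b = run_study(exp), run_study(exp)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.ranks, b.ranks)

    def test_rank_matrix_validity(self):
        exp = RankExperiment(spec=study_spec("S1"),
                             criteria=("cc", "npc:0.2", "wilcoxon"),
                             reps=2, seed=34, N=200, B=2)
        res = run_study(exp)
        d = study_spec("S1").d
        # every per-rep rank vector is a valid (possibly tied) ranking
        assert res.ranks.shape == (2, 3, d)
        np.testing.assert_allclose(res.ranks.sum(axis=2),
                                   d * (d + 1) / 2)
        freqs = res.top_rank_frequency()
        assert ((freqs >= 0) & (freqs <= 1)).all().all()
        assert np.allclose(freqs.sum(axis=0), 1.0, atol=1.0)  # ties may drop

    def test_correct_order_frequency(self):
        exp = RankExperiment(spec=study_spec("S6"), criteria=("cc",),
                             reps=3, seed=35, N=300, B=3)
        res = run_study(exp)
        freq = res.correct_order_frequency([1, 0])   # feature 2 then feature 1
        assert 0.0 <= freq.iloc[0] <= 1.0
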