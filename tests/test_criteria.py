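"""Sample splitting, s-CC, s-NPC and rank assignment."""

import numpy as np
import pytest
from scipy.stats import norm

from marginalrank.criteria import (CriterionFailure, TwoClassSample,
                                   make_splits, npc_from_scores, rank_subsets,
                                   s_cc, s_npc, split_scores)
from marginalrank.kde import KDEOptions
from marginalrank.umbrella import NoValidOrderError


class TestMakeSplits:
    def test_half_half_partition(self):
        plan = make_splits(4, 4, 1, seed=3)
        assert len(plan.ts0[0]) == 2 and len(plan.lo0[0]) == 2
        assert set(plan.ts0[0]) | set(plan.lo0[0]) == set(range(4))
        assert set(plan.ts0[0]) & set(plan.lo0[0]) == set()

    def test_floor_rule_for_odd_sizes(self):
        plan = make_splits(5, 7, 3, seed=0)
        assert (plan.m1, plan.m2, plan.n1, plan.n2) == (2, 3, 3, 4)
        for b in range(3):
            assert len(plan.ts0[b]) == 2 and len(plan.lo0[b]) == 3
            assert len(plan.ts1[b]) == 3 and len(plan.lo1[b]) == 4

    def test_deterministic_in_seed(self):
        assert make_splits(20, 30, 5, seed=7) == make_splits(20, 30, 5, seed=7)
        assert make_splits(20, 30, 5, seed=7) != make_splits(20, 30, 5, seed=8)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_splits(3, 10, 1, seed=0)


class TestTwoClassSample:
    def test_shape_and_name_validation(self):
        with pytest.raises(ValueError):
            TwoClassSample(X0=np.zeros((4, 2)), X1=np.zeros((4, 3)))
        with pytest.raises(ValueError):
            TwoClassSample(X0=np.zeros((3, 2)), X1=np.zeros((4, 2)))
        s = TwoClassSample(X0=np.zeros((4, 2)), X1=np.ones((5, 2)))
        assert s.feature_names == ("x1", "x2")

    def test_from_dataframe_explicit_class0(self):
        import pandas as pd
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 5,
                           "f1": np.arange(9.0), "f2": np.arange(9.0) ** 2})
        s = TwoClassSample.from_dataframe(df, "g", class0="b")
        assert (s.m, s.n) == (5, 4)
        with pytest.raises(ValueError):
            TwoClassSample.from_dataframe(df, "missing", class0="b")
        with pytest.raises(ValueError):
            TwoClassSample.from_dataframe(df, "g", class0="zzz")


def _micro_sample():
    return TwoClassSample(
        X0=np.array([0.0, 0.2, 0.4, 0.6])[:, None],
        X1=np.array([5.0, 5.2, 5.4, 5.6])[:, None])


class TestSCC:
    def test_disjoint_supports_near_zero_risk(self):
        rng = np.random.default_rng(1)
        sample = TwoClassSample(X0=rng.normal(-100, 1, (500, 1)),
                                X1=rng.normal(100, 1, (500, 1)))
        plan = make_splits(500, 500, 3, seed=2)
        res = s_cc(sample, (0,), plan)
        assert res.value < 0.01

    def test_micro_dataset_matches_brute_force(self):
        """B=1, fixed h: hand-evaluate the kernel sums on left-out points."""
        sample = _micro_sample()
        plan = make_splits(4, 4, 1, seed=5)
        opts = KDEOptions(bandwidth=1.0)
        res = s_cc(sample, (0,), plan, opts)

        ts0 = sample.X0[list(plan.ts0[0]), 0]
        ts1 = sample.X1[list(plan.ts1[0]), 0]
        lo0 = sample.X0[list(plan.lo0[0]), 0]
        lo1 = sample.X1[list(plan.lo1[0]), 0]

        def kde(train, x):
            return np.mean([norm.pdf(x - t) for t in train])

        thr = plan.m1 / plan.n1  # = 1
        errors = sum(kde(ts1, x) / kde(ts0, x) > thr for x in lo0)
        errors += sum(kde(ts1, x) / kde(ts0, x) <= thr for x in lo1)
        assert res.value == pytest.approx(errors / 4)
        assert res.per_split_values.shape == (1,)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        sample = TwoClassSample(X0=rng.normal(0, 1, (40, 2)),
                                X1=rng.normal(0.5, 1, (44, 2)))
        plan = make_splits(40, 44, 7, seed=4)
        for subset in [(0,), (1,), (0, 1)]:
            res = s_cc(sample, subset, plan)
            assert np.all((res.per_split_values >= 0)
                          & (res.per_split_values <= 1))

    def test_zero_variance_feature_fails(self):
        sample = TwoClassSample(X0=np.ones((8, 1)), X1=np.ones((8, 1)) * 2)
        plan = make_splits(8, 8, 2, seed=0)
        with pytest.raises(CriterionFailure):
            s_cc(sample, (0,), plan)

    def test_reproducible_with_fixed_plan(self):
        rng = np.random.default_rng(8)
        sample = TwoClassSample(X0=rng.normal(0, 1, (30, 1)),
                                X1=rng.normal(1, 1, (30, 1)))
        plan = make_splits(30, 30, 4, seed=9)
        a = s_cc(sample, (0,), plan)
        b = s_cc(sample, (0,), plan)
        np.testing.assert_array_equal(a.per_split_values, b.per_split_values)


class TestSNPC:
    def test_injected_scores_reproduce_counting(self):
        # k* = 59 at alpha = delta1 = .05 -> threshold 59; one of three
        # class-1 scores (10) falls at or below it
        val = npc_from_scores(np.arange(1.0, 60.0), [10.0, 60.0, 70.0],
                              alpha=0.05, delta1=0.05)
        assert val == pytest.approx(1 / 3)

    def test_split_contributes_zero_when_class1_clears_threshold(self):
        val = npc_from_scores(np.arange(1.0, 60.0), [59.5, 80.0],
                              alpha=0.05, delta1=0.05)
        assert val == 0.0

    def test_scorer_hook_bypasses_kde(self):
        """The umbrella is score-agnostic: inject the identity score."""
        rng = np.random.default_rng(11)
        sample = TwoClassSample(X0=rng.normal(0, 1, (200, 1)),
                                X1=rng.normal(3, 1, (200, 1)))
        plan = make_splits(200, 200, 2, seed=12)

        def identity_scorer(x0_ts, x1_ts):
            return lambda pts: np.asarray(pts, dtype=float)

        res = s_npc(sample, (0,), 0.1, 0.1, plan, scorer=identity_scorer)
        assert 0.0 <= res.value <= 1.0

    def test_insufficient_m2_raises_actionable_error(self):
        rng = np.random.default_rng(13)
        sample = TwoClassSample(X0=rng.normal(0, 1, (12, 1)),
                                X1=rng.normal(1, 1, (40, 1)))
        plan = make_splits(12, 40, 1, seed=0)   # m2 = 6 < 59
        with pytest.raises(NoValidOrderError) as exc:
            s_npc(sample, (0,), 0.05, 0.05, plan)
        assert exc.value.minimal_m2 == 59

    def test_monotone_in_alpha_under_shared_scores(self):
        rng = np.random.default_rng(14)
        sample = TwoClassSample(X0=rng.normal(0, 2, (300, 1)),
                                X1=rng.normal(1.5, 2, (300, 1)))
        plan = make_splits(300, 300, 5, seed=15)
        scores = split_scores(sample, (0,), plan)
        vals = [s_npc(sample, (0,), a, 0.05, plan,
                      precomputed_scores=scores).value
                for a in (0.05, 0.1, 0.2, 0.3)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)


class TestRankSubsets:
    def test_ascending_ranks(self):
        np.testing.assert_array_equal(rank_subsets([0.1, 0.3, 0.2]), [1, 3, 2])

    def test_average_rank_ties(self):
        np.testing.assert_array_equal(rank_subsets([0.2, 0.2, 0.5]),
                                      [1.5, 1.5, 3])

    def test_all_tied_gets_midrank(self):
        ranks = rank_subsets([0.3] * 6)
        np.testing.assert_array_equal(ranks, [3.5] * 6)

    def test_mixed_criteria_rejected(self):
        rng = np.random.default_rng(16)
        sample = TwoClassSample(X0=rng.normal(0, 1, (200, 2)),
                                X1=rng.normal(1, 1, (200, 2)))
        plan = make_splits(200, 200, 1, seed=17)
        scores = split_scores(sample, (0,), plan)
        cc = s_cc(sample, (0,), plan, precomputed_scores=scores)
        npc = s_npc(sample, (0,), 0.2, 0.05, plan, precomputed_scores=scores)
        with pytest.raises(ValueError):
            rank_subsets([cc, npc])


def test_toy_concentration_around_population_values():
    """With large N, s-CC and s-NPC(.20) on toy feature 1 settle near the
    population risk .106 and type II error .049."""
    from marginalrank.simulate import sample_study, study_spec

    spec = study_spec("TOY")
    for seed in (101, 102, 103):
        sample = sample_study(spec, N=20_000, seed=seed)
        plan = make_splits(sample.m, sample.n, 11, seed=seed + 1000)
        scores = split_scores(sample, (0,), plan)
        cc = s_cc(sample, (0,), plan, precomputed_scores=scores).value
        npc = s_npc(sample, (0,), 0.20, 0.05, plan,
                    precomputed_scores=scores).value
        assert abs(cc - 0.106) <= 0.02
        assert abs(npc - 0.049) <= 0.02
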