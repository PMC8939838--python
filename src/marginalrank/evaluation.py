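"""Ranking experiments, stability metrics, and baseline marginal criteria.

`run_study` repeats: draw a replicate from a study design, build one shared
split plan, compute every requested criterion for every feature, and rank.
Aggregates (top-rank frequencies, average ranks, correct-order frequency)
mirror the usual summaries of ranking simulations.

The Kuncheva index measures chance-corrected overlap of top-k feature sets
from two rank lists:  (|A_k ∩ B_k| - k^2/d) / (k - k^2/d), in [-1, 1].

Baselines: absolute Pearson correlation, distance correlation (biased
V-statistic, double-centering form), two-sample t test and Wilcoxon
rank-sum test (two-sided p-values).  Each returns a ranking key oriented so
that a smaller key means a better feature, matching `rank_subsets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .criteria import (CriterionFailure, SplitPlan, TwoClassSample,
                       make_splits, npc_from_scores, rank_subsets,
                       split_scores)
from .kde import KDEOptions
from .simulate import StudySpec, sample_study

__all__ = ["kuncheva_index", "baseline_criterion", "BASELINES",
           "RankExperiment", "StudyResult", "run_study", "parse_criterion"]

BASELINES = ("pearson", "dcor", "ttest", "wilcoxon")


# ---------------------------------------------------------------------------
# Kuncheva stability index
# ---------------------------------------------------------------------------

def kuncheva_index(list_a: Sequence, list_b: Sequence, k: int,
                   d: int | None = None) -> float:
    """Chance-corrected overlap of the top-k sets of two rank lists."""
    list_a, list_b = list(list_a), list(list_b)
    if d is None:
        d = len(list_a)
    if set(list_a) != set(list_b) or len(list_a) != d:
        raise ValueError("lists must be permutations of the same d features")
    if not (1 <= k < d):
        raise ValueError(f"k must satisfy 1 <= k < d (got k={k}, d={d})")
    overlap = len(set(list_a[:k]) & set(list_b[:k]))
    chance = k * k / d
    return (overlap - chance) / (k - chance)


def kuncheva_index_multi(lists: Sequence[Sequence], k: int,
                         d: int | None = None) -> float:
    """Mean pairwise Kuncheva index over more than two rank lists."""
    lists = [list(l) for l in lists]
    if len(lists) < 2:
        raise ValueError("need at least two rank lists")
    vals = [kuncheva_index(a, b, k, d)
            for i, a in enumerate(lists) for b in lists[i + 1:]]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Baseline marginal criteria
# ---------------------------------------------------------------------------

def _distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Biased (V-statistic) distance correlation via double-centering."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()
    B = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(dcov2 / np.sqrt(dvar_x * dvar_y)))


def baseline_criterion(name: str, x, y) -> tuple[float, float]:
    """(statistic, ranking_key) of a baseline criterion for one feature.

    ``y`` holds binary labels in {0, 1}.  Smaller ranking key = better
    feature: association measures are negated, tests use the two-sided
    p-value directly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    x0, x1 = x[y == 0], x[y == 1]
    if x0.size == 0 or x1.size == 0:
        raise ValueError("both classes must be non-empty")
    if name == "pearson":
        if np.std(x) == 0:
            raise CriterionFailure("constant feature: Pearson undefined")
        r = abs(float(np.corrcoef(x, y.astype(float))[0, 1]))
        return r, -r
    if name == "dcor":
        if np.std(x) == 0:
            raise CriterionFailure("constant feature: dcor degenerate")
        r = _distance_correlation(x, y.astype(float))
        return r, -r
    if name == "ttest":
        if np.std(x) == 0:
            raise CriterionFailure("constant feature: t test undefined")
        res = stats.ttest_ind(x0, x1, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if name == "wilcoxon":
        res = stats.mannwhitneyu(x0, x1, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown baseline {name!r}; one of {BASELINES}")


# ---------------------------------------------------------------------------
# Criterion spec parsing ("cc", "npc:0.05", "pearson", ...)
# ---------------------------------------------------------------------------

def parse_criterion(spec: str) -> tuple[str, float | None]:
    spec = spec.strip().lower()
    if spec == "cc":
        return "cc", None
    if spec.startswith("npc"):
        if ":" not in spec:
            raise ValueError("npc needs a level, e.g. 'npc:0.05'")
        alpha = float(spec.split(":", 1)[1])
        if not (0.0 < alpha < 1.0):
            raise ValueError(f"alpha outside (0,1): {alpha}")
        return "npc", alpha
    if spec in BASELINES:
        return spec, None
    raise ValueError(f"unknown criterion {spec!r}")


def criterion_label(kind: str, alpha: float | None) -> str:
    return f"npc:{alpha:g}" if kind == "npc" else kind


# ---------------------------------------------------------------------------
# Study runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankExperiment:
    """A repeated ranking experiment on a synthetic study design."""

    spec: StudySpec
    criteria: tuple                     # e.g. ("cc", "npc:0.01", "pearson")
    reps: int
    seed: int
    N: int | None = None
    B: int = 11
    delta1: float = 0.05
    kde_options: KDEOptions = field(default_factory=KDEOptions)
    fixed_counts: bool = False


@dataclass
class StudyResult:
    """Per-replicate criterion values and ranks, with summary accessors."""

    experiment: RankExperiment
    criteria: tuple                     # parsed (kind, alpha) pairs
    labels: tuple                       # printable criterion names
    feature_names: tuple
    values: np.ndarray                  # (reps, n_criteria, d)
    ranks: np.ndarray                   # (reps, n_criteria, d)
    n_failed_reps: int = 0

    def top_rank_frequency(self) -> pd.DataFrame:
        """Fraction of replicates in which each feature is the unique top."""
        top = self.ranks == 1.0         # average-rank ties never equal 1.0
        freq = top.mean(axis=0)         # (n_criteria, d)
        return pd.DataFrame(freq.T, index=self.feature_names, columns=self.labels)

    def average_ranks(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks.mean(axis=0).T, index=self.feature_names,
                            columns=self.labels)

    def correct_order_frequency(self, order: Sequence[int]) -> pd.Series:
        """Fraction of replicates ranking the given features in strict order.

        ``order`` lists 0-based feature indices from best to worst; a
        replicate counts only when the criterion values are strictly
        increasing along it.
        """
        order = np.asarray(order, dtype=int)
        v = self.values[:, :, order]
        ok = np.all(np.diff(v, axis=2) > 0, axis=2)
        return pd.Series(ok.mean(axis=0), index=list(self.labels))


def run_study(experiment: RankExperiment) -> StudyResult:
    """Run the experiment: per replicate, draw data, rank by all criteria.

    One split plan is shared by all features and all split-based criteria
    within a replicate; left-out scores per (feature, split) are computed
    once and reused by s-CC and every s-NPC level.
    """
    parsed = tuple(parse_criterion(c) for c in experiment.criteria)
    labels = tuple(criterion_label(k, a) for k, a in parsed)
    spec = experiment.spec
    N = experiment.N or spec.N
    d = spec.d
    needs_scores = any(k in ("cc", "npc") for k, _ in parsed)
    root = np.random.SeedSequence(experiment.seed)
    rep_seeds = root.generate_state(2 * experiment.reps) % (2 ** 31)

    values = np.full((experiment.reps, len(parsed), d), np.nan)
    n_failed = 0
    for r in range(experiment.reps):
        sample = sample_study(spec, N, int(rep_seeds[2 * r]),
                              fixed_counts=experiment.fixed_counts)
        plan = make_splits(sample.m, sample.n, experiment.B,
                           int(rep_seeds[2 * r + 1]))
        y = np.concatenate([np.zeros(sample.m, dtype=int),
                            np.ones(sample.n, dtype=int)])
        xfull = np.vstack([sample.X0, sample.X1])
        for j in range(d):
            scores = None
            if needs_scores:
                try:
                    scores = split_scores(sample, (j,), plan,
                                          experiment.kde_options)
                except CriterionFailure:
                    scores = None
            for c, (kind, alpha) in enumerate(parsed):
                try:
                    if kind == "cc":
                        vals = [(np.sum(s["scores_lo0"] > plan.m1 / plan.n1)
                                 + np.sum(s["scores_lo1"] <= plan.m1 / plan.n1))
                                / (plan.m2 + plan.n2)
                                for s in scores if "failed" not in s]
                        if not vals:
                            raise CriterionFailure("all splits failed")
                        values[r, c, j] = np.mean(vals)
                    elif kind == "npc":
                        vals = [npc_from_scores(s["scores_lo0"], s["scores_lo1"],
                                                alpha, experiment.delta1)
                                for s in scores if "failed" not in s]
                        if not vals:
                            raise CriterionFailure("all splits failed")
                        values[r, c, j] = np.mean(vals)
                    else:
                        _, key = baseline_criterion(kind, xfull[:, j], y)
                        values[r, c, j] = key
                except (CriterionFailure, TypeError):
                    n_failed += 1
    ranks = np.empty_like(values)
    for r in range(experiment.reps):
        for c in range(len(parsed)):
            ranks[r, c] = rank_subsets(values[r, c])
    return StudyResult(experiment=experiment, criteria=parsed, labels=labels,
                       feature_names=tuple(f"x{j + 1}" for j in range(d)),
                       values=values, ranks=ranks, n_failed_reps=n_failed)
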