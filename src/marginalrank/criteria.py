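"""Sample-level ranking criteria: s-CC and s-NPC.

Both criteria estimate, from data alone, how well a candidate feature (or
feature pair) can classify under a given objective:

* s-CC estimates the misclassification risk of the plug-in classifier
  1(p1_hat/p0_hat > m1/n1) on left-out halves, averaged over B random
  half/half splits of each class.  The threshold m1/n1 mimics the class
  prior ratio pi0/pi1, which is why s-CC is sensitive to sampling bias.
* s-NPC estimates the type II error of an NP classifier whose threshold is
  set by the umbrella algorithm on left-out class-0 scores, so that the
  type I error exceeds alpha with probability at most delta1.  Only
  class-conditional quantities enter, which makes the ranking robust to
  sampling bias.

Smaller criterion values are better; `rank_subsets` assigns rank 1 to the
smallest value with average ranks on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kde import DegenerateSampleError, KDEOptions, fit_score_model
from .umbrella import NoValidOrderError, minimal_m2, np_threshold

__all__ = ["TwoClassSample", "SplitPlan", "CriterionResult", "make_splits",
           "split_scores", "s_cc", "s_npc", "rank_subsets", "CriterionFailure"]

logger = logging.getLogger(__name__)


class CriterionFailure(RuntimeError):
    """All B splits failed for a feature subset (e.g. zero-variance feature)."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoClassSample:
    """Class-0 and class-1 observation matrices over the same features.

    Class 0 is the class whose type I error the NP paradigm controls; the
    caller must designate it explicitly when ingesting labelled data
    (`from_dataframe`) -- which class plays this role is a substantive
    modelling choice, not something to infer silently.
    """

    X0: np.ndarray                      # (m, d)
    X1: np.ndarray                      # (n, d)
    feature_names: tuple = ()

    def __post_init__(self):
        X0 = np.atleast_2d(np.asarray(self.X0, dtype=float))
        X1 = np.atleast_2d(np.asarray(self.X1, dtype=float))
        if X0.ndim != 2 or X1.ndim != 2 or X0.shape[1] != X1.shape[1]:
            raise ValueError("X0 and X1 must be 2-D with equal column counts")
        if X0.shape[0] < 4 or X1.shape[0] < 4:
            raise ValueError("each class needs at least 4 observations to split")
        if not (np.all(np.isfinite(X0)) and np.all(np.isfinite(X1))):
            raise ValueError("missing or non-finite values in the sample")
        names = tuple(self.feature_names) or tuple(
            f"x{j + 1}" for j in range(X0.shape[1]))
        if len(names) != X0.shape[1]:
            raise ValueError("feature_names length mismatch")
        object.__setattr__(self, "X0", X0)
        object.__setattr__(self, "X1", X1)
        object.__setattr__(self, "feature_names", names)

    @property
    def m(self) -> int:
        return self.X0.shape[0]

    @property
    def n(self) -> int:
        return self.X1.shape[0]

    @property
    def d(self) -> int:
        return self.X0.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str, class0,
                       class1=None) -> "TwoClassSample":
        """Build a sample from a table with a label column.

        ``class0`` names the label value coded as class 0 (the error-to-
        control class under NP); ``class1`` defaults to the only other value.
        """
        if label_col not in df.columns:
            raise ValueError(
                f"label column {label_col!r} not found; available: "
                f"{list(df.columns)}")
        labels = df[label_col]
        values = pd.unique(labels)
        if class0 not in set(values):
            raise ValueError(f"class-0 label {class0!r} not present in {list(values)}")
        if class1 is None:
            rest = [v for v in values if v != class0]
            if len(rest) != 1:
                raise ValueError("label column is not binary; pass class1 explicitly")
            class1 = rest[0]
        feats = df.drop(columns=[label_col])
        if feats.isna().any().any():
            raise ValueError("missing values in feature columns")
        return cls(X0=feats[labels == class0].to_numpy(dtype=float),
                   X1=feats[labels == class1].to_numpy(dtype=float),
                   feature_names=tuple(feats.columns.astype(str)))


@dataclass(frozen=True)
class SplitPlan:
    """B reproducible half/half partitions of each class.

    A pure function of (m, n, B, seed).  The same plan is reused for every
    feature subset and every criterion within a run, so rankings compare
    like with like.  m1 = floor(m/2) indices go to the train-scoring half.
    """

    m: int
    n: int
    B: int
    seed: int
    ts0: tuple = field(repr=False, default=())   # B tuples of class-0 train indices
    lo0: tuple = field(repr=False, default=())
    ts1: tuple = field(repr=False, default=())
    lo1: tuple = field(repr=False, default=())

    @property
    def m1(self) -> int:
        return self.m // 2

    @property
    def m2(self) -> int:
        return self.m - self.m // 2

    @property
    def n1(self) -> int:
        return self.n // 2

    @property
    def n2(self) -> int:
        return self.n - self.n // 2


def make_splits(m: int, n: int, B: int, seed: int) -> SplitPlan:
    """Draw B uniform half/half partitions of {0..m-1} and {0..n-1}."""
    if m < 4 or n < 4:
        raise ValueError("each class needs at least 4 observations to split")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    m1, n1 = m // 2, n // 2
    ts0, lo0, ts1, lo1 = [], [], [], []
    for _ in range(B):
        p0 = rng.permutation(m)
        p1 = rng.permutation(n)
        ts0.append(tuple(np.sort(p0[:m1])))
        lo0.append(tuple(np.sort(p0[m1:])))
        ts1.append(tuple(np.sort(p1[:n1])))
        lo1.append(tuple(np.sort(p1[n1:])))
    return SplitPlan(m=m, n=n, B=B, seed=seed, ts0=tuple(ts0), lo0=tuple(lo0),
                     ts1=tuple(ts1), lo1=tuple(lo1))


@dataclass(frozen=True)
class CriterionResult:
    """Per-split and averaged criterion values for one feature subset."""

    subset: tuple
    criterion: str                      # "CC" or "NPC"
    per_split_values: np.ndarray        # values of the successful splits
    value: float
    alpha: float | None = None
    delta1: float | None = None
    n_failed_splits: int = 0


# ---------------------------------------------------------------------------
# Shared split-score engine
# ---------------------------------------------------------------------------

Scorer = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def _subset_matrix(X: np.ndarray, subset) -> np.ndarray:
    cols = np.atleast_1d(np.asarray(subset, dtype=int))
    if cols.size not in (1, 2):
        raise ValueError("feature subsets of size 1 or 2 are supported")
    sub = X[:, cols]
    return sub[:, 0] if cols.size == 1 else sub


def split_scores(sample: TwoClassSample, subset, plan: SplitPlan,
                 kde_options: KDEOptions | None = None,
                 scorer: Scorer | None = None) -> list[dict]:
    """Per-split left-out scores for one feature subset.

    For each split b, fits the scoring function on the train-scoring halves
    (the kernel density ratio by default; ``scorer`` may inject any other
    scoring-type method) and scores both left-out halves.  Bandwidths are
    re-fitted per split.  Splits whose training half is degenerate (e.g.
    all-identical values) are recorded as failures and skipped.

    Returns a list of dicts with keys ``scores_lo0``, ``scores_lo1`` (or
    ``failed``).
    """
    if plan.m != sample.m or plan.n != sample.n:
        raise ValueError("split plan does not match the sample sizes")
    kde_options = kde_options or KDEOptions()
    x0 = _subset_matrix(sample.X0, subset)
    x1 = _subset_matrix(sample.X1, subset)
    out = []
    for b in range(plan.B):
        i_ts0, i_lo0 = np.array(plan.ts0[b]), np.array(plan.lo0[b])
        i_ts1, i_lo1 = np.array(plan.ts1[b]), np.array(plan.lo1[b])
        try:
            if scorer is not None:
                score = scorer(x0[i_ts0], x1[i_ts1])
            else:
                score = fit_score_model(x0[i_ts0], x1[i_ts1], kde_options).score
            out.append({
                "scores_lo0": np.asarray(score(x0[i_lo0]), dtype=float),
                "scores_lo1": np.asarray(score(x1[i_lo1]), dtype=float),
            })
        except DegenerateSampleError as exc:
            logger.warning("split %d failed for subset %s: %s", b, subset, exc)
            out.append({"failed": str(exc)})
    return out


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

def _cc_from_split(scores_lo0, scores_lo1, threshold: float) -> float:
    n_err0 = int(np.sum(scores_lo0 > threshold))       # class-0 labelled 1
    n_err1 = int(np.sum(scores_lo1 <= threshold))      # class-1 labelled 0
    return (n_err0 + n_err1) / (scores_lo0.size + scores_lo1.size)


def npc_from_scores(scores_lo0, scores_lo1, alpha: float, delta1: float) -> float:
    """One split's NPC value from explicit left-out scores.

    Sets the umbrella threshold on the class-0 scores and returns the
    fraction of class-1 scores <= threshold (non-strict, the type II error
    of the strict-">" NP classifier).
    """
    thr = np_threshold(scores_lo0, alpha, delta1)
    scores_lo1 = np.asarray(scores_lo1, dtype=float)
    return float(np.mean(scores_lo1 <= thr.threshold))


def _collect(sample, subset, plan, kde_options, scorer, precomputed):
    if precomputed is not None:
        return precomputed
    return split_scores(sample, subset, plan, kde_options, scorer)


def s_cc(sample: TwoClassSample, subset, plan: SplitPlan,
         kde_options: KDEOptions | None = None, *,
         scorer: Scorer | None = None,
         precomputed_scores: list[dict] | None = None) -> CriterionResult:
    """Sample-level classical criterion for one feature subset.

    Averages, over the B splits, the left-out misclassification fraction of
    the plug-in classifier 1(score > m1/n1).
    """
    subset = tuple(np.atleast_1d(np.asarray(subset, dtype=int)))
    per_split = _collect(sample, subset, plan, kde_options, scorer,
                         precomputed_scores)
    threshold = plan.m1 / plan.n1
    values = [
        _cc_from_split(s["scores_lo0"], s["scores_lo1"], threshold)
        for s in per_split if "failed" not in s
    ]
    n_failed = plan.B - len(values)
    if not values:
        raise CriterionFailure(f"all {plan.B} splits failed for subset {subset}")
    return CriterionResult(subset=subset, criterion="CC",
                           per_split_values=np.asarray(values),
                           value=float(np.mean(values)), n_failed_splits=n_failed)


def s_npc(sample: TwoClassSample, subset, alpha: float, delta1: float,
          plan: SplitPlan, kde_options: KDEOptions | None = None, *,
          scorer: Scorer | None = None,
          precomputed_scores: list[dict] | None = None) -> CriterionResult:
    """Sample-level Neyman-Pearson criterion for one feature subset.

    Per split, the umbrella threshold is set from left-out class-0 scores
    and the fraction of left-out class-1 scores <= threshold is the split's
    type II error estimate; the B values are averaged.
    """
    subset = tuple(np.atleast_1d(np.asarray(subset, dtype=int)))
    if plan.m2 < minimal_m2(alpha, delta1):
        raise NoValidOrderError(plan.m2, alpha, delta1)
    per_split = _collect(sample, subset, plan, kde_options, scorer,
                         precomputed_scores)
    values = [
        npc_from_scores(s["scores_lo0"], s["scores_lo1"], alpha, delta1)
        for s in per_split if "failed" not in s
    ]
    n_failed = plan.B - len(values)
    if not values:
        raise CriterionFailure(f"all {plan.B} splits failed for subset {subset}")
    return CriterionResult(subset=subset, criterion="NPC",
                           per_split_values=np.asarray(values),
                           value=float(np.mean(values)),
                           alpha=alpha, delta1=delta1, n_failed_splits=n_failed)


def rank_subsets(results: Sequence[CriterionResult] | Sequence[float]) -> np.ndarray:
    """Ascending ranks: smallest criterion value gets rank 1; ties averaged."""
    if len(results) == 0:
        raise ValueError("nothing to rank")
    if isinstance(results[0], CriterionResult):
        tags = {(r.criterion, r.alpha) for r in results}
        if len(tags) > 1:
            raise ValueError("cannot rank results from mixed criteria")
        values = np.array([r.value for r in results])
    else:
        values = np.asarray(results, dtype=float)
    return stats.rankdata(values, method="average")
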