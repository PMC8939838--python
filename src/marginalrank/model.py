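"""Model/Results interface for marginal feature ranking.

`MarginalRanking` is constructed from a two-class dataset (matrices or a
labelled DataFrame) and holds the ranking configuration; `fit()` computes
the requested criteria for every feature under one shared split plan and
returns a `RankingResults` carrying per-feature values, per-split spread,
ranks, diagnostics and a `summary()` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .criteria import (CriterionFailure, SplitPlan, TwoClassSample,
                       make_splits, npc_from_scores, rank_subsets,
                       split_scores)
from .evaluation import baseline_criterion, criterion_label, parse_criterion
from .kde import KDEOptions

__all__ = ["MarginalRanking", "RankingResults"]


class MarginalRanking:
    """Marginal feature ranking model for a two-class sample.

    Parameters
    ----------
    sample : TwoClassSample or (X0, X1) pair of matrices
        Class 0 is the error-to-control class under the NP objective.
    criteria : sequence of str
        Criterion specs: ``"cc"``, ``"npc:<alpha>"`` or a baseline name
        (``"pearson"``, ``"dcor"``, ``"ttest"``, ``"wilcoxon"``).
    B : int
        Number of random half/half splits (default 1000, the data-analysis
        setting; simulations conventionally use 11).
    delta1 : float
        Allowed probability that an NP classifier's type I error exceeds
        its alpha (default .05).
    """

    def __init__(self, sample, criteria=("cc", "npc:0.05"), *, B: int = 1000,
                 delta1: float = 0.05, seed: int = 0,
                 kde_options: KDEOptions | None = None):
        if not isinstance(sample, TwoClassSample):
            X0, X1 = sample
            sample = TwoClassSample(X0=X0, X1=X1)
        self.sample = sample
        self.criteria = tuple(criteria)
        self.parsed = tuple(parse_criterion(c) for c in self.criteria)
        if B < 1:
            raise ValueError("B must be >= 1")
        if not (0.0 < delta1 < 1.0):
            raise ValueError("delta1 must lie in (0, 1)")
        self.B = B
        self.delta1 = delta1
        self.seed = seed
        self.kde_options = kde_options or KDEOptions()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str, class0,
                       class1=None, **kwargs) -> "MarginalRanking":
        sample = TwoClassSample.from_dataframe(df, label_col, class0, class1)
        return cls(sample, **kwargs)

    def fit(self) -> "RankingResults":
        sample = self.sample
        plan = make_splits(sample.m, sample.n, self.B, self.seed)
        labels = [criterion_label(k, a) for k, a in self.parsed]
        needs_scores = any(k in ("cc", "npc") for k, _ in self.parsed)
        y = np.concatenate([np.zeros(sample.m, dtype=int),
                            np.ones(sample.n, dtype=int)])
        xfull = np.vstack([sample.X0, sample.X1])

        rows = []
        failures: dict[str, str] = {}
        for j, name in enumerate(sample.feature_names):
            scores = split_scores(sample, (j,), plan, self.kde_options) \
                if needs_scores else None
            for (kind, alpha), label in zip(self.parsed, labels):
                rec = {"feature": name, "criterion": label, "alpha": alpha,
                       "value": np.nan, "spread": np.nan, "n_failed_splits": 0}
                try:
                    if kind == "cc":
                        thr = plan.m1 / plan.n1
                        vals = [(np.sum(s["scores_lo0"] > thr)
                                 + np.sum(s["scores_lo1"] <= thr))
                                / (plan.m2 + plan.n2)
                                for s in scores if "failed" not in s]
                    elif kind == "npc":
                        vals = [npc_from_scores(s["scores_lo0"],
                                                s["scores_lo1"], alpha,
                                                self.delta1)
                                for s in scores if "failed" not in s]
                    else:
                        _, key = baseline_criterion(kind, xfull[:, j], y)
                        vals = [key]
                    if not vals:
                        raise CriterionFailure("all splits failed")
                    rec["value"] = float(np.mean(vals))
                    rec["spread"] = float(np.std(vals)) if len(vals) > 1 else 0.0
                    rec["n_failed_splits"] = plan.B - len(vals) \
                        if kind in ("cc", "npc") else 0
                except (CriterionFailure, ValueError) as exc:
                    failures[f"{name}/{label}"] = str(exc)
                rows.append(rec)
        table = pd.DataFrame(rows)
        # ranks within each criterion; failed features keep NaN rank
        table["rank"] = np.nan
        for label in labels:
            mask = (table["criterion"] == label) & table["value"].notna()
            if mask.any():
                table.loc[mask, "rank"] = rank_subsets(
                    table.loc[mask, "value"].to_numpy())
        return RankingResults(model=self, plan=plan, table=table,
                              failures=failures)


@dataclass
class RankingResults:
    """Fitted ranking: one row per (feature, criterion)."""

    model: MarginalRanking
    plan: SplitPlan
    table: pd.DataFrame
    failures: dict

    @property
    def values(self) -> pd.DataFrame:
        """Features x criteria matrix of averaged criterion values."""
        return self.table.pivot(index="feature", columns="criterion",
                                values="value")

    @property
    def ranks(self) -> pd.DataFrame:
        return self.table.pivot(index="feature", columns="criterion",
                                values="rank")

    def top(self, k: int, criterion: str | None = None) -> list[str]:
        """The k best feature names under one criterion."""
        criterion = criterion or self.table["criterion"].iloc[0]
        sub = self.table[self.table["criterion"] == criterion].dropna(
            subset=["rank"])
        return list(sub.sort_values("rank")["feature"].head(k))

    def summary(self) -> str:
        lines = [
            "Marginal feature ranking",
            "=" * 64,
            f"class 0: m = {self.model.sample.m}   class 1: n = "
            f"{self.model.sample.n}   features: d = {self.model.sample.d}",
            f"splits: B = {self.plan.B} (m1 = {self.plan.m1}, n1 = "
            f"{self.plan.n1})   delta1 = {self.model.delta1}   seed = "
            f"{self.model.seed}",
            "-" * 64,
        ]
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:.4f}".format):
            out = self.table[["feature", "criterion", "value", "spread",
                              "rank", "n_failed_splits"]]
            lines.append(out.to_string(index=False))
        if self.failures:
            lines.append("-" * 64)
            lines.append(f"failed: {len(self.failures)} feature/criterion "
                         "pairs (no rank assigned)")
            for key, msg in list(self.failures.items())[:10]:
                lines.append(f"  {key}: {msg}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["feature", "criterion", "alpha", "value", "rank"]
        self.table[cols].to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        """Everything needed to reproduce this run."""
        return {
            "package": "marginalrank",
            "version": __version__,
            "m": self.model.sample.m,
            "n": self.model.sample.n,
            "d": self.model.sample.d,
            "criteria": list(self.model.criteria),
            "B": self.model.B,
            "delta1": self.model.delta1,
            "seed": self.model.seed,
            "bandwidth_method": self.model.kde_options.bandwidth_method,
            "failures": self.failures,
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)

    def plot(self, criterion: str | None = None, ax=None):
        """Bar plot of criterion values in rank order (requires matplotlib)."""
        import matplotlib.pyplot as plt

        criterion = criterion or self.table["criterion"].iloc[0]
        sub = self.table[self.table["criterion"] == criterion].sort_values("rank")
        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, 0.4 * len(sub)), 3))
        ax.bar(sub["feature"], sub["value"])
        ax.set_ylabel(criterion)
        ax.set_xlabel("feature (rank order)")
        ax.tick_params(axis="x", rotation=90)
        return ax
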