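"""Population-level ranking criteria p-CC and p-NPC for 1-D parametric models.

For a pair of class-conditional densities (p0, p1) with class-1 prior pi1:

* p-CC is the risk of the classical oracle 1(p1/p0 > pi0/pi1):
  pi0 * P0(ratio > C) + pi1 * P1(ratio <= C) with C = pi0/pi1.
* p-NPC(alpha) is the type II error of the level-alpha NP oracle
  1(p1/p0 > C*), where C* solves P0(ratio > C*) = alpha.

Both are computed deterministically: the acceptance region {ratio > C} is
resolved by root-finding on the log density ratio over a grid covering the
effective supports, and class masses come from CDF differences.  Gaussian,
Gaussian-mixture and chi-squared class-conditionals are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["Gaussian", "GaussianMixture", "ChiSquared", "PopulationModel",
           "OracleReport", "oracle_classical", "oracle_np", "oracle_table"]


# ---------------------------------------------------------------------------
# Distribution specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gaussian:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def logpdf(self, x):
        return stats.norm.logpdf(x, self.mu, self.sigma)

    def cdf(self, x):
        return stats.norm.cdf(x, self.mu, self.sigma)

    def ppf(self, q):
        return stats.norm.ppf(q, self.mu, self.sigma)

    def rvs(self, size, rng):
        return rng.normal(self.mu, self.sigma, size)

    lower = -np.inf


@dataclass(frozen=True)
class GaussianMixture:
    components: tuple  # ((weight, mu, sigma), ...)

    def __post_init__(self):
        comps = tuple((float(w), float(m), float(s)) for w, m, s in self.components)
        if not np.isclose(sum(w for w, _, _ in comps), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if any(s <= 0 for _, _, s in comps):
            raise ValueError("component sigmas must be positive")
        object.__setattr__(self, "components", comps)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        parts = [np.log(w) + stats.norm.logpdf(x, m, s)
                 for w, m, s in self.components]
        return np.logaddexp.reduce(parts)

    def cdf(self, x):
        return sum(w * stats.norm.cdf(x, m, s) for w, m, s in self.components)

    def ppf(self, q):
        """Quantile via bracketed root-finding on the mixture CDF."""
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        los = [stats.norm.ppf(qs.min(), m, s) for _, m, s in self.components]
        his = [stats.norm.ppf(qs.max(), m, s) for _, m, s in self.components]
        lo, hi = min(los) - 1.0, max(his) + 1.0
        out = np.array([optimize.brentq(lambda x, qq=qq: self.cdf(x) - qq, lo, hi,
                                        xtol=1e-12) for qq in qs])
        return out[0] if np.isscalar(q) else out

    def rvs(self, size, rng):
        ws = np.array([w for w, _, _ in self.components])
        idx = rng.choice(len(ws), size=size, p=ws)
        mus = np.array([m for _, m, _ in self.components])[idx]
        sds = np.array([s for _, _, s in self.components])[idx]
        return rng.normal(mus, sds)

    lower = -np.inf


@dataclass(frozen=True)
class ChiSquared:
    df: float

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")

    def logpdf(self, x):
        return stats.chi2.logpdf(x, self.df)

    def cdf(self, x):
        return stats.chi2.cdf(x, self.df)

    def ppf(self, q):
        return stats.chi2.ppf(q, self.df)

    def rvs(self, size, rng):
        return rng.chisquare(self.df, size)

    lower = 0.0


@dataclass(frozen=True)
class PopulationModel:
    """1-D class-conditional distributions plus the class-1 prior."""

    dist0: object
    dist1: object
    pi1: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.pi1 < 1.0):
            raise ValueError("pi1 must lie in (0, 1)")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1


@dataclass(frozen=True)
class OracleReport:
    criterion: str                       # "pCC" | "pNPC"
    threshold: float                     # C on the density-ratio scale
    acceptance_region: tuple             # disjoint sorted (lo, hi) intervals
    type1: float
    type2: float
    risk: float | None = None            # pCC only
    alpha: float | None = None           # pNPC only
    flat_ratio: bool = False             # identical class-conditionals


# ---------------------------------------------------------------------------
# Region machinery
# ---------------------------------------------------------------------------

_GRID_SIZE = 4001
_QUANTILE_EPS = 1e-8


def _support_grid(model: PopulationModel) -> np.ndarray:
    lo = min(model.dist0.ppf(_QUANTILE_EPS), model.dist1.ppf(_QUANTILE_EPS))
    hi = max(model.dist0.ppf(1 - _QUANTILE_EPS), model.dist1.ppf(1 - _QUANTILE_EPS))
    bound = max(model.dist0.lower, model.dist1.lower)
    if np.isfinite(bound):
        lo = max(lo, bound + 1e-12)
    return np.linspace(lo, hi, _GRID_SIZE)


def _log_ratio(model: PopulationModel, x):
    return model.dist1.logpdf(x) - model.dist0.logpdf(x)


def _region_above(model: PopulationModel, grid, log_c: float) -> tuple:
    """Disjoint intervals where log p1 - log p0 > log_c, via grid + brentq."""
    f = _log_ratio(model, grid) - log_c
    sign = f > 0
    edges = []
    for i in np.nonzero(sign[:-1] != sign[1:])[0]:
        root = optimize.brentq(lambda x: float(_log_ratio(model, x)) - log_c,
                               grid[i], grid[i + 1], xtol=1e-12)
        edges.append(root)
    # segments between consecutive roots alternate in/out of the region;
    # classify each by the sign at an interior test point
    lo_bound = grid[0] if np.isfinite(max(model.dist0.lower, model.dist1.lower)) \
        else -np.inf
    segs = []
    seg_bounds = [lo_bound] + edges + [np.inf]
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        if np.isfinite(a) and np.isfinite(b):
            test = 0.5 * (a + b)
        elif np.isfinite(a):
            test = max(a + 1.0, grid[-1])
        elif np.isfinite(b):
            test = min(b - 1.0, grid[0])
        else:
            test = grid[len(grid) // 2]
        if float(_log_ratio(model, test)) - log_c > 0:
            segs.append((a, b))
    # merge adjacent segments sharing an endpoint (shouldn't occur, but safe)
    merged = []
    for seg in segs:
        if merged and np.isclose(merged[-1][1], seg[0]):
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(list(seg))
    return tuple((float(a), float(b)) for a, b in merged)


def _mass(dist, intervals) -> float:
    total = 0.0
    for a, b in intervals:
        ca = dist.cdf(a) if np.isfinite(a) else 0.0
        cb = dist.cdf(b) if np.isfinite(b) else 1.0
        total += cb - ca
    return float(min(max(total, 0.0), 1.0))


def _is_flat(model: PopulationModel, grid) -> bool:
    lr = _log_ratio(model, grid)
    return float(np.max(lr) - np.min(lr)) < 1e-10


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def _report(model, grid, log_c, criterion, alpha=None) -> OracleReport:
    region = _region_above(model, grid, log_c)
    t1 = _mass(model.dist0, region)
    t2 = 1.0 - _mass(model.dist1, region)
    risk = model.pi0 * t1 + model.pi1 * t2 if criterion == "pCC" else None
    return OracleReport(criterion=criterion, threshold=float(np.exp(log_c)),
                        acceptance_region=region, type1=t1, type2=t2,
                        risk=risk, alpha=alpha)


def oracle_classical(model: PopulationModel) -> OracleReport:
    """Risk of the classical oracle 1(p1/p0 > pi0/pi1) (p-CC)."""
    grid = _support_grid(model)
    log_c = float(np.log(model.pi0 / model.pi1))
    if _is_flat(model, grid):
        # constant ratio 1: with strict ">", the classifier is identically 0
        # when C >= 1, identically 1 when C < 1
        if log_c <= 0:  # covers C < 1; C == 1 with flat ratio -> region empty
            lab1 = log_c < 0
        else:
            lab1 = False
        t1 = 1.0 if lab1 else 0.0
        t2 = 0.0 if lab1 else 1.0
        return OracleReport(criterion="pCC", threshold=float(np.exp(log_c)),
                            acceptance_region=(), type1=t1, type2=t2,
                            risk=model.pi0 * t1 + model.pi1 * t2, flat_ratio=True)
    return _report(model, grid, log_c, "pCC")


def oracle_np(model: PopulationModel, alpha: float, *,
              tol: float = 5e-4, max_iter: int = 200) -> OracleReport:
    """Type II error of the level-alpha NP oracle (p-NPC).

    Finds C* by monotone bisection on C -> P0(ratio > C), which is
    non-increasing in C, to within ``tol`` on the type I constraint.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    grid = _support_grid(model)
    if _is_flat(model, grid):
        # any region of class-0 mass alpha is optimal; type2 = 1 - alpha
        return OracleReport(criterion="pNPC", threshold=1.0,
                            acceptance_region=(), type1=alpha,
                            type2=1.0 - alpha, alpha=alpha, flat_ratio=True)
    lr = _log_ratio(model, grid)
    lo, hi = float(np.min(lr)) - 1.0, float(np.max(lr)) + 1.0

    def excess(log_c):
        return _mass(model.dist0, _region_above(model, grid, log_c)) - alpha

    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo < -tol or f_hi > tol:
        raise RuntimeError(
            f"bisection bracket failed: P0 at bounds = "
            f"{f_lo + alpha:.3g}, {f_hi + alpha:.3g}, alpha={alpha}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = excess(mid)
        if abs(f_mid) <= 0.2 * tol or (hi - lo) < 1e-13:
            break
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    else:
        f_mid = excess(0.5 * (lo + hi))
        if abs(f_mid) > tol:
            raise RuntimeError(
                f"NP oracle bisection did not reach |P0 - alpha| <= {tol}: "
                f"residual {f_mid:.3g}")
        mid = 0.5 * (lo + hi)
    return _report(model, grid, mid, "pNPC", alpha=alpha)


def oracle_table(model: PopulationModel, alphas=()) -> pd.Series:
    """p-CC plus p-NPC at each alpha for one model, as a labelled Series."""
    out = {"p-CC": oracle_classical(model).risk}
    for a in alphas:
        out[f"p-NPC({a:g})"] = oracle_np(model, a).type2
    return pd.Series(out)
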