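"""Synthetic two-class generators for the benchmark study designs.

Seven named designs are provided:

* ``TOY`` -- two Gaussian features (d = 2) whose population ranking differs
  between the classical objective and the NP objective at small alpha:
  feature 1 is N(-5, 2^2) vs N(0, 2^2), feature 2 is N(-5, 2^2) vs
  N(1.5, 3.5^2), equal class priors.
* ``S1`` -- two-class Gaussian, d = 30, first s = 10 features informative
  with class-1 means (1, .9, ..., .1) against class-0 means -1.5; the
  remaining 20 features share fixed N(0,1)-drawn nuisance means in both
  classes; covariance 4*I.
* ``S2`` -- independent chi-squared margins, d = 30: class 1 has df
  11, 10, ..., 2 on the first 10 features, df 1 elsewhere and in class 0.
* ``S3`` -- S1's Gaussian design with sampling bias (class 1 drawn with
  probability .1 in the sample although its population proportion is .5),
  optionally with Toeplitz feature correlation rho_ij = .9^|i-j| (x4).
* ``S4`` -- S1 scaled to d = 500; ``S5`` -- d = 10,000 with class-0
  informative means -2.5.
* ``S6`` -- d = 2: feature 1 N(0,1) vs N(1,1); feature 2 N(0,1) vs the
  symmetric mixture .5 N(-2,1) + .5 N(2,1).

Nuisance means are drawn once from a dedicated seed and held fixed across
replicates, so every replicate of a study sees the same noise-feature
population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .criteria import TwoClassSample
from .oracles import ChiSquared, Gaussian, GaussianMixture, PopulationModel

__all__ = ["StudySpec", "study_spec", "nuisance_means", "toeplitz_cov",
           "sample_study", "population_models", "STUDY_IDS"]

STUDY_IDS = ("TOY", "S1", "S2", "S3", "S4", "S5", "S6")

_DEFAULT_NUISANCE_SEED = 20210531  # fixed so "drawn once, held fixed" holds


@dataclass(frozen=True)
class StudySpec:
    """Parameters of one simulation design."""

    study_id: str
    d: int
    s: int                       # number of informative features
    N: int                       # default total sample size
    pi1_population: float = 0.5
    pi1_sample: float = 0.5
    covariance: str = "diagonal"     # "diagonal" | "toeplitz"
    rho: float = 0.9                 # Toeplitz correlation base
    sigma2: float = 4.0              # Gaussian marginal variance
    mu0_informative: float = -1.5
    nuisance_seed: int = _DEFAULT_NUISANCE_SEED

    def __post_init__(self):
        if self.s > self.d:
            raise ValueError("informative count s cannot exceed d")
        for p in (self.pi1_population, self.pi1_sample):
            if not (0.0 < p < 1.0):
                raise ValueError("class-1 proportions must lie in (0, 1)")


def study_spec(study_id: str, **overrides) -> StudySpec:
    """The named design with its default parameters; fields may be overridden."""
    study_id = study_id.upper()
    base = {
        "TOY": StudySpec("TOY", d=2, s=2, N=2000),
        "S1": StudySpec("S1", d=30, s=10, N=1000),
        "S2": StudySpec("S2", d=30, s=10, N=1000),
        "S3": StudySpec("S3", d=30, s=10, N=1000, pi1_sample=0.1),
        "S4": StudySpec("S4", d=500, s=10, N=400),
        "S5": StudySpec("S5", d=10_000, s=10, N=200, mu0_informative=-2.5),
        "S6": StudySpec("S6", d=2, s=2, N=400),
    }
    if study_id not in base:
        raise ValueError(f"unknown study id {study_id!r}; one of {STUDY_IDS}")
    return replace(base[study_id], **overrides) if overrides else base[study_id]


@lru_cache(maxsize=64)
def nuisance_means(d: int, s: int, seed: int = _DEFAULT_NUISANCE_SEED) -> np.ndarray:
    """The d - s fixed nuisance means, N(0,1) draws from a dedicated seed."""
    if d <= s:
        raise ValueError("d must exceed s")
    out = np.random.default_rng(seed).standard_normal(d - s)
    out.setflags(write=False)
    return out


def toeplitz_cov(d: int, rho: float, sigma2: float) -> np.ndarray:
    """AR(1)-type covariance: entry (i, j) = sigma2 * rho^|i-j|."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    idx = np.arange(d)
    return sigma2 * rho ** np.abs(idx[:, None] - idx[None, :])


def _gaussian_means(spec: StudySpec):
    nm = nuisance_means(spec.d, spec.s, spec.nuisance_seed)
    mu0 = np.concatenate([np.full(spec.s, spec.mu0_informative), nm])
    mu1 = np.concatenate([np.round(np.arange(spec.s, 0, -1) * 0.1, 10), nm])
    return mu0, mu1


def _draw_gaussian(spec: StudySpec, mu0, mu1, y, rng):
    N = y.size
    sd = np.sqrt(spec.sigma2)
    if spec.covariance == "toeplitz":
        cov = toeplitz_cov(spec.d, spec.rho, spec.sigma2)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((N, spec.d)) @ chol.T
    elif spec.covariance == "diagonal":
        z = rng.standard_normal((N, spec.d)) * sd
    else:
        raise ValueError(f"unknown covariance {spec.covariance!r}")
    means = np.where(y[:, None] == 1, mu1[None, :], mu0[None, :])
    return z + means


def _draw_chisq(spec: StudySpec, y, rng):
    # class 0: df 1 everywhere; class 1: df 12 - j on features j = 1..s
    df = np.ones((y.size, spec.d))
    df1 = np.ones(spec.d)
    df1[:spec.s] = np.arange(spec.s + 1, 1, -1)   # 11, 10, ..., 2 for s = 10
    df[y == 1] = df1
    return rng.chisquare(df)


def _draw_s6(spec: StudySpec, y, rng):
    X = rng.standard_normal((y.size, 2))
    is1 = y == 1
    X[is1, 0] += 1.0
    signs = rng.choice([-2.0, 2.0], size=int(is1.sum()))
    X[is1, 1] += signs
    return X


def _draw_toy(spec: StudySpec, y, rng):
    X = np.empty((y.size, 2))
    is1 = y == 1
    n1, n0 = int(is1.sum()), int((~is1).sum())
    X[~is1, 0] = rng.normal(-5.0, 2.0, n0)
    X[~is1, 1] = rng.normal(-5.0, 2.0, n0)
    X[is1, 0] = rng.normal(0.0, 2.0, n1)
    X[is1, 1] = rng.normal(1.5, 3.5, n1)
    return X


def sample_study(spec: StudySpec, N: int | None = None, seed: int = 0, *,
                 fixed_counts: bool = False) -> TwoClassSample:
    """Draw one replicate of the named design as a `TwoClassSample`.

    Labels are Bernoulli(pi1_sample) by default, so per-replicate class
    counts vary; ``fixed_counts=True`` instead fixes the class-1 count to
    round(N * pi1_sample) for exact-size experiments.  Fully reproducible
    from (spec, N, seed).
    """
    N = spec.N if N is None else int(N)
    rng = np.random.default_rng(seed)
    if fixed_counts:
        n1 = int(round(N * spec.pi1_sample))
        y = np.zeros(N, dtype=int)
        y[rng.permutation(N)[:n1]] = 1
    else:
        y = (rng.random(N) < spec.pi1_sample).astype(int)
    if y.sum() < 4 or (N - y.sum()) < 4:
        raise ValueError(
            f"replicate drew fewer than 4 observations in one class "
            f"(N={N}, pi1_sample={spec.pi1_sample}); increase N or use "
            f"fixed_counts=True")
    sid = spec.study_id
    if sid == "TOY":
        X = _draw_toy(spec, y, rng)
    elif sid in ("S1", "S3", "S4", "S5"):
        mu0, mu1 = _gaussian_means(spec)
        X = _draw_gaussian(spec, mu0, mu1, y, rng)
    elif sid == "S2":
        X = _draw_chisq(spec, y, rng)
    elif sid == "S6":
        X = _draw_s6(spec, y, rng)
    else:
        raise ValueError(f"unknown study id {sid!r}")
    names = tuple(f"x{j + 1}" for j in range(spec.d))
    return TwoClassSample(X0=X[y == 0], X1=X[y == 1], feature_names=names)


def population_models(study_id: str) -> tuple[PopulationModel, ...]:
    """Exact per-feature population models, where the design admits them.

    Available for the two 2-feature designs (TOY and S6); used to compute
    population criteria against which the sample-level rankings are judged.
    """
    study_id = study_id.upper()
    if study_id == "TOY":
        return (PopulationModel(Gaussian(-5, 2), Gaussian(0, 2), 0.5),
                PopulationModel(Gaussian(-5, 2), Gaussian(1.5, 3.5), 0.5))
    if study_id == "S6":
        return (PopulationModel(Gaussian(0, 1), Gaussian(1, 1), 0.5),
                PopulationModel(Gaussian(0, 1),
                                GaussianMixture(((0.5, -2, 1), (0.5, 2, 1))),
                                0.5))
    if study_id == "S2":
        spec = study_spec("S2")
        dfs1 = [spec.s + 1 - j for j in range(spec.s)] + [1] * (spec.d - spec.s)
        return tuple(PopulationModel(ChiSquared(1), ChiSquared(df), 0.5)
                     for df in dfs1)
    raise ValueError(
        f"population models are defined for TOY, S6 and S2, not {study_id!r}")
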