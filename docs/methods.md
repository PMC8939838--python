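# Methods

## The ranking criteria

Let (X, Y) be a feature vector and binary label, π₁ = P(Y=1), and let
p₀A, p₁A be the class-conditional densities of the sub-vector X_A for a
candidate feature set A (|A| = 1 in all standard uses; |A| = 2 is supported
through a product kernel). Two population criteria order candidate sets,
smaller = better:

* **p-CC(A)** — the risk of the classical oracle
  `φ*_A = 1(p₁A/p₀A > π₀/π₁)`:  `π₀·P₀(ratio > C) + π₁·P₁(ratio ≤ C)`.
* **p-NPC(α, A)** — the type II error of the level-α NP oracle
  `1(p₁A/p₀A > C*_α)` where C*_α satisfies `P₀(ratio > C*_α) = α`.

The two objectives can genuinely disagree: in the built-in `TOY` design
(feature 1: N(−5,2²) vs N(0,2²); feature 2: N(−5,2²) vs N(1.5,3.5²), equal
priors) p-CC prefers feature 1 (.106 vs .113) and so does p-NPC at α=.20
(.049 vs .084), but p-NPC at α=.01 prefers feature 2 (.299 vs .431),
because the tight type-I budget favours the class-1 density with the
heavier right tail.

### Sample-level estimates

Given m class-0 and n class-1 observations, each class is randomly halved
B times (m₁ = ⌊m/2⌋ train-scoring, m₂ left out; likewise n₁/n₂). Per split:

* the scoring function is the KDE ratio `ŝ = p̂₁/p̂₀` fitted on the
  train-scoring halves;
* **s-CC** classifies left-out points with threshold m₁/n₁ (the empirical
  stand-in for π₀/π₁) and records the misclassification fraction
  (class-0 errors + class-1 errors over m₂ + n₂);
* **s-NPC** scores the left-out class-0 points, sets the threshold at
  their k*-th order statistic (umbrella rule below) and records the
  fraction of left-out class-1 scores ≤ threshold.

The B values are averaged. One split plan is shared by **all** features and
**all** criteria in a run — the literature is not explicit on this point,
but sharing makes rankings compare like with like and removes split noise
from between-feature contrasts. Bandwidths are re-fitted per split
(statistically cleaner than freezing them across splits, since each
train-scoring half is a different sample).

### The NP umbrella rule

For m₂ left-out class-0 scores, level α and violation rate δ₁, the
threshold order is

    k* = min{ k : Σ_{j=k}^{m₂} C(m₂,j)(1−α)^j α^{m₂−j} ≤ δ₁ },

which guarantees P(type I error > α) ≤ δ₁ for *any* scoring function. A
finite k* exists iff (1−α)^{m₂} ≤ δ₁; otherwise an error reports the
minimal feasible m₂. The binomial tail is evaluated through scipy's
binomial survival function (regularised incomplete beta), stable for m₂ in
the thousands; a brute-force exact-arithmetic oracle cross-checks every
(m₂ ≤ 60, α, δ₁) combination in the tests. k* is 1-based, matching
order-statistic notation.

Conventions kept exactly as the estimators define them: classification
uses strict `score > threshold`; the s-NPC type-II count uses non-strict
`score ≤ threshold`. Score ties (possible in floating point even though
the score distribution is assumed continuous) therefore resolve toward
label 0.

## Kernel density estimation

Gaussian kernel, `p̂(x) = (n h)⁻¹ Σ K((xᵢ−x)/h)`. The default bandwidth is
a univariate **two-stage direct plug-in** (Wand–Jones style): ψ₈ from a
normal reference on scale min(sd, IQR/1.349), kernel functional estimates
of ψ₆ and ψ₄ at the corresponding pilot bandwidths, then
`h = (R(K)/(ψ̂₄ n))^{1/5}`. On N(0,1) samples it reproduces the
AMISE-optimal `(4/3n)^{1/5}` to within ~1%. Above n = 1500 the ψ
functionals are computed from linearly binned data (512 bins; the pair
sums reduce to an autocorrelation of bin counts), the standard device for
plug-in selection at large n — it changes the selected bandwidth by well
under 0.1%. Silverman's rule is available as `method="silverman"`. No exact numeric parity with any other
implementation of plug-in selection is claimed; ranking results are
insensitive at this level. Higher-order (β-valid) kernels that appear in
the consistency theory are not implemented — the Gaussian kernel is the
practical choice throughout.

Numerical choices:

* the density-ratio denominator is floored at 1e-300 (configurable) so
  scores stay finite and strict-">" thresholding is well defined;
* kernel contributions with |u| > 38 are skipped — φ(u) underflows to
  exactly 0 there in double precision, so this is a pure speed-up;
* a train-scoring half with zero spread (constant feature) raises a
  degenerate-sample error; the criteria skip such splits with a logged
  warning and record the count (`n_failed_splits`); a feature whose every
  split fails gets a failure instead of a rank.

## Population oracles

The acceptance region {x : p₁(x)/p₀(x) > C} is found by evaluating the
log-ratio on a 4001-point grid spanning both classes' 1e-8…1−1e-8
quantiles, refining each sign change with Brent root-finding; class masses
are CDF differences over the resulting disjoint intervals. This uniformly
handles Gaussian pairs (quadratic or linear log-ratio), Gaussian mixtures
(multi-interval regions) and chi-squared pairs (bounded support). For
p-NPC, C*_α comes from monotone bisection on C ↦ P₀(ratio > C), with the
type-I constraint met to ≤ 5e-4. Identical class-conditionals (flat ratio)
are handled by convention, not error: the classical oracle outputs 0
everywhere (risk π₁·1 if C ≥ 1), and the NP oracle reports
type2 = 1 − α with a `flat_ratio` flag. Monte-Carlo cross-checks at 10⁶
draws agree with the quadrature within sampling error (tested).
Quadrature is the primary engine because it is deterministic and fast;
Monte Carlo is kept only as an independent check.

## Synthetic designs

The built-in study specs cover the standard benchmark settings:
low-dimensional Gaussian (S1: d=30, s=10 informative, class-1 means
1,.9,…,.1 vs class-0 −1.5, Σ=4I), chi-squared margins (S2: class-1 dfs
11…2 on the informative features, df 1 elsewhere), Gaussian with sampling
bias (S3: class 1 drawn with probability .1 though its population share is
.5, optional Toeplitz correlation .9^|i−j|×4), high-dimensional (S4:
d=500, N=400; S5: d=10,000, N=200, class-0 informative means −2.5), and
the normal-vs-mixture pair (S6) where only prediction-objective criteria
get the order right. Nuisance means are N(0,1) draws from a dedicated
seed, cached so every replicate of a study shares them ("drawn once and
held fixed"). Labels are Bernoulli(π₁_sample) per observation — the
designs state class *probabilities*, not counts — with a `fixed_counts`
flag for exact-size experiments.

What the generators do **not** emulate: heavy-tailed or zero-inflated
marginals of real omics data, feature-block correlation structures beyond
AR(1), batch effects, missingness. Passing the simulation suite shows the
estimators track their population targets under the stated models; it does
not certify behaviour on any particular real dataset.

## Baselines and evaluation

Pearson correlation (|r|, larger = better), distance correlation (biased
V-statistic, double-centering; the unbiased variant is not used), and
two-sided two-sample t / Wilcoxon rank-sum tests (smaller p = better).
Ranking keys are oriented so that "smaller = better" uniformly, matching
the criteria. Ties in criterion values receive average ranks; a feature
counts as "top" only when it is the unique rank-1 holder. The Kuncheva
index `(|A_k ∩ B_k| − k²/d)/(k − k²/d)` quantifies chance-corrected
overlap of top-k sets; k = d is rejected (zero denominator).

## Defaults and problem sizes

* B = 11 splits for simulation studies, B = 1000 for data analysis
  (the Model-layer default), δ₁ = .05 — the conventional settings for
  these estimators.
* The replicated-study checks in the test-suite and acceptance script use
  300 toy replicates (N = 2000) and 200 mixture replicates (N = 400),
  with tolerances widened to three binomial standard errors at those
  replicate counts; the concentration check uses N = 20,000 at 3 seeds,
  and the informative-vs-noise separation check 100 replicates at
  N = 1000. These sizes make the whole suite desk-scale while keeping
  every check's expected outcome unambiguous.
* The type-I-control check exploits that, with N(0,1) calibration scores
  and the identity scoring function, each replicate's true type I error is
  exactly the normal survival function at its threshold — no evaluation
  sample needed.

## Known limitations

* Only |A| ≤ 2 feature subsets; no joint multivariate ranking, no
  cost-sensitive or AUROC/AUPRC criteria.
* Oracles cover the three parametric families used by the built-in
  designs, not arbitrary user densities.
* s-NPC needs m₂ ≥ log δ₁ / log(1−α) left-out class-0 observations
  (59 at α = δ₁ = .05); small class-0 samples force larger α or δ₁.
* KDE-based scoring inherits the usual univariate KDE caveats (boundary
  bias for supported-on-half-line features; bandwidth sensitivity for
  multimodal densities at small n).
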