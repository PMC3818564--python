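# Methods

`phylotraits` implements the statistical core of a phylogenetic comparative
study of trait evolution: assembling a usable ultrametric phylogeny from
heterogeneous sources, quantifying phylogenetic signal in continuous and
binary traits, and regressing morphology on ecology while accounting for
shared ancestry. This note records the models, their assumptions, the
defaults, and the numerical choices; it also states what the synthetic-data
generator does and does not emulate.

## Tree assembly

Composite phylogenies are built from a backbone tree plus published
intrageneric trees using three explicit rules:

* **Sibling insertion** (`attach_sibling_halfway`): when a genus contributes
  exactly two study species and only one is on the backbone, the second is
  attached as a sibling with the branching point halfway along the existing
  pendant edge. Both siblings get pendant length `b/2`, so ultrametricity
  and all other depths are preserved.
* **Rescaled grafting** (`graft_rescaled`): an intrageneric tree sharing a
  reference species with the backbone is rescaled by
  `s = d_back / d_sub` (backbone pendant length over subtree root-to-
  reference distance) and substituted for the pendant edge, rooted at the
  attachment node. The reference tip keeps its backbone depth exactly (one
  multiply/divide of rounding). The operation refuses subtrees without
  branch lengths: sources with topology only must first pass through
  `set_equal_branch_lengths`, which makes the "all branches equal" fallback
  an explicit, auditable step rather than an implicit default.
* **Pruning** (`prune_to`) suppresses unbranched internal nodes with their
  lengths summed, so retained tips keep their root-to-tip depths. The root
  is never suppressed.

## Penalized-likelihood ultrametricization

`ultrametricize_pl` converts a tree whose branch lengths are expected
substitution counts `x_k` into a relative-time chronogram. Node ages `a`
(root fixed at 1, tips at 0) and per-edge rates `r_k > 0` maximize

```
sum_k [ x_k ln(r_k t_k) - r_k t_k ]  -  lambda_s * Phi(r)
```

with `t_k = a(parent) - a(child)` and the roughness penalty
`Phi = sum_{non-root-parent edges} (r_k - r_parent(k))^2 + Var(root daughter rates)`.
The first term is the Poisson-type branch likelihood; the penalty shrinks
rate changes between adjacent edges.

Numerical choices:

* Ages are parameterized as logistic fractions of the parent age in
  preorder, so `1 = a_root > a_internal > a_tip = 0` holds by construction
  and the optimization is unconstrained; rates live on the log scale.
* The objective has an analytic gradient (reverse accumulation through the
  age chain), unit-tested against central finite differences.
* Optimizer: L-BFGS-B, multi-start (default 3; the first start is a
  clock-like initialization with ages proportional to remaining path
  length and a single global rate, further starts are Gaussian
  perturbations of it). The returned solution is never worse than the
  initialization.
* Zero-length edges are replaced by `1e-8 ×` tree height; polytomies are
  resolved by zero-length left-grouping (with a logged warning) — neutral
  for path lengths.
* The smoothing weight defaults to 10 and is exposed as a parameter;
  cross-validated selection of the weight is out of scope. On clock-like
  input the penalty vanishes at the truth and the true relative ages are
  recovered to numerical precision; under lognormal rate noise (sd 0.3 on
  the log scale) estimated internal-node ages correlate with truth at
  r ≥ 0.9 on 40-tip trees (tested).

Because the root age is fixed at 1, chronogram scale is arbitrary; the
downstream statistics (lambda, D, PGLS) are invariant to a global rescaling
of the covariance matrix (tested), so no absolute calibration is needed.

## Phylogenetic signal

**Continuous traits — Pagel's lambda.** The Brownian expectation for the
tip covariance is `sigma2 * V`, where `V(i, j)` is the shared root-to-MRCA
path length. Lambda multiplies the off-diagonal of `V`; the ML value in
[0, 1] is found by profiling the GLS likelihood (intercept-only design)
over lambda with a 101-point grid pre-scan followed by bounded Brent
refinement, ties broken toward 0. Significance against lambda = 0 uses a
likelihood-ratio test on the upper tail of chi-square with 1 df; because 0
is on the boundary of the parameter space this is conservative by roughly
a factor of two relative to the 50:50 boundary mixture, matching common
practice in the comparative-methods toolchain. Estimates are capped at 1;
a fitted value printed as 1 means the box constraint is active.

**Binary traits — the D statistic.** For a binary character, nodal values
are estimated bottom-up as unweighted means of the two daughter values and
`d_obs` is the sum over internal nodes of the absolute daughter
difference; branch lengths deliberately do not enter this sum (they enter
only the Brownian null). D scales `d_obs` between the means of two
simulated nulls that both preserve the observed number of state-1 tips:

* random null — a uniform shuffle of states across tips (`D = 1` regime);
* Brownian-threshold null — a Brownian liability thresholded so the top
  `n_ones` tips are state 1 (`D = 0` regime).

`D = (d_obs - mean_brownian) / (mean_random - mean_brownian)`. Values
below 0 mean the trait is more clumped than the Brownian expectation;
values above 1 more overdispersed than random. Defaults: 1000 simulations
per null; p-values are raw tail proportions (no +1 correction):
`p_random = P(d_null_random <= d_obs)` tests departure from D = 1,
`p_brownian = P(d_null_brownian >= d_obs)` departure from D = 0. Both
nulls are vectorized across replicates, so full-scale use is cheap.

## PGLS regression and model selection

`fit_pgls` fits `y = X beta + e`, `e ~ N(0, sigma2 * V(lambda))`, with
lambda either fixed or ML-estimated jointly with the coefficients (same
grid + Brent profiling as the signal module, for determinism). Estimators:

* `beta_hat = (X' V^-1 X)^-1 X' V^-1 y`; `sigma2_hat = e' V^-1 e / n` (ML);
* standard errors from `sigma2_hat * n/(n - p) * (X' V^-1 X)^-1` — the
  unbiased-variance scaling mirrors common GLS reporting and affects only
  the standard errors, never the likelihood, AIC or evidence ratios;
* `R^2 = 1 - (e' V^-1 e) / (e0' V^-1 e0)` against an intercept-only GLS
  fit under the *model's own* lambda, making it a pure association
  measure (the alternative — the null's own lambda — would mix signal and
  association);
* `AIC = 2k - 2 lnL` with `k` = number of coefficients + 1 (sigma2) + 1 if
  lambda is estimated. The parameter-count convention is stated
  prominently because only AIC differences within a battery matter for
  evidence ratios, and both model and null estimate lambda, so the
  convention cancels there;
* evidence ratio `ER = exp((AIC_null - AIC_model)/2)`, recomputed from
  full-precision AICs (published tables that used unrounded AICs can
  disagree in the last digit with arithmetic on their printed values).

Categorical predictors enter as 0/1 codes without standardization so
coefficients stay in response units per predictor unit. Response-scale
residuals (`y - X beta_hat`) from the allometric fit of log antennal area
on log body length define "residual antennal size", whose phylogenetic
signal is reported as its own row in the signal battery.

With lambda fixed at 1 on an ultrametric tree, PGLS reproduces the
through-origin regression of phylogenetically independent contrasts
(tested to 1e-6 against a contrasts implementation); on a star tree it
reduces to OLS (tested to 1e-10).

## Parsimony origin counts

`count_origins_fitch` returns the Fitch parsimony length of a binary
character (standard union/intersection bottom-up pass; an ambiguous root
set adds no change), equal to the minimum number of origins-plus-losses.
Polytomies are resolved by zero-length left-grouping, which cannot
decrease the count. Verified against exhaustive minimization over all
internal assignments on trees of up to 8 tips.

## Synthetic-data generator

`synthetic_study` emulates the *structure* of a parasitoid-wasp
morphology/ecology table on a simulated phylogeny; it makes no attempt to
match real clade values. Components and defaults:

* Tree: pure-birth (Yule), 126 species, birth rate 1 (relative time).
* Log body length: Brownian, `sigma2 = 0.25` per unit time on the log-mm
  scale, root 0.4 (≈ a 1.5 mm wasp) — spans roughly the 0.2–20 mm range of
  small parasitoids over a unit-height tree.
* Log antennal area: `-2.0 + 1.7 × log body length` plus a
  lambda-structured residual (lambda 0.5, variance 0.02). The slope
  default is the negatively allometric value reported for this kind of
  data; simulations for the isometry-recovery experiment override it to 2.
* Host-species counts: lognormal latent (log-mean 1.0, log-sd 1.2) rounded
  up to ≥ 1 — strongly right-skewed, as such counts are in host-use
  databases. These parameters are configuration, not estimates.
* Host-order counts grow noisily with host-species counts (Poisson with
  rate `0.35 ln(1 + hosts)`, plus 1, capped at 6); plant-genus counts are
  independent right-skewed counts that may be 0.
* Binary flags: each drawn at a configured prevalence, either
  Brownian-threshold ("clumped") or uniform-random. Defaults clump all
  host-use flags (prevalences approximating published group sizes, e.g.
  0.16 egg parasitoids, 0.07 non-sternorrhynchan-Hemiptera parasitoids);
  the Hemiptera flag is the union of its two suborder flags; the
  specialist flag is *derived* from the counts by the coding rule (fewer
  than 10 host species, all in one order, parasitoids only) and is
  therefore effectively unclumped.

Everything is bit-reproducible from a single integer seed via spawned
generator streams.

What passing tests on this generator show — and what they do not: they
validate the estimators under their own generating assumptions
(multivariate-normal traits, exactly binary characters, complete data, a
correct tree). Real data add measurement error in the morphometrics,
phylogenetic uncertainty, database artifacts in host counts, and model
misspecification; none of those are emulated, so recovery here is a
correctness check, not a field-performance claim.

## Problem sizes and determinism

The recovery experiments (`phylotraits.recovery`) run 200 replicates on
128-tip trees for lambda and D (1000 simulations per D null) and 126-tip
trees for the slope — sizes at which the estimators are effectively
unbiased and a few seconds to a half-minute of compute suffice. All
randomness flows from explicit integer seeds; sub-seeds are spawned from
a master seed and kept below 2^31.

## Known limitations

* No Ornstein–Uhlenbeck or Blomberg's K signal models; no multi-state D;
  no phylogenetic logistic regression for binary responses.
* The lambda LR test's chi-square reference is conservative at the
  boundary (documented above).
* Penalized-likelihood smoothing uses a fixed weight; no cross-validation.
* Missing data are handled per-analysis by complete-case dropping with
  logged counts; no imputation.
* `R^2` can be negative for badly misspecified models (it is reported as
  computed).
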