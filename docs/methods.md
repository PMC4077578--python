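# Methods

## Model

### Component distributions

Each cell population is one component of a finite mixture. Two families
are supported.

**Multivariate t.** Location `mu`, symmetric positive-definite scale
`Sigma`, degrees of freedom `nu > 0`. Small `nu` downweights outlying
events (debris, doublets, acquisition artifacts); `nu` is estimated by
maximum likelihood per component and capped at 400, at which point the
component is effectively Gaussian.

**Unrestricted (Sahu-form) skew t.** Built from the latent representation
`y = mu + Delta |u0| + u1` with `w ~ Gamma(nu/2, nu/2)`,
`(u0, u1) | w ~ N(0, blockdiag(I, Sigma)/w)` and `Delta = diag(delta)`.
Its density is

```
f(y) = 2^p t_p(y; mu, Omega, nu) T_p(q(y) s(y); 0, Lambda, nu + p),
Omega  = Sigma + Delta^2
q(y)   = Delta Omega^{-1} (y - mu)
s(y)   = sqrt((nu + p) / (nu + d_Omega(y)))
Lambda = I - Delta Omega^{-1} Delta,
```

with `d_Omega` the squared Mahalanobis distance under `Omega`. The skew
matrix is diagonal, which matches the marker-wise asymmetry seen in
fluorescence data (tail subpopulations attached to a main population
along particular markers) and keeps every 1-D marginal an exact
univariate skew t — the overlay-plot module relies on this.

The implementation of the density was validated two ways before any
fitting code depended on it: numerical normalization (1-D quadrature to
1e-6; 2-D grid quadrature to ~1e-3) and agreement with histograms of
samples drawn through the latent construction.

### The multivariate t distribution function

`T_p` appears per cell inside the skew-t density, so it must be fast,
vectorized and deterministic.

- p = 1: `scipy.stats.t.cdf` (exact).
- p = 2: exact bivariate normal CDF via Owen's T function combined with
  fixed-node Gauss–Legendre quadrature (48 nodes by default) over the
  gamma mixing variable. Deterministic, vectorized over evaluation
  points, and within ~1e-5 of scipy's randomized-QMC evaluation (which is
  itself accurate to about that level).
- 3 <= p <= 20: scipy's randomized quasi-Monte-Carlo evaluation, seeded
  from the caller's seed; a handful of independent randomizations provide
  the standard-error estimate. This path is accurate but slow per point,
  so skew-t *fitting* is practical at p <= 2 while density evaluation
  remains available at higher p.

### Two-level batch model

A batch (class) of m samples shares a g-component template. Conditional
on membership of population h, the measurement of variable i for cell j
of sample k is

```
y_ijk = a_hik mu_hi + b_hik + e_hijk,
a_hik ~ N(1, sigma_a^2),   b_hik ~ N(0, sigma_b^2),
```

independently over populations, variables and samples; the error term
follows the component's residual distribution. Scale, skewness and
degrees of freedom are template-level: only component means and mixing
proportions vary per sample. Mixing proportions `pi_k` are free per
sample; the template proportion is their cell-count-weighted mean. Label
h therefore denotes the same population in every sample (registration by
construction), and the file convention for registered labels is 1..g with
0 reserved for outlier/unassigned cells (an optional posterior floor of
1/(2g), off by default).

**Identifiability of (a, b).** For fixed (h, i, k) the pair acts through
the single scalar `a mu + b`, so the two effects are separated only by
their priors; they are estimated by MAP (a closed-form 2x2 ridge solve),
not maximum likelihood. Consequences: the combined mean shift is well
identified, but the a/b split is prior-dominated, and when scaling noise
acts on large mean magnitudes part of it is absorbed into `b`, inflating
the `sigma_b^2` estimate. A `translation_only` option pins `a = 1`.
Fixing a variance at 0 freezes the corresponding effect entirely.

## Fitting

### Single-sample EM

Initialization is k-means (scikit-learn) on a subsample of at most 20,000
cells: cluster centers, within-cluster covariances (regularized),
fractions, `nu = 30`. For the skew family the initial `delta` comes from
the coordinate-wise within-cluster sample skewness — `delta = 0` is
nearly a fixed point of the updates, so an informative start matters.

**t family:** classical ECM. Responsibilities and gamma weights
`w = (nu+p)/(nu+d)` in the E-step; weighted-moment updates for
proportions, means and scales; `nu` from the standard digamma score
equation solved by bracketed root finding on [0.5, 400].

**Skew-t family:** a safeguarded ECM. The E-step computes
responsibilities exactly and approximates the conditional moments of the
latent skewing vector coordinate-wise (univariate truncated-normal
moments of its exact conditional Gaussian; exact at p = 1) with the
gamma weight taken at its t-family form under `Omega`. These feed
closed-form proposal updates for all parameters. Every proposal is then
passed through a backtracking line search on the *observed-data*
log-likelihood (geometric interpolation toward the current parameters;
convex combination for scale matrices, log-scale for `nu`), so the
recorded trace is non-decreasing by construction regardless of the
quality of the approximation. When the ECM stalls, a conditional
coordinate search polishes each skew entry (moving `mu` along the
mean-preserving ridge `mu -> mu + c_nu * d delta`, where `c_nu` is the
mean of `|t_nu|`) and each `nu`; convergence is declared only when the
polish pass also fails to improve the likelihood by the relative
tolerance.

**Skew-t identifiability.** The likelihood has near-flat ridges trading
`delta` against `nu` and `Sigma`: fits routinely reach the generating
model's log-likelihood while raw `delta` differs substantially. Recovery
is therefore assessed on stable functionals — component means
`mu + c_nu delta`, proportions, and model-level KL divergence — not raw
skew parameters.

Component collapse (occupancy below `min_cluster_fraction * n`, default
0.001) triggers one restart with a fresh k-means seed; a second collapse
fails that start. The best of `n_starts` runs (default 3) by final
log-likelihood is returned. Ties in posterior labels break to the lowest
component index. Defaults: relative tolerance 1e-6, max 500 iterations.

### Order selection

BIC = -2 loglik + d log n with d = (g-1) + gp + gp(p+1)/2 + g for the t
family, plus gp for skew-t; the fit minimizing BIC over the requested
range wins, ties toward smaller g.

### Two-level ECM

1. Template initialized by a single-sample fit on a balanced pooled
   subsample (at most 5,000 cells per sample); transforms at identity.
2. E-step per sample under its transformed template.
3. CM-1: template means by an exact per-component weighted least-squares
   solve across samples (each sample's cells enter through its mean
   transform); pooled scatter for scales; pooled digamma equation for
   `nu`; pooled moment update for `delta`.
4. CM-2: per-sample (a, b) by the closed-form ridge MAP; `pi_k` from
   responsibilities.
5. CM-3: `sigma_a^2`, `sigma_b^2` as mean squared deviations of the
   fitted effects from 1 and 0 (floored at 1e-8), unless fixed.
6. A full-state backtracking safeguard keeps the total observed
   log-likelihood trace non-decreasing (tolerance 1e-6 absolute).

With one sample and both REM variances fixed at zero the model is
mathematically identical to the single-sample mixture, and the
implementation takes exactly that code path, so the reduction holds to
machine precision.

The JCM BIC counts template parameters plus (g-1) proportions per sample
plus the two REM variances; the shrunk random effects are not counted as
free parameters.

`estimate_transform` freezes the template and iterates steps 2 and 4
only; it is the primitive behind classification of new samples
(transform-adjusted per-cell log-likelihood by default — deterministic —
with symmetric Monte-Carlo KL as the alternative; ties break to the
lexicographically smallest class id).

## Evaluation

The misclassification rate is the minimum error fraction over one-to-one
matchings of predicted clusters to reference classes, computed by optimal
assignment on the contingency table (`scipy.optimize.linear_sum_assignment`),
which attains the same optimum as exhaustive permutation search — the
test suite verifies equality on hundreds of random instances. Predicted
label 0 (outlier) always counts as an error; unmatched predicted clusters
count entirely as errors (how published comparisons penalized surplus
clusters is not documented; this rule is ours). The F-measure follows the
flowCAP convention: size-weighted best harmonic mean of precision and
recall per true class. Display rounding of table summaries is half-up to
4 decimals, matching the precision of the published benchmark tables
bundled under `jcmflow/data/`.

## Synthetic batches

The generator draws exactly the model's data-generating process: per
sample and population, `a ~ N(1, sigma_a^2)` truncated to (0, inf)
(truncation negligible for sigma_a <= 0.3), `b ~ N(0, sigma_b^2)`,
proportions from a Dirichlet centered on the template (concentration
infinity = fixed; the Dirichlet jitter is our minimal mechanism for
weight variation across samples), cells from the transformed mixture via
the latent construction. Ground truth (transforms, 1-based component
labels) is always returned. What the generator does **not** emulate:
compensation/spillover error, saturation, debris and doublets,
acquisition drift within a sample, or non-affine population deformation.
Passing tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to every
instrument artifact of real cytometry data.

Default study conditions used by the recovery suite: p = 3 markers, g = 3
populations, separation 4 (minimum inter-mean distance 4*sqrt(p)),
n = 2000 cells per sample, batches of m = 4 or 8, translation SD 0 or
0.3, scaling SD 0.05, 10 seeds. With sigma_b = 0.3 the template mean is
identifiable only up to the batch's mean translation draw (irreducible
standard error sigma_b/sqrt(m), about 0.15 at m = 4 — for any
estimator), so recovery is asserted on seed-averaged errors; per-seed
absolute errors are reported as diagnostics by the acceptance script.
Monotonicity suites use 20 single-sample fits per family (n = 600 for t,
n = 250 for skew-t at p <= 2) and 5 batch fits; these sizes exercise
every code path while keeping the default test run fast.

## Numerical choices

- Mahalanobis distances and log-determinants via Cholesky; a failed
  factorization is retried once with `1e-8 * trace/p` added to the
  diagonal before raising.
- Scale-matrix updates are symmetrized and floored with a relative
  1e-10 diagonal jitter.
- Truncated-normal hazard ratios use `erfcx` for stability deep in the
  left tail.
- Log-sum-exp throughout mixture density evaluation; a cell at which all
  component densities vanish raises with the cell index.
- All randomness flows through `numpy.random.default_rng` from a single
  caller seed; fits, simulations and the CLI are bit-reproducible given
  the seed.

## Known limitations

- REM variances are scalars shared across populations and markers; a
  per-component variance option is not implemented.
- Only component means and proportions vary per sample; no sample-level
  transformation of scale matrices (rotations/shears), and no third
  class-level tier above the batch.
- Skew-t fitting is practical at p <= 2 (the p >= 3 distribution-function
  path is per-point); the t family has no such limit.
- The skew-t E-step moments are approximate (diagonal truncation); the
  safeguard guarantees monotone ascent but steps can be conservative,
  which the polish pass mitigates.
- FCS support covers 3.0/3.1 float list mode only; integer data and
  FCS 2.0 are rejected deliberately.
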