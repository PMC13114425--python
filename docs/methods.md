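# Methods

## The model

The Unit Arcsine–Rayleigh distribution (UASRD) is the law of `Z = exp(−X)`
where `X` has the Arcsine–Rayleigh lifetime distribution with CDF
`(2/π)·arcsin√(1 − e^{−x²/(2ζ²)})` on `(0, ∞)`. The single shape `ζ > 0` is
dimensionless. Small ζ concentrates mass near the upper endpoint (left-skewed
spike near 1); large ζ pushes mass toward 0 with a heavy standardized right
tail. The parameter is identifiable (equal CDFs force equal shapes — the test
suite checks the max CDF gap on a grid), and the quantile function is closed
form, so sampling is plain inverse transform with no rejection.

All expectations are, internally, integrals against the parent lifetime
density `f_X(x) = x e^{−x²/(4ζ²)} / (πζ²√(1 − e^{−x²/(2ζ²)}))`, which is
bounded (`f_X(0+) = √2/(πζ)`) and smooth; quadrature in this scale is robust
for every ζ we exercise (0.03–31), whereas z-scale integrands develop
near-boundary spikes at extreme shapes.

## Series engine

Most closed forms of the family are infinite series over the
central-binomial weight `w_k = C(2k,k)/4^k ~ 1/√(πk)` arising from the
expansion of `(1 − e^{−x²/2ζ²})^{−1/2}`. The terms decay like `k^{−3/2}`
(sometimes with a log factor), so truncation error falls only like
`K^{−1/2}`: four-decimal accuracy by brute force would need ~10^10 terms.
The engine therefore sums an exact vectorised block (default up to 2·10^5
terms, usually far fewer) and closes the tail by an Euler–Maclaurin
correction

```
Σ_{k≥K} g(k) ≈ ∫_K^∞ g + g(K)/2 − g′(K)/12,
```

with the integral mapped to `(0, 1]` by `k = K/u²`. This needs `g` to be
evaluable at real `k`; every internal term function is, through log-gamma
forms. The same device handles the log-modified tail of the Shannon series.
Geometrically decaying series (incomplete moments away from the boundary,
the generating-function identities) terminate early on a tolerance rule;
terms that fail to decay (empirical decay exponent ≤ 1) are flagged
non-convergent rather than extrapolated. Series results carry
`(value, terms_used, converged, tail_estimate)` and every public series is
cross-validated against an adaptive-quadrature oracle to at least 1e−6
relative in the tests (typically 1e−9).

Overflow discipline: wherever a term contains `e^{m²ζ²/(2k+1)}·erfc(·)`, the
scaled complement `erfcx` is used, so the series is overflow-free across the
full shape range. The entropy kernel's confluent-hypergeometric closed form
(`1F1`) grows like `e^x`; its series path is exercised at moderate shapes
(ζ ≤ ~3) where scipy's `hyp1f1` is accurate, and the quadrature path is the
default everywhere.

## Two moment conventions

`raw_moment`, `central_moment` and `describe` accept `convention`:

- `"exact"` (default): quadrature in the parent scale; agrees with the
  tail-corrected series and with inverse-CDF Monte Carlo to sampling error.
- `"table"`: the moment series summed to exactly 2000 terms with no tail
  correction. This reproduces, cell for cell, the family's published
  descriptive reference table. The fixed truncation under-counts every raw
  moment by `≈ Σ_{k≥2000} w_k·2/(π(2k+1)) ≈ 0.0079` — nearly independent of
  the order and the shape. The deficit largely cancels in quartile-free
  location comparisons but is magnified in central and standardized
  measures when the true variance is small: at ζ = 0.03 the convention
  yields variance 0.0081 and skewness −9.51 where the exact values are
  ≈ 0.0010 and ≈ −0.76. The table convention is for reproducing the
  reference table; analyses should use the exact convention. (Quartiles are
  always computed from the exact quantile closed form; the two conventions
  agree there.)

## Inference

**Maximum likelihood.** The log-likelihood is smooth and empirically
unimodal in ζ (grid scans on both packaged datasets find a single sign
change of the derivative). Maximisation uses bounded L-BFGS-B with the
analytic score, multistarted from `{0.5, 1, 2}·ζ₀` where
`ζ₀ = √(mean(log²z)/2)` (the Rayleigh-backbone moment start), then polished
with bounded Brent to 1e−10. Standard errors are `1/√I` with `I` the
negative central-difference curvature (relative step 1e−5) of the
log-likelihood at the optimum, cross-checked against differencing the
analytic score.

**Maximum product of spacings.** The objective is the mean log CDF-spacing
over the n+1 gaps between consecutive order statistics (boundary gaps to 0
and 1 included; the spacings telescope to 1 by construction). Structurally
tied observations would zero a spacing; the standard remedy substitutes the
log-density at the tied point, with a loud warning. Spacings that merely
underflow during optimisation sweeps at extreme shapes are floored at
1e−300, which penalises without breaking the optimiser. The MPS "observed
information" is taken from the curvature of the *unnormalised* spacings sum
`(n+1)·ℓ_MPS`; this is the convention that matches the family's published
spacings standard errors, and it treats each spacing as one observation-unit
of information.

**Delta method.** Plug-in `R(z; ζ̂)` and `h(z; ζ̂)` get variances
`(∂g/∂ζ)²·Var(ζ̂)` with central-difference derivatives (relative step 1e−6).

**Bayesian.** Priors are Gamma(a₁, b₁) (moment-matched: `a₁ = m²/v`,
`b₁ = m/v`) or Jeffreys' scale prior `1/ζ` as the a₁ = b₁ = 0 limit. The
sampler is random-walk Metropolis–Hastings started at the frequentist
estimate with proposal SD equal to its standard error; non-positive
proposals are auto-rejected (the kernel is −∞ there) while still counting in
the acceptance denominator — a deliberate, simple implementation of the
positivity constraint that slightly perturbs detailed balance near 0 and is
irrelevant for posteriors bounded away from it. Acceptance rates outside
(0.05, 0.95) set a mixing warning. Two kernel details were genuinely open
and are settable: the prior exponent (`standard` uses the Gamma density's
`ζ^{a₁−1}`; a `printed` variant absorbs one power of ζ) and the spacings
basis, which uses the full product of spacings `exp((n+1)·ℓ_MPS)` — a
geometric-mean normalised product would down-weight the data by a factor of
n+1 and produces posterior spreads inconsistent with the family's published
summaries. HPD intervals follow the sorted-chain shortest-window rule
exactly (window size `⌊level·M⌋`; ties resolve to the smallest lower
endpoint for determinism); the implementation is tested against an
exhaustive window search.

## Goodness of fit

AIC/CAIC/BIC/HQIC use `−2ℓ + 2p`, `−2ℓ + 2pn/(n−p−1)`, `−2ℓ + p·log n` and
`−2ℓ + 2p·log log n`. EDF statistics are the plain Anderson–Darling A² and
Cramér–von Mises W² on the probability-integral transforms (the
small-sample-modified variants deliberately are not applied), and the
Kolmogorov–Smirnov statistic with its exact finite-n two-sided p-value —
appropriate at the packaged sample sizes (21 and 30).

## Monte Carlo harness

Each design cell (n, ζ, estimator) draws replicates by inverse transform,
fits, and summarises AE, RMSE, MRAB, and 90/95% interval length and
coverage for ζ, R(0.25) and h(0.25). Replicate streams are spawned from the
master seed via `SeedSequence`, so any cell is independently reproducible;
failed replicates are counted and excluded, never silently dropped. Default
working sizes are 200 replications with 2 500-iteration chains (500
burn-in) per Bayesian replicate — enough to resolve the qualitative
orderings (RMSE falling in n, informative HPD intervals shortest, coverage
near nominal) within binomial noise bands; the classical recipe's 1 000
replications and 12 000/2 000 chains are plain design fields. Informative
priors in simulations are elicited from the true shape with variance
0.25·ζ², a moderately informative choice (prior CV 0.5) that encodes "right
location, honest uncertainty" without dominating small samples.

## Numerical edges and degenerate inputs

- The density is 0/0 at `z → 1`; evaluation switches to the expansion
  `√2·ζ·(1 + u/4 + 7u²/96)` of `x/√(1 − e^{−u})` for `u < 1e−8` and attains
  the analytic limit `√2/(πζ)`.
- The CDF's central form `1 − (2/π)arcsin√(1 − e^{−u})` underflows in the
  lower tail; for `u > 36` the algebraically identical
  `(2/π)arcsin(e^{−u/2})` is used instead (and its complement for the
  survival function), keeping tail probabilities representable down to
  ~1e−300.
- Support boundaries are outside the domain; `allow_boundary=True` opts into
  the limiting values 0/1 explicitly. Boundary observations in data raise
  with the offending row reported, never silently clamp.
- MRL near `z → 1` and MIT near `z → 0` return their analytic limits (both
  0) once the conditioning probability falls below 1e−12 rather than
  dividing by underflow.
- The mode equation `(1 + x)(1 − e^{−x²/2ζ²}) = x²/(2ζ²)` (x = −log z)
  always has a root analytically, but for large ζ it sits at
  `x ≈ 2ζ²`, far outside representable z; the search brackets sign changes
  on a 512-point geometric grid in (1e−10, 1−1e−10) and reports a boundary
  supremum instead of inventing an interior root when none is bracketable.
- The order-statistic CDF uses the binomial-tail form; the alternating
  double sum is kept only as a tested equivalence because it cancels
  catastrophically for n ≳ 30.

## What the synthetic data does and does not show

The generator is the model's own inverse-CDF sampler, so simulation results
validate estimator behaviour *under the model*: consistency, interval
calibration, the relative efficiency of spacing- versus likelihood-based
estimation, and the stabilising effect of informative priors. They say
nothing about robustness to contamination, measurement rounding (the real
datasets are printed to 3 decimals), dependence, or model misspecification —
none of which the family's methodology addresses. Reproduction of the real
data analyses is exact because those datasets are packaged digit-for-digit.

## Known limitations

- The entropy series path degrades for very large ζ (unscaled `1F1`
  growth); the default quadrature path has no such restriction.
- The hazard-ratio diagnostic makes no monotonicity claim; across the
  scanned parameter range the ratio for ζ₁ < ζ₂ stays below 1, so no
  hazard-order reversal was observed despite the possibility being left
  open analytically.
- Single-chain MCMC diagnostics only (acceptance rate, split-half
  stationarity, batch-means MCSE); no multi-chain convergence machinery.
- Stress–strength reliability is a population quantity; estimating it from
  two samples is out of scope.
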