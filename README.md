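# uasrd

Statistical toolkit for the **Unit Arcsine–Rayleigh distribution (UASRD)** — a
one-parameter family on the open unit interval for modelling proportions and
bounded reliability data (normalised strengths, rates, computing-time
fractions).

If `X` follows the Arcsine–Rayleigh lifetime law with shape `ζ > 0`, then
`Z = exp(−X)` follows the UASRD, with

```
F(z; ζ) = 1 − (2/π) · arcsin√(1 − e^{−log²z / (2ζ²)}),      0 < z < 1,
f(z; ζ) = −log z · e^{−log²z/(4ζ²)} / (π ζ² z √(1 − e^{−log²z/(2ζ²)})),
Q(q; ζ) = exp(−ζ √(−2 log sin²(πq/2))).
```

A single shape parameter buys a lot of flexibility: the density ranges from a
sharp spike near 1 (small ζ) to a heavily right-skewed spike near 0 (large ζ),
and the hazard can be increasing, bathtub- or U-shaped.

The package covers:

- **Distribution theory** — CDF/PDF/quantile/survival/hazard, inverse-CDF
  sampling, interior-mode search, raw/central/incomplete moments, MGF/CF/CGF
  truncations, mean residual life and mean inactivity time, order statistics,
  likelihood- and hazard-ratio diagnostics, stress–strength reliability
  P(Z₁ > Z₂), and six entropy measures (Shannon, Rényi, Arimoto, Tsallis,
  Havrda–Charvát, Mathai–Haubold). Every closed-form series has an
  independent quadrature path and the two are cross-validated in the tests.
- **Classical inference** — maximum likelihood and maximum product of
  spacings, observed-information standard errors, Wald intervals, and
  delta-method intervals for the plug-in reliability and hazard.
- **Bayesian inference** — Gamma/Jeffreys priors, random-walk
  Metropolis–Hastings on the likelihood or spacings basis, squared-error-loss
  estimates and shortest-window HPD credible intervals.
- **Goodness of fit** — AIC/CAIC/BIC/HQIC, Anderson–Darling, Cramér–von
  Mises, and the exact finite-sample Kolmogorov–Smirnov test.
- **A Monte Carlo harness** comparing six estimator flavours (ML, MPS, and
  Bayesian variants under informative/non-informative priors) by bias, RMSE,
  interval length and coverage over (n, ζ) grids.

## Worked example

Two classical datasets ship with the package: 30 polyester-fiber tensile
strengths and 21 normalised P3-algorithm computing times.

```python
from uasrd import fit_ml, fit_mps, delta_method_estimates, load_builtin, fit_report

data = load_builtin("tensile-strength").values
ml = fit_ml(data)
der = delta_method_estimates(ml, 0.25)
print(f"ML   zeta = {ml.estimate:.4f}  SE = {ml.std_error:.4f}")
print(f"MPS  zeta = {fit_mps(data).estimate:.4f}")
print(f"R(0.25) = {der.reliability_result.estimate:.4f} (SE {der.reliability_result.std_error:.4f})")
print(f"h(0.25) = {der.hazard_result.estimate:.4f} (SE {der.hazard_result.std_error:.4f})")
rep = fit_report(data)
print(f"-2l = {rep.minus_2_loglik:.4f}  AIC = {rep.aic:.4f}  K-S = {rep.ks_stat:.4f} (p = {rep.ks_pvalue:.4f})")
```

prints

```
ML   zeta = 1.0179  SE = 0.1206
MPS  zeta = 1.0709
R(0.25) = 0.5670 (SE 0.0566)
h(0.25) = 2.4308 (SE 0.1085)
-2l = -7.7408  AIC = -5.7408  K-S = 0.0680 (p = 0.9974)
```

The fitted shape 1.02 says the fibers' strength fractions are nearly
"standard" UASRD; the survival estimate means ~57% of fibers withstand a
quarter of the nominal maximum stress, and the large K-S p-value (0.997)
indicates an excellent fit.

The same is available from the shell:

```bash
uasrd fit --data builtin:tensile-strength --method ml --z 0.25
uasrd gof --data builtin:p3-times
uasrd bayes --data builtin:tensile-strength --prior gamma --iters 12000 --burnin 2000 --seed 1
uasrd describe --zetas 0.5,0.95,2.0
uasrd simulate --config design.yaml --out grid.csv
```

## A note on moment conventions

Descriptive moments admit two evaluation conventions. The default,
`convention="exact"`, evaluates moments by adaptive quadrature (cross-checked
against the tail-corrected series and against inverse-CDF Monte Carlo).
`convention="table"` reproduces the family's published descriptive reference
table, which was generated from the moment series truncated at a fixed 2000
terms; because the series tail decays only like k^(−3/2), that truncation
carries a small systematic deficit in every raw moment (about 0.008) that is
magnified in standardized shape measures at small ζ. Use `"table"` to
reproduce the reference table, `"exact"` for analysis. `docs/methods.md` has
the full story.

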