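"""Goodness of fit and model selection for a fitted UASRD.

Information criteria use the standard definitions (the ones that reproduce
the family's published comparison tables):

    AIC  = -2l + 2p              CAIC = -2l + 2pn/(n - p - 1)
    BIC  = -2l + p log n         HQIC = -2l + 2p log(log n)

Empirical-distribution statistics are the plain (unmodified) Anderson-Darling
A^2 and Cramer-von Mises W^2 on the PIT values u_(i) = F(z_(i); zhat), plus
the Kolmogorov-Smirnov statistic with its exact finite-sample two-sided
p-value.  The small-sample-modified A*/W* variants do not match the published
tables and are deliberately not used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classical import fit_ml, log_likelihood
from .distribution import UnitSample, cdf

__all__ = ["FitReport", "information_criteria", "edf_statistics", "fit_report"]


@dataclass(frozen=True)
class FitReport:
    minus_2_loglik: float
    aic: float
    caic: float
    bic: float
    hqic: float
    ad_stat: float
    cvm_stat: float
    ks_stat: float
    ks_pvalue: float
    n: int
    p: int
    zeta_hat: float


def information_criteria(minus_2_loglik: float, n: int, p: int) -> dict:
    """AIC / CAIC / BIC / HQIC from -2 log-likelihood, n and parameter count."""
    if n <= p + 1:
        raise ValueError(f"CAIC undefined: need n > p + 1, got n={n}, p={p}")
    return dict(
        aic=minus_2_loglik + 2.0 * p,
        caic=minus_2_loglik + 2.0 * p * n / (n - p - 1.0),
        bic=minus_2_loglik + p * math.log(n),
        hqic=minus_2_loglik + 2.0 * p * math.log(math.log(n)),
    )


def edf_statistics(sample, zeta_hat: float) -> tuple[float, float, float, float]:
    """(A^2, W^2, KS, KS p-value) of the fitted CDF against the sample EDF."""
    s = sample if isinstance(sample, UnitSample) else UnitSample(sample)
    u = np.sort(cdf(s.sorted(), zeta_hat))
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn("PIT values at 0/1 clamped to [1e-15, 1-1e-15]", RuntimeWarning, stacklevel=2)
        u = np.clip(u, 1e-15, 1.0 - 1e-15)
    n = s.n
    i = np.arange(1, n + 1)
    a2 = -n - float(np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))
    w2 = float(np.sum((u - (2 * i - 1) / (2.0 * n)) ** 2)) + 1.0 / (12.0 * n)
    ks = stats.kstest(s.values, lambda x: cdf(x, zeta_hat), method="exact")
    return a2, w2, float(ks.statistic), float(ks.pvalue)


def fit_report(sample, zeta_hat: float | None = None, p: int = 1) -> FitReport:
    """Fit (if needed) and assemble the full goodness-of-fit report."""
    s = sample if isinstance(sample, UnitSample) else UnitSample(sample)
    if zeta_hat is None:
        zeta_hat = fit_ml(s).estimate
    m2l = -2.0 * log_likelihood(s, zeta_hat)
    crit = information_criteria(m2l, s.n, p)
    a2, w2, ks, ksp = edf_statistics(s, zeta_hat)
    return FitReport(
        minus_2_loglik=m2l, ad_stat=a2, cvm_stat=w2, ks_stat=ks, ks_pvalue=ksp,
        n=s.n, p=p, zeta_hat=zeta_hat, **crit,
    )
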