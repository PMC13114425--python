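"""Shared numerics for the infinite binomial series behind the UASRD closed forms.

Almost every closed-form quantity of the family (moments, incomplete moments,
mean residual life, entropies, stress-strength reliability) is an infinite
series over the central-binomial weight

    w_k = C(2k, k) / 4^k = Gamma(k + 1/2) / (sqrt(pi) * Gamma(k + 1)),

arising from the expansion (1 - w)^(-1/2) = sum_k w_k w^k.  The terms decay
only like k^(-3/2) (sometimes with a log factor), so naive truncation loses
the fourth decimal even after 10^5 terms.  The engine here sums an exact
vectorised block and closes the tail by an Euler-Maclaurin correction,

    sum_{k>=K} g(k) ~ int_K^inf g + g(K)/2 - g'(K)/12,

which requires the term function to be evaluable at real (non-integer) k;
every internal series satisfies this through log-gamma forms.  Quadrature of
the defining integrals is the independent oracle for each series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import integrate, special

__all__ = [
    "SeriesControl",
    "SeriesResult",
    "SeriesError",
    "central_binomial_weight",
    "sum_series",
    "sum_binomial_series",
    "quadrature_oracle",
]


class SeriesError(RuntimeError):
    """Raised when a series term is non-finite or a quadrature fails."""


@dataclass(frozen=True)
class SeriesControl:
    """Truncation and tolerance policy.

    rel_tol / abs_tol bound the accepted tail estimate relative to the partial
    sum; k_max caps direct summation; acceleration enables the Euler-Maclaurin
    tail closure for algebraically decaying terms.
    """

    rel_tol: float = 1e-10
    abs_tol: float = 1e-14
    k_max: int = 200_000
    acceleration: bool = True
    block: int = 4096

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


@dataclass(frozen=True)
class SeriesResult:
    value: float
    terms_used: int
    converged: bool
    tail_estimate: float

    def require(self) -> float:
        if not self.converged:
            raise SeriesError(
                f"series did not converge after {self.terms_used} terms "
                f"(tail estimate {self.tail_estimate:.3e})"
            )
        return self.value


def central_binomial_weight(k) -> np.ndarray | float:
    """C(2k, k) / 4^k, in log space; valid for real k >= 0 via Gamma.

    Decays like 1/sqrt(pi*k); equals 1 at k = 0 and 1/2 at k = 1.
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("index k must be >= 0")
    out = np.exp(special.gammaln(k_arr + 0.5) - special.gammaln(k_arr + 1.0)) / math.sqrt(math.pi)
    return out if out.ndim else float(out)


def _euler_maclaurin_tail(term: Callable[[np.ndarray], np.ndarray], K: int) -> tuple[float, float]:
    """Tail sum_{k>=K} term(k) via Euler-Maclaurin; returns (tail, error_estimate).

    The integral over (K, inf) is mapped to (0, 1] by k = K/u^2, which turns an
    algebraic k^(-p) tail (p > 1) into a bounded smooth integrand.
    """

    def g(u: float) -> float:
        kk = K / (u * u)
        val = float(np.asarray(term(np.array([kk])))[0]) * 2.0 * K / u**3
        return val if math.isfinite(val) else 0.0

    import warnings as _warnings

    with _warnings.catch_warnings():
        # the substituted integrand is noisy at extreme k; accuracy is
        # verified against quadrature oracles, not quad's own estimate
        _warnings.simplefilter("ignore", integrate.IntegrationWarning)
        tail_int, int_err = integrate.quad(g, 0.0, 1.0, epsabs=1e-13, epsrel=1e-12, limit=400)
    if not math.isfinite(tail_int):
        raise SeriesError(f"tail integral diverged at K={K}")
    h = max(1e-3, 1e-6 * K)
    tK = float(np.asarray(term(np.array([float(K)])))[0])
    tm, tp = (float(np.asarray(term(np.array([K + s * h])))[0]) for s in (-1.0, 1.0))
    d1 = (tp - tm) / (2.0 * h)
    # magnitude of the next Euler-Maclaurin term bounds the correction error
    d3 = abs(tp - 2.0 * tK + tm) / h**2 / max(K, 1)
    tail = tail_int + tK / 2.0 - d1 / 12.0
    return tail, abs(d3) / 720.0 + int_err


def sum_series(term: Callable[[np.ndarray], np.ndarray], control: Optional[SeriesControl] = None) -> SeriesResult:
    """Sum sum_{k=0}^inf term(k) for terms that eventually decay in magnitude.

    Terms are evaluated in vectorised blocks.  Convergence is declared when
    the last few terms and a tail bound both fall below tolerance; otherwise,
    when acceleration is enabled and the empirical decay exponent exceeds 1,
    the remaining tail is closed by Euler-Maclaurin.  Diverging or non-finite
    terms are flagged (non-finite ones with the offending index).
    """
    control = control or SeriesControl()
    total = 0.0
    k0 = 0
    last_block: Optional[np.ndarray] = None
    while k0 < control.k_max:
        k1 = min(k0 + control.block, control.k_max)
        k = np.arange(k0, k1, dtype=float)
        t = np.asarray(term(k), dtype=float)
        if not np.all(np.isfinite(t)):
            bad = int(k[np.argwhere(~np.isfinite(t)).ravel()[0]])
            raise SeriesError(f"series term is non-finite at k={bad}")
        total += float(t.sum())
        last_block = t
        k0 = k1
        tol = max(control.abs_tol, control.rel_tol * abs(total))
        tail_mag = np.max(np.abs(t[-3:]))
        if tail_mag == 0.0:
            return SeriesResult(total, k0, True, 0.0)
        # geometric decay: bound the tail by a geometric sum
        if t.size >= 8:
            num, den = np.abs(t[-1]), np.abs(t[-4])
            rho = (num / den) ** (1.0 / 3.0) if den > 0 else 0.0
            if rho < 0.9:
                tail_bound = abs(t[-1]) * rho / (1.0 - rho)
                if abs(t[-1]) < tol and tail_bound < tol:
                    return SeriesResult(total, k0, True, tail_bound)
    assert last_block is not None
    # algebraic regime: estimate the decay exponent from the last block
    ia, ib = last_block.size // 2, last_block.size - 1
    ta, tb = abs(last_block[ia]), abs(last_block[ib])
    ka, kb = k0 - last_block.size + ia, k0 - 1
    if ta == 0 or tb == 0 or tb >= ta:
        return SeriesResult(total, k0, False, math.inf)
    p_hat = math.log(ta / tb) / math.log(kb / ka)
    if p_hat <= 1.02:
        # (sub)harmonic decay: the series diverges or is out of reach
        return SeriesResult(total, k0, False, math.inf)
    if not control.acceleration:
        tail_guess = tb * kb / (p_hat - 1.0)
        tol = max(control.abs_tol, control.rel_tol * abs(total))
        return SeriesResult(total, k0, tail_guess < tol, tail_guess)
    try:
        tail, err = _euler_maclaurin_tail(term, k0)
    except (FloatingPointError, integrate.IntegrationWarning, ValueError) as exc:  # pragma: no cover
        raise SeriesError(f"tail closure failed at K={k0}: {exc}") from exc
    return SeriesResult(total + tail, k0, True, err)


def sum_binomial_series(term: Callable[[np.ndarray], np.ndarray], control: Optional[SeriesControl] = None) -> SeriesResult:
    """Sum sum_k C(2k,k)/4^k * term(k) (the family's canonical series form)."""
    return sum_series(lambda k: central_binomial_weight(k) * np.asarray(term(k), dtype=float), control)


def quadrature_oracle(
    integrand: Callable[[float], float],
    domain: str = "unit",
    tol: float = 1e-10,
    points=None,
) -> float:
    """Adaptive quadrature with an error guarantee; the ground truth for series.

    domain 'unit' integrates over (0, 1); 'positive' over (0, inf).  Raises
    SeriesError when the estimated absolute error exceeds ``tol`` scaled by
    the result magnitude.
    """
    if domain == "unit":
        a, b = 0.0, 1.0
    elif domain == "positive":
        a, b = 0.0, np.inf
    else:
        raise ValueError(f"unknown domain tag {domain!r}")
    if not np.isfinite(b):
        points = None  # scipy.quad rejects break points on infinite ranges
    val, err = integrate.quad(integrand, a, b, epsabs=1e-12, epsrel=1e-12, limit=500, points=points)
    if err > tol * max(1.0, abs(val)):
        raise SeriesError(f"quadrature error estimate {err:.3e} exceeds tolerance {tol:.1e}")
    return val
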