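"""Core distributional functions of the Unit Arcsine-Rayleigh distribution.

The Unit Arcsine-Rayleigh distribution (UASRD) is the law of ``Z = exp(-X)``
where ``X`` follows the Arcsine-Rayleigh lifetime distribution with shape
``zeta > 0``.  Its support is the open unit interval, which makes it a
candidate model for proportions, normalised strengths and other bounded
reliability data.  All closed forms used here:

    F(z; zeta) = 1 - (2/pi) * arcsin( sqrt(1 - exp(-log(z)^2 / (2 zeta^2))) )
    f(z; zeta) = -log(z) * exp(-log(z)^2 / (4 zeta^2))
                 / ( pi zeta^2 z sqrt(1 - exp(-log(z)^2 / (2 zeta^2))) )
    Q(q; zeta) = exp( -zeta * sqrt(-2 * log(sin^2(pi q / 2))) )

The density is a 0/0 form at the upper support limit with finite limit
``sqrt(2) / (pi * zeta)``; evaluation switches to a series expansion there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

__all__ = [
    "UnitSample",
    "ModeResult",
    "validate_shape",
    "cdf",
    "pdf",
    "logpdf",
    "reliability",
    "hazard",
    "quantile",
    "sample",
    "mode",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]

# interior band used when allow_boundary evaluation is requested
_BOUNDARY_EPS = 1e-300


def validate_shape(zeta: float) -> float:
    """Validate the shape parameter: a finite positive real."""
    zeta = float(zeta)
    if not math.isfinite(zeta) or zeta <= 0.0:
        raise ValueError(f"shape parameter zeta must be finite and > 0, got {zeta!r}")
    return zeta


def _validate_unit(z: ArrayLike, allow_boundary: bool = False, name: str = "z") -> np.ndarray:
    z = np.asarray(z, dtype=float)
    lo, hi = (0.0, 1.0)
    if allow_boundary:
        bad = (z < lo) | (z > hi) | ~np.isfinite(z)
    else:
        bad = (z <= lo) | (z >= hi) | ~np.isfinite(z)
    if np.any(bad):
        idx = np.argwhere(np.atleast_1d(bad)).ravel()
        raise ValueError(
            f"{name} must lie strictly inside (0, 1); "
            f"offending positions {idx[:5].tolist()} with values "
            f"{np.atleast_1d(z)[idx[:5]].tolist()}"
        )
    return z


@dataclass(frozen=True)
class UnitSample:
    """An i.i.d. sample of observations strictly inside (0, 1).

    Validation reports the position of every out-of-range value.  The sorted
    view is computed once and cached; estimation code never assumes the input
    arrives ordered.
    """

    values: np.ndarray

    def __init__(self, values: ArrayLike):
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("a UnitSample needs at least one observation")
        bad = ~((arr > 0.0) & (arr < 1.0) & np.isfinite(arr))
        if np.any(bad):
            rows = np.argwhere(bad).ravel()
            raise ValueError(
                "observations must lie strictly inside (0, 1); offending "
                f"positions {rows[:10].tolist()} with values {arr[rows[:10]].tolist()}"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def sorted(self) -> np.ndarray:
        """Deterministic ordered view z_(1) <= ... <= z_(n)."""
        return np.sort(self.values, kind="stable")

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


def cdf(z: ArrayLike, zeta: float, allow_boundary: bool = False) -> Union[float, np.ndarray]:
    """Distribution function F(z; zeta) on (0, 1).

    With ``allow_boundary`` the limits F(0)=0 and F(1)=1 are returned for
    boundary arguments instead of raising; silent boundary evaluation is
    deliberately not offered because boundary data usually signal an input
    error.
    """
    zeta = validate_shape(zeta)
    z = _validate_unit(z, allow_boundary=allow_boundary)
    zin = np.clip(z, _BOUNDARY_EPS, 1.0 - 1e-17) if allow_boundary else z
    L = np.log(zin)
    u = L * L / (2.0 * zeta * zeta)
    # central form is accurate near the upper support limit; the equivalent
    # arcsin(e^{-u/2}) form keeps the lower tail from underflowing to 0
    out = np.where(
        u > 36.0,
        (2.0 / np.pi) * np.arcsin(np.exp(-u / 2.0)),
        1.0 - (2.0 / np.pi) * np.arcsin(np.sqrt(-np.expm1(-np.minimum(u, 36.0)))),
    )
    if allow_boundary:
        out = np.where(z == 0.0, 0.0, np.where(z == 1.0, 1.0, out))
    return out if out.ndim else float(out)


def reliability(z: ArrayLike, zeta: float, allow_boundary: bool = False) -> Union[float, np.ndarray]:
    """Survival function R(z; zeta) = 1 - F(z; zeta), computed from the same
    arcsine expression so that ``reliability + cdf == 1`` holds exactly."""
    zeta = validate_shape(zeta)
    z = _validate_unit(z, allow_boundary=allow_boundary)
    zin = np.clip(z, _BOUNDARY_EPS, 1.0 - 1e-17) if allow_boundary else z
    L = np.log(zin)
    u = L * L / (2.0 * zeta * zeta)
    out = np.where(
        u > 36.0,
        1.0 - (2.0 / np.pi) * np.arcsin(np.exp(-u / 2.0)),
        (2.0 / np.pi) * np.arcsin(np.sqrt(-np.expm1(-np.minimum(u, 36.0)))),
    )
    if allow_boundary:
        out = np.where(z == 0.0, 1.0, np.where(z == 1.0, 0.0, out))
    return out if out.ndim else float(out)


def _stable_ratio(x: np.ndarray, zeta: float) -> np.ndarray:
    """x / sqrt(1 - exp(-x^2/(2 zeta^2))) evaluated stably for small x.

    For u = x^2/(2 zeta^2) below 1e-8 the direct ratio is 0/0-prone; the
    expansion sqrt(2)*zeta*(1 + u/4 + 7u^2/96) carries the limit.
    """
    u = x * x / (2.0 * zeta * zeta)
    small = u < 1e-8
    denom = np.sqrt(-np.expm1(-np.where(small, 1.0, u)))
    direct = np.where(small, 0.0, x) / denom
    series = math.sqrt(2.0) * zeta * (1.0 + u / 4.0 + 7.0 * u * u / 96.0)
    return np.where(small, series, direct)


def pdf(z: ArrayLike, zeta: float) -> Union[float, np.ndarray]:
    """Density f(z; zeta); finite at the upper limit with f -> sqrt(2)/(pi*zeta)."""
    zeta = validate_shape(zeta)
    z = _validate_unit(z)
    x = -np.log(z)
    ratio = _stable_ratio(x, zeta)
    out = ratio * np.exp(-x * x / (4.0 * zeta * zeta)) / (np.pi * zeta * zeta * z)
    return out if out.ndim else float(out)


def logpdf(z: ArrayLike, zeta: float) -> Union[float, np.ndarray]:
    """Log-density; the per-observation term of the log-likelihood."""
    zeta = validate_shape(zeta)
    z = _validate_unit(z)
    x = -np.log(z)
    out = (
        np.log(_stable_ratio(x, zeta))
        + x
        - x * x / (4.0 * zeta * zeta)
        - math.log(math.pi)
        - 2.0 * math.log(zeta)
    )
    return out if out.ndim else float(out)


def hazard(z: ArrayLike, zeta: float) -> Union[float, np.ndarray]:
    """Hazard rate h = f / R; diverges as z -> 1 (R -> 0 with f finite)."""
    return pdf(z, zeta) / reliability(z, zeta)


def quantile(q: ArrayLike, zeta: float) -> Union[float, np.ndarray]:
    """Quantile function Q(q; zeta) = exp(-zeta * sqrt(-2 log sin^2(pi q / 2)))."""
    zeta = validate_shape(zeta)
    q = _validate_unit(q, name="q")
    # -2*log(sin^2) = -4*log(sin); the log form avoids squaring a subnormal
    t = -4.0 * np.log(np.sin(np.pi * q / 2.0))
    out = np.exp(-zeta * np.sqrt(t))
    return out if out.ndim else float(out)


def sample(n: int, zeta: float, seed: Optional[Union[int, np.random.Generator]] = None) -> np.ndarray:
    """Draw ``n`` variates by inverse-transform sampling.

    ``seed`` may be an integer (deterministic stream) or a Generator to share
    a stream across calls.  No rejection steps are involved, so the draw
    count equals the uniform consumption exactly.
    """
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    zeta = validate_shape(zeta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(int(n))
    # a uniform draw of exactly 0.0 would map outside the open support
    u = np.clip(u, np.finfo(float).tiny, None)
    return quantile(u, zeta)


@dataclass(frozen=True)
class ModeResult:
    """Outcome of the interior-mode search.

    ``interior`` is True when a stationary point of the density was bracketed
    inside the search window and verified as a local maximum; then ``z`` holds
    it.  Otherwise ``z`` is nan and ``boundary`` names the side of the support
    ('lower' or 'upper') where the density supremum sits within the window.
    """

    z: float
    interior: bool
    boundary: Optional[str] = field(default=None)


def _mode_equation(x: np.ndarray, zeta: float) -> np.ndarray:
    """Stationarity condition of the log-density in x = -log(z):
    (1 + x) * (1 - exp(-x^2/(2 zeta^2))) - x^2/(2 zeta^2) = 0."""
    u = x * x / (2.0 * zeta * zeta)
    return (1.0 + x) * (-np.expm1(-u)) - u


def mode(zeta: float, z_lo: float = 1e-10, z_hi: float = 1.0 - 1e-10, grid: int = 512) -> ModeResult:
    """Locate the density mode by bracketing the stationarity equation.

    The equation is scanned on a geometric grid of ``grid`` points in
    ``(z_lo, z_hi)``; a sign change is refined by Brent's method to ~1e-14.
    For large zeta the stationary point satisfies x* ~ 2*zeta^2 and may fall
    outside any representable z; the result then reports the boundary where
    the density supremum lies instead of returning a spurious root.
    """
    zeta = validate_shape(zeta)
    # geometric in x = -log z covers many decades of z near 0
    x_lo = -math.log(z_hi)
    x_hi = -math.log(z_lo)
    xs = np.geomspace(x_lo, x_hi, grid)
    g = _mode_equation(xs, zeta)
    sign_change = np.nonzero(np.diff(np.sign(g)) != 0)[0]
    if sign_change.size == 0:
        # g > 0: density increasing in x, i.e. rising toward z -> 0
        side = "lower" if np.all(g > 0) else "upper"
        return ModeResult(z=math.nan, interior=False, boundary=side)
    i = int(sign_change[0])
    x_star = optimize.brentq(_mode_equation, xs[i], xs[i + 1], args=(zeta,), xtol=1e-14, rtol=1e-14)
    z_star = math.exp(-x_star)
    eps = max(1e-9, 1e-6 * min(z_star, 1.0 - z_star))
    f0 = pdf(z_star, zeta)
    if f0 < pdf(max(z_star - eps, z_lo), zeta) or f0 < pdf(min(z_star + eps, z_hi), zeta):
        # stationary but not a maximum (cannot occur for this family; guard anyway)
        side = "lower" if pdf(np.exp(-x_hi), zeta) > pdf(np.exp(-x_lo), zeta) else "upper"
        return ModeResult(z=math.nan, interior=False, boundary=side)
    return ModeResult(z=z_star, interior=True)
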